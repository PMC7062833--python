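"""Microbiome diversity and family-abundance trajectory analysis.

Summary-measures approach to longitudinal stool data: each subject's
series (inverse Simpson diversity, or one family's relative abundance)
is reduced to a Theil–Sen slope, slopes are summarised per clinical
group by a weighted median (weights = number of contributing samples),
and groups are contrasted with a weighted Mann–Whitney permutation test.

Diversity is computed from all taxa regardless of abundance; the >1%
mean-abundance filter applies only to which families are described, and
never-colonised status means no sample of a subject exceeded 1% relative
abundance for that family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import weighted_median, weighted_midranks
from .io import TaxaTable

__all__ = [
    "SubjectSlope",
    "inverse_simpson",
    "diversity_series",
    "family_inclusion_filter",
    "colonisation_status",
    "theil_sen_slope",
    "subject_slopes",
    "group_slope_summary",
    "weighted_mann_whitney",
]


@dataclass(frozen=True)
class SubjectSlope:
    subject_id: str
    quantity: str  # "diversity" or "family:<name>"
    slope_per_week: float
    n_points: int


def inverse_simpson(abundances) -> float:
    """D = 1 / sum(p_i^2) for a relative-abundance vector.

    Equals 1 when a single taxon has all mass and S (the taxon count)
    at the uniform composition.
    """
    p = np.asarray(abundances, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = p / total
    return float(1.0 / np.sum(p**2))


def diversity_series(taxa: TaxaTable) -> pd.DataFrame:
    """Per-sample inverse Simpson diversity as a tidy frame."""
    d = [inverse_simpson(row) for row in taxa.data.to_numpy()]
    out = taxa.data.index.to_frame(index=False)
    out["inverse_simpson"] = d
    return out


def family_inclusion_filter(taxa: TaxaTable, threshold: float = 0.01) -> list[str]:
    """Families with mean relative abundance over all samples > threshold."""
    means = taxa.data.mean(axis=0)
    return [f for f in taxa.families if means[f] > threshold]


def colonisation_status(abundance_series, threshold: float = 0.01) -> bool:
    """True iff any sample exceeds the threshold (strict >)."""
    vals = np.asarray(abundance_series, dtype=float)
    if vals.size == 0:
        raise ValueError("empty abundance series")
    return bool(np.max(vals) > threshold)


def theil_sen_slope(ages_days, values) -> float:
    """Median of all pairwise slopes, converted to per-week units.

    Robust nonparametric regression coefficient: for every pair of
    time points, (y_j - y_i) / (t_j - t_i); the slope is the median of
    those, times 7.  Pairs at identical ages are skipped.
    """
    t = np.asarray(ages_days, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("need >=2 (age, value) points")
    dt = t[:, None] - t[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(len(t), k=1)
    dt, dy = dt[iu], dy[iu]
    informative = dt != 0
    if not informative.any():
        raise ValueError("all ages identical")
    slopes = dy[informative] / dt[informative]
    return float(np.median(slopes)) * 7.0


def subject_slopes(
    series: pd.DataFrame,
    value_col: str,
    quantity: str,
    min_points: int = 2,
) -> list[SubjectSlope]:
    """Per-subject Theil–Sen slopes of a tidy (subject, age, value) frame."""
    out = []
    for sid, grp in series.groupby("subject_id", sort=True):
        ages = grp["postnatal_age_days"].to_numpy(dtype=float)
        vals = grp[value_col].to_numpy(dtype=float)
        if len(ages) < min_points or np.all(ages == ages[0]):
            continue
        out.append(
            SubjectSlope(
                subject_id=str(sid),
                quantity=quantity,
                slope_per_week=theil_sen_slope(ages, vals),
                n_points=len(ages),
            )
        )
    return out


def group_slope_summary(slopes: list[SubjectSlope]) -> float:
    """Weighted median of per-subject slopes, weights = sample counts."""
    if not slopes:
        raise ValueError("no subject slopes to summarise")
    return weighted_median(
        [s.slope_per_week for s in slopes], [s.n_points for s in slopes]
    )


def weighted_mann_whitney(
    slopes_a,
    weights_a,
    slopes_b,
    weights_b,
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided weighted Mann–Whitney permutation p-value.

    Weights act as replicate multiplicities: pooled observations get
    weighted mid-ranks, the statistic is the weighted rank sum of group
    A, and the null distribution comes from randomly relabelling which
    (value, weight) units belong to group A.  The pooled rank vector is
    label-invariant, so each permutation only re-selects indices.
    p = (#{|T_perm - mean| >= |T_obs - mean|} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    wa = np.asarray(weights_a, dtype=float)
    wb = np.asarray(weights_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(wa <= 0) or np.any(wb <= 0):
        raise ValueError("weights must be positive")
    values = np.concatenate([a, b])
    weights = np.concatenate([wa, wb])
    ranks = weighted_midranks(values, weights)
    contrib = weights * ranks
    n_a, n_tot = len(a), len(values)
    t_obs = float(contrib[:n_a].sum())

    rng = np.random.default_rng(seed)
    # each row of `picks`: indices assigned to group A in one relabelling
    stats_null = np.empty(n_perm)
    chunk = 20_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n_tot)), axis=1)[:, :n_a]
        stats_null[done : done + m] = contrib[order].sum(axis=1)
        done += m
    # exact null mean of the statistic: a uniform size-n_a subset of the
    # contributions (an empirical estimate would wobble around lattice
    # points of the discrete statistic and bias the two-sided count)
    centre = n_a * contrib.mean()
    extreme = np.abs(stats_null - centre) >= abs(t_obs - centre) - 1e-12
    return float((extreme.sum() + 1) / (n_perm + 1))
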