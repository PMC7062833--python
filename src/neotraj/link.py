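"""Intra-individual immune–microbiome correlation with a consistency criterion.

Blood and stool sampling schedules differ, so series are matched by
binning postnatal age into 5-day windows (half-open [5k, 5k+5), anchored
at day 0) and averaging multiple samples within a subject-bin.  For each
(immune parameter, bacterial family) pair, Spearman correlation is
computed within each subject alone; the pair is flagged only when every
included subject yields p < 0.2.  Under independent per-subject nulls
the probability that all k subjects pass is 0.2^k — the aggregate
significance threshold of the procedure (0.008 at k = 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import spearman_rho_p

logger = logging.getLogger(__name__)

__all__ = [
    "ConsistencyResult",
    "bin_align",
    "intra_individual_correlation",
    "consistency_criterion",
    "aggregate_threshold",
    "run_link_stage",
]

BIN_WIDTH_DAYS = 5.0
PER_SUBJECT_ALPHA = 0.2
MIN_BINS = 4


@dataclass
class ConsistencyResult:
    immune_parameter: str
    taxa_family: str
    per_subject: list[tuple[str, float, float, int]]  # (subject, rho, p, n_bins)
    mean_rho: float
    significant: bool
    aggregate_alpha: float
    n_subjects: int = field(init=False)

    def __post_init__(self):
        self.n_subjects = len(self.per_subject)


def bin_align(
    immune_samples: pd.DataFrame,
    taxa_samples: pd.DataFrame,
    immune_col: str,
    taxa_col: str,
    bin_width_days: float = BIN_WIDTH_DAYS,
) -> pd.DataFrame:
    """Match blood and stool series through time bins.

    Inputs are tidy frames with columns (subject_id, postnatal_age_days,
    <value>).  bin_index = floor(age / width); a row is emitted only when
    a subject-bin holds both an immune and a taxa value, each averaged
    within the bin.  Idempotent: re-binning the output changes nothing,
    because binned rows sit at bin-representative ages.
    """
    def _binned(df: pd.DataFrame, col: str) -> pd.DataFrame:
        d = df[["subject_id", "postnatal_age_days", col]].dropna()
        d = d.assign(
            bin_index=np.floor(
                d["postnatal_age_days"].to_numpy(dtype=float) / bin_width_days
            ).astype(int)
        )
        return d.groupby(["subject_id", "bin_index"], as_index=False)[col].mean()

    left = _binned(immune_samples, immune_col).rename(columns={immune_col: "immune_value"})
    right = _binned(taxa_samples, taxa_col).rename(columns={taxa_col: "taxa_value"})
    merged = left.merge(right, on=["subject_id", "bin_index"], how="inner")
    n_lost = left["subject_id"].nunique() - merged["subject_id"].nunique()
    if n_lost > 0:
        logger.info("%d subject(s) had no matched bins", n_lost)
    return merged.sort_values(["subject_id", "bin_index"]).reset_index(drop=True)


def intra_individual_correlation(
    binned_pairs: pd.DataFrame, min_bins: int = MIN_BINS
) -> list[tuple[str, float, float, int]]:
    """Per-subject Spearman (rho, p) on that subject's binned pairs alone.

    Subjects with fewer than ``min_bins`` matched bins, or a constant
    series, are excluded (exact Spearman p is undefined below 4
    informative points).
    """
    out = []
    for sid, grp in binned_pairs.groupby("subject_id", sort=True):
        if len(grp) < min_bins:
            continue
        rho, p = spearman_rho_p(
            grp["immune_value"].to_numpy(), grp["taxa_value"].to_numpy()
        )
        if not np.isfinite(rho):
            logger.info("subject %s excluded: constant series within subject", sid)
            continue
        out.append((str(sid), rho, p, len(grp)))
    return out


def aggregate_threshold(per_subject_alpha: float, k_subjects: int) -> float:
    """alpha^k: chance that k independent null subjects all pass alpha.

    The family-wise significance level implied by requiring p < alpha in
    every one of k subjects (1.0 for k = 0 — the empty conjunction).
    """
    if not 0.0 < per_subject_alpha < 1.0:
        raise ValueError("per_subject_alpha must be in (0, 1)")
    if k_subjects < 0:
        raise ValueError("k_subjects must be non-negative")
    return per_subject_alpha**k_subjects


def consistency_criterion(
    per_subject_results: list[tuple[str, float, float, int]],
    per_subject_alpha: float = PER_SUBJECT_ALPHA,
    immune_parameter: str = "",
    taxa_family: str = "",
) -> ConsistencyResult:
    """Flag a pair significant iff every included subject has p < alpha.

    mean_rho is the unweighted mean of per-subject correlation
    coefficients; aggregate_alpha reports the implied family-wise level
    alpha^k for the included subject count.
    """
    if not per_subject_results:
        raise ValueError("no included subjects")
    ps = np.array([r[2] for r in per_subject_results], dtype=float)
    rhos = np.array([r[1] for r in per_subject_results], dtype=float)
    return ConsistencyResult(
        immune_parameter=immune_parameter,
        taxa_family=taxa_family,
        per_subject=list(per_subject_results),
        mean_rho=float(rhos.mean()),
        significant=bool(np.all(ps < per_subject_alpha)),
        aggregate_alpha=aggregate_threshold(per_subject_alpha, len(ps)),
    )


def run_link_stage(
    immune_tidy: pd.DataFrame,
    taxa_tidy: pd.DataFrame,
    immune_parameters: list[str],
    taxa_families: list[str],
    bin_width_days: float = BIN_WIDTH_DAYS,
    min_bins: int = MIN_BINS,
    per_subject_alpha: float = PER_SUBJECT_ALPHA,
    min_subjects: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All (immune parameter, family) pairs through the full procedure.

    Returns (pair-level table, per-subject table).  ``immune_tidy`` /
    ``taxa_tidy`` are wide frames with subject_id and postnatal_age_days
    columns plus one column per parameter / family.
    """
    pair_rows, subj_rows = [], []
    for ip in immune_parameters:
        for tf in taxa_families:
            binned = bin_align(immune_tidy, taxa_tidy, ip, tf, bin_width_days)
            per_subject = intra_individual_correlation(binned, min_bins=min_bins)
            if len(per_subject) < min_subjects:
                continue
            res = consistency_criterion(
                per_subject, per_subject_alpha, immune_parameter=ip, taxa_family=tf
            )
            pair_rows.append(
                (ip, tf, res.mean_rho, res.significant, res.n_subjects,
                 res.aggregate_alpha)
            )
            for sid, rho, p, n in per_subject:
                subj_rows.append((ip, tf, sid, rho, p, n))
    pairs = pd.DataFrame(
        pair_rows,
        columns=["immune_parameter", "taxa_family", "mean_rho", "significant",
                 "n_subjects", "aggregate_alpha"],
    )
    per_subj = pd.DataFrame(
        subj_rows,
        columns=["immune_parameter", "taxa_family", "subject_id", "rho", "p",
                 "n_bins"],
    )
    return pairs, per_subj
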