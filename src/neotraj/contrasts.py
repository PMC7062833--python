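"""Clinical-group contrasts of immune parameters.

Extends the single-group longitudinal model with fixed group main
effects and group x age interactions (random intercept and slope per
subject): value ~ group + age + group:age + (age | subject).  Offsets
and interaction slopes are reported against the stable reference group
with Wald p-values.  Bacteraemia episodes can be stratified into
coagulase-negative staphylococci (CoNS) versus other confirmed
organisms for finer contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "GroupModelFit",
    "fit_group_model",
    "infection_strata_split",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
INFECTION_LABELS = ("none", "suspected", "CoNS", "other_confirmed")


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return ""


@dataclass
class GroupModelFit:
    parameter: str
    reference_group: str
    offsets: dict[str, tuple[float, float, float]]  # group -> (est, se, p)
    interaction_slopes: dict[str, tuple[float, float, float]]
    base_slope: tuple[float, float, float]
    unreliable_groups: list[str] = field(default_factory=list)
    model: str = "value ~ group + age + group:age + (age | subject)"


def fit_group_model(
    values,
    ages,
    subject_ids,
    groups,
    reference_group: str = "stable",
    parameter: str = "",
) -> GroupModelFit:
    """Mixed model with group main effects and group x age interactions.

    Subjects with more samples contribute more rows, realising the
    samples-per-baby weighting.  A group with a single subject is still
    estimated but flagged unreliable.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    subject_ids = np.asarray(subject_ids)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, ages, subject_ids, groups = (
        values[keep], ages[keep], subject_ids[keep], groups[keep]
    )
    levels = [g for g in dict.fromkeys(groups) if g != reference_group]
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} absent from data")
    if not levels:
        raise ValueError("need at least two groups")
    unreliable = []
    for g in levels + [reference_group]:
        if len(np.unique(subject_ids[groups == g])) < 2:
            unreliable.append(g)

    # design: intercept, age, then per non-reference group (offset, group:age)
    cols = [np.ones_like(ages), ages]
    names = ["intercept", "age"]
    for g in levels:
        ind = (groups == g).astype(float)
        cols += [ind, ind * ages]
        names += [f"offset[{g}]", f"slope[{g}]"]
    X = np.column_stack(cols)
    exog_re = np.column_stack([np.ones_like(ages), ages])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = MixedLM(values, X, groups=subject_ids, exog_re=exog_re).fit(
                reml=True, method="lbfgs"
            )
            params, bse = np.asarray(fit.fe_params), np.asarray(fit.bse_fe)
            pvals = np.asarray(fit.pvalues)[: len(names)]
        except (np.linalg.LinAlgError, ValueError):
            beta, *_ = np.linalg.lstsq(X, values, rcond=None)
            resid = values - X @ beta
            sigma2 = float(resid @ resid) / max(len(values) - X.shape[1], 1)
            cov = sigma2 * np.linalg.inv(X.T @ X)
            params, bse = beta, np.sqrt(np.diag(cov))
            pvals = 2 * stats.norm.sf(np.abs(params / np.maximum(bse, 1e-300)))
    pvals = np.where(np.isfinite(pvals), pvals,
                     2 * stats.norm.sf(np.abs(params / np.maximum(bse, 1e-300))))

    def _triple(i):
        return float(params[i]), float(bse[i]), float(pvals[i])

    offsets, inter = {reference_group: (0.0, 0.0, 1.0)}, {reference_group: (0.0, 0.0, 1.0)}
    for j, g in enumerate(levels):
        offsets[g] = _triple(2 + 2 * j)
        inter[g] = _triple(3 + 2 * j)
    return GroupModelFit(
        parameter=parameter,
        reference_group=reference_group,
        offsets=offsets,
        interaction_slopes=inter,
        base_slope=_triple(1),
        unreliable_groups=unreliable,
    )


def infection_strata_split(
    clinical_groups: dict[str, str],
    infection_annotations: dict[str, str],
) -> dict[str, str]:
    """Relabel subjects into infection strata for stratified fitting.

    Annotation per subject is one of none / suspected / CoNS /
    other_confirmed; unannotated subjects keep the ``stable`` stratum if
    clinically stable, else ``suspected``.  Unknown labels are an error.
    """
    strata = {}
    for sid, group in clinical_groups.items():
        ann = infection_annotations.get(sid, "none")
        if ann not in INFECTION_LABELS:
            raise ValueError(f"unknown infection annotation {ann!r} for {sid!r}")
        if ann == "CoNS":
            strata[sid] = "CoNS"
        elif ann == "other_confirmed":
            strata[sid] = "other"
        elif ann == "suspected":
            strata[sid] = "suspected"
        else:
            strata[sid] = "stable" if group == "stable" else "suspected"
    return strata


def group_fits_table(fits: list[GroupModelFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        for g, (est, se, p) in f.offsets.items():
            rows.append((f.parameter, g, "offset", est, se, p, significance_stars(p)))
        for g, (est, se, p) in f.interaction_slopes.items():
            rows.append((f.parameter, g, "group_x_age", est, se, p,
                         significance_stars(p)))
        est, se, p = f.base_slope
        rows.append((f.parameter, f.reference_group, "age_slope", est, se, p,
                     significance_stars(p)))
    return pd.DataFrame(
        rows,
        columns=["parameter", "group", "term", "estimate", "se", "p", "stars"],
    )
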