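"""Adult-deviation mapping and longitudinal slope estimation for immune parameters.

Two questions per parameter: how far from the adult level does each baby
start (log2 fold change of the first blood sample against the adult
median, rank-sum tested with Benjamini–Hochberg correction across
parameters), and how does the parameter move with postnatal age (mixed
linear model with a random intercept and slope per subject, or the mean
of per-subject fits weighted by samples per baby).  The two axes place
each parameter in a quadrant: start high/low x decreasing/increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .io import CohortBundle

__all__ = [
    "AdultDeviation",
    "SlopeFit",
    "QuadrantLabel",
    "adult_deviation",
    "bh_adjust",
    "fit_longitudinal_slope",
    "classify_quadrant",
    "paired_timepoint_test",
    "first_samples",
    "run_adult_deviation_stage",
    "run_slope_stage",
]

QUADRANTS = (
    "start_high_decreasing",
    "start_high_increasing",
    "start_low_increasing",
    "start_low_decreasing",
)


@dataclass(frozen=True)
class AdultDeviation:
    parameter: str
    log2fc: float
    ranksum_p: float
    bh_q: float | None = None
    n_infants: int = 0
    n_adults: int = 0


@dataclass(frozen=True)
class SlopeFit:
    parameter: str
    slope: float  # units per day
    slope_se: float
    p_value: float
    model: str  # "mixed" or "per_subject"
    n_subjects: int
    n_samples: int


@dataclass(frozen=True)
class QuadrantLabel:
    parameter: str
    quadrant: str
    significant: bool


def _epsilon_for(values: np.ndarray) -> float:
    """Scale-aware pseudocount: half the smallest positive observed value."""
    pos = values[values > 0]
    return float(pos.min()) / 2.0 if pos.size else 0.0


def adult_deviation(
    first_samples_per_subject,
    adult_values,
    epsilon: float | None = None,
    parameter: str = "",
) -> AdultDeviation:
    """log2 fold change of first infant samples vs the adult median, with
    a two-sided Wilcoxon rank-sum p-value.

    ``epsilon`` guards the log against zeros; by default it is half the
    smallest positive value observed across both sides.  The fold change
    is the median over subjects of log2((first + eps) / (adult_median + eps)).
    """
    infants = np.asarray(first_samples_per_subject, dtype=float)
    adults = np.asarray(adult_values, dtype=float)
    infants = infants[~np.isnan(infants)]
    adults = adults[~np.isnan(adults)]
    if len(infants) < 2 or len(adults) < 2:
        raise ValueError("need at least two values on each side")
    if epsilon is None:
        epsilon = _epsilon_for(np.concatenate([infants, adults]))
    adult_median = float(np.median(adults))
    if adult_median + epsilon == 0 or np.any(infants + epsilon < 0):
        raise ValueError("cannot form log2 ratio: zero denominator at epsilon=0")
    log2fc = float(np.median(np.log2((infants + epsilon) / (adult_median + epsilon))))
    pooled = np.concatenate([infants, adults])
    if np.all(pooled == pooled[0]):
        p_value = 1.0  # fully tied: no evidence of a shift
    else:
        # Wilcoxon rank-sum == Mann-Whitney U; exact enumeration at small n
        res = stats.mannwhitneyu(infants, adults, alternative="two-sided", method="auto")
        p_value = float(res.pvalue)
    return AdultDeviation(
        parameter=parameter,
        log2fc=log2fc,
        ranksum_p=p_value,
        n_infants=len(infants),
        n_adults=len(adults),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def first_samples(bundle: CohortBundle, parameter: str) -> np.ndarray:
    """Each subject's earliest blood-sample value for one parameter."""
    df = bundle.immune.data[parameter].reset_index()
    df = df.dropna(subset=[parameter])
    firsts = df.loc[df.groupby("subject_id")["postnatal_age_days"].idxmin()]
    return firsts[parameter].to_numpy(dtype=float)


def _pooled_ols(values, ages, weights=None):
    w = np.ones_like(values) if weights is None else np.asarray(weights, float)
    X = np.column_stack([np.ones_like(ages), ages])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ values, rcond=None)
    resid = values - X @ beta
    dof = max(len(values) - 2, 1)
    sigma2 = float(w @ resid**2) / dof
    cov = sigma2 * np.linalg.inv(WX.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    return float(beta[1]), se


def fit_longitudinal_slope(
    values,
    ages,
    subject_ids,
    weights=None,
    model: str = "mixed",
    parameter: str = "",
) -> SlopeFit:
    """Group-level slope of a parameter against postnatal age.

    ``model="mixed"``: linear mixed model with a random intercept and
    slope per subject; the fixed-effect slope carries a Wald p-value.
    Every sample contributes a row, so subjects with more samples carry
    proportionally more weight, which realises the samples-per-baby
    weighting; explicit per-sample ``weights`` additionally scale rows in
    the degenerate OLS path.  In the limit of zero random-effect variance
    and equal weights the estimate equals the pooled OLS slope.

    ``model="per_subject"``: per-subject OLS slopes averaged with weights
    proportional to each subject's sample count.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    subject_ids = np.asarray(subject_ids)
    keep = ~np.isnan(values)
    values, ages, subject_ids = values[keep], ages[keep], subject_ids[keep]
    if np.all(ages == ages[0]):
        raise ValueError("singular design: all ages identical")
    subjects, counts = np.unique(subject_ids, return_counts=True)
    n_subjects = len(subjects)

    if model == "per_subject":
        slopes, wts = [], []
        for sid in subjects:
            m = subject_ids == sid
            if m.sum() < 2 or np.all(ages[m] == ages[m][0]):
                continue
            b, _ = _pooled_ols(values[m], ages[m])
            slopes.append(b)
            wts.append(m.sum())
        slopes, wts = np.asarray(slopes), np.asarray(wts, float)
        mean = float(np.average(slopes, weights=wts))
        # weighted SE of the weighted mean of per-subject slopes
        var = float(np.average((slopes - mean) ** 2, weights=wts)) / max(
            len(slopes) - 1, 1
        )
        se = float(np.sqrt(var))
        t = mean / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(t), df=max(len(slopes) - 1, 1)))
        return SlopeFit(parameter, mean, se, p, "per_subject", len(slopes), len(values))
    if model != "mixed":
        raise ValueError(f"unknown model {model!r}")

    if n_subjects < 2 or np.min(counts) < 2:
        raise ValueError("mixed model needs >=2 subjects with >=2 samples each")
    # degenerate zero-variance data breaks REML; fall back to (weighted) OLS,
    # which is the exact mixed-model limit there
    pooled_slope, pooled_se = _pooled_ols(values, ages, weights)
    resid_scale = np.std(values - np.polyval(np.polyfit(ages, values, 1), ages))
    if resid_scale < 1e-10:
        p = 0.0 if pooled_slope != 0 else 1.0
        return SlopeFit(parameter, pooled_slope, pooled_se, p, "mixed",
                        n_subjects, len(values))
    exog = np.column_stack([np.ones_like(ages), ages])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = MixedLM(values, exog, groups=subject_ids, exog_re=exog)
            fit = md.fit(reml=True, method="lbfgs")
            slope = float(fit.fe_params[1])
            se = float(fit.bse_fe[1])
            p = float(fit.pvalues[1])
        except (np.linalg.LinAlgError, ValueError):
            slope, se = pooled_slope, pooled_se
            p = float(2 * stats.norm.sf(abs(slope / se))) if se > 0 else 1.0
    if not np.isfinite(p):
        p = float(2 * stats.norm.sf(abs(slope / se))) if se > 0 else 1.0
    return SlopeFit(parameter, slope, se, p, "mixed", n_subjects, len(values))


def classify_quadrant(
    deviation: AdultDeviation, slope_fit: SlopeFit, alpha: float = 0.05
) -> QuadrantLabel:
    """Place a parameter in the deviation x slope quadrant map.

    Sign conventions: positive log2fc = starts above adult, negative
    slope = decreases with age.  Exact zeros classify as start_low /
    decreasing (documented tie rule).  ``significant`` reflects the slope
    p-value against ``alpha``.
    """
    if deviation.parameter and slope_fit.parameter and (
        deviation.parameter != slope_fit.parameter
    ):
        raise ValueError("deviation and slope describe different parameters")
    high = deviation.log2fc > 0
    increasing = slope_fit.slope > 0
    quadrant = (
        f"start_{'high' if high else 'low'}_"
        f"{'increasing' if increasing else 'decreasing'}"
    )
    return QuadrantLabel(
        parameter=deviation.parameter or slope_fit.parameter,
        quadrant=quadrant,
        significant=bool(slope_fit.p_value < alpha),
    )


def paired_timepoint_test(values_t1, values_t2) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p, exact at n <= 12.

    Pairs with zero difference are dropped (Wilcoxon convention); if all
    differences are zero the test is degenerate and p = 1.
    """
    a = np.asarray(values_t1, dtype=float)
    b = np.asarray(values_t2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    diffs = b - a
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 1.0
    if len(a) < 2:
        raise ValueError("need at least two informative pairs")
    method = "exact" if len(nz) <= 12 else "auto"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                         zero_method="wilcox")
    return float(res.pvalue)


def run_adult_deviation_stage(
    bundle: CohortBundle, epsilon: float | None = None
) -> pd.DataFrame:
    """Adult-deviation table for every parameter, with BH q-values."""
    if bundle.adult_reference is None:
        raise ValueError("cohort bundle has no adult reference table")
    results = []
    for param in bundle.immune.parameters:
        infants = first_samples(bundle, param)
        adults = bundle.adult_reference[param].dropna().to_numpy()
        results.append(adult_deviation(infants, adults, epsilon, parameter=param))
    q = bh_adjust([r.ranksum_p for r in results])
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in results],
            "log2fc": [r.log2fc for r in results],
            "ranksum_p": [r.ranksum_p for r in results],
            "bh_q": q,
            "n_infants": [r.n_infants for r in results],
            "n_adults": [r.n_adults for r in results],
        }
    )


def run_slope_stage(
    bundle: CohortBundle, model: str = "mixed", alpha: float = 0.05,
    deviations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slope table (and quadrant table when deviations are given)."""
    idx = bundle.immune.data.index
    ages = idx.get_level_values("postnatal_age_days").to_numpy(dtype=float)
    sids = idx.get_level_values("subject_id").to_numpy()
    rows = []
    for param in bundle.immune.parameters:
        vals = bundle.immune.data[param].to_numpy(dtype=float)
        if bundle.immune.kinds.get(param) == "mfi":
            # expression intensities are right-skewed: fit on log10 scale
            vals = np.where(vals > 0, vals, np.nan)
            vals = np.log10(vals)
        fit = fit_longitudinal_slope(vals, ages, sids, model=model, parameter=param)
        rows.append(fit)
    slopes = pd.DataFrame(
        {
            "parameter": [f.parameter for f in rows],
            "slope_per_day": [f.slope for f in rows],
            "slope_se": [f.slope_se for f in rows],
            "p_value": [f.p_value for f in rows],
            "model": [f.model for f in rows],
            "n_subjects": [f.n_subjects for f in rows],
            "n_samples": [f.n_samples for f in rows],
        }
    )
    quadrants = pd.DataFrame()
    if deviations is not None:
        dev_map = {
            r.parameter: AdultDeviation(r.parameter, r.log2fc, r.ranksum_p, r.bh_q)
            for r in deviations.itertuples()
        }
        labels = [
            classify_quadrant(dev_map[f.parameter], f, alpha=alpha) for f in rows
        ]
        quadrants = pd.DataFrame(
            {
                "parameter": [l.parameter for l in labels],
                "quadrant": [l.quadrant for l in labels],
                "significant": [l.significant for l in labels],
            }
        )
    return slopes, quadrants
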