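"""Synthetic longitudinal cohort generator.

Emulates the derived data tables of a preterm-infant immune/microbiome
study so that every downstream stage has a ground-truth recovery test:

* ~39 subjects in three clinical groups (stable 10, unstable 16,
  chorioamnionitis/BCM 13; microbiome subsets 10/13/11), a mean of eight
  roughly weekly blood samples per subject, 186 immune parameters;
* immune parameters that start at a configurable log2 deviation from the
  adult level and drift toward it with subject-level random intercepts
  and slopes plus measurement noise;
* selected parameter pairs coupled through a Gaussian copula calibrated
  to a target Spearman rank correlation (latent Pearson r = 2·sin(πρ/6));
* faecal family-abundance tracks in which Enterobacteriaceae starts
  dominant and declines at a configurable rate per week, with the
  remaining mass split so the per-sample inverse Simpson diversity
  follows a configured linear trend where that is compositionally
  feasible;
* a direct "diversity-track" mode emitting scalar inverse-Simpson series
  y = a + slope·(age/7) + N(0, σ) for exact slope-recovery experiments.

Group-level generating values are the study's reported estimates:
diversity slopes 0.56 / 0.035 / 0.053 U per week and Enterobacteriaceae
slopes −5.6 / +0.16 / +0.38 % per week for stable / unstable / BCM, and
planted rank correlations 0.62, 0.50 and 0.41 for the three highlighted
immune parameter pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalRecord, CohortBundle, ImmuneMatrix, TaxaTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "generate_cohort",
    "generate_taxa_tracks",
    "generate_diversity_tracks",
]

#: analogue names for the parameter pairs with planted rank correlations
CORRELATED_ANALOGUES = [
    ("CXCL8pos_CD4_T", "CXCL8pos_CD8_T", 0.62),
    ("CD161pos_gd_T", "IFNg_pos_gd_T", 0.50),
    ("IFNg_CXCL8neg_gd_T", "IFNg_pos_CD8_T", 0.41),
]

MINOR_FAMILIES = (
    "Veillonellaceae",
    "Bifidobacteriaceae",
    "Staphylococcaceae",
    "Clostridiaceae",
    "Enterococcaceae",
    "Streptococcaceae",
    "Lactobacillaceae",
    "Bacteroidaceae",
    "Ruminococcaceae",
    "Lachnospiraceae",
    "Coriobacteriaceae",
)

#: gestational-age ranges at birth per clinical group, weeks (cohort Table 1)
_GA_RANGE_WEEKS = {
    "stable": (29.1, 31.7),
    "unstable": (23.6, 31.7),
    "BCM": (24.0, 30.1),
}


@dataclass
class SimConfig:
    """Generating conditions for one synthetic cohort.

    Defaults reproduce the study's cohort structure and reported
    group-level effect sizes; noise scales are relative to each
    parameter's adult SD unless stated otherwise.
    """

    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"stable": 10, "unstable": 16, "BCM": 13}
    )
    microbiome_subset: dict[str, int] = field(
        default_factory=lambda: {"stable": 10, "unstable": 13, "BCM": 11}
    )
    samples_per_subject: int = 8
    sample_interval_days: float = 7.0
    n_parameters: int = 186
    n_adults: int = 9
    #: per-parameter marginals; None -> drawn once from the config seed
    adult_means: np.ndarray | None = None
    adult_sds: np.ndarray | None = None
    #: log2 deviation from adult at birth; scalar broadcasts to all parameters
    infant_start_log2fc: np.ndarray | float | None = None
    #: drift toward adult, parameter units per week; None -> close the
    #: birth-to-adult gap linearly over ~12 weeks
    approach_rate: np.ndarray | float | None = None
    #: (name_a, name_b, target Spearman rho) planted via a Gaussian copula
    rank_correlations: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(CORRELATED_ANALOGUES)
    )
    #: additive offsets keyed by (group, parameter name)
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    #: subject random effects and measurement noise, in adult-SD units
    intercept_noise_sd: float = 0.5
    slope_noise_sd: float = 0.15
    measurement_noise_sd: float = 1.0
    #: scale per-subject immune drift by days_preterm (0 = no dependence)
    prematurity_drift: float = 0.0
    #: inverse-Simpson trend per clinical group, units per week
    diversity_slope: dict[str, float] = field(
        default_factory=lambda: {"stable": 0.56, "unstable": 0.035, "BCM": 0.053}
    )
    diversity_intercept: float = 2.5
    diversity_noise_sd: float = 0.5
    #: Enterobacteriaceae relative-abundance trend, fraction per week
    ent_slope: dict[str, float] = field(
        default_factory=lambda: {"stable": -0.056, "unstable": 0.0016, "BCM": 0.0038}
    )
    ent_start: float = 0.75
    ent_noise_sd: float = 0.03
    minor_families: tuple[str, ...] = MINOR_FAMILIES
    seed: int = 0

    def groups(self) -> list[str]:
        return list(self.n_subjects_per_group)

    def parameter_names(self) -> list[str]:
        named = [n for pair in self.rank_correlations for n in pair[:2]]
        # preserve first-appearance order, drop duplicates
        named = list(dict.fromkeys(named))
        if len(named) > self.n_parameters:
            raise ValueError("more correlated parameters than n_parameters")
        fillers = [
            f"param_{i:03d}" for i in range(1, self.n_parameters - len(named) + 1)
        ]
        return named + fillers

    def validate(self) -> "SimConfig":
        for g, n in self.n_subjects_per_group.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        if self.samples_per_subject < 2:
            raise ValueError("need at least two samples per subject")
        for a, b, rho in self.rank_correlations:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target rho {rho} for ({a}, {b}) outside [-1, 1]")
        return self


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode()) % 1000


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stream]))


def _marginals(config: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-parameter adult mean/SD and infant birth log2 fold change."""
    p = config.n_parameters
    rng = _rng(config.seed, 101)
    means = (
        np.asarray(config.adult_means, dtype=float)
        if config.adult_means is not None
        else rng.uniform(5.0, 60.0, size=p)
    )
    sds = (
        np.asarray(config.adult_sds, dtype=float)
        if config.adult_sds is not None
        else 0.2 * means
    )
    if config.infant_start_log2fc is None:
        lfc = np.clip(rng.normal(0.0, 0.6, size=p), -1.5, 1.5)
    else:
        lfc = np.broadcast_to(
            np.asarray(config.infant_start_log2fc, dtype=float), (p,)
        ).copy()
    if means.shape != (p,) or sds.shape != (p,):
        raise ValueError("adult_means / adult_sds must have length n_parameters")
    return means, sds, lfc


def _latent_correlation(config: SimConfig, names: list[str]) -> tuple[list[str], np.ndarray]:
    """Joint latent-normal correlation over parameters in planted pairs.

    Spearman rho maps to the latent Pearson r of a Gaussian copula via
    r = 2·sin(π·rho/6).  A non-positive-definite request fails before any
    sampling.
    """
    involved = [n for n in names if any(n in p[:2] for p in config.rank_correlations)]
    k = len(involved)
    corr = np.eye(k)
    idx = {n: i for i, n in enumerate(involved)}
    for a, b, rho in config.rank_correlations:
        r = 2.0 * math.sin(math.pi * rho / 6.0)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "infeasible rank-correlation set: latent correlation matrix "
            "is not positive definite"
        ) from None
    return involved, corr


def _schedule(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Roughly weekly sampling ages in days, first sample on day 1-7."""
    start = rng.integers(1, 8)
    ages = start + config.sample_interval_days * np.arange(config.samples_per_subject)
    jitter = rng.integers(-1, 2, size=len(ages)).astype(float)
    ages = ages + jitter
    ages[0] = max(ages[0], 1.0)
    return np.maximum.accumulate(ages)  # keep strictly scheduled order


def _clinical_records(config: SimConfig) -> dict[str, ClinicalRecord]:
    rng = _rng(config.seed, 102)
    records: dict[str, ClinicalRecord] = {}
    for group in config.groups():
        lo, hi = _GA_RANGE_WEEKS.get(group, (24.0, 32.0))
        for i in range(config.n_subjects_per_group[group]):
            sid = f"{group}{i + 1:02d}"
            ga_days = float(rng.uniform(lo * 7.0, hi * 7.0))
            sex = "M" if rng.random() < 0.5 else "F"
            records[sid] = ClinicalRecord(
                subject_id=sid, gestational_age_days=ga_days, group=group, sex=sex
            )
    return records


def generate_cohort(config: SimConfig, seed: int | None = None) -> CohortBundle:
    """Generate immune table + clinical metadata + adult reference.

    Immune values follow
    ``adult_mean·2^lfc + drift·(age/7) + b0_i + b1_i·(age/7) + noise``
    clipped to the legal range of the parameter kind; parameters that
    participate in a planted rank correlation are held stationary (no
    drift or subject random effects) so the pooled Spearman correlation
    matches the copula target.  Identical (config, seed) gives an
    identical bundle.
    """
    config = dataclasses.replace(config, seed=config.seed if seed is None else seed)
    config.validate()
    names = config.parameter_names()
    means, sds, lfc = _marginals(config)
    involved, latent_corr = _latent_correlation(config, names)
    chol = np.linalg.cholesky(latent_corr) if involved else None
    inv_idx = {n: i for i, n in enumerate(involved)}
    clinical = _clinical_records(config)

    # birth levels kept inside the measurable frequency range: a start
    # level at or beyond a clip bound would saturate the whole series
    # into ties and destroy rank structure
    start_level = np.clip(means * np.exp2(lfc), 1.0, 90.0)
    if config.approach_rate is None:
        drift = (means - start_level) / 12.0  # close the gap over ~12 weeks
    else:
        drift = np.broadcast_to(
            np.asarray(config.approach_rate, dtype=float), (len(names),)
        ).copy()
    is_stationary = np.array([n in inv_idx for n in names])

    mean_dp = float(
        np.mean([rec.days_preterm for rec in clinical.values()])
    )
    rows, keys = [], []
    for s_i, (sid, rec) in enumerate(sorted(clinical.items())):
        rng = _rng(config.seed, 200, s_i)
        ages = _schedule(rng, config)
        b0 = rng.normal(0.0, config.intercept_noise_sd, size=len(names)) * sds
        b1 = rng.normal(0.0, config.slope_noise_sd, size=len(names)) * sds
        drift_scale = 1.0
        if config.prematurity_drift:
            drift_scale = 1.0 + config.prematurity_drift * (
                rec.days_preterm - mean_dp
            ) / max(mean_dp, 1.0)
        offsets = np.array(
            [config.group_effects.get((rec.group, n), 0.0) for n in names]
        )
        for age in ages:
            wk = age / 7.0
            z = rng.normal(size=len(names))
            if chol is not None:
                z_lat = chol @ rng.normal(size=len(involved))
                for n, i_lat in inv_idx.items():
                    z[names.index(n)] = z_lat[i_lat]
            values = np.where(
                is_stationary,
                start_level + offsets + sds * z,
                start_level
                + offsets
                + drift * drift_scale * wk
                + b0
                + b1 * wk
                + sds * config.measurement_noise_sd * z,
            )
            values = np.clip(values, 0.0, 100.0)  # all defaults are frequencies
            rows.append(values)
            keys.append((sid, float(age)))

    index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "postnatal_age_days"])
    immune = ImmuneMatrix(
        data=pd.DataFrame(np.array(rows), index=index, columns=names),
        kinds={n: "frequency_percent" for n in names},
    ).validate()

    adult_rng = _rng(config.seed, 103)
    adults = np.clip(
        means + sds * adult_rng.normal(size=(config.n_adults, len(names))), 0.0, 100.0
    )
    adult_reference = pd.DataFrame(
        adults,
        index=[f"adult{i + 1}" for i in range(config.n_adults)],
        columns=names,
    )
    return CohortBundle(
        immune=immune, clinical=clinical, adult_reference=adult_reference
    )


def _split_minor_mass(q: float, s: float, k: int) -> np.ndarray:
    """Split mass q over k minors with sum of squares s.

    One heavier minor plus an even remainder; feasible iff
    q²/k <= s <= q².  Closed form from the quadratic in the heavy share.
    """
    if k == 1:
        return np.array([q])
    km1 = k - 1
    disc = km1 * (k * s - q * q)
    a = (q + math.sqrt(max(disc, 0.0))) / k
    b = max((q - a) / km1, 0.0)  # guard roundoff at the feasibility edge
    out = np.array([a] + [b] * km1)
    return out * (q / out.sum()) if out.sum() > 0 else out


def generate_taxa_tracks(
    config: SimConfig, seed: int | None = None, diversity_targets: bool = True
) -> TaxaTable:
    """Generate family-level relative-abundance time series.

    Enterobacteriaceae starts dominant (``ent_start``, default 75%) and
    moves at the group's configured slope per week plus noise; remaining
    mass is split across the minor families so the composition's inverse
    Simpson tracks the group's linear diversity trend wherever that is
    compositionally feasible given the dominant share (the target is
    clipped into the feasible band otherwise, with a logged warning).
    """
    config = dataclasses.replace(config, seed=config.seed if seed is None else seed)
    config.validate()
    clinical = _clinical_records(config)
    families = ["Enterobacteriaceae", *config.minor_families]
    k_minor = len(config.minor_families)
    clipped = 0
    rows, keys = [], []
    for group in config.groups():
        n_sub = config.microbiome_subset.get(group, config.n_subjects_per_group[group])
        subjects = sorted(s for s, r in clinical.items() if r.group == group)[:n_sub]
        for s_i, sid in enumerate(subjects):
            rng = _rng(config.seed, 300, _stable_hash(group), s_i)
            ages = _schedule(rng, config)
            perm = rng.permutation(k_minor)
            for age in ages:
                wk = age / 7.0
                p_ent = config.ent_start + config.ent_slope[group] * wk
                p_ent += rng.normal(0.0, config.ent_noise_sd)
                if not 0.01 <= p_ent <= 0.98:
                    clipped += 1
                    p_ent = float(np.clip(p_ent, 0.01, 0.98))
                q = 1.0 - p_ent
                if diversity_targets:
                    d_target = (
                        config.diversity_intercept
                        + config.diversity_slope[group] * wk
                        + rng.normal(0.0, 0.1)
                    )
                    s_req = 1.0 / max(d_target, 1.0 + 1e-9) - p_ent * p_ent
                    lo, hi = q * q / k_minor, q * q
                    if not lo <= s_req <= hi:
                        clipped += 1
                        s_req = float(np.clip(s_req, lo, hi))
                    minors = _split_minor_mass(q, s_req, k_minor)[perm]
                else:
                    w = rng.dirichlet(np.ones(k_minor))
                    minors = q * w
                rows.append(np.concatenate([[p_ent], minors]))
                keys.append((sid, float(age)))
    if clipped:
        logger.warning(
            "taxa generator clipped %d values to keep compositions legal", clipped
        )
    index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "postnatal_age_days"])
    data = pd.DataFrame(np.array(rows), index=index, columns=families)
    return TaxaTable(data=data).validate()


def generate_diversity_tracks(
    config: SimConfig,
    seed: int | None = None,
    group: str = "stable",
    n_subjects: int | None = None,
    n_samples: int = 15,
) -> pd.DataFrame:
    """Scalar inverse-Simpson tracks for exact slope-recovery tests.

    Emits ``y = intercept + slope·(age/7) + N(0, diversity_noise_sd)``
    for each subject on a weekly schedule, bypassing compositions
    entirely, so the per-subject slope ground truth is exact.
    Returns a tidy frame (subject_id, postnatal_age_days, inverse_simpson,
    group).
    """
    base_seed = config.seed if seed is None else seed
    slope = config.diversity_slope[group]
    if n_subjects is None:
        n_subjects = config.microbiome_subset.get(
            group, config.n_subjects_per_group[group]
        )
    records = []
    for s_i in range(n_subjects):
        rng = _rng(base_seed, 400, _stable_hash(group), s_i)
        start = rng.integers(1, 8)
        ages = start + config.sample_interval_days * np.arange(n_samples)
        noise = rng.normal(0.0, config.diversity_noise_sd, size=n_samples)
        y = config.diversity_intercept + slope * ages / 7.0 + noise
        sid = f"{group}{s_i + 1:02d}"
        for age, val in zip(ages, y):
            records.append((sid, float(age), float(val), group))
    return pd.DataFrame(
        records,
        columns=["subject_id", "postnatal_age_days", "inverse_simpson", "group"],
    )
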