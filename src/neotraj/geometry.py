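"""Whole-immune-profile ordination and developmental trajectory distances.

All immune parameters are z-scored (per-parameter mean/SD over retained
samples, median-imputed missing cells) and projected by PCA.  Each baby's
developmental movement is the Euclidean distance in (PC1, PC2) between
an early sample (first week of life) and a late sample (closest to day
37 within days 28-49), and that distance is related to how many days
preterm the baby was born.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import CohortBundle, ImmuneMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileScores",
    "TrajectoryDistance",
    "standardize_and_project",
    "trajectory_distance",
    "trajectory_distances",
    "prematurity_association",
]


@dataclass
class ProfileScores:
    scores: pd.DataFrame  # index = sample keys, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    center: pd.Series  # per-parameter mean used for z-scoring
    scale: pd.Series  # per-parameter SD used for z-scoring
    dropped_parameters: list[str]


@dataclass(frozen=True)
class TrajectoryDistance:
    subject_id: str
    early_age: float
    late_age: float
    distance: float
    days_preterm: float


def standardize_and_project(
    immune: ImmuneMatrix, n_components: int = 2
) -> ProfileScores:
    """Median-impute, z-score per parameter, and project onto principal axes.

    Zero-variance parameters are dropped with a warning (they carry no
    ordination information and break scaling).
    """
    df = immune.data.astype(float)
    if len(df) < 2:
        raise ValueError("PCA needs at least two samples")
    medians = df.median(axis=0, skipna=True)
    filled = df.fillna(medians)
    center = filled.mean(axis=0)
    scale = filled.std(axis=0, ddof=1)
    dropped = list(scale.index[(scale == 0) | scale.isna()])
    if dropped:
        logger.warning("dropping %d zero-variance parameters", len(dropped))
    kept = [c for c in filled.columns if c not in dropped]
    z = (filled[kept] - center[kept]) / scale[kept]
    k = min(n_components, len(kept), len(df))
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(z.to_numpy())
    scores = pd.DataFrame(
        coords, index=df.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return ProfileScores(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        center=center[kept],
        scale=scale[kept],
        dropped_parameters=dropped,
    )


def trajectory_distance(
    scores: ProfileScores,
    subject_id: str,
    days_preterm: float = float("nan"),
    early_max_day: float = 7.0,
    late_target_day: float = 37.0,
    late_window: tuple[float, float] = (28.0, 49.0),
) -> TrajectoryDistance | None:
    """Distance moved in (PC1, PC2) from the first-week sample to the
    sample nearest the late target day.

    Early sample: the subject's earliest sample at age <= ``early_max_day``.
    Late sample: the sample with age closest to ``late_target_day`` inside
    ``late_window``.  Returns None (with a logged reason) when either
    window is empty.
    """
    sub = scores.scores.loc[
        scores.scores.index.get_level_values("subject_id") == subject_id
    ]
    ages = sub.index.get_level_values("postnatal_age_days").to_numpy(dtype=float)
    early_mask = ages <= early_max_day
    late_mask = (ages >= late_window[0]) & (ages <= late_window[1])
    if not early_mask.any() or not late_mask.any():
        logger.info(
            "subject %s excluded from trajectory distance: missing %s window",
            subject_id,
            "early" if not early_mask.any() else "late",
        )
        return None
    early_i = np.where(early_mask)[0][np.argmin(ages[early_mask])]
    late_candidates = np.where(late_mask)[0]
    late_i = late_candidates[np.argmin(np.abs(ages[late_candidates] - late_target_day))]
    d = sub.iloc[late_i][["PC1", "PC2"]] - sub.iloc[early_i][["PC1", "PC2"]]
    return TrajectoryDistance(
        subject_id=subject_id,
        early_age=float(ages[early_i]),
        late_age=float(ages[late_i]),
        distance=float(np.hypot(d["PC1"], d["PC2"])),
        days_preterm=days_preterm,
    )


def trajectory_distances(
    bundle: CohortBundle, scores: ProfileScores, **kwargs
) -> pd.DataFrame:
    """Per-subject trajectory distances as a tidy frame."""
    rows = []
    for sid in sorted(
        set(scores.scores.index.get_level_values("subject_id"))
    ):
        rec = bundle.clinical.get(sid)
        td = trajectory_distance(
            scores, sid, days_preterm=rec.days_preterm if rec else float("nan"),
            **kwargs,
        )
        if td is not None:
            rows.append(td)
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in rows],
            "early_age": [t.early_age for t in rows],
            "late_age": [t.late_age for t in rows],
            "distance": [t.distance for t in rows],
            "days_preterm": [t.days_preterm for t in rows],
        }
    )


def prematurity_association(distances: pd.DataFrame) -> dict:
    """Spearman correlation between trajectory distance and days preterm."""
    if len(distances) < 5:
        raise ValueError("need at least five subjects")
    d = distances["distance"].to_numpy(dtype=float)
    dp = distances["days_preterm"].to_numpy(dtype=float)
    if np.all(d == d[0]) or np.all(dp == dp[0]):
        return {"rho": float("nan"), "p": float("nan"), "n": len(d)}
    res = stats.spearmanr(d, dp)
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": len(d)}
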