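"""Entropy-weight scoring and ranking of fixation positions.

The entropy-weight method assigns each metric an objective weight from its
information content across the alternatives: a metric whose (normalized)
values are nearly uniform carries high Shannon entropy e_j and little
information, so its utility d_j = 1 - e_j and weight w_j = d_j / sum(d)
are small.  Composite scores are the weighted sums of the min-max
normalized decision matrix, with stiffness oriented as a benefit and the
stress/gap metrics as costs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stability_metrics import MetricTable, METRIC_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "OrientationSpec",
    "WeightVector",
    "RankingResult",
    "orient_normalize",
    "entropy_weights",
    "composite_scores",
    "rank_models",
    "DEFAULT_ORIENTATION",
]


@dataclass(frozen=True)
class OrientationSpec:
    """Per-metric optimization direction: 'benefit' (larger better) or
    'cost' (smaller better)."""

    directions: dict

    def __post_init__(self):
        for k, v in self.directions.items():
            if v not in ("benefit", "cost"):
                raise ValueError(f"direction for {k!r} must be 'benefit' or 'cost'")


DEFAULT_ORIENTATION = OrientationSpec(
    directions={
        "stiffness_N_mm": "benefit",
        "mivs_MPa": "cost",
        "miss_MPa": "cost",
        "mig_mm": "cost",
    }
)


@dataclass(frozen=True)
class WeightVector:
    metrics: tuple
    entropy_e: np.ndarray
    utility_d: np.ndarray
    weight_w: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.entropy_e, float)
        d = np.asarray(self.utility_d, float)
        w = np.asarray(self.weight_w, float)
        if np.any((e < -1e-12) | (e > 1 + 1e-12)):
            raise ValueError("entropy values must lie in [0, 1]")
        if not np.allclose(d, 1.0 - e):
            raise ValueError("utility must equal 1 - entropy")
        if abs(w.sum() - 1.0) > 1e-12 or np.any(w < -1e-15):
            raise ValueError("weights must be nonnegative and sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(self.metrics),
                "e": self.entropy_e,
                "d": self.utility_d,
                "w_percent": 100.0 * self.weight_w,
            }
        )


@dataclass(frozen=True)
class RankingResult:
    labels: tuple
    scores: np.ndarray  # composite score per model, table order
    order: np.ndarray  # indices sorted best -> worst
    ties_note: str = ""

    def to_frame(self) -> pd.DataFrame:
        rank = np.empty(len(self.order), int)
        rank[self.order] = np.arange(1, len(self.order) + 1)
        return pd.DataFrame(
            {
                "model_label": list(self.labels),
                "composite_score": self.scores,
                "rank": rank,
            }
        )


def _table_matrix(table: MetricTable):
    df = table.to_frame()
    return df["model_label"].tolist(), df[METRIC_COLUMNS].to_numpy(float)


def orient_normalize(table: MetricTable, spec: OrientationSpec = DEFAULT_ORIENTATION) -> np.ndarray:
    """Min-max normalization with benefit/cost orientation, in [0, 1].

    Benefit columns map x -> (x - min)/(max - min), cost columns
    x -> (max - x)/(max - min).  A constant column becomes all zeros (no
    information) with a logged warning.
    """
    labels, X = _table_matrix(table)
    if len(labels) < 2:
        raise ValueError("need at least 2 models to normalize")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in metric table")
    Z = np.empty_like(X)
    for j, col in enumerate(METRIC_COLUMNS):
        x = X[:, j]
        span = x.max() - x.min()
        if span == 0:
            log.warning("metric column %s is constant; normalized to zeros", col)
            Z[:, j] = 0.0
            continue
        if spec.directions.get(col, "benefit") == "benefit":
            Z[:, j] = (x - x.min()) / span
        else:
            Z[:, j] = (x.max() - x) / span
    return Z


def entropy_weights(Z: np.ndarray, metrics=tuple(METRIC_COLUMNS)) -> WeightVector:
    """Entropy, utility and weight per column of a normalized matrix.

    p_ij = z_ij / sum_i z_ij, e_j = -(1/ln n) sum_i p_ij ln p_ij with
    0 ln 0 := 0; an all-zero column gets e = 1 (maximum entropy, zero
    weight).  Raises if every column is constant (no information at all).
    """
    Z = np.asarray(Z, float)
    n, m = Z.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    if Z.min() < -1e-12 or Z.max() > 1 + 1e-12:
        raise ValueError("normalized matrix must lie in [0, 1]")
    e = np.ones(m)
    for j in range(m):
        s = Z[:, j].sum()
        if s == 0:
            continue
        p = Z[:, j] / s
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e[j] = -plogp.sum() / np.log(n)
    e = np.clip(e, 0.0, 1.0)
    d = 1.0 - e
    if d.sum() == 0:
        raise ValueError("all columns constant: entropy weights are undefined")
    w = d / d.sum()
    return WeightVector(metrics=tuple(metrics), entropy_e=e, utility_d=d, weight_w=w)


def weights_from_utilities(d, metrics=tuple(METRIC_COLUMNS)) -> WeightVector:
    """Weight vector straight from printed utility values d = 1 - e."""
    d = np.asarray(d, float)
    return WeightVector(
        metrics=tuple(metrics), entropy_e=1.0 - d, utility_d=d, weight_w=d / d.sum()
    )


def composite_scores(
    Z: np.ndarray,
    weights: WeightVector,
    labels=None,
    tie_break: np.ndarray | None = None,
) -> RankingResult:
    """Weighted-sum composite scores s_i = sum_j w_j z_ij, ranked
    descending.  Ties are broken by lower raw MIG, then higher stiffness,
    then label (lexicographic), when the raw matrix is supplied."""
    Z = np.asarray(Z, float)
    w = weights.weight_w
    if Z.shape[1] != len(w):
        raise ValueError("weight/matrix dimension mismatch")
    s = Z @ w
    labels = tuple(labels) if labels is not None else tuple(f"m{i}" for i in range(len(s)))
    if tie_break is not None:
        keys = list(zip(-np.round(s, 12), tie_break[:, 3], -tie_break[:, 0], labels))
    else:
        keys = list(zip(-np.round(s, 12), labels))
    order = np.array(sorted(range(len(s)), key=lambda i: keys[i]), int)
    tie = ""
    if len(np.unique(np.round(s, 12))) < len(s):
        tie = "ties broken by lower MIG, then higher stiffness, then label"
    return RankingResult(labels=labels, scores=s, order=order, ties_note=tie)


def rank_models(table: MetricTable, spec: OrientationSpec = DEFAULT_ORIENTATION):
    """Full pipeline: orientation + normalization, entropy weights,
    composite scores.  Returns (WeightVector, RankingResult, audit) where
    audit carries every intermediate for inspection."""
    labels, X = _table_matrix(table)
    Z = orient_normalize(table, spec)
    wv = entropy_weights(Z)
    res = composite_scores(Z, wv, labels=labels, tie_break=X)
    with np.errstate(divide="ignore", invalid="ignore"):
        colsum = Z.sum(axis=0)
        P = np.where(colsum > 0, Z / np.where(colsum == 0, 1.0, colsum), np.nan)
    audit = {
        "normalized": Z,
        "p": P,
        "e": wv.entropy_e,
        "d": wv.utility_d,
        "w": wv.weight_w,
        "scores": res.scores,
    }
    return wv, res, audit
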