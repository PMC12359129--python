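"""Combined Compromise Solution (CoCoSo) ranking.

CoCoSo blends a simple-additive-weighting view of a decision matrix
with an exponentially-weighted-product view and compromises between
them.  For min-max normalized scores n_ij and weights w_j:

    CS_i = Σ_j w_j n_ij                (weighted comparability sum)
    P_i  = Σ_j n_ij ** w_j             (power comparability sum)

    ka_i = (P_i + CS_i) / Σ_i (P_i + CS_i)
    kb_i = CS_i / min CS + P_i / min P
    kc_i = (λ CS_i + (1-λ) P_i) / (λ max CS + (1-λ) max P)

    Ci   = (ka_i kb_i kc_i)^(1/3) + (ka_i + kb_i + kc_i) / 3

Rank 1 is the largest Ci.  The balance coefficient λ ∈ [0, 1]
(default 0.5) trades additive against multiplicative dominance in kc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .entropy import compute_entropy_weights
from .matrix import DecisionMatrix

__all__ = [
    "NormalizedMatrix",
    "CocosoResult",
    "CocosoRanker",
    "minmax_normalize",
    "comparability_sums",
    "appraisal_scores",
    "composite_index",
    "rank_alternatives",
    "rank_cocoso",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Min-max normalized decision matrix with per-column orientation."""

    values: np.ndarray                  # (m, n) in [0, 1]
    orientation: tuple[str, ...]        # "benefit" | "cost" per column
    column_extremes: np.ndarray         # (n, 2): per-column (min, max)


@dataclass(frozen=True)
class CocosoResult:
    """Per-country CoCoSo quantities and final ranking."""

    countries: tuple[str, ...]
    CS: np.ndarray
    P: np.ndarray
    ka: np.ndarray
    kb: np.ndarray
    kc: np.ndarray
    lam: float
    Ci: np.ndarray
    rank: np.ndarray


def _resolve_orientation(n: int, orientation) -> tuple[str, ...]:
    if orientation is None:
        return ("benefit",) * n
    if isinstance(orientation, str):
        return (orientation,) * n
    orientation = tuple(orientation)
    if len(orientation) != n:
        raise ValueError(f"orientation length {len(orientation)} != n={n}")
    bad = set(orientation) - {"benefit", "cost"}
    if bad:
        raise ValueError(f"unknown orientation flags: {sorted(bad)}")
    return orientation


def minmax_normalize(
    matrix: DecisionMatrix | np.ndarray,
    orientation: Sequence[str] | str | None = None,
) -> NormalizedMatrix:
    """Min-max normalize each column into [0, 1].

    Benefit columns map (g - min)/(max - min); cost columns flip so the
    smallest raw score maps to 1.  Constant columns normalize to all
    zeros by convention (they carry entropy weight 0 in this pipeline,
    so the value cannot move Ci); a warning is logged for standalone
    use.
    """
    scores = matrix.scores if isinstance(matrix, DecisionMatrix) else np.asarray(
        matrix, dtype=float
    )
    m, n = scores.shape
    orient = _resolve_orientation(n, orientation)
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    values = np.zeros_like(scores)
    for j in range(n):
        if span[j] == 0:
            log.warning("constant column %d normalizes to 0", j)
            continue
        if orient[j] == "benefit":
            values[:, j] = (scores[:, j] - lo[j]) / span[j]
        else:
            values[:, j] = (hi[j] - scores[:, j]) / span[j]
    return NormalizedMatrix(
        values=values,
        orientation=orient,
        column_extremes=np.column_stack([lo, hi]),
    )


def comparability_sums(
    norm: NormalizedMatrix | np.ndarray,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-sum CS_i and power-product P_i comparability sequences.

    Uses the 0**w ≡ 0 convention for w > 0, so P_i ∈ [0, n].
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(
        norm, dtype=float
    )
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != values.shape[1]:
        raise ValueError("weights length does not match indicator count")
    if np.any(weights < 0):
        raise ValueError("negative weights")
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    cs = values @ weights
    # 0**0 == 1 in numpy; zero-weight columns must contribute 1 (the
    # w -> 0 limit of n**w for n > 0) and do, except at n == 0 where the
    # convention 0**w = 0 only applies to w > 0.
    with np.errstate(invalid="ignore"):
        powers = values ** weights
    powers[:, weights == 0] = 1.0
    powers[(values == 0) & (weights > 0)] = 0.0
    p = powers.sum(axis=1)
    return cs, p


def appraisal_scores(
    CS: np.ndarray,
    P: np.ndarray,
    lam: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three CoCoSo appraisal scores (ka, kb, kc).

    kb divides by min(CS) and min(P); a country at the column minimum of
    every criterion makes min(CS) = 0 and is surfaced as a hard error
    (see ``eps`` on :class:`CocosoRanker` for an optional shift).
    """
    CS = np.asarray(CS, dtype=float)
    P = np.asarray(P, dtype=float)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    for name, arr in (("CS", CS), ("P", P)):
        if arr.min() <= 0:
            i = int(arr.argmin())
            raise ValueError(
                f"min({name}) = {arr.min():g} at alternative index {i}: "
                "appraisal score kb undefined (check for an all-minimum row "
                "or enable an epsilon shift)"
            )
    ka = (P + CS) / (P + CS).sum()
    kb = CS / CS.min() + P / P.min()
    kc = (lam * CS + (1 - lam) * P) / (lam * CS.max() + (1 - lam) * P.max())
    return ka, kb, kc


def composite_index(
    ka: np.ndarray, kb: np.ndarray, kc: np.ndarray
) -> np.ndarray:
    """Ci = geometric mean + arithmetic mean of the appraisal scores."""
    ka, kb, kc = (np.asarray(v, dtype=float) for v in (ka, kb, kc))
    if not (ka.shape == kb.shape == kc.shape):
        raise ValueError("appraisal score vectors must share a shape")
    if np.any(ka <= 0) or np.any(kb <= 0) or np.any(kc <= 0):
        raise ValueError("appraisal scores must be positive")
    return np.cbrt(ka * kb * kc) + (ka + kb + kc) / 3.0


def rank_alternatives(Ci: np.ndarray) -> np.ndarray:
    """Descending competition ranks (1 = largest Ci; ties share a rank)."""
    Ci = np.asarray(Ci, dtype=float)
    ranks = rankdata(-Ci, method="min").astype(int)
    if len(np.unique(Ci)) != len(Ci):
        warnings.warn("tied composite indices: competition ranking applied")
    return ranks


class CocosoRanker(BaseEstimator):
    """Rank alternatives by CoCoSo, optionally with entropy weights.

    Parameters
    ----------
    weights : array-like of shape (n,), or "entropy" (default)
        Indicator weights summing to 1; ``"entropy"`` computes them from
        the fitted matrix by the entropy weight method.
    lam : float in [0, 1], default 0.5
        Balance coefficient of the kc appraisal score; 0.5 gives parity
        between the additive and multiplicative views.
    orientation : per-indicator "benefit"/"cost" flags, a single string,
        or None (all benefit — the GHSI convention, where every pillar
        including Risk Environment is scored so higher is better).
    eps : float, default 0.0
        Optional shift added to normalized values before the
        comparability sums, guarding against min(CS) = 0.  Off by
        default; no regularization is applied unless requested.

    Attributes
    ----------
    normalized_ : NormalizedMatrix
    weights_ : weights actually used
    cs_, p_, ka_, kb_, kc_, ci_, ranks_ : per-alternative vectors
    """

    def __init__(
        self,
        weights="entropy",
        lam: float = 0.5,
        orientation=None,
        eps: float = 0.0,
    ):
        self.weights = weights
        self.lam = lam
        self.orientation = orientation
        self.eps = eps

    def fit(self, X: DecisionMatrix | np.ndarray, y=None) -> "CocosoRanker":
        if isinstance(self.weights, str):
            if self.weights != "entropy":
                raise ValueError(f"unknown weights spec {self.weights!r}")
            w = compute_entropy_weights(X).weights
        else:
            w = np.asarray(self.weights, dtype=float)
        norm = minmax_normalize(X, self.orientation)
        values = norm.values + self.eps if self.eps else norm.values
        cs, p = comparability_sums(values, w)
        ka, kb, kc = appraisal_scores(cs, p, self.lam)
        ci = composite_index(ka, kb, kc)
        self.normalized_ = norm
        self.weights_ = w
        self.cs_, self.p_ = cs, p
        self.ka_, self.kb_, self.kc_ = ka, kb, kc
        self.ci_ = ci
        self.ranks_ = rank_alternatives(ci)
        if isinstance(X, DecisionMatrix):
            self.countries_ = X.countries
            self.feature_names_in_ = np.asarray(X.indicators, dtype=object)
        else:
            self.countries_ = tuple(f"a{i}" for i in range(len(ci)))
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the integer ranks (1 = best)."""
        return self.fit(X).ranks_

    def result(self) -> CocosoResult:
        if not hasattr(self, "ci_"):
            raise RuntimeError("CocosoRanker is not fitted")
        return CocosoResult(
            countries=self.countries_,
            CS=self.cs_,
            P=self.p_,
            ka=self.ka_,
            kb=self.kb_,
            kc=self.kc_,
            lam=self.lam,
            Ci=self.ci_,
            rank=self.ranks_,
        )


def rank_cocoso(
    matrix: DecisionMatrix | np.ndarray,
    weights="entropy",
    lam: float = 0.5,
    orientation=None,
) -> CocosoResult:
    """One-call CoCoSo ranking of a decision matrix."""
    return CocosoRanker(
        weights=weights, lam=lam, orientation=orientation
    ).fit(matrix).result()
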