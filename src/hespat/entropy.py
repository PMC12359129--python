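"""Objective indicator weighting by the Shannon entropy weight method.

Each indicator column is first converted to shares of its column sum,
n_ij = g_ij / Σ_i g_ij.  The column's Shannon entropy on those shares,

    Ent_j = -(1/ln m) Σ_i n_ij ln n_ij        (0·ln 0 ≡ 0),

lies in [0, 1]; 1 - Ent_j (the divergence) measures how unevenly the
indicator separates countries.  Normalizing divergences gives the
weights W_j = (1 - Ent_j) / Σ_j (1 - Ent_j): indicators with greater
dispersion — hence more discriminating power — weigh more, with no
analyst judgement involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .matrix import DecisionMatrix

__all__ = [
    "EntropyResult",
    "EntropyWeighter",
    "entropy_shares",
    "entropy_values",
    "divergence_weights",
    "compute_entropy_weights",
]


@dataclass(frozen=True)
class EntropyResult:
    """Bundled stages of the entropy weighting of one decision matrix."""

    indicators: tuple[str, ...]
    shares: np.ndarray          # (m, n), columns sum to 1
    entropies: np.ndarray       # (n,), each in [0, 1]
    divergences: np.ndarray     # (n,), 1 - entropy
    weights: np.ndarray         # (n,), nonnegative, sums to 1


def _as_scores(matrix) -> np.ndarray:
    if isinstance(matrix, DecisionMatrix):
        return matrix.scores
    return np.asarray(matrix, dtype=float)


def entropy_shares(matrix: DecisionMatrix | np.ndarray) -> np.ndarray:
    """Column-share normalization n_ij = g_ij / Σ_i g_ij.

    Requires nonnegative scores and strictly positive column sums;
    entropy is undefined otherwise.
    """
    scores = _as_scores(matrix)
    if np.any(scores < 0):
        raise ValueError("negative scores: entropy shares undefined")
    colsum = scores.sum(axis=0)
    if np.any(colsum <= 0):
        bad = np.where(colsum <= 0)[0].tolist()
        raise ValueError(f"zero column sum at indicator index {bad}")
    return scores / colsum


def entropy_values(shares: np.ndarray, m: int | None = None) -> np.ndarray:
    """Per-indicator Shannon entropy Ent_j of column shares, in [0, 1].

    Uses the natural logarithm and the 0·ln 0 ≡ 0 convention.  ``m``
    defaults to the number of rows of ``shares``.
    """
    shares = np.asarray(shares, dtype=float)
    if m is None:
        m = shares.shape[0]
    if m < 2:
        raise ValueError("entropy needs at least 2 countries (1/ln m undefined)")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(shares > 0, shares * np.log(shares), 0.0)
    ent = -plogp.sum(axis=0) / np.log(m)
    # clip float noise at the boundaries; Ent_j in [0, 1] analytically
    return np.clip(ent, 0.0, 1.0)


def divergence_weights(entropies: np.ndarray) -> np.ndarray:
    """Normalize divergences 1 - Ent_j into weights summing to 1.

    A constant column (Ent_j = 1) gets weight exactly 0.  If every
    column is constant no indicator discriminates and weighting is
    impossible — a hard error by default (see ``uniform_fallback`` on
    :class:`EntropyWeighter` for robustness studies).
    """
    entropies = np.asarray(entropies, dtype=float)
    if np.any((entropies < -1e-12) | (entropies > 1 + 1e-12)):
        raise ValueError("entropies must lie in [0, 1]")
    div = np.clip(1.0 - entropies, 0.0, None)
    total = div.sum()
    if total <= 0:
        raise ValueError(
            "all indicator columns are constant: no discriminating information"
        )
    return div / total


class EntropyWeighter(BaseEstimator):
    """Estimator computing entropy weights from a decision matrix.

    Parameters
    ----------
    uniform_fallback : bool, default False
        When every column is constant, return uniform weights instead of
        raising.  Off by default: an all-constant matrix almost always
        signals an upstream data problem, and silently equal weights
        would hide it.

    Attributes
    ----------
    shares_ : (m, n) column-share matrix.
    entropies_ : (n,) per-indicator entropy in [0, 1].
    divergences_ : (n,) 1 - entropy.
    weights_ : (n,) normalized weights.
    feature_names_in_ : indicator names when fit on a DecisionMatrix.
    """

    def __init__(self, uniform_fallback: bool = False):
        self.uniform_fallback = uniform_fallback

    def fit(self, X: DecisionMatrix | np.ndarray, y=None) -> "EntropyWeighter":
        names = X.indicators if isinstance(X, DecisionMatrix) else None
        shares = entropy_shares(X)
        ent = entropy_values(shares)
        try:
            weights = divergence_weights(ent)
        except ValueError:
            if not self.uniform_fallback:
                raise
            weights = np.full(ent.shape, 1.0 / len(ent))
        self.shares_ = shares
        self.entropies_ = ent
        self.divergences_ = 1.0 - ent
        self.weights_ = weights
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def transform(self, X: DecisionMatrix | np.ndarray) -> np.ndarray:
        """Column shares of ``X`` scaled by the fitted weights."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("EntropyWeighter is not fitted")
        return entropy_shares(X) * self.weights_

    def result(self) -> EntropyResult:
        if not hasattr(self, "weights_"):
            raise RuntimeError("EntropyWeighter is not fitted")
        names = tuple(getattr(self, "feature_names_in_", ()))
        return EntropyResult(
            indicators=names,
            shares=self.shares_,
            entropies=self.entropies_,
            divergences=self.divergences_,
            weights=self.weights_,
        )


def compute_entropy_weights(matrix: DecisionMatrix | np.ndarray) -> EntropyResult:
    """End-to-end entropy weighting: shares → entropies → weights."""
    est = EntropyWeighter().fit(matrix)
    if not isinstance(matrix, DecisionMatrix) and not hasattr(
        est, "feature_names_in_"
    ):
        est.feature_names_in_ = np.asarray(
            [f"x{j}" for j in range(est.weights_.shape[0])], dtype=object
        )
    return est.result()
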