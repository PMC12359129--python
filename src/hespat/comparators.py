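"""Cross-method validation: TOPSIS, EDAS, WASPAS, VIKOR vs CoCoSo.

The same weighted decision matrix is ranked by four further MCDM
methods in their canonical published formulations, and agreement
between every method pair is quantified by Spearman's rank
correlation.  Rankings are harmonized so rank 1 is always the best
alternative, whether the method maximizes its score (TOPSIS closeness,
EDAS appraisal, WASPAS joint score, CoCoSo Ci) or minimizes it
(VIKOR Q).

Formulation defaults (configurable per call):

* TOPSIS — vector (root-sum-square) column normalization, weighted
  Euclidean distances to the ideal and anti-ideal points, closeness
  d⁻/(d⁺ + d⁻).
* EDAS — positive/negative distances from the column-average solution,
  weighted sums normalized by their maxima, appraisal (NSP + NSN)/2.
* WASPAS — linear max normalization, joint score
  λ_w·WSM + (1-λ_w)·WPM with λ_w = 0.5.
* VIKOR — min-max normalized group utility S and individual regret R,
  Q = v·(S-S*)/(S⁻-S*) + (1-v)·(R-R*)/(R⁻-R*) with v = 0.5; ranked by
  ascending Q (the compromise-set conditions are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.base import BaseEstimator

from .cocoso import minmax_normalize, rank_cocoso
from .entropy import compute_entropy_weights
from .matrix import DecisionMatrix

__all__ = [
    "METHODS",
    "MethodRanking",
    "AgreementMatrix",
    "MCDMRanker",
    "run_comparator",
    "spearman_rho",
    "agreement_study",
]

METHODS = ("cocoso", "topsis", "edas", "waspas", "vikor")


@dataclass(frozen=True)
class MethodRanking:
    method: str
    countries: tuple[str, ...]
    score: np.ndarray
    rank: np.ndarray            # 1 = best, competition ranking


@dataclass(frozen=True)
class AgreementMatrix:
    methods: tuple[str, ...]
    rho: np.ndarray             # symmetric, unit diagonal


def _prep(matrix, weights, orientation):
    scores = matrix.scores if isinstance(matrix, DecisionMatrix) else np.asarray(
        matrix, dtype=float
    )
    countries = (
        matrix.countries
        if isinstance(matrix, DecisionMatrix)
        else tuple(f"a{i}" for i in range(scores.shape[0]))
    )
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != scores.shape[1]:
        raise ValueError("weights length does not match indicator count")
    n = scores.shape[1]
    if orientation is None:
        orient = ("benefit",) * n
    elif isinstance(orientation, str):
        orient = (orientation,) * n
    else:
        orient = tuple(orientation)
    benefit = np.array([o == "benefit" for o in orient])
    return scores, countries, w, benefit


def _ranks_desc(score: np.ndarray) -> np.ndarray:
    return rankdata(-score, method="min").astype(int)


def _topsis(scores, w, benefit):
    norm = np.linalg.norm(scores, axis=0)
    norm[norm == 0] = 1.0
    r = scores / norm
    v = r * w
    ideal = np.where(benefit, v.max(axis=0), v.min(axis=0))
    anti = np.where(benefit, v.min(axis=0), v.max(axis=0))
    d_plus = np.linalg.norm(v - ideal, axis=1)
    d_minus = np.linalg.norm(v - anti, axis=1)
    denom = d_plus + d_minus
    denom[denom == 0] = 1.0
    return d_minus / denom                      # closeness, larger better


def _edas(scores, w, benefit):
    av = scores.mean(axis=0)
    av_safe = np.where(av == 0, 1.0, av)
    diff = scores - av
    pda = np.where(benefit, np.maximum(diff, 0), np.maximum(-diff, 0)) / av_safe
    nda = np.where(benefit, np.maximum(-diff, 0), np.maximum(diff, 0)) / av_safe
    sp = pda @ w
    sn = nda @ w
    nsp = sp / sp.max() if sp.max() > 0 else np.ones_like(sp)
    nsn = 1 - sn / sn.max() if sn.max() > 0 else np.ones_like(sn)
    return (nsp + nsn) / 2                      # appraisal, larger better


def _waspas(scores, w, benefit, lam_w=0.5):
    hi = scores.max(axis=0)
    lo = scores.min(axis=0)
    n = np.empty_like(scores)
    for j in range(scores.shape[1]):
        if benefit[j]:
            n[:, j] = scores[:, j] / hi[j] if hi[j] > 0 else 1.0
        else:
            n[:, j] = lo[j] / scores[:, j] if np.all(scores[:, j] > 0) else 1.0
    wsm = n @ w
    with np.errstate(divide="ignore"):
        wpm = np.prod(np.where(n > 0, n, 1e-300) ** w, axis=1)
    return lam_w * wsm + (1 - lam_w) * wpm      # joint score, larger better


def _vikor(scores, w, benefit, v=0.5):
    best = np.where(benefit, scores.max(axis=0), scores.min(axis=0))
    worst = np.where(benefit, scores.min(axis=0), scores.max(axis=0))
    span = best - worst
    span[span == 0] = 1.0
    gap = w * (best - scores) / span
    S = gap.sum(axis=1)
    R = gap.max(axis=1)
    s_span = S.max() - S.min()
    r_span = R.max() - R.min()
    Q = np.zeros_like(S)
    if s_span > 0:
        Q += v * (S - S.min()) / s_span
    if r_span > 0:
        Q += (1 - v) * (R - R.min()) / r_span
    return Q                                     # smaller better


def run_comparator(
    matrix: DecisionMatrix | np.ndarray,
    weights: np.ndarray,
    method: str,
    orientation: Sequence[str] | str | None = None,
    lam: float = 0.5,
    waspas_lambda: float = 0.5,
    vikor_v: float = 0.5,
) -> MethodRanking:
    """Rank a weighted decision matrix with one MCDM method.

    ``method`` is one of ``cocoso``, ``topsis``, ``edas``, ``waspas``,
    ``vikor``.  Rank 1 is the best alternative for every method.
    """
    scores, countries, w, benefit = _prep(matrix, weights, orientation)
    if method == "cocoso":
        res = rank_cocoso(matrix, weights=w, lam=lam, orientation=orientation)
        return MethodRanking("cocoso", countries, res.Ci, res.rank)
    if method == "topsis":
        score = _topsis(scores, w, benefit)
        return MethodRanking("topsis", countries, score, _ranks_desc(score))
    if method == "edas":
        score = _edas(scores, w, benefit)
        return MethodRanking("edas", countries, score, _ranks_desc(score))
    if method == "waspas":
        score = _waspas(scores, w, benefit, waspas_lambda)
        return MethodRanking("waspas", countries, score, _ranks_desc(score))
    if method == "vikor":
        if scores.shape[0] < 2:
            raise ValueError("VIKOR needs at least 2 alternatives")
        q = _vikor(scores, w, benefit, vikor_v)
        rank = rankdata(q, method="min").astype(int)   # ascending Q
        return MethodRanking("vikor", countries, q, rank)
    raise ValueError(f"unknown method {method!r}")


class MCDMRanker(BaseEstimator):
    """Estimator facade over :func:`run_comparator`.

    ``weights="entropy"`` derives weights from the fitted matrix.
    Fitted attributes: ``score_``, ``ranks_``, ``countries_``.
    """

    def __init__(
        self,
        method: str = "cocoso",
        weights="entropy",
        orientation=None,
        lam: float = 0.5,
        waspas_lambda: float = 0.5,
        vikor_v: float = 0.5,
    ):
        self.method = method
        self.weights = weights
        self.orientation = orientation
        self.lam = lam
        self.waspas_lambda = waspas_lambda
        self.vikor_v = vikor_v

    def fit(self, X, y=None) -> "MCDMRanker":
        if isinstance(self.weights, str) and self.weights == "entropy":
            w = compute_entropy_weights(X).weights
        else:
            w = np.asarray(self.weights, dtype=float)
        ranking = run_comparator(
            X,
            w,
            self.method,
            orientation=self.orientation,
            lam=self.lam,
            waspas_lambda=self.waspas_lambda,
            vikor_v=self.vikor_v,
        )
        self.weights_ = w
        self.score_ = ranking.score
        self.ranks_ = ranking.rank
        self.countries_ = ranking.countries
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).ranks_


def spearman_rho(rank_a, rank_b) -> float:
    """Spearman correlation of two rankings (average-rank tie handling)."""
    rank_a = np.asarray(rank_a, dtype=float)
    rank_b = np.asarray(rank_b, dtype=float)
    if rank_a.shape != rank_b.shape:
        raise ValueError("rankings must have equal length")
    if rank_a.size < 2:
        raise ValueError("need at least 2 alternatives")
    rho = spearmanr(rank_a, rank_b).statistic
    return float(rho)


def agreement_study(
    matrices: Sequence[DecisionMatrix],
    lam: float = 0.5,
    orientation=None,
    methods: Sequence[str] = METHODS,
    waspas_lambda: float = 0.5,
    vikor_v: float = 0.5,
) -> AgreementMatrix:
    """Mean cross-method Spearman agreement over assessment periods.

    Per period: entropy weights are computed, every method ranks the
    matrix, and pairwise rho is taken between rankings; the returned
    grid is the arithmetic mean across periods.
    """
    methods = tuple(methods)
    if not matrices:
        raise ValueError("need at least one period matrix")
    acc = np.zeros((len(methods), len(methods)))
    for matrix in matrices:
        w = compute_entropy_weights(matrix).weights
        rankings = [
            run_comparator(
                matrix,
                w,
                method,
                orientation=orientation,
                lam=lam,
                waspas_lambda=waspas_lambda,
                vikor_v=vikor_v,
            ).rank
            for method in methods
        ]
        for a in range(len(methods)):
            for b in range(len(methods)):
                acc[a, b] += (
                    1.0 if a == b else spearman_rho(rankings[a], rankings[b])
                )
    rho = acc / len(matrices)
    rho = (rho + rho.T) / 2
    np.fill_diagonal(rho, 1.0)
    return AgreementMatrix(methods=methods, rho=rho)
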