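"""Synthetic GHSI-like decision matrices with planted structure.

The generator emulates the statistical shape of a country × indicator
health-security score table: bounded 0-100 scores, per-indicator
dispersion profiles (so the entropy weighting has a known
highest-information indicator to recover), and additive performance
tiers (so composite-score clustering has a known partition to
recover).  Scores are drawn as

    score(i, j) = clip(base_mean_j + tier_offset(i)
                       + dispersion_j * noise_sd_j * z_ij, bounds)

with z_ij standard normal from one seeded generator per call.  The
clipping fraction is reported because heavy clipping would distort the
planted dispersion ordering.

Defaults mirror the EU-27 study's scale: 27 countries, the six GHSI
pillars, three tiers of 11/12/4 countries at offsets +15/0/-20, noise
sd 5 with dispersion multipliers (4, 2, 1, 1, 0.5, 0.5), and
GHSI-like pillar base means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .matrix import DEFAULT_BOUNDS, DecisionMatrix

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "eu_like_spec",
    "generate_matrix",
    "generate_panel",
    "DEFAULT_INDICATORS",
]

DEFAULT_INDICATORS = (
    "Prevention",
    "Detection and reporting",
    "Rapid response",
    "Health system",
    "Compliance with norms",
    "Risk environment",
)
# GHSI-like pillar levels and a steeply graded dispersion profile so
# the top-dispersion indicator is recoverable from entropy weights.
DEFAULT_BASE_MEANS = (55.0, 50.0, 45.0, 55.0, 65.0, 75.0)
DEFAULT_DISPERSION = (4.0, 2.0, 1.0, 1.0, 0.5, 0.5)
DEFAULT_TIERS = (("High", 11, 15.0), ("Intermediate", 12, 0.0), ("Dangerous", 4, -20.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic decision matrix."""

    m: int = 27
    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    base_means: tuple[float, ...] = DEFAULT_BASE_MEANS
    dispersion: tuple[float, ...] = DEFAULT_DISPERSION
    tiers: tuple[tuple[str, int, float], ...] = DEFAULT_TIERS
    noise_sd: float | tuple[float, ...] = 5.0
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    seed: int = 0
    period_label: str = "synthetic"

    def noise_vector(self) -> np.ndarray:
        n = len(self.indicators)
        sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (n,)
        ).astype(float)
        return sd

    def validate(self, enforce_offset_order: bool = True) -> None:
        n = len(self.indicators)
        if len(self.base_means) != n or len(self.dispersion) != n:
            raise ValueError("base_means/dispersion length must match indicators")
        counts = [c for _, c, _ in self.tiers]
        if sum(counts) != self.m:
            raise ValueError(
                f"tier counts {counts} sum to {sum(counts)}, expected m={self.m}"
            )
        offsets = [o for _, _, o in self.tiers]
        if enforce_offset_order and not all(
            a > b for a, b in zip(offsets, offsets[1:])
        ):
            raise ValueError("tier offsets must strictly decrease best to worst")
        vals = list(self.base_means) + list(self.dispersion) + list(offsets)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite spec parameters")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion multipliers must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure returned alongside a generated matrix."""

    tier: dict[str, int] = field(default_factory=dict)   # 1 = best tier
    tier_names: tuple[str, ...] = ()
    dispersion_rank: tuple[str, ...] = ()  # indicators, most dispersed first
    clip_fraction: float = 0.0


def eu_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default EU-scale spec with a chosen seed."""
    return replace(SyntheticSpec(seed=seed), **overrides)


def generate_matrix(
    spec: SyntheticSpec, _enforce_offset_order: bool = True
) -> tuple[DecisionMatrix, GroundTruth]:
    """Draw one decision matrix with planted tiers and dispersion order.

    Deterministic given ``spec.seed``; the ground truth carries the
    per-country tier (1 = best), the planted dispersion ordering of the
    indicators, and the fraction of cells affected by boundary
    clipping.
    """
    spec.validate(enforce_offset_order=_enforce_offset_order)
    rng = np.random.default_rng(spec.seed)
    n = len(spec.indicators)
    base = np.asarray(spec.base_means, dtype=float)
    scale = np.asarray(spec.dispersion, dtype=float) * spec.noise_vector()

    offsets = np.concatenate(
        [np.full(count, off) for _, count, off in spec.tiers]
    )
    tier_ids = np.concatenate(
        [np.full(count, t + 1, dtype=int) for t, (_, count, _) in enumerate(spec.tiers)]
    )
    z = rng.standard_normal((spec.m, n))
    raw = base[None, :] + offsets[:, None] + scale[None, :] * z
    lo, hi = spec.bounds
    clipped = np.clip(raw, lo, hi)
    clip_fraction = float(np.mean(clipped != raw))

    countries = tuple(f"C{i + 1:02d}" for i in range(spec.m))
    matrix = DecisionMatrix(
        countries=countries,
        indicators=spec.indicators,
        scores=clipped,
        period_label=spec.period_label,
        bounds=spec.bounds,
    )
    order = np.argsort(-scale, kind="stable")
    truth = GroundTruth(
        tier={c: int(t) for c, t in zip(countries, tier_ids)},
        tier_names=tuple(name for name, _, _ in spec.tiers),
        dispersion_rank=tuple(spec.indicators[j] for j in order),
        clip_fraction=clip_fraction,
    )
    return matrix, truth


def generate_panel(
    spec: SyntheticSpec,
    n_periods: int,
    drift: Sequence[Sequence[float]] | None = None,
) -> list[tuple[DecisionMatrix, GroundTruth]]:
    """Multi-period panel over a shared country set.

    ``drift[p]`` adjusts the tier offsets of period ``p`` (added to the
    spec's offsets), so cross-period rank and tier shifts are known by
    construction.  Tier identity is defined by the base spec, so
    drifted offsets may legitimately reorder tiers (a demoted tier
    sinking below a lower one); the strict offset ordering is enforced
    on the base spec only.  Period p uses seed ``spec.seed + p`` so
    periods differ while the panel stays deterministic.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if drift is not None and len(drift) != n_periods:
        raise ValueError("drift must have one entry per period")
    panel = []
    for p in range(n_periods):
        tiers = spec.tiers
        if drift is not None:
            adj = list(drift[p])
            if len(adj) != len(tiers):
                raise ValueError("drift entry length must match tier count")
            tiers = tuple(
                (name, count, off + d)
                for (name, count, off), d in zip(tiers, adj)
            )
        period_spec = replace(
            spec,
            tiers=tiers,
            seed=spec.seed + p,
            period_label=f"period{p + 1}",
        )
        panel.append(
            generate_matrix(period_spec, _enforce_offset_order=(drift is None))
        )
    return panel
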