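"""End-to-end orchestration: weights → CoCoSo → tiers → shifts → agreement.

A run is described by a :class:`RunConfig` (programmatic or YAML): one
decision matrix per (region, period), the CoCoSo balance coefficient,
the tier count and clustering restarts/seed, and output options.  All
internal computation stays at full float precision; rounding happens
only when tables are serialized, so downstream stages never consume
re-read rounded CSVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterResult, kmeans_scores
from .cocoso import CocosoResult, rank_cocoso
from .comparators import METHODS, AgreementMatrix, agreement_study
from .entropy import EntropyResult, compute_entropy_weights
from .matrix import (
    DEFAULT_BOUNDS,
    DecisionMatrix,
    read_decision_matrix,
    validate_matrix,
    write_table,
)
from .shifts import ShiftTable, rank_shift, shift_summary, weight_shift

__all__ = ["RunConfig", "PeriodResult", "ResultBundle", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and input that caused it."""

    def __init__(self, stage: str, key, message: str):
        super().__init__(f"[{stage}] {key}: {message}")
        self.stage = stage
        self.key = key


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    ``inputs`` maps (region, period) to a CSV/TSV path or an in-memory
    :class:`DecisionMatrix`.  Periods are compared pairwise in the
    order given within each region.
    """

    inputs: Mapping[tuple[str, str], str | Path | DecisionMatrix]
    lam: float = 0.5
    k: int = 3
    restarts: int = 50
    seed: int = 0
    orientation: Sequence[str] | str | None = None
    compare_methods: bool = True
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    out_dir: str | Path | None = None
    precision: int = 3
    methods: tuple[str, ...] = METHODS

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input matrix is required")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class PeriodResult:
    region: str
    period: str
    matrix: DecisionMatrix
    entropy: EntropyResult
    cocoso: CocosoResult
    clusters: ClusterResult


@dataclass
class ResultBundle:
    periods: dict[tuple[str, str], PeriodResult]
    rank_shifts: dict[tuple[str, str, str], ShiftTable] = field(default_factory=dict)
    tier_shifts: dict[tuple[str, str, str], ShiftTable] = field(default_factory=dict)
    weight_shifts: dict[tuple[str, str, str], ShiftTable] = field(default_factory=dict)
    shift_summaries: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    agreement: AgreementMatrix | None = None
    manifest: dict = field(default_factory=dict)


def _package_version() -> str:
    try:
        return version("hespat")
    except PackageNotFoundError:
        return "unknown"


def _load_input(key, source, config: RunConfig) -> DecisionMatrix:
    if isinstance(source, DecisionMatrix):
        return source
    path = Path(source)
    dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    return read_decision_matrix(
        path, dialect=dialect, bounds=config.bounds, period_label=key[1]
    )


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full workflow for every configured input.

    Per input: entropy weights → CoCoSo(λ) ranking → k-means tiers on
    the composite index.  For consecutive period pairs within a region:
    weight, rank, and tier shift tables plus the improvement summary.
    Optionally the five-method agreement study across all inputs.
    Tables are written under ``out_dir`` when configured.
    """
    bundle = ResultBundle(periods={})
    t0 = time.time()
    for key, source in config.inputs.items():
        region, period = key
        try:
            matrix = _load_input(key, source, config)
        except Exception as exc:
            raise PipelineError("read", key, str(exc)) from exc
        report = validate_matrix(matrix)
        for sev, loc, msg in report.issues:
            log.log(
                logging.ERROR if sev == "error" else logging.WARNING,
                "validate %s %s: %s", key, loc, msg,
            )
        if not report.ok:
            raise PipelineError("validate", key, "matrix failed validation")
        try:
            ent = compute_entropy_weights(matrix)
        except Exception as exc:
            raise PipelineError("entropy", key, str(exc)) from exc
        try:
            coc = rank_cocoso(
                matrix,
                weights=ent.weights,
                lam=config.lam,
                orientation=config.orientation,
            )
        except Exception as exc:
            raise PipelineError("cocoso", key, str(exc)) from exc
        try:
            clu = kmeans_scores(
                coc.Ci, k=config.k, restarts=config.restarts, seed=config.seed
            )
        except Exception as exc:
            raise PipelineError("cluster", key, str(exc)) from exc
        bundle.periods[key] = PeriodResult(
            region=region,
            period=period,
            matrix=matrix,
            entropy=ent,
            cocoso=coc,
            clusters=clu,
        )
        log.info("stage pipeline input=%s elapsed=%.2fs", key, time.time() - t0)

    # consecutive-period shifts within each region
    by_region: dict[str, list[tuple[str, PeriodResult]]] = {}
    for (region, period), res in bundle.periods.items():
        by_region.setdefault(region, []).append((period, res))
    for region, entries in by_region.items():
        for (pa, ra), (pb, rb) in zip(entries, entries[1:]):
            skey = (region, pa, pb)
            wa = pd.Series(ra.entropy.weights, index=list(ra.matrix.indicators))
            wb = pd.Series(rb.entropy.weights, index=list(rb.matrix.indicators))
            bundle.weight_shifts[skey] = weight_shift(wa, wb)
            ranks_a = pd.Series(ra.cocoso.rank, index=list(ra.matrix.countries))
            ranks_b = pd.Series(rb.cocoso.rank, index=list(rb.matrix.countries))
            rs = rank_shift(ranks_a, ranks_b)
            bundle.rank_shifts[skey] = rs
            tiers_a = pd.Series(ra.clusters.tier, index=list(ra.matrix.countries))
            tiers_b = pd.Series(rb.clusters.tier, index=list(rb.matrix.countries))
            bundle.tier_shifts[skey] = rank_shift(tiers_a, tiers_b)
            bundle.shift_summaries[skey] = shift_summary(rs)

    if config.compare_methods:
        bundle.agreement = agreement_study(
            [res.matrix for res in bundle.periods.values()],
            lam=config.lam,
            orientation=config.orientation,
            methods=config.methods,
        )

    bundle.manifest = {
        "package_version": _package_version(),
        "lambda": config.lam,
        "k": config.k,
        "restarts": config.restarts,
        "seed": config.seed,
        "precision": config.precision,
        "inputs": {
            f"{region}|{period}": (
                str(src) if not isinstance(src, DecisionMatrix) else "<in-memory>"
            )
            for (region, period), src in config.inputs.items()
        },
    }

    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: ResultBundle, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.precision
    for (region, period), res in bundle.periods.items():
        tag = f"{region}_{period}".replace(" ", "_")
        write_table(
            pd.DataFrame(
                {
                    "indicator": list(res.matrix.indicators),
                    "entropy": res.entropy.entropies,
                    "divergence": res.entropy.divergences,
                    "weight": res.entropy.weights,
                }
            ),
            out / f"weights_{tag}.csv",
            precision=p,
        )
        write_table(
            pd.DataFrame(
                {
                    "country": list(res.matrix.countries),
                    "CS": res.cocoso.CS,
                    "P": res.cocoso.P,
                    "ka": res.cocoso.ka,
                    "kb": res.cocoso.kb,
                    "kc": res.cocoso.kc,
                    "Ci": res.cocoso.Ci,
                    "rank": res.cocoso.rank,
                }
            ),
            out / f"cocoso_{tag}.csv",
            precision=p,
        )
        write_table(
            pd.DataFrame(
                {
                    "country": list(res.matrix.countries),
                    "Ci": res.cocoso.Ci,
                    "tier": res.clusters.tier,
                }
            ),
            out / f"clusters_{tag}.csv",
            precision=p,
        )
    for (region, pa, pb), table in bundle.rank_shifts.items():
        tag = f"{region}_{pa}_vs_{pb}".replace(" ", "_")
        write_table(table.to_frame(), out / f"rank_shifts_{tag}.csv", precision=p)
        write_table(
            bundle.weight_shifts[(region, pa, pb)].to_frame(),
            out / f"weight_shifts_{tag}.csv",
            precision=p,
        )
        write_table(
            bundle.shift_summaries[(region, pa, pb)],
            out / f"shift_summary_{tag}.csv",
            precision=p,
        )
    if bundle.agreement is not None:
        frame = pd.DataFrame(
            bundle.agreement.rho,
            index=list(bundle.agreement.methods),
            columns=list(bundle.agreement.methods),
        )
        frame.index.name = "method"
        write_table(frame, out / "agreement.csv", precision=6)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2), encoding="utf-8"
    )


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML document.

    Expected shape::

        inputs:
          - region: European Union
            period: "2019"
            path: eu_2019.csv
        lambda: 0.5
        k: 3
        restarts: 50
        seed: 0
        out_dir: results/
        precision: 3
        compare_methods: true
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    inputs = {
        (str(item["region"]), str(item["period"])): item["path"]
        for item in doc["inputs"]
    }
    return RunConfig(
        inputs=inputs,
        lam=float(doc.get("lambda", 0.5)),
        k=int(doc.get("k", 3)),
        restarts=int(doc.get("restarts", 50)),
        seed=int(doc.get("seed", 0)),
        orientation=doc.get("orientation"),
        compare_methods=bool(doc.get("compare_methods", True)),
        out_dir=doc.get("out_dir"),
        precision=int(doc.get("precision", 3)),
    )
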