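"""Config-driven end-to-end richness analysis.

Synthesizes (or ingests) survey tables, builds per-region and pooled
global incidence, runs every estimator, and emits a Table-style report
(sampling units, S_obs, coverage %, Chao2 ± CI, Chao2_adj ± CI, species
still to be discovered, share of global richness), accumulation curves,
rarity tables, the 2^R − 1 partition table, and a JSON run manifest.

The global row is always estimated independently on the pooled
incidence, never by summing regional estimates: species shared between
regions and estimator nonlinearity make the pooled estimate smaller
than the regional sum, and that gap is informative, not an error.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up
from .accumulation import accumulation_with_bands
from .estimators import (
    adjusted_chao2,
    chao2,
    chao2_ci,
    estimate_true_uniques,
    sample_coverage,
)
from .grid import GridIncidence, assign_cells, build_incidence, read_records, tally_frequencies
from .partition import partition_richness, pool_subset, rarity_metrics, to_be_discovered
from .synthetic import (
    WorldConfig,
    generate_world,
    inject_misidentification,
    sample_abundance_survey,
    sample_occurrence_survey,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "report_share"]

GLOBAL_LABEL = "Global"

REPORT_COLUMNS = [
    "region", "sampling_units", "species_observed", "coverage_pct",
    "chao2", "chao2_ci_lower", "chao2_ci_upper",
    "chao2_adj", "chao2_adj_ci_lower", "chao2_adj_ci_upper",
    "to_be_discovered", "share_of_global_pct",
]


@dataclass
class RunConfig:
    """One reproducible analysis run.

    Exactly one input mode: ``world`` (synthetic) or the two file paths.
    ``seed`` governs every stochastic stage (synthesis, bootstrap bands)
    and is echoed into all output artifacts.
    """

    world: WorldConfig | None = None
    abundance_path: str | None = None
    occurrence_path: str | None = None
    seed: int = 0
    ci_level: float = 0.95
    squared_first_term: bool = False
    curve_replicates: int = 200
    compute_curves: bool = True
    compute_partition: bool = True
    partition_estimator: str = "chao2_adj"
    outdir: str | None = None

    def __post_init__(self):
        synthetic = self.world is not None
        files = self.abundance_path is not None or self.occurrence_path is not None
        if synthetic == files:
            raise ValueError(
                "exactly one input mode: give a WorldConfig or survey file paths"
            )
        if synthetic:
            self.world.seed = self.seed


@dataclass
class RunResult:
    report: pd.DataFrame
    rarity: pd.DataFrame
    partition: pd.DataFrame | None
    curves: pd.DataFrame | None
    manifest: dict
    incidences: dict[str, GridIncidence] = field(repr=False, default_factory=dict)


def report_share(region_adjusted: float, global_adjusted: float) -> tuple[int, float]:
    """A region's share of global estimated richness.

    Returns ``(display, exact)``: the half-up-rounded integer percentage
    for reporting and the unrounded value.
    """
    if global_adjusted <= 0:
        raise ValueError("global_adjusted must be > 0")
    exact = 100.0 * region_adjusted / global_adjusted
    return int(round_half_up(exact)), exact


def _load_records(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Synthesize or read the combined record table."""
    meta: dict = {}
    if config.world is not None:
        world = generate_world(config.world)
        abund = sample_abundance_survey(world)
        occ = sample_occurrence_survey(world)
        frames = [f for f in (abund, occ) if not f.empty]
        if not frames:
            raise ValueError("synthetic surveys produced no records")
        records = pd.concat(frames, ignore_index=True)
        misid_map: dict = {}
        if config.world.misid_rate > 0:
            records, misid_map = inject_misidentification(
                records, config.world.misid_rate, config.seed
            )
        meta["mode"] = "synthetic"
        meta["true_richness"] = world.truth_summary()
        meta["n_misidentified_species"] = len(misid_map)
        return records, meta

    frames = []
    if config.abundance_path:
        frames.append(read_records(config.abundance_path, "abundance"))
    if config.occurrence_path:
        frames.append(read_records(config.occurrence_path, "occurrence"))
    records = pd.concat(frames, ignore_index=True)
    meta["mode"] = "files"
    return records, meta


def _estimate_row(inc: GridIncidence, config: RunConfig) -> dict:
    counts = tally_frequencies(inc)
    cov = sample_coverage(counts)
    raw = chao2_ci(chao2(counts), level=config.ci_level)
    q1_hat, fallback = estimate_true_uniques(
        counts, squared_first_term=config.squared_first_term
    )
    adj = adjusted_chao2(counts, q1_hat, fallback_used=fallback, level=config.ci_level)
    tbd, tbd_clamped = to_be_discovered(adj.point, counts.s_obs)
    return {
        "region": inc.region,
        "sampling_units": inc.T,
        "species_observed": counts.s_obs,
        "coverage_pct": 100.0 * cov.c_n,
        "chao2": raw.point,
        "chao2_ci_lower": raw.ci_lower,
        "chao2_ci_upper": raw.ci_upper,
        "chao2_adj": adj.point,
        "chao2_adj_ci_lower": adj.ci_lower,
        "chao2_adj_ci_upper": adj.ci_upper,
        "to_be_discovered": tbd,
        "_q1_hat": q1_hat,
        "_fallback": fallback,
        "_tbd_clamped": tbd_clamped,
        "_counts": counts,
    }


def _rarity_rows(label: str, records: pd.DataFrame,
                 inc: GridIncidence, q1_hat: float) -> list[dict]:
    """Occurrence-mode (across cells) and abundance-mode (stems) rarity."""
    rows = []
    counts = tally_frequencies(inc)
    occ = rarity_metrics(counts, adjusted_singletons=q1_hat)
    rows.append({
        "region": label, "mode": "occurrence",
        "adjusted_singletons": q1_hat, "doubletons": counts.q2,
        "s_obs": counts.s_obs, "rare_count": occ.rare_count,
        "rarity_pct": 100.0 * occ.rarity_fraction, "s1_s2_ratio": occ.ratio,
    })
    ab = records.loc[(records["source"] == "abundance")]
    if label != GLOBAL_LABEL:
        ab = ab.loc[ab["region"] == label]
    if not ab.empty:
        per_species = ab.groupby("species")["stems"].sum()
        a_counts = tally_frequencies(per_species.to_dict(), mode="abundance")
        a_rar = rarity_metrics(a_counts)
        rows.append({
            "region": label, "mode": "abundance",
            "adjusted_singletons": a_counts.q1, "doubletons": a_counts.q2,
            "s_obs": a_counts.s_obs, "rare_count": a_rar.rare_count,
            "rarity_pct": 100.0 * a_rar.rarity_fraction, "s1_s2_ratio": a_rar.ratio,
        })
    return rows


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and (optionally) write artifacts to ``outdir``."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    records, meta = _load_records(config)
    if records.empty:
        raise ValueError("no input records; nothing to analyze")
    records, rejections = assign_cells(records)
    timings["ingest_s"] = time.perf_counter() - t0

    regions = sorted(records["region"].unique())
    if not regions:
        raise ValueError("no regions present after ingest")
    incidences = {r: build_incidence(records, r) for r in regions}

    rows, rarity_rows = [], []
    for r in regions:
        row = _estimate_row(incidences[r], config)
        rarity_rows.extend(_rarity_rows(r, records, incidences[r], row["_q1_hat"]))
        rows.append(row)

    if len(regions) > 1:
        global_inc = pool_subset(incidences, regions)
        global_inc.region = GLOBAL_LABEL
    else:
        global_inc = incidences[regions[0]]
    global_row = _estimate_row(global_inc, config)
    global_row["region"] = GLOBAL_LABEL
    rarity_rows.extend(
        _rarity_rows(GLOBAL_LABEL, records, global_inc, global_row["_q1_hat"])
    )
    timings["estimators_s"] = time.perf_counter() - t0 - timings["ingest_s"]

    g_adj = global_row["chao2_adj"]
    for row in rows:
        row["share_of_global_pct"] = report_share(row["chao2_adj"], g_adj)[1]
    global_row["share_of_global_pct"] = 100.0
    report = pd.DataFrame(
        [{k: r[k] for k in REPORT_COLUMNS} for r in [global_row] + rows]
    )
    rarity = pd.DataFrame(rarity_rows)

    curves = None
    if config.compute_curves:
        t1 = time.perf_counter()
        pieces = [
            accumulation_with_bands(
                incidences[r], n_random=config.curve_replicates,
                seed=config.seed, level=config.ci_level,
            ).to_frame()
            for r in regions
        ]
        pieces.append(
            accumulation_with_bands(
                global_inc, n_random=config.curve_replicates,
                seed=config.seed, level=config.ci_level,
            ).to_frame()
        )
        curves = pd.concat(pieces, ignore_index=True)
        timings["curves_s"] = time.perf_counter() - t1

    partition = None
    if config.compute_partition and len(regions) >= 2:
        t1 = time.perf_counter()
        table = partition_richness(incidences, estimator=config.partition_estimator)
        partition = table.to_frame()
        meta["partition_residual"] = table.residual
        meta["endemic"] = table.endemic
        meta["shared_all_regions"] = table.shared_all
        timings["partition_s"] = time.perf_counter() - t1

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "records_read": int(len(records)) + sum(rejections.values()),
        "records_rejected": rejections,
        "regions": regions,
        "fallback_regions": [
            r["region"] for r in [global_row] + rows if r["_fallback"]
        ],
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        **meta,
    }

    result = RunResult(report=report, rarity=rarity, partition=partition,
                       curves=curves, manifest=manifest, incidences=incidences)
    if config.outdir:
        _write_artifacts(result, Path(config.outdir))
    return result


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    if echo.get("world") and echo["world"].get("sharing_matrix") is not None:
        echo["world"]["sharing_matrix"] = np.asarray(
            echo["world"]["sharing_matrix"]
        ).tolist()
    return echo


def _write_artifacts(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(outdir / "report.csv", index=False)
    result.rarity.to_csv(outdir / "rarity.csv", index=False)
    if result.partition is not None:
        result.partition.to_csv(outdir / "partition.csv", index=False)
    if result.curves is not None:
        result.curves.to_csv(outdir / "curves.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True, default=str)
    logger.info("wrote artifacts to %s", outdir)
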