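"""End-to-end orchestration: simulate → analyze every stage per scenario.

The pipeline regenerates the three-scenario synthetic study and pushes each
data stream through its analysis: flux logs through the resistance/decline
stage, FTIR series through 2D correlation spectroscopy, EEM cubes through
the fluorescence-quotient comparison, predictor tables through commonality
partitioning and abundance tables through network-role analysis.  Artifacts
are written per stage as CSV/TSV/JSON; a combined ``summary.json`` and the
serialized config make a run reproducible from its output directory alone.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import cos2d, eemfq, hydraulics, io, micronet, synthdata, varpart
from .config import RunConfig

logger = logging.getLogger("foulcast.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and scenario names."""

    def __init__(self, stage: str, scenario: str | None, cause: Exception):
        self.stage = stage
        self.scenario = scenario
        where = f"stage {stage!r}" + (f", scenario {scenario!r}" if scenario else "")
        super().__init__(f"pipeline aborted in {where}: {cause}")


def _run_stage(stage, scenario, fn):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:  # partial outputs remain on disk
        raise StageError(stage, scenario, exc) from exc
    logger.info("stage %-8s %-5s done in %.2fs", stage, scenario or "-", time.perf_counter() - t0)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    summary: dict = {"scenarios": {s: {} for s in config.scenarios}, "cross_scenario": {}}
    eem_cubes: dict[str, eemfq.EEMCube] = {}
    network_nodes: dict[str, list[str]] = {}
    all_taxa: list[str] = []

    try:
        for scen in config.scenarios:
            sdir = out / scen
            sdir.mkdir(exist_ok=True)
            block = summary["scenarios"][scen]

            if config.stages["flux"]:
                block["flux"] = _run_stage("flux", scen, lambda: _flux_stage(config, scen, sdir))
            if config.stages["ftir"]:
                block["ftir"] = _run_stage("ftir", scen, lambda: _ftir_stage(config, scen, sdir))
            if config.stages["eem"]:
                cube = _run_stage("eem", scen, lambda: _eem_stage(config, scen, sdir))
                eem_cubes[scen] = cube
                block["eem"] = {"n_samples": cube.n_samples}
            if config.stages["varpart"]:
                block["varpart"] = _run_stage(
                    "varpart", scen, lambda: _varpart_stage(config, scen, sdir)
                )
            if config.stages["network"]:
                net = _run_stage("network", scen, lambda: _network_stage(config, scen, sdir))
                block["network"] = net["summary"]
                network_nodes[scen] = net["nodes"]
                all_taxa = net["all_taxa"]

        if config.stages["eem"] and set(eem_cubes) >= {"Ctrl", "Al", "Fe"}:
            summary["cross_scenario"]["fq_regions"] = _run_stage(
                "eem", None, lambda: _fq_stage(eem_cubes, out)
            )
        if config.stages["network"] and network_nodes:
            sets = {"Feed": all_taxa, **network_nodes}
            summary["cross_scenario"]["otu_venn"] = micronet.otu_venn(sets)
    finally:
        io.write_json(summary, out / "summary.json")
        logger.removeHandler(handler)
        handler.close()
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _flux_stage(config: RunConfig, scen: str, sdir: Path) -> dict:
    kw = dict(config.overrides.get("flux", {}))
    log, truth = synthdata.gen_flux_series(scen, seed=config.stage_seed("flux", scen), **kw)
    io.write_flux_log(log, sdir / "flux_log.csv")
    res = hydraulics.resistance_series(log)
    res.to_csv(sdir / "resistance.csv", index=False)
    decline = hydraulics.percent_flux_decline(log["flux_lmh"])
    return {
        "decline_pct": round(float(decline), 3),
        "expected_decline_pct": round(float(truth["expected_decline_pct"]), 3),
        "final_fouling_resistance_m-1": float(res["R_f"].iloc[-1]),
    }


def _ftir_stage(config: RunConfig, scen: str, sdir: Path) -> dict:
    kw = dict(config.overrides.get("ftir", {}))
    series, truth = synthdata.gen_ftir_series(scen, seed=config.stage_seed("ftir", scen), **kw)
    io.write_spectra_csv(series, sdir / "ftir_series.csv")
    maps = cos2d.correlation_maps(series)
    peaks = cos2d.autopeaks(maps.synchronous, maps.wavenumbers)
    bands = [b.center for b in truth["bands"]]
    seq = cos2d.sequence_order(maps.synchronous, maps.asynchronous, maps.wavenumbers, bands)
    report = {
        "n_autopeaks": len(peaks),
        "autopeaks_cm-1": [p[0] for p in peaks],
        "band_order": {f"{c:g}": r for c, r in sorted(seq.ranks.items(), key=lambda kv: kv[1])},
        "planted_order": {f"{c:g}": r for c, r in truth["onset_ranks"].items()},
        "inconsistent_triads": seq.inconsistent_triads,
    }
    io.write_json(report, sdir / "cos2d_report.json")
    return {"n_autopeaks": len(peaks), "n_bands_planted": truth["n_bands"]}


def _eem_stage(config: RunConfig, scen: str, sdir: Path) -> eemfq.EEMCube:
    kw = dict(config.overrides.get("eem", {}))
    cube, _ = synthdata.gen_eem_set(scen, seed=config.stage_seed("eem", scen), **kw)
    io.write_eem_cube(cube, sdir / "eem")
    return cube


def _fq_stage(cubes: dict, out: Path) -> dict:
    norm = {s: eemfq.normalize_eem(c) for s, c in cubes.items()}
    pairs = {
        "ctrl_al": eemfq.fq_map(norm["Ctrl"], norm["Al"]),
        "ctrl_fe": eemfq.fq_map(norm["Ctrl"], norm["Fe"]),
        "al_fe": eemfq.fq_map(norm["Al"], norm["Fe"]),
    }
    fdir = out / "fq"
    fdir.mkdir(exist_ok=True)
    for name, fq in pairs.items():
        io.write_fq_map(fq, fdir / f"fq_{name}.csv", fdir / f"fq_{name}_mask.csv")
    labels, counts = eemfq.prominent_regions(
        pairs["ctrl_al"], pairs["ctrl_fe"], pairs["al_fe"]
    )
    np.savetxt(fdir / "prominent_labels.csv", labels, fmt="%d", delimiter=",")
    return counts


def _varpart_stage(config: RunConfig, scen: str, sdir: Path) -> dict:
    kw = dict(config.overrides.get("varpart", {}))
    dataset, truth = synthdata.gen_fouling_dataset(
        scen, seed=config.stage_seed("varpart", scen), **kw
    )
    part, pct = varpart.variance_partition(dataset)
    report = {
        "R2_full": part.R2_full,
        "components": part.components,
        "percent_explained": pct,
        "targets": truth["target"].as_dict(),
        "suppression": part.suppression,
    }
    io.write_json(report, sdir / "varpart_report.json")
    return {k: round(v, 2) for k, v in pct.items()} | {"R2_full": round(part.R2_full, 4)}


def _network_stage(config: RunConfig, scen: str, sdir: Path) -> dict:
    kw = dict(config.overrides.get("network", {}))
    table, truth = synthdata.gen_abundance_table(seed=config.stage_seed("network", scen), **kw)
    io.write_abundance_tsv(table, sdir / "abundance.tsv")
    graph = micronet.build_network(
        table, method=truth["method"], threshold=truth["edge_threshold"]
    )
    partition, Q = micronet.detect_modules(graph)
    roles = micronet.zi_pi(graph, partition)
    io.write_graph(graph, sdir / "network.graphml")
    io.write_json(
        {
            "modularity": Q,
            "roles": [
                {"node": r.node, "zi": r.zi, "pi": r.pi, "role": r.role} for r in roles
            ],
        },
        sdir / "network_roles.json",
    )
    role_counts: dict[str, int] = {}
    for r in roles:
        role_counts[r.role] = role_counts.get(r.role, 0) + 1
    return {
        "summary": {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_modules": len(set(partition.values())),
            "modularity_Q": round(float(Q), 4),
            "role_counts": role_counts,
        },
        "nodes": sorted(graph.nodes),
        "all_taxa": list(table.index),
    }
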