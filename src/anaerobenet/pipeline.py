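"""End-to-end orchestration: differential calls -> gLV inference ->
consensus filter -> topology -> concordance, from a single run config.

Every stage writes plain-text outputs into the run directory, and a JSON
manifest records the seed, every threshold actually used, per-sign edge
counts and unmatched-edge counts, so a run can be audited and reproduced
exactly."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .concordance import match_edges, read_index_table, strength_index_regression
from .confidence import BrpAnnotation, ConsensusNetworkFilter
from .differential import differential_table
from .table import AbundanceTable, Thresholds, read_abundance_table
from .topology import export_graph, influential_report, top_k_edges

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths, thresholds and options for a full run."""

    meso_table: str
    thermo_table: str
    annotation: str
    indices: str | None = None
    output_dir: str = "anaerobenet_run"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    top_k: int = 100
    n_components: int | str = "auto"
    percent: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


def _check_exists(path: str | None, what: str) -> None:
    if path is not None and not Path(path).exists():
        raise FileNotFoundError(f"{what} file not found: {path}")


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    for p, what in (
        (config.meso_table, "mesophilic table"),
        (config.thermo_table, "thermophilic table"),
        (config.annotation, "annotation"),
        (config.indices, "trophic index"),
    ):
        _check_exists(p, what)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(thr, k)
            for k in (
                "high_cut",
                "low_cut",
                "fold_threshold",
                "t_cut",
                "early_min",
                "late_min",
                "p_threshold",
                "n_sim",
                "n_nbrp_sample",
            )
        },
        "top_k": config.top_k,
        "stages": {},
    }

    current_stage = "load"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage: %s", name)
        return time.perf_counter()

    try:
        t0 = stage("load")
        meso = read_abundance_table(config.meso_table, "mesophilic", percent=config.percent)
        thermo = read_abundance_table(config.thermo_table, "thermophilic", percent=config.percent)
        annotation = BrpAnnotation.read(config.annotation)
        manifest["stages"]["load"] = {"seconds": time.perf_counter() - t0}

        t0 = stage("differential")
        calls = differential_table(meso, thermo, thr)
        calls.to_csv(out / "differential_calls.tsv", sep="\t", index=False)
        manifest["stages"]["differential"] = {
            "seconds": time.perf_counter() - t0,
            "n_up": int((calls["direction"] == "UP").sum()),
            "n_dn": int((calls["direction"] == "DN").sum()),
        }

        for label, table in (("mesophilic", meso), ("thermophilic", thermo)):
            t0 = stage(f"network:{label}")
            filt = ConsensusNetworkFilter(
                n_sim=thr.n_sim,
                n_nbrp_sample=thr.n_nbrp_sample,
                p_threshold=thr.p_threshold,
                n_components=config.n_components,
                seed=config.seed,
            ).fit(table, annotation)
            net = filt.network_
            net.edges.to_csv(out / f"network_{label}.tsv", sep="\t", index=False)
            filt.raw_.edge_list().to_csv(
                out / f"raw_edges_{label}.tsv", sep="\t", index=False
            )
            top = top_k_edges(net, config.top_k) if net.n_edges else net
            top.edges.to_csv(out / f"network_{label}_top{config.top_k}.tsv", sep="\t", index=False)
            if top.n_edges:
                influential_report(top).to_csv(
                    out / f"topology_{label}.tsv", sep="\t", index=False
                )
                export_graph(top, out / f"network_{label}.graphml", "graphml")
                export_graph(top, out / f"network_{label}.gexf", "gexf")
            manifest["stages"][f"network:{label}"] = {
                "seconds": time.perf_counter() - t0,
                "n_edges": net.n_edges,
                "n_activation": int((net.edges["sign"] == "activation").sum()),
                "n_repression": int((net.edges["sign"] == "repression").sum()),
            }
            if label == "mesophilic" and config.indices is not None:
                t0 = stage("concordance")
                indices = read_index_table(config.indices, level="family")
                records, unmatched = match_edges(top, indices)
                records.to_csv(out / "concordance_records.tsv", sep="\t", index=False)
                conc: dict = {"seconds": 0.0, "n_matched": len(records), "n_unmatched": unmatched}
                for subset in ("positive", "negative"):
                    try:
                        res = strength_index_regression(records, subset)
                        conc[subset] = {
                            "n": res.n,
                            "slope": res.slope,
                            "intercept": res.intercept,
                            "r_squared": res.r_squared,
                            "p_value": res.p_value,
                        }
                    except ValueError as exc:
                        conc[subset] = {"error": str(exc)}
                conc["seconds"] = time.perf_counter() - t0
                manifest["stages"]["concordance"] = conc
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {current_stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
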