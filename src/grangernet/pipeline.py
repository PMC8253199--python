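"""End-to-end orchestration: panel -> stationarity screen -> pairwise
Granger tests -> weighted adjacency -> centrality report.

A run consumes either a panel file (long/wide CSV/TSV, possibly holding
several experimental conditions) or the built-in synthetic diet-study
preset, and emits, per condition, a self-contained output bundle:

    <out>/<condition>/transform_log.json   differencing decisions per variable
    <out>/<condition>/pairwise.tsv         one row per ordered variable pair
    <out>/<condition>/adjacency.tsv        V x V weighted adjacency
    <out>/<condition>/centrality.tsv       betweenness / out / in per variable
    <out>/<condition>/density.json         density, edge and test counts, hubs
    <out>/<condition>/graph.graphml        the thresholded weighted digraph
    <out>/config.yaml                      the effective configuration
    <out>/run.log                          every decision point, append-only

Numbers are stored at full precision; ``paper_style=True`` additionally
writes ``centrality_2dp.tsv`` rounded to 2 decimals (half away from zero)
in the shape journals print such tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import network as net_mod
from .granger import pairwise_matrix
from .panel import PanelDataset, read_panel, read_conditions
from .stationarity import ensure_stationary
from .synthetic import DIET_CONDITIONS, diet_study_preset, simulate_panel_var

__all__ = ["PipelineConfig", "run_pipeline", "benjamini_hochberg"]


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    input: str | None = None            # panel file; None -> synthetic preset
    layout: str = "long"
    preset: str = "diet"                # synthetic preset family
    conditions: tuple[str, ...] | None = None  # None -> all found/known
    lag_order: int = 1
    alpha: float = 0.05
    variance_mode: str = "clustered"
    n_boot: int = 499
    weight_mode: str = "wald"
    correction: str = "none"            # none | bh
    moments_mode: str = "simulated"
    n_moment_reps: int = 2000
    lags: int | str = "auto"
    deterministic: str = "intercept"
    max_diff: int = 2
    seed: int = 0
    output_dir: str = "grangernet_out"
    paper_style: bool = False

    def __post_init__(self):
        if self.correction not in ("none", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.conditions is not None:
            object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.seed is None and (
            self.moments_mode == "simulated" or self.variance_mode == "bootstrap"
            or self.input is None
        ):
            raise ValueError("seed is mandatory when any stochastic stage is active")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["conditions"] is not None:
            d["conditions"] = list(d["conditions"])
        return d


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def _condition_seed(seed: int, condition: str) -> int:
    import zlib

    key = zlib.crc32(condition.encode())
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(key,))
               .generate_state(1)[0] & 0x7FFFFFFF)


def _load_panels(config: PipelineConfig, log) -> dict[str, PanelDataset]:
    if config.input is not None:
        try:
            panels = read_conditions(config.input, layout=config.layout)
        except Exception:
            panels = {"all": read_panel(config.input, layout=config.layout)}
        if config.conditions:
            panels = {c: panels[c] for c in config.conditions}
        log(f"loaded {config.input}: conditions {sorted(panels)}")
        return panels
    conditions = config.conditions or DIET_CONDITIONS
    panels = {}
    for cond in conditions:
        spec = diet_study_preset(cond, seed=_condition_seed(config.seed, cond))
        panel, truth = simulate_panel_var(spec)
        panels[cond] = panel
        log(f"simulated preset condition {cond!r}: N={panel.n_subjects}, "
            f"T={panel.n_times}, V={panel.n_variables}, "
            f"{truth.n_edges} ground-truth edges")
    return panels


def _write_pairwise_tsv(path: str, results, adjusted=None) -> None:
    with open(path, "w") as fh:
        cols = ["cause", "effect", "lag", "beta_hpj", "rho_hpj", "wald", "df",
                "p_value"]
        if adjusted is not None:
            cols.append("p_adjusted")
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(results):
            row = [r.cause, r.effect, str(r.lag_order),
                   ",".join(repr(float(b)) for b in r.theta_hpj[r.lag_order:]),
                   ",".join(repr(float(b)) for b in r.theta_hpj[:r.lag_order]),
                   repr(r.wald), str(r.df), repr(r.p_value)]
            if adjusted is not None:
                row.append(repr(float(adjusted[i])))
            fh.write("\t".join(row) + "\n")


def _write_adjacency_tsv(path: str, net: net_mod.CausalNetwork) -> None:
    with open(path, "w") as fh:
        fh.write("cause\\effect\t" + "\t".join(net.nodes) + "\n")
        for j, v in enumerate(net.nodes):
            fh.write(v + "\t" + "\t".join(repr(float(w)) for w in net.weights[j]) + "\n")


def _write_centrality_tsv(path: str, report: net_mod.CentralityReport,
                          round_2dp: bool = False) -> None:
    fmt = (lambda x: f"{net_mod.round2(x):.2f}") if round_2dp else (lambda x: repr(float(x)))
    with open(path, "w") as fh:
        fh.write("variable\tbetweenness\toutdegree_centrality\tindegree_centrality\n")
        for v in report.nodes:
            fh.write("\t".join([
                v, fmt(report.betweenness[v]),
                fmt(report.outdegree_centrality[v]),
                fmt(report.indegree_centrality[v]),
            ]) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, dict]:
    """Execute the full workflow and write the output bundle.

    Returns a per-condition dict with the in-memory panel, test results,
    network, centrality report, and hub summary.  Two runs with the same
    config (seed included) produce byte-identical bundles.

    Stage errors abort with the stage name; partial outputs already
    flushed are accompanied by a FAILED marker file.
    """
    out_root = config.output_dir
    os.makedirs(out_root, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    def flush_log() -> None:
        with open(os.path.join(out_root, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")

    with open(os.path.join(out_root, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    stage = "load"
    try:
        panels = _load_panels(config, log)
        outputs: dict[str, dict] = {}
        for cond, panel in panels.items():
            cond_dir = os.path.join(out_root, cond)
            os.makedirs(cond_dir, exist_ok=True)

            stage = f"stationarity[{cond}]"
            stat_panel, stat_log = ensure_stationary(
                panel, alpha=config.alpha, max_diff=config.max_diff,
                deterministic=config.deterministic, lags=config.lags,
                moments_mode=config.moments_mode,
                n_moment_reps=config.n_moment_reps,
                seed=_condition_seed(config.seed, cond + "/llc"),
            )
            for v, entry in stat_log.items():
                log(f"[{cond}] stationarity {v}: diff_order={entry['diff_order']} "
                    f"stationary={entry['stationary']} "
                    f"p={entry['result'].p_value:.4f}")
                if not entry["stationary"]:
                    log(f"[{cond}] WARNING {entry['warning']}")
            with open(os.path.join(cond_dir, "transform_log.json"), "w") as fh:
                json.dump({v: {"diff_order": e["diff_order"],
                               "stationary": e["stationary"],
                               "p_value": e["result"].p_value}
                           for v, e in stat_log.items()}, fh, indent=2)

            stage = f"granger[{cond}]"
            results, failures = pairwise_matrix(
                stat_panel, p=config.lag_order,
                variance_mode=config.variance_mode, n_boot=config.n_boot,
                seed=_condition_seed(config.seed, cond + "/granger"),
                on_error="collect",
            )
            v_count = stat_panel.n_variables
            log(f"[{cond}] granger: {len(results)} of {v_count * (v_count - 1)} "
                f"ordered-pair tests completed, {len(failures)} failed")
            for c, e, msg in failures:
                log(f"[{cond}] WARNING pair {c}->{e} failed: {msg}")

            stage = f"network[{cond}]"
            adjusted = None
            if config.correction == "bh":
                adjusted = benjamini_hochberg([r.p_value for r in results])
                thresholded = [
                    dataclasses.replace(r, p_value=float(q))
                    for r, q in zip(results, adjusted)
                ]
                log(f"[{cond}] Benjamini-Hochberg correction applied over "
                    f"{len(results)} tests")
            else:
                thresholded = results
                log(f"[{cond}] no multiplicity correction (alpha={config.alpha} per pair)")
            net = net_mod.build_adjacency(
                thresholded, alpha=config.alpha, weight_mode=config.weight_mode,
                nodes=tuple(stat_panel.variables),
                warn=lambda m: log(f"[{cond}] WARNING {m}"),
            )
            report = net_mod.centrality_report(net)
            hubs = net_mod.hub_report(report)
            log(f"[{cond}] network: {net.n_edges} significant edges, "
                f"density={report.density:.4f}")

            _write_pairwise_tsv(os.path.join(cond_dir, "pairwise.tsv"),
                                results, adjusted)
            _write_adjacency_tsv(os.path.join(cond_dir, "adjacency.tsv"), net)
            _write_centrality_tsv(os.path.join(cond_dir, "centrality.tsv"), report)
            if config.paper_style:
                _write_centrality_tsv(
                    os.path.join(cond_dir, "centrality_2dp.tsv"), report,
                    round_2dp=True)
            with open(os.path.join(cond_dir, "density.json"), "w") as fh:
                json.dump({
                    "density": report.density,
                    "n_edges": report.n_edges,
                    "n_tests": len(results),
                    "n_failed_pairs": len(failures),
                    "hubs": hubs,
                }, fh, indent=2)
            net_mod.export_graph(net, os.path.join(cond_dir, "graph.graphml"),
                                 "graphml")
            net_mod.export_graph(net, os.path.join(cond_dir, "graph.dot"), "dot")

            outputs[cond] = {
                "panel": stat_panel, "stationarity": stat_log,
                "results": results, "failures": failures,
                "network": net, "report": report, "hubs": hubs,
            }
        flush_log()
        return outputs
    except Exception as err:
        log(f"FAILED at stage {stage}: {err}")
        flush_log()
        with open(os.path.join(out_root, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err
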