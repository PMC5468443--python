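"""End-to-end pipeline for the packaged mTOR-associated regulatory network.

The package ships the six-entity mTOR BRN (PI3K, PTEN, mTORC2, Akt, mTORC1,
FOXO) with its logical-parameter ranges, the retained parameterization, and
the three CTL observations used for inference.  ``run_pipeline`` re-derives
everything from those inputs: CTL-based parameter inference, the
asynchronous state graph with its stable states and attractors, betweenness
centrality, selection of the dominant homeostatic cycle, and the delay
(invariance-kernel) analysis of that cycle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

from . import delay_kernel as dk
from . import state_graph_analysis as sga
from .ctl_engine import read_formulas
from .logical_model import LogicalNetwork, Parameterization, read_model
from .parameter_inference import classify_by_stable_state, infer
from .state_dynamics import attractors, build_state_graph, stable_states

__all__ = ["model_path", "ctl_path", "builtin_model", "builtin_formulas",
           "PipelineConfig", "run_pipeline", "render_report"]

log = logging.getLogger(__name__)

_DATA = importlib_resources.files("brnkit") / "data"


def model_path() -> Path:
    return Path(str(_DATA / "mtor.yaml"))


def ctl_path() -> Path:
    return Path(str(_DATA / "mtor.ctl"))


def builtin_model() -> tuple[LogicalNetwork, Parameterization]:
    """The packaged mTOR network and its retained 26-entry parameterization."""
    net = read_model(model_path())
    assert net.selected is not None
    return net, net.selected


def builtin_formulas(network: LogicalNetwork | None = None):
    if network is None:
        network, _ = builtin_model()
    return read_formulas(ctl_path(), network)


@dataclass
class PipelineConfig:
    model: str | Path | None = None      # defaults to the packaged network
    ctl: str | Path | None = None        # defaults to the packaged formulas
    # The packaged mTOR run applies the Snoussi (inclusion-monotonicity)
    # condition: the admissible candidate space is the 50 monotone members
    # of the 128 range-products, of which CTL filtering retains 8.
    snoussi: bool = True
    cycle_scoring: str = "sum"
    max_cycle_len: int = sga.DEFAULT_MAX_LEN
    max_cycles: int = sga.DEFAULT_MAX_COUNT
    state_cap: int = 10**6


@dataclass
class Report:
    config: PipelineConfig
    data: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)


def _sid(state) -> str:
    return "".join(str(v) for v in state)


def run_pipeline(config: PipelineConfig | None = None) -> Report:
    """Run inference, dynamics, centrality/cycle selection and delay
    analysis; every stage is timed and logged."""
    config = config or PipelineConfig()
    report = Report(config)
    net = read_model(config.model) if config.model else builtin_model()[0]
    if net.selected is None:
        raise ValueError("model file has no selected parameterization")
    K = net.selected
    formulas = (read_formulas(config.ctl, net) if config.ctl
                else builtin_formulas(net))

    def stage(name):
        log.info("stage: %s", name)
        report.timings[name] = time.perf_counter()
        return name

    def done(name):
        report.timings[name] = round(time.perf_counter() - report.timings[name], 3)

    s = stage("inference")
    models = infer(net, formulas, snoussi=config.snoussi, cap=config.state_cap)
    selected_retained = any(m.K == K for m in models)
    done(s)
    report.data["inference"] = {
        "n_candidates": _n_candidates(net),
        "n_retained": len(models),
        "retained_indices": [m.index for m in models],
        "selected_parameterization_retained": selected_retained,
    }

    s = stage("state_graph")
    sg = build_state_graph(net, K, cap=config.state_cap)
    stables = stable_states(sg)
    rep = attractors(sg)
    done(s)
    out_deg_sum = sum(d for _, d in sg.graph.out_degree())
    assert out_deg_sum == sg.n_edges, "edge count / out-degree mismatch"
    report.data["state_graph"] = {
        "n_states": sg.n_states,
        "n_edges": sg.n_edges,
        "stable_states": [_sid(x) for x in stables],
        "n_attractors": rep.n_attractors,
        "attractors": [{"kind": k, "states": sorted(_sid(x) for x in a)}
                       for a, k in zip(rep.attractors, rep.kinds)],
    }
    if stables:
        cls = classify_by_stable_state(models, net, stables[0])
        report.data["inference"]["stable_state_classification"] = cls["counts"]

    s = stage("centrality_and_cycles")
    b = sga.betweenness(sg)
    cycles = sga.elementary_cycles(sg, max_count=config.max_cycles,
                                   max_len=config.max_cycle_len)
    ranking = sga.select_cycle(sg, cycles, scoring=config.cycle_scoring)
    best = ranking.best
    done(s)
    report.data["centrality"] = {
        "top_states": [
            {"state": _sid(st), "betweenness": val}
            for st, val in sorted(b.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        ],
    }
    report.data["cycles"] = {
        "n_elementary_circuits": len(cycles),
        "scoring": ranking.scoring,
        "selected_cycle": [_sid(st) for st in best.states],
        "ranking_head": [
            {"cycle": [_sid(st) for st in c.states], "score": score}
            for c, score in ranking.ranked[:5]
        ],
    }

    s = stage("delay_kernel")
    events, constants = dk.cycle_events(best, net.entity_order)
    system = dk.build_timing_system(events, len(best), constants)
    kernel = dk.project_delay_constraints(system)
    matrix = dk.relation_matrix(kernel)
    done(s)
    report.data["delay_kernel"] = {
        "constant_entities": constants,
        "events": [{"entity": e.entity, "direction": e.direction,
                    "position": e.position} for e in events],
        "kernel_constraints": [str(c) for c in kernel],
        "relation_matrix": {f"{a} vs {b}": r
                            for a, b, r in matrix.forced_pairs()},
        "n_forced_pairs": len(matrix.forced_pairs()),
        "relation_table": matrix.to_dataframe().to_dict(orient="split"),
    }
    return report


def _n_candidates(net: LogicalNetwork) -> int:
    n = 1
    for spec in net.parameter_specs:
        n *= len(spec.range)
    return n


def render_report(report: Report, outdir: str | Path) -> dict[str, Path]:
    """Write machine- (JSON) and human-readable renderings; deterministic
    content for identical inputs (timings live only in the text log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report.data, indent=2, sort_keys=True)
                         + "\n")
    lines = ["mTOR regulatory-network analysis report", ""]
    inf = report.data["inference"]
    lines += [
        f"candidate parameterizations : {inf['n_candidates']}",
        f"retained by CTL inference   : {inf['n_retained']}",
        f"packaged selection retained : {inf['selected_parameterization_retained']}",
        "",
    ]
    sgd = report.data["state_graph"]
    lines += [
        f"state graph                 : {sgd['n_states']} states, "
        f"{sgd['n_edges']} transitions",
        f"stable states               : {', '.join(sgd['stable_states']) or '-'}",
        f"attractors                  : {sgd['n_attractors']}",
        "",
    ]
    cyc = report.data["cycles"]
    lines += [
        f"elementary circuits (<= len {report.config.max_cycle_len}) : "
        f"{cyc['n_elementary_circuits']}",
        f"selected cycle ({cyc['scoring']} betweenness): "
        + " -> ".join(cyc["selected_cycle"]),
        "",
        "invariance-kernel delay constraints:",
    ]
    lines += [f"  {c}" for c in report.data["delay_kernel"]["kernel_constraints"]]
    lines += ["", "forced delay orderings:"]
    forced = report.data["delay_kernel"]["relation_matrix"]
    lines += [f"  {pair}: {rel}" for pair, rel in forced.items()] or ["  none"]
    lines += ["", "stage timings (s): "
              + ", ".join(f"{k}={v}" for k, v in report.timings.items())]
    txt_path = outdir / "report.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "text": txt_path}
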