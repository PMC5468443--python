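"""Parameter inference by exhaustive enumeration + CTL model checking.

Candidate logical parameterizations are the Cartesian product of the declared
per-parameter ranges; each candidate's asynchronous state graph is checked
against a set of CTL observations, and exactly those candidates satisfying
every formula in every state are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Iterator

from .ctl_engine import CTLFormula, model_satisfies
from .logical_model import (LogicalNetwork, Parameterization, regulators,
                            snoussi_holds)
from .state_dynamics import build_state_graph, state_graph_summary

__all__ = [
    "enumerate_parameterizations",
    "infer",
    "InferenceResult",
    "classify_by_stable_state",
    "write_inference_results",
]

log = logging.getLogger(__name__)


def _spec_keys(network: LogicalNetwork) -> list[tuple[str, frozenset]]:
    """All (target, resource-set) keys in deterministic order.

    Targets follow ``entity_order``; resource sets are ordered by size then
    sorted member names.
    """
    network.complete_specs()
    keys = []
    for target in network.entity_order:
        regs = regulators(network, target)
        for r in range(len(regs) + 1):
            for combo in combinations(regs, r):
                keys.append((target, frozenset(combo)))
    return keys


def enumerate_parameterizations(network: LogicalNetwork,
                                snoussi: bool = False
                                ) -> Iterator[Parameterization]:
    """Cartesian product of all parameter ranges, in deterministic order.

    With ``snoussi=True`` only parameterizations monotone over resource-set
    inclusion are yielded.
    """
    keys = _spec_keys(network)
    ranges = [network.spec_for(*key).range for key in keys]
    for values in product(*ranges):
        K = Parameterization(zip(keys, values))
        if snoussi and not snoussi_holds(network, K):
            continue
        yield K


@dataclass
class InferenceResult:
    """One retained model: its index in enumeration order, parameters and
    state-graph summary."""

    index: int
    K: Parameterization
    summary: dict


def infer(network: LogicalNetwork, formulas: Iterable[CTLFormula],
          snoussi: bool = False, log_every: int = 50,
          cap: int = 10**6) -> list[InferenceResult]:
    """Retain the candidates whose state graph satisfies all ``formulas``
    in every state (universal model-level satisfaction)."""
    formulas = list(formulas)
    retained = []
    for i, K in enumerate(enumerate_parameterizations(network, snoussi)):
        if log_every and i and i % log_every == 0:
            log.info("checked %d candidates, retained %d", i, len(retained))
        sg = build_state_graph(network, K, cap=cap)
        if all(model_satisfies(sg, f) for f in formulas):
            retained.append(InferenceResult(i, K, state_graph_summary(sg)))
    log.info("retained %d models", len(retained))
    return retained


def classify_by_stable_state(models: list[InferenceResult],
                             network: LogicalNetwork,
                             state) -> dict:
    """Partition retained models by stability of ``state``.

    Two readings are reported: models in which ``state`` is *a* stable state,
    and models in which it is the *unique* stable state.
    """
    state_id = "".join(str(v) for v in network.check_state(state))
    is_stable, is_unique, rest = [], [], []
    for m in models:
        stables = m.summary["stable_states"]
        if state_id in stables:
            is_stable.append(m)
            if len(stables) == 1:
                is_unique.append(m)
        else:
            rest.append(m)
    return {
        "state": state_id,
        "stable_in": is_stable,
        "unique_stable_in": is_unique,
        "not_stable_in": rest,
        "counts": {
            "stable": len(is_stable),
            "unique_stable": len(is_unique),
            "not_stable": len(rest),
        },
    }


def _K_record(network: LogicalNetwork, K: Parameterization) -> list[dict]:
    return [
        {"target": t, "resources": sorted(res), "value": K[(t, res)]}
        for t, res in _spec_keys(network)
    ]


def write_inference_results(models: list[InferenceResult],
                            network: LogicalNetwork,
                            path: str | Path) -> None:
    records = [
        {"index": m.index, "parameters": _K_record(network, m.K),
         "summary": m.summary}
        for m in models
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
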