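from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from offtargetnet.io_core import (
    DrugRecord,
    DrugTargetRow,
    DrugTargetTable,
    Interactome,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_interactome() -> Interactome:
    """T's neighbors are N1, N2; D2 will bind N1; X is an outside protein."""
    return Interactome(
        edges=[("T", "N1"), ("T", "N2"), ("N1", "X")],
    )


@pytest.fixture
def toy_drug_table() -> DrugTargetTable:
    records = {
        "D1": DrugRecord("D1", "drug-one", group="classA"),
        "D1b": DrugRecord("D1b", "drug-one-b", group="classA"),
        "D2": DrugRecord("D2", "drug-two"),
    }
    rows = (
        DrugTargetRow("D1", "T", "HUMAN"),
        DrugTargetRow("D1b", "T", "HUMAN"),
        DrugTargetRow("D2", "N1", "HUMAN"),
    )
    return DrugTargetTable(rows=rows, drugs=records)


def random_graph(rng, n_max: int = 8, p: float = 0.4,
                 self_pairs: bool = False) -> tuple[list[str], list[tuple[str, str]]]:
    """Random labeled graph for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if self_pairs:
        edges += [(v, v) for v in nodes if rng.random() < 0.2]
    return nodes, edges
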