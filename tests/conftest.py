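"""Shared fixtures: small hand-checkable graphs and event logs."""

import numpy as np
import pandas as pd
import pytest

from carefrag.event_log import from_frame
from carefrag.network import PatientSharingNetwork, from_mapping


@pytest.fixture
def barbell_net() -> PatientSharingNetwork:
    """Two unit-weight triangles joined by one unit edge (m = 7)."""
    return from_mapping({
        ("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1,
        ("d", "e"): 1, ("e", "f"): 1, ("d", "f"): 1,
        ("c", "d"): 1,
    })


@pytest.fixture
def two_cliques_net() -> PatientSharingNetwork:
    """Two 4-cliques joined by one unit edge; optimum is the two cliques."""
    w = {}
    for grp in ("abcd", "efgh"):
        for i in range(4):
            for j in range(i + 1, 4):
                w[(grp[i], grp[j])] = 1.0
    w[("d", "e")] = 1.0
    return from_mapping(w)


def random_weighted_net(rng: np.random.Generator, n: int,
                        p_edge: float = 0.5) -> PatientSharingNetwork:
    """Random graph on n nodes, integer weights 1..9, at least one edge."""
    nodes = [chr(97 + i) for i in range(n)]
    while True:
        w = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_edge:
                    w[(nodes[i], nodes[j])] = float(rng.integers(1, 10))
        if w:
            return from_mapping(w, nodes=nodes)


@pytest.fixture
def three_patient_log():
    """3 patients, 8 events; transitions enumerable by hand.

    p1: A, A, B        -> (A,A, kept) (A,B, fragmented)
    p2: C              -> none
    p3: B, C, C, A     -> (B,C, fragmented) (C,C, kept) (C,A, fragmented)
    """
    rows = [
        ("p1", "A", "2013-04-01", "OP", "L1"),
        ("p1", "A", "2013-04-10", "IP", "L1"),
        ("p1", "B", "2013-05-01", "AE", "L1"),
        ("p2", "C", "2013-04-02", "OP", "L2"),
        ("p3", "B", "2013-04-03", "AE", "L2"),
        ("p3", "C", "2013-04-20", "OP", "L2"),
        ("p3", "C", "2013-06-01", "OP", "L3"),
        ("p3", "A", "2013-07-01", "IP", "L2"),
    ]
    return from_frame(pd.DataFrame(
        rows, columns=["patient_id", "provider_code", "event_date", "setting",
                       "lsoa_code"]))
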