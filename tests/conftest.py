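"""Shared fixtures: toy ontologies and random-instance builders."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phenomatch.ontology import Ontology, Term, parse_obo

DIAMOND_OBO = """format-version: 1.2

[Term]
id: T:0000001
name: A
namespace: shared

[Term]
id: T:0000002
name: B
namespace: shared
is_a: T:0000001 ! A

[Term]
id: T:0000003
name: C
namespace: shared
is_a: T:0000001 ! A

[Term]
id: T:0000004
name: D
namespace: shared
is_a: T:0000002 ! B
is_a: T:0000003 ! C
"""


@pytest.fixture
def diamond():
    """A; B is_a A; C is_a A; D is_a B, C."""
    return parse_obo(DIAMOND_OBO)


def build_ontology(parents: dict[str, list[str]]) -> Ontology:
    """Ontology straight from a parent map (bypasses the OBO round trip)."""
    return Ontology(
        {
            tid: Term(id=tid, name=tid, namespace="shared", parents=tuple(sorted(ps)))
            for tid, ps in parents.items()
        }
    )


def random_dag(
    rng: np.random.Generator, n_terms: int, max_parents: int = 3, p_root: float = 0.12
) -> dict[str, list[str]]:
    """Random rooted DAG as a parent map; node 0 is always a root."""
    ids = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, list[str]] = {ids[0]: []}
    for i in range(1, n_terms):
        if rng.random() < p_root:
            parents[ids[i]] = []
        else:
            k = min(int(rng.integers(1, max_parents + 1)), i)
            picks = rng.choice(i, size=k, replace=False)
            parents[ids[i]] = sorted(ids[int(j)] for j in picks)
    return parents


def random_corpus(
    rng: np.random.Generator, parents: dict[str, list[str]], n_entities: int
) -> list[tuple[str, set[str]]]:
    ids = sorted(parents)
    return [
        (
            f"E{e}",
            {
                ids[int(j)]
                for j in rng.choice(len(ids), size=int(rng.integers(1, 5)), replace=False)
            },
        )
        for e in range(n_entities)
    ]
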