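"""Shared fixtures and helpers for the test suite.

All random structures are generated with explicit numpy seeds so every run
is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from ribophy.trees import parse_newick


def random_tree_newick(labels: list[str], rng, blen_range=(0.05, 0.5)) -> str:
    """Random binary tree over the labels by repeated random joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(*blen_range, size=2)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    return nodes[0] + ";"


def random_tree(n_leaves: int, rng, prefix: str = "t"):
    labels = [f"{prefix}{i:02d}" for i in range(n_leaves)]
    return parse_newick(random_tree_newick(labels, rng))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study_fixture():
    """One study-shaped two-locus fixture reused by several tests."""
    from ribophy.simulate import make_study_fixture

    return make_study_fixture(seed=42)
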