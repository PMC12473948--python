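import numpy as np
import pytest
from hypothesis import settings

from octagg import (ClusterPlant, PlantSpec, StackingCriteria, build_conformation,
                    load_registry)

# deterministic property tests; no wall-clock deadline on a loaded machine
settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def criteria():
    return StackingCriteria()


@pytest.fixture
def small_planted():
    """12 molecules: one f2f dimer, one e2f trimer, one offset dimer, 5 monomers."""
    spec = PlantSpec(
        n_molecules=12, box_edge=30.0,
        clusters=(ClusterPlant(2, "face-to-face"),
                  ClusterPlant(3, "edge-to-face"),
                  ClusterPlant(2, "offset-face-to-face")),
        seed=7)
    return spec, build_conformation(spec)


def brute_force_min_image(p, q, box):
    """Independent oracle: minimum distance over all 27 periodic images."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * np.asarray(box, float)
                best = min(best, float(np.linalg.norm(np.asarray(p) - np.asarray(q) + shift)))
    return best


class UnionFind:
    """Independent clustering oracle for contact graphs."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def partition(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}
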