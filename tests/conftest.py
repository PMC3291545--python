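import numpy as np
import pytest

from waterplace import Atom, FixtureSpec, Structure, assign_roles, make_pocket


def union_find_clusters(points, cutoff):
    """Brute-force single-linkage oracle: union-find over all pairs."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


def as_sorted_partition(groups):
    return sorted(sorted(int(i) for i in g) for g in groups)


@pytest.fixture
def acceptor_structure():
    """One backbone-like acceptor oxygen at the origin, roles assigned."""
    atom = Atom(1, "O", "O", np.zeros(3), record_kind="protein",
                resname="GLY", resseq=1)
    return assign_roles(Structure(atoms=[atom], id="acc"))


@pytest.fixture
def default_spec():
    return FixtureSpec(seed=11)


@pytest.fixture
def pocket(default_spec):
    return make_pocket(default_spec)
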