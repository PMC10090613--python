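import itertools

import numpy as np
import pytest

from bivesdelim.distance import DistanceMatrix
from bivesdelim.seq_core import Alignment, Sequence
from bivesdelim.synthetic_data import build_bivesicula_fixture


@pytest.fixture(scope="session")
def study_fixture():
    return build_bivesicula_fixture()


@pytest.fixture(scope="session")
def study_evidence(study_fixture):
    return study_fixture.evidence


def make_alignment(rows, marker="other"):
    """Alignment from {id: residues} pairs (insertion-ordered)."""
    return Alignment([Sequence(id=k, residues=v, marker=marker)
                      for k, v in rows.items()], marker=marker)


def random_alignment(rng, n_seqs, n_cols, p_missing=0.1):
    """Random A/C/G/T alignment with gaps, N and ambiguity codes mixed in."""
    bases = np.array(list("ACGT"))
    missing = np.array(list("-NRY"))
    rows = {}
    for i in range(n_seqs):
        chars = bases[rng.integers(0, 4, n_cols)].copy()
        mask = rng.random(n_cols) < p_missing
        chars[mask] = missing[rng.integers(0, len(missing), int(mask.sum()))]
        rows[f"s{i}"] = "".join(chars)
    return make_alignment(rows)


def brute_force_differences(aln):
    """Column-by-column oracle for pairwise deletion raw differences."""
    unambiguous = set("ACGT")
    ids = aln.ids
    n = len(ids)
    values = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        a, b = aln[i].residues, aln[j].residues
        comp = diff = 0
        for x, y in zip(a, b):
            if x in unambiguous and y in unambiguous:
                comp += 1
                if x != y:
                    diff += 1
        comparable[i, j] = comparable[j, i] = comp
        values[i, j] = values[j, i] = diff if comp else np.nan
    comparable[np.diag_indices(n)] = len(aln[0].residues)
    return values, comparable


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree topology with positive edge lengths.

    Returns (newick string, patristic DistanceMatrix). Built by
    sequential random attachment; path distances are the oracle for the
    four-point condition the generating tree satisfies.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_node("internal0")
    for leaf in ("t0", "t1", "t2"):
        g.add_edge("internal0", leaf, length=float(rng.uniform(0.5, 5.0)))
    next_internal = 1
    for i in range(3, n_taxa):
        edges = list(g.edges)
        u, v = edges[rng.integers(0, len(edges))]
        length = g.edges[u, v]["length"]
        mid = f"internal{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.25, 0.75))
        g.remove_edge(u, v)
        g.add_edge(u, mid, length=length * split)
        g.add_edge(mid, v, length=length * (1 - split))
        g.add_edge(mid, f"t{i}", length=float(rng.uniform(0.5, 5.0)))
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1)
    import networkx as nx
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    n = len(leaves)
    values = np.zeros((n, n))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            values[i, j] = dist[a][b]
    dm = DistanceMatrix(tuple(leaves), values,
                        np.full((n, n), 1000, dtype=np.int64))
    newick = graph_to_newick(g)
    return newick, dm


def graph_to_newick(g):
    """Serialize an unrooted tree graph, rooted at an internal node."""
    root = next(n for n in g.nodes if g.degree(n) > 1)

    def render(node, parent):
        children = [n for n in g.neighbors(node) if n != parent]
        if not children:
            return f"{node}:{g.edges[node, parent]['length']:.8f}"
        inner = ",".join(render(c, node) for c in children)
        if parent is None:
            return f"({inner})"
        return f"({inner}):{g.edges[node, parent]['length']:.8f}"

    return render(root, None) + ";"


def tree_split_sets(tree):
    """Non-trivial bipartitions of a dendropy tree, canonicalized."""
    from bivesdelim.phylo import edge_bipartitions
    return edge_bipartitions(tree)
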