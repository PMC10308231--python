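import numpy as np
import pytest

from strainsort import pipeline as pl
from strainsort import synthetic as sy


@pytest.fixture(scope="session")
def small_cfg() -> sy.SimConfig:
    """Desk-scale panel: 60 kb genomes, 12 core genes, short markers —
    small enough that the whole suite stays fast, large enough that
    every stage has real signal."""
    return sy.SimConfig(
        seed=3,
        genome_length=60_000,
        n_genes=12,
        marker_16s_length=600,
        marker_rpod_length=300,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg) -> sy.SimPanel:
    return sy.simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_report(small_panel):
    """One full pipeline run shared by the pipeline tests."""
    inputs = pl.PanelInputs.from_sim_panel(small_panel)
    cfg = pl.RunConfig(type_strain_id="IN01", bootstrap_reps=30, seed=11)
    return pl.run_reclassification(inputs, cfg)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree with positive branch lengths plus its exact
    leaf-to-leaf path-distance matrix (an additive matrix by
    construction).  Returns (edges, leaf names, distance matrix) where
    edges is a list of (node_u, node_v, length).
    """
    leaves = [f"L{i}" for i in range(n_leaves)]
    # start from a 3-star and attach remaining leaves to random edges
    edges: list[tuple[str, str, float]] = []
    center = "N0"
    next_internal = 1
    for leaf in leaves[:3]:
        edges.append((center, leaf, float(rng.uniform(0.05, 1.0))))
    for leaf in leaves[3:]:
        idx = int(rng.integers(len(edges)))
        u, v, w = edges.pop(idx)
        mid = f"N{next_internal}"
        next_internal += 1
        frac = float(rng.uniform(0.25, 0.75))
        edges.append((u, mid, w * frac))
        edges.append((mid, v, w * (1 - frac)))
        edges.append((mid, leaf, float(rng.uniform(0.05, 1.0))))
    # path distances by BFS over the adjacency map
    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(leaves):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + w
                    stack.append(nxt)
        for j, dst in enumerate(leaves):
            dist[i, j] = seen[dst]
    return edges, leaves, dist


def tree_splits_from_edges(edges, leaves):
    """Non-trivial bipartitions of the leaf set induced by each edge."""
    adj: dict[str, list[str]] = {}
    for u, v, _ in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    all_leaves = frozenset(leaves)
    splits = set()
    for u, v, _ in edges:
        # leaves on v's side when the edge u-v is removed
        seen = {v, u}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node in all_leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side_f = frozenset(side)
        if 2 <= len(side_f) <= len(all_leaves) - 2:
            splits.add(frozenset([side_f, all_leaves - side_f]))
    return splits


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def patristic(tree):
    """Leaf-to-leaf path lengths of a PhyloTree, keyed (min, max) name."""
    dists = {}

    def walk(node, depth, acc):
        if node.is_leaf:
            acc.append((node.name, depth))
            return
        for c in node.children:
            walk(c, depth + (c.length or 0.0), acc)

    def pairs_below(node):
        child_leaves = []
        for c in node.children:
            acc = []
            walk(c, c.length or 0.0, acc)
            child_leaves.append(acc)
        for i in range(len(child_leaves)):
            for j in range(i + 1, len(child_leaves)):
                for a, da in child_leaves[i]:
                    for b, db in child_leaves[j]:
                        dists[(min(a, b), max(a, b))] = da + db
        for c in node.children:
            pairs_below(c)

    pairs_below(tree.root)
    return dists
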