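"""Marker-gene analysis: pairwise identity, OTU clustering, NJ trees.

A strain panel's 16S-like and rpoD-like sequences (or their
concatenation) are compared by global alignment; strains are grouped
into operational taxonomic units (OTUs) at an identity threshold
(default >= 98%), and a neighbor-joining tree with bootstrap supports
summarizes their relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage, to_tree as _scipy_to_tree
from scipy.spatial.distance import squareform

from .align import Scoring, global_align, global_identity
from .phylo import Node, PhyloTree
from .seqio import MarkerProfile


class MarkerError(ValueError):
    pass


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with 100 on the diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise MarkerError("identity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise MarkerError("identity matrix is not symmetric")
        if not np.all(v.diagonal() == 100.0):
            raise MarkerError("identity matrix diagonal must be exactly 100")
        self.values = v

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise MarkerError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise MarkerError("distance matrix is not symmetric")
        if np.any(v < 0) or np.any(v.diagonal() != 0):
            raise MarkerError("distances must be non-negative with zero diagonal")
        self.values = (v + v.T) / 2.0


@dataclass
class OtuAssignment:
    """strain_id -> OTU label; clusters of one are labeled "ST"."""

    mapping: dict[str, str]
    clusters: list[list[str]] = field(default_factory=list)

    def n_otus(self) -> int:
        return len({v for v in self.mapping.values() if v != "ST"})

    def n_singletons(self) -> int:
        return sum(1 for v in self.mapping.values() if v == "ST")


_MODE_ATTR = {"concat": "concat", "s16_only": "seq_16s", "rpod_only": "seq_rpod"}


def _marker_seq(profile: MarkerProfile, mode: str) -> str:
    try:
        attr = _MODE_ATTR[mode]
    except KeyError:
        raise MarkerError(f"unknown marker mode {mode!r}") from None
    seq = getattr(profile, attr)
    if not seq:
        raise MarkerError(f"strain {profile.strain_id!r} is missing the {mode} marker")
    return seq


def identity_matrix(
    profiles: Sequence[MarkerProfile],
    mode: str = "concat",
    scoring: Scoring | None = None,
) -> IdentityMatrix:
    """All pairwise global identities on the selected marker sequence."""
    if len(profiles) < 2:
        raise MarkerError("need at least 2 marker profiles")
    labels = [p.strain_id for p in profiles]
    if len(set(labels)) != len(labels):
        raise MarkerError("duplicate strain ids in marker panel")
    seqs = [_marker_seq(p, mode) for p in profiles]
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(seqs[i], seqs[j], scoring)
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels, values)


_LINKAGES = {
    "complete": min,
    "single": max,
    "average": lambda sims: sum(sims) / len(sims),
}


def cluster_otus(
    m: IdentityMatrix, threshold: float = 98.0, linkage: str = "complete"
) -> OtuAssignment:
    """Agglomerative clustering on similarity.

    Repeatedly merges the cluster pair with the highest linkage
    similarity while that similarity is >= threshold; merge ties are
    broken by the lexicographically smallest member pair, so the result
    is independent of input row order.  Clusters of size >= 2 are
    labeled OTU1, OTU2, ... in decreasing size (ties by smallest member
    id); singletons are labeled "ST".
    """
    if not (0.0 < threshold <= 100.0):
        raise MarkerError(f"threshold must be in (0, 100], got {threshold}")
    if linkage not in _LINKAGES:
        raise MarkerError(f"unknown linkage {linkage!r}")
    agg = _LINKAGES[linkage]
    idx = {lab: i for i, lab in enumerate(m.labels)}
    clusters: list[list[str]] = [[lab] for lab in sorted(m.labels)]

    def sim(c1: list[str], c2: list[str]) -> float:
        return agg([m.values[idx[a], idx[b]] for a in c1 for b in c2])

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                s = sim(clusters[i], clusters[j])
                key = tuple(sorted((clusters[i][0], clusters[j][0])))
                if best is None or s > best[0] or (s == best[0] and key < best[1]):
                    best = (s, key, i, j)
        if best is None or best[0] < threshold:
            break
        _, _, i, j = best
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])

    multi = sorted((c for c in clusters if len(c) >= 2), key=lambda c: (-len(c), c[0]))
    mapping: dict[str, str] = {}
    for rank, members in enumerate(multi, start=1):
        for s in members:
            mapping[s] = f"OTU{rank}"
    for c in clusters:
        if len(c) == 1:
            mapping[c[0]] = "ST"
    return OtuAssignment(mapping=mapping, clusters=sorted(clusters, key=lambda c: c[0]))


def distances_from_identity(m: IdentityMatrix) -> DistanceMatrix:
    """d = (100 - identity) / 100 — the simple proportion of differing
    positions, the units used for NJ branch lengths here."""
    values = (100.0 - m.values) / 100.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(m.labels), values)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q matrix are broken by the smallest (label, label) pair;
    negative branch lengths are clamped to 0 with the deficit moved to
    the sibling edge (their sum is preserved).
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise MarkerError("need at least 2 taxa")
    nodes: dict[str, Node] = {lab: Node(name=lab) for lab in labels}
    dist: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[_key(labels[i], labels[j])] = float(d.values[i, j])
    active = sorted(labels)

    if n == 2:
        a, b = active
        h = dist[_key(a, b)] / 2.0
        nodes[a].length = nodes[b].length = h
        return PhyloTree(root=Node(children=[nodes[a], nodes[b]]))

    while len(active) > 3:
        r = len(active)
        row_sum = {a: sum(dist[_key(a, b)] for b in active if b != a) for a in active}
        best = None
        for x in range(r):
            for y in range(x + 1, r):
                a, b = active[x], active[y]
                q = (r - 2) * dist[_key(a, b)] - row_sum[a] - row_sum[b]
                if best is None or q < best[0] - 1e-15 or (
                    abs(q - best[0]) <= 1e-15 and (a, b) < best[1]
                ):
                    best = (q, (a, b))
        a, b = best[1]
        dab = dist[_key(a, b)]
        la = dab / 2.0 + (row_sum[a] - row_sum[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        nodes[a].length = la
        nodes[b].length = lb
        parent = Node(children=[nodes[a], nodes[b]])
        new_label = min(a, b)  # cluster label for deterministic tie-breaking
        for c in active:
            if c in (a, b):
                continue
            duk = (dist[_key(a, c)] + dist[_key(b, c)] - dab) / 2.0
            dist[_key(new_label, c)] = max(duk, 0.0)
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
        nodes[new_label] = parent

    a, b, c = active
    dab, dac, dbc = dist[_key(a, b)], dist[_key(a, c)], dist[_key(b, c)]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return PhyloTree(root=Node(children=[nodes[a], nodes[b], nodes[c]]))


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


# ---------------------------------------------------------------------------
# alignment-matrix utilities and bootstrap
# ---------------------------------------------------------------------------


def _encode_alignment(seqs: Sequence[str]) -> np.ndarray:
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise MarkerError("aligned sequences must all have the same length")
    return np.vstack(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    )


def alignment_identity_matrix(labels: Sequence[str], seqs: Sequence[str]) -> IdentityMatrix:
    """Pairwise percent identity (p-distance complement) on an alignment.

    Columns where either row has a gap are excluded from the
    denominator; N never counts as a match.
    """
    arr = _encode_alignment(seqs)
    return _identity_from_encoded(list(labels), arr, np.arange(arr.shape[1]))


def _identity_from_encoded(labels, arr, cols) -> IdentityMatrix:
    sub = arr[:, cols]
    gap = ord("-")
    nn = ord("N")
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sub[i], sub[j]
            valid = (a != gap) & (b != gap)
            denom = int(valid.sum())
            if denom == 0:
                ident = 0.0
            else:
                matches = int(((a == b) & valid & (a != nn)).sum())
                ident = 100.0 * matches / denom
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(list(labels), values)


def bootstrap_supports(
    labels: Sequence[str],
    aligned_seqs: Sequence[str],
    n_reps: int = 500,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree from an alignment with bootstrap supports.

    Columns are resampled with replacement per replicate (seeded and
    reproducible); each internal edge of the reference tree gets the
    percent of replicate trees containing the same bipartition.
    """
    if n_reps < 1:
        raise MarkerError("n_reps must be >= 1")
    arr = _encode_alignment(aligned_seqs)
    L = arr.shape[1]
    ref_ident = _identity_from_encoded(list(labels), arr, np.arange(L))
    ref_tree = nj_tree(distances_from_identity(ref_ident))
    ref_splits = ref_tree.topology_splits()
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        ident = _identity_from_encoded(list(labels), arr, cols)
        rep_tree = nj_tree(distances_from_identity(ident))
        for s in rep_tree.topology_splits():
            if s in counts:
                counts[s] += 1

    def annotate(node: Node, all_leaves: frozenset) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, all_leaves) for c in node.children))
        key = frozenset([below, all_leaves - below])
        if key in counts and min(len(below), len(all_leaves - below)) >= 2:
            node.support = int(round(100.0 * counts[key] / n_reps))
        return below

    annotate(ref_tree.root, frozenset(ref_tree.leaf_names()))
    return ref_tree


# ---------------------------------------------------------------------------
# progressive multiple alignment (guide-tree + consensus merging)
# ---------------------------------------------------------------------------


def _consensus(rows: list[str]) -> str:
    out = []
    for col in zip(*rows):
        bases = [c for c in col if c != "-"]
        if not bases:
            out.append("-")
            continue
        counts: dict[str, int] = {}
        for c in bases:
            counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=lambda c: counts[c]))
    return "".join(out)


def _apply_gaps(rows: list[str], aligned_consensus: str) -> list[str]:
    """Insert the gap pattern of an aligned consensus into every row."""
    out = []
    for row in rows:
        res = []
        it = iter(row)
        for c in aligned_consensus:
            res.append("-" if c == "-" else next(it))
        out.append("".join(res))
    return out


def progressive_align(
    labels: Sequence[str],
    seqs: Sequence[str],
    guide_distances: np.ndarray | None = None,
) -> list[str]:
    """Progressive multiple alignment guided by a UPGMA tree.

    Pairwise global alignments give the guide distances (precomputed
    distances in label order may be supplied instead); profiles are
    merged by globally aligning their consensus sequences and
    propagating the resulting gap pattern to every member.  Adequate for
    the near-identical marker genes this package clusters; arbitrary
    externally produced alignments are also accepted downstream.
    """
    n = len(seqs)
    if n == 1:
        return [seqs[0]]
    if n == 2:
        al = global_align(seqs[0], seqs[1])
        return [al.aligned_a, al.aligned_b]
    if guide_distances is not None:
        condensed = list(squareform(np.asarray(guide_distances), checks=False))
    else:
        condensed = []
        for i in range(n):
            for j in range(i + 1, n):
                condensed.append((100.0 - global_identity(seqs[i], seqs[j])) / 100.0)
    z = _scipy_linkage(np.asarray(condensed), method="average")
    tree = _scipy_to_tree(z)
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }

    def merge(node) -> int:
        if node.is_leaf():
            return node.id
        li = merge(node.left)
        ri = merge(node.right)
        ids_l, rows_l = profiles.pop(li)
        ids_r, rows_r = profiles.pop(ri)
        al = global_align(_consensus(rows_l), _consensus(rows_r))
        rows = _apply_gaps(rows_l, al.aligned_a) + _apply_gaps(rows_r, al.aligned_b)
        profiles[node.id] = (ids_l + ids_r, rows)
        return node.id

    root_id = merge(tree)
    ids, rows = profiles[root_id]
    ordered = [""] * n
    for idx, row in zip(ids, rows):
        ordered[idx] = row
    return ordered
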