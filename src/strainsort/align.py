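"""Pairwise alignment engines.

Two engines live here:

* a global Needleman–Wunsch/Gotoh aligner with affine gaps, used for
  marker-gene identity (the currency of OTU clustering), plus a slow
  recursive reference implementation used for validation;
* a seeded local aligner (exact k-mer seeds, diagonal anchoring, edlib
  gapped refinement) standing in for BLASTn/USEARCH in the genome
  similarity and gene-presence computations.

Identity conventions: percent identity is 100 x matches / aligned
columns; ``N`` never counts as a match; for global alignments,
terminal-gap columns are excluded from the denominator so trimmed
amplicon length is not conflated with divergence.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .seqio import reverse_complement

NEG = -1e18


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring. A gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def identity(self) -> float:
        """Percent identity over non-terminal-gap columns (N never matches)."""
        a, b = self.aligned_a, self.aligned_b
        n = len(a)
        lead = 0
        while lead < n and (a[lead] == "-" or b[lead] == "-"):
            lead += 1
        trail = n
        while trail > lead and (a[trail - 1] == "-" or b[trail - 1] == "-"):
            trail -= 1
        cols = trail - lead
        if cols == 0:
            return 0.0
        matches = sum(
            1
            for i in range(lead, trail)
            if a[i] == b[i] and a[i] != "-" and a[i] != "N"
        )
        return 100.0 * matches / cols


def _dp_matrices(a: str, b: str, sc: Scoring):
    """Fill Gotoh matrices; rows vectorized, the within-row (left-gap)
    recurrence closed-form via a running maximum."""
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(aa[:, None] == bb[None, :], sc.match, sc.mismatch)
    # N never scores as a match
    is_n = ord("N")
    n_mask = (aa[:, None] == is_n) | (bb[None, :] == is_n)
    sub = np.where(n_mask, sc.mismatch, sub)

    M = np.full((n + 1, m + 1), NEG)
    U = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a; "up")
    L = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b; "left")
    M[0, 0] = 0.0  # the empty-prefix start state
    j = np.arange(1, m + 1)
    L[0, 1:] = sc.gap_open + sc.gap_extend * (j - 1)
    i = np.arange(1, n + 1)
    U[1:, 0] = sc.gap_open + sc.gap_extend * (i - 1)
    ext = sc.gap_extend

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], U[i - 1]), L[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        U[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], L[i - 1, 1:]) + sc.gap_open,
            U[i - 1, 1:] + ext,
        )
        if i == 1:
            U[i, 0] = sc.gap_open
        # L[i, j] = gap_open + max_{k<j}( H[i,k] + ext*(j-1-k) ), H = max(M, U)
        H = np.maximum(M[i], U[i])
        A = H - ext * np.arange(m + 1)
        runmax = np.maximum.accumulate(A)
        L[i, 1:] = sc.gap_open + ext * (j - 1) + runmax[:-1]
    return M, U, L


_PREF = ("M", "U", "L")  # diagonal, then up, then left


def global_align(a: str, b: str, scoring: Scoring | None = None) -> GlobalAlignment:
    """Optimal global alignment with a deterministic path: the alignment
    is reconstructed front-to-back, at each step taking the first move in
    (diagonal, up, left) order that still attains the optimal score.

    The matrices are filled on the reversed sequences, so each cell holds
    the best score of the remaining suffix given the type of the next
    column; continuing an open gap is credited gap_extend - gap_open
    relative to the stored (freshly opened) value.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    sc = scoring or Scoring()
    n, m = len(a), len(b)
    Mr, Ur, Lr = _dp_matrices(a[::-1], b[::-1], sc)
    suffix = {"M": Mr, "U": Ur, "L": Lr}
    cont = sc.gap_extend - sc.gap_open
    i = j = 0
    prev = "start"
    out_a: list[str] = []
    out_b: list[str] = []
    score = float(max(mat[n, m] for mat in suffix.values()))
    while i < n or j < m:
        vals: dict[str, float] = {}
        if i < n and j < m:
            vals["M"] = suffix["M"][n - i, m - j]
        if i < n:
            vals["U"] = suffix["U"][n - i, m - j] + (cont if prev == "U" else 0.0)
        if j < m:
            vals["L"] = suffix["L"][n - i, m - j] + (cont if prev == "L" else 0.0)
        top = max(vals.values())
        move = next(s for s in _PREF if s in vals and vals[s] >= top - 1e-9)
        if move == "M":
            out_a.append(a[i])
            out_b.append(b[j])
            i, j = i + 1, j + 1
        elif move == "U":
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
        prev = move
    return GlobalAlignment("".join(out_a), "".join(out_b), score)


def global_identity(a: str, b: str, scoring: Scoring | None = None) -> float:
    """Percent identity of the optimal global alignment (terminal gaps
    excluded from the denominator)."""
    return global_align(a, b, scoring).identity()


def reference_global_identity(a: str, b: str, scoring: Scoring | None = None) -> float:
    """Slow reference for :func:`global_identity`.

    Plain memoized recursion over (consumed a, consumed b, previous
    column type) with explicit open/extend bookkeeping and the same
    diagonal > up > left preference; shares no code with the vectorized
    engine.  Intended for validation at small lengths only.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    sc = scoring or Scoring()

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = sc.match if (a[i] == b[j] and a[i] != "N") else sc.mismatch
            options.append(s + best(i + 1, j + 1, "M"))
        if i < len(a):
            g = sc.gap_extend if prev == "U" else sc.gap_open
            options.append(g + best(i + 1, j, "U"))
        if j < len(b):
            g = sc.gap_extend if prev == "L" else sc.gap_open
            options.append(g + best(i, j + 1, "L"))
        return max(options)

    # reconstruct forward, taking the first move (diagonal, up, left) that
    # attains the optimum from the current state
    i = j = 0
    prev = "start"
    cols: list[tuple[str, str]] = []
    while i < len(a) or j < len(b):
        target = best(i, j, prev)
        if i < len(a) and j < len(b):
            s = sc.match if (a[i] == b[j] and a[i] != "N") else sc.mismatch
            if abs(s + best(i + 1, j + 1, "M") - target) < 1e-9:
                cols.append((a[i], b[j]))
                i, j, prev = i + 1, j + 1, "M"
                continue
        if i < len(a):
            g = sc.gap_extend if prev == "U" else sc.gap_open
            if abs(g + best(i + 1, j, "U") - target) < 1e-9:
                cols.append((a[i], "-"))
                i, prev = i + 1, "U"
                continue
        cols.append(("-", b[j]))
        j, prev = j + 1, "L"
    al = GlobalAlignment("".join(c[0] for c in cols), "".join(c[1] for c in cols), best(0, 0, "start"))
    return al.identity()


# ---------------------------------------------------------------------------
# seeded local alignment
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers (base-4 packed); -1 where a window
    contains a non-ACGT character."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(k):
        window = arr[off : off + n]
        codes = codes * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    codes[~valid] = -1
    return codes


@dataclass
class LocalHit:
    """One local alignment of a query against a subject sequence."""

    score: float
    identity: float
    matches: int
    columns: int
    q_start: int  # 0-based half-open on the forward query
    q_end: int
    s_start: int  # 0-based half-open on the forward subject
    s_end: int
    strand: str

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


def _cigar_stats(cigar: str, q_aln: str, t_aln: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap_columns, columns); N never matches."""
    matches = mismatches = gaps = 0
    for qa, ta in zip(q_aln, t_aln):
        if qa == "-" or ta == "-":
            gaps += 1
        elif qa == ta and qa != "N":
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, gaps, matches + mismatches + gaps


def _refine(query_sub: str, subj_sub: str) -> tuple[int, int, int, int]:
    """Gapped refinement of an anchored region via edlib (NW).

    Returns (matches, mismatches, gap_columns, columns).
    """
    res = edlib.align(query_sub, subj_sub, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query_sub, subj_sub)
    return _cigar_stats(res["cigar"], nice["query_aligned"], nice["target_aligned"])


def _score(matches: int, mismatches: int, gaps: int) -> float:
    # match +1, mismatch -1, gap column -2 (the seeded-aligner convention)
    return matches - mismatches - 2 * gaps


def _diagonal_clusters(
    q_pos: np.ndarray, s_pos: np.ndarray, band: int
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Group seed matches into diagonal bands; returns
    (representative diagonal, q positions, s positions) per cluster,
    ordered by descending seed count then smallest diagonal."""
    if len(q_pos) == 0:
        return []
    diag = q_pos - s_pos
    order = np.argsort(diag, kind="stable")
    diag_sorted = diag[order]
    breaks = np.nonzero(np.diff(diag_sorted) > band)[0] + 1
    groups = np.split(order, breaks)
    clusters = []
    for g in groups:
        d = int(np.median(diag[g]))
        clusters.append((d, q_pos[g], s_pos[g]))
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


def local_best_hit(
    query: str,
    subject: str,
    k: int = 15,
    band: int = 16,
    both_strands: bool = True,
    subject_index: dict | None = None,
) -> LocalHit | None:
    """Best seeded local alignment of query against one subject sequence.

    Exact k-mer seeds are grouped into diagonal bands; the densest band
    is anchored and the spanned region refined with a gapped alignment.
    Deterministic: ties resolved by smallest diagonal, then '+' strand.
    """
    if subject_index is None:
        subject_index = build_kmer_index(subject, k)
    best: LocalHit | None = None
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        qseq = query if strand == "+" else reverse_complement(query)
        codes = kmer_codes(qseq, k)
        q_hits: list[int] = []
        s_hits: list[int] = []
        for qp, code in enumerate(codes):
            if code < 0:
                continue
            positions = subject_index.get(int(code))
            if positions:
                for sp in positions:
                    q_hits.append(qp)
                    s_hits.append(sp)
        clusters = _diagonal_clusters(np.asarray(q_hits), np.asarray(s_hits), band)
        for d, qp, sp in clusters[:3]:
            hit = anchored_local_hit(
                query, qseq, subject, qp, sp, k=k, band=band, strand=strand
            )
            if hit is not None and (best is None or hit.score > best.score):
                best = hit
    return best


def _xdrop_walk(eq: np.ndarray, xdrop: float = 40.0) -> int:
    """How far to extend along a match/mismatch array before the running
    score (match +1, mismatch -1) drops xdrop below its maximum; returns
    the extension length achieving the maximum."""
    if len(eq) == 0:
        return 0
    score = np.cumsum(np.where(eq, 1.0, -1.0))
    run_max = np.maximum.accumulate(score)
    violations = np.nonzero(run_max - score > xdrop)[0]
    if len(violations) == 0:
        # never dropped: homology plausibly runs to the sequence end, so
        # include every column (back-tracking to the maximum here would
        # shave mismatch-rich tails and bias identity upward)
        return len(score)
    stop = int(violations[0])
    if stop == 0:
        return 0
    best_i = int(np.argmax(score[:stop]))
    return best_i + 1 if score[best_i] > 0 else 0


def anchored_local_hit(
    query: str,
    qseq: str,
    subject: str,
    q_pos: np.ndarray,
    s_pos: np.ndarray,
    k: int,
    band: int,
    strand: str,
) -> LocalHit | None:
    """Refine one diagonal seed cluster into a gapped local alignment.

    ``qseq`` is the query on the seeded strand (the reverse complement of
    ``query`` when strand is '-'); reported query coordinates are always
    on the forward query.
    """
    qs = int(q_pos.min())
    qe = int(q_pos.max()) + k
    ss = int(s_pos.min())
    se = int(s_pos.max()) + k
    # widen the anchor beyond the outermost seeds with an X-drop walk
    # along the diagonal.  Through homologous sequence the walk reaches
    # the sequence ends almost surely, so identity is measured on every
    # overlapping column (stopping at surviving seeds would bias it
    # upward); at a homology boundary — e.g. a fragment offset by an
    # indel elsewhere in the genome — it stops within ~2X columns, so
    # partial overlaps fail the coverage filter instead of absorbing
    # unrelated tails.
    nn = ord("N")
    max_left = min(qs, ss)
    if max_left > 0:
        qa = np.frombuffer(qseq[qs - max_left : qs].encode(), dtype=np.uint8)[::-1]
        sa = np.frombuffer(subject[ss - max_left : ss].encode(), dtype=np.uint8)[::-1]
        ext_left = _xdrop_walk((qa == sa) & (qa != nn))
        qs, ss = qs - ext_left, ss - ext_left
    max_right = min(len(qseq) - qe, len(subject) - se)
    if max_right > 0:
        qa = np.frombuffer(qseq[qe : qe + max_right].encode(), dtype=np.uint8)
        sa = np.frombuffer(subject[se : se + max_right].encode(), dtype=np.uint8)
        ext_right = _xdrop_walk((qa == sa) & (qa != nn))
        qe, se = qe + ext_right, se + ext_right
    # slack for indels inside the band
    ss2 = max(0, ss - band)
    se2 = min(len(subject), se + band)
    res = edlib.align(qseq[qs:qe], subject[ss2:se2], mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, qseq[qs:qe], subject[ss2:se2])
    m, mm, g, cols = _cigar_stats(
        res["cigar"], nice["query_aligned"], nice["target_aligned"]
    )
    if cols == 0:
        return None
    loc = res["locations"][0]
    # edlib minimizes unit-cost edits, which can open gap pairs our
    # scoring would reject; keep the plain ungapped diagonal alignment
    # when it scores at least as well under the declared scoring
    if qe - qs == se - ss and se <= len(subject):
        q_arr = np.frombuffer(qseq[qs:qe].encode(), dtype=np.uint8)
        s_arr = np.frombuffer(subject[ss:se].encode(), dtype=np.uint8)
        m0 = int(((q_arr == s_arr) & (q_arr != ord("N"))).sum())
        mm0 = (qe - qs) - m0
        if _score(m0, mm0, 0) >= _score(m, mm, g):
            m, mm, g, cols = m0, mm0, 0, qe - qs
            loc = (ss - ss2, se - ss2 - 1)
    if strand == "+":
        q0, q1 = qs, qe
    else:  # map back to forward query coordinates
        q0, q1 = len(query) - qe, len(query) - qs
    return LocalHit(
        score=_score(m, mm, g),
        identity=100.0 * m / cols,
        matches=m,
        columns=cols,
        q_start=q0,
        q_end=q1,
        s_start=ss2 + loc[0],
        s_end=ss2 + loc[1] + 1,
        strand=strand,
    )


def seed_matches(q_codes: np.ndarray, s_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (query position, subject position) pairs whose k-mer codes
    are equal (invalid codes, marked -1, never match)."""
    valid_s = np.nonzero(s_codes >= 0)[0]
    order = np.argsort(s_codes[valid_s], kind="stable")
    s_sorted = s_codes[valid_s][order]
    s_positions = valid_s[order]
    valid_q = np.nonzero(q_codes >= 0)[0]
    qc = q_codes[valid_q]
    left = np.searchsorted(s_sorted, qc, side="left")
    right = np.searchsorted(s_sorted, qc, side="right")
    counts = right - left
    hit_mask = counts > 0
    q_rep = np.repeat(valid_q[hit_mask], counts[hit_mask])
    starts = left[hit_mask]
    lens = counts[hit_mask]
    if len(lens) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    idx = np.concatenate([np.arange(s, s + l) for s, l in zip(starts, lens)])
    return q_rep.astype(np.int64), s_positions[idx].astype(np.int64)


def build_kmer_index(seq: str, k: int) -> dict[int, list[int]]:
    index: dict[int, list[int]] = {}
    for pos, code in enumerate(kmer_codes(seq, k)):
        if code >= 0:
            index.setdefault(int(code), []).append(pos)
    return index


class FragmentIndex:
    """k-mer index over a collection of equal-role sequences (fragments or
    proteome members), mapping seeds to (member, position)."""

    def __init__(self, seqs: Sequence[str], k: int):
        self.k = k
        self.seqs = list(seqs)
        self.index: dict[int, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(self.seqs):
            for pos, code in enumerate(kmer_codes(seq, k)):
                if code >= 0:
                    self.index.setdefault(int(code), []).append((idx, pos))

    def candidates(self, query: str, both_strands: bool = True):
        """Member indices sharing at least one seed with the query, per
        strand, with seed (q,s) position arrays."""
        out: dict[tuple[int, str], tuple[list[int], list[int]]] = {}
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            qseq = query if strand == "+" else reverse_complement(query)
            for qp, code in enumerate(kmer_codes(qseq, self.k)):
                if code < 0:
                    continue
                for idx, sp in self.index.get(int(code), ()):
                    key = (idx, strand)
                    qh, sh = out.setdefault(key, ([], []))
                    qh.append(qp)
                    sh.append(sp)
        return out
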