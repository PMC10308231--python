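"""Whole-genome similarity: fragment-based ANI, GBDP-style dDDH, and the
same-species decision rule.

ANI follows the orthologous-fragment scheme: both genomes are cut into
1020-bp windows, fragments are matched by a seeded local aligner in both
directions, and ANI is the mean identity of reciprocal best-hit fragment
pairs.  dDDH uses the genome-distance route: high-scoring segment pairs
(HSPs) are collected genome-vs-genome, overlaps are greedily trimmed,
and "formula 2" converts d = 1 - (sum identities / sum HSP length) into
a DDH-scale percentage via a logistic model.  Two genomes are called the
same species when ANI >= 95% and dDDH >= 70% (both inclusive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .align import (
    FragmentIndex,
    _diagonal_clusters,
    anchored_local_hit,
    kmer_codes,
    seed_matches,
)
from .seqio import GenomeRecord, reverse_complement


class SimilarityError(ValueError):
    pass


class UndefinedResultError(SimilarityError):
    """No reciprocal fragment pairs / no HSPs: the statistic is undefined
    (deliberately not reported as 0)."""


# ---------------------------------------------------------------------------
# fragmentation and fragment hits
# ---------------------------------------------------------------------------


@dataclass
class Fragment:
    fragment_id: str
    contig_id: str
    start: int  # 1-based inclusive on the source contig
    sequence: str


@dataclass
class FragmentSet:
    genome_id: str
    length: int
    fragments: list[Fragment]


def fragment_genome(g: GenomeRecord, L: int = 1020) -> FragmentSet:
    """Cut each contig into consecutive non-overlapping windows of
    exactly L bp; sub-length remainders are discarded."""
    if L < 100:
        raise SimilarityError("fragment length must be >= 100")
    fragments: list[Fragment] = []
    for contig_id, seq in g.contigs:
        for i in range(0, len(seq) - L + 1, L):
            fragments.append(
                Fragment(
                    fragment_id=f"{contig_id}|{i + 1}",
                    contig_id=contig_id,
                    start=i + 1,
                    sequence=seq[i : i + L],
                )
            )
    return FragmentSet(genome_id=g.strain_id, length=L, fragments=fragments)


@dataclass
class FragmentHit:
    query_id: str
    subject_id: str
    identity: float
    coverage: float
    score: float
    strand: str


@dataclass
class AniParams:
    L: int = 1020
    k: int = 15
    min_identity: float = 35.0
    min_coverage: float = 0.7
    band: int = 16


def _best_against_index(
    query: Fragment,
    index: FragmentIndex,
    subject: FragmentSet,
    params: AniParams,
) -> FragmentHit | None:
    best: tuple | None = None  # (score, subject_id, hit)
    for (idx, strand), (q_hits, s_hits) in sorted(index.candidates(query.sequence).items()):
        subj = subject.fragments[idx]
        clusters = _diagonal_clusters(np.asarray(q_hits), np.asarray(s_hits), params.band)
        for _, qp, sp in clusters[:2]:
            qseq = (
                query.sequence if strand == "+" else reverse_complement(query.sequence)
            )
            hit = anchored_local_hit(
                query.sequence, qseq, subj.sequence, qp, sp,
                k=params.k, band=params.band, strand=strand,
            )
            if hit is None:
                continue
            coverage = hit.q_span / len(query.sequence)
            if hit.identity < params.min_identity or coverage < params.min_coverage:
                continue
            cand = FragmentHit(
                query_id=query.fragment_id,
                subject_id=subj.fragment_id,
                identity=hit.identity,
                coverage=coverage,
                score=hit.score,
                strand=strand,
            )
            # highest score wins; ties go to the smallest subject id
            key = (-cand.score, cand.subject_id)
            if best is None or key < best[0]:
                best = (key, cand)
    return best[1] if best else None


def best_fragment_hit(
    query: Fragment | str,
    subject: FragmentSet,
    params: AniParams | None = None,
    index: FragmentIndex | None = None,
) -> FragmentHit | None:
    """Best seeded local alignment of one fragment against a fragment
    set (both strands); None when nothing passes the identity/coverage
    thresholds."""
    params = params or AniParams()
    if isinstance(query, str):
        query = Fragment(fragment_id="query", contig_id="query", start=1, sequence=query)
    if index is None:
        index = FragmentIndex([f.sequence for f in subject.fragments], params.k)
    return _best_against_index(query, index, subject, params)


@dataclass
class AniResult:
    genome_a: str
    genome_b: str
    ani: float
    n_rbh_pairs: int


def orthoani(
    a: GenomeRecord, b: GenomeRecord, params: AniParams | None = None
) -> AniResult:
    """Fragment-based reciprocal-best-hit ANI (symmetric by construction).

    Each RBH fragment pair contributes the mean of its two directional
    identities; ANI is the arithmetic mean over pairs.
    """
    params = params or AniParams()
    first, second = (a, b) if a.strain_id <= b.strain_id else (b, a)
    fa = fragment_genome(first, params.L)
    fb = fragment_genome(second, params.L)
    if not fa.fragments or not fb.fragments:
        raise UndefinedResultError(
            f"genome with no {params.L}-bp fragment: "
            f"{first.strain_id if not fa.fragments else second.strain_id}"
        )
    index_b = FragmentIndex([f.sequence for f in fb.fragments], params.k)
    index_a = FragmentIndex([f.sequence for f in fa.fragments], params.k)
    best_ab = {
        f.fragment_id: h
        for f in fa.fragments
        if (h := _best_against_index(f, index_b, fb, params)) is not None
    }
    best_ba = {
        f.fragment_id: h
        for f in fb.fragments
        if (h := _best_against_index(f, index_a, fa, params)) is not None
    }
    identities: list[float] = []
    for qid in sorted(best_ab):
        hit = best_ab[qid]
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == qid:
            identities.append((hit.identity + back.identity) / 2.0)
    if not identities:
        raise UndefinedResultError(
            f"no reciprocal best-hit fragment pairs between "
            f"{a.strain_id} and {b.strain_id}: ANI undefined"
        )
    return AniResult(
        genome_a=a.strain_id,
        genome_b=b.strain_id,
        ani=float(np.mean(identities)),
        n_rbh_pairs=len(identities),
    )


# ---------------------------------------------------------------------------
# GBDP HSPs and dDDH
# ---------------------------------------------------------------------------


@dataclass
class Hsp:
    contig_a: str
    a_start: int  # 1-based inclusive
    a_end: int
    contig_b: str
    b_start: int
    b_end: int
    strand: str
    length: int  # aligned columns
    identities: int  # matching columns
    score: float = 0.0


@dataclass
class GbdpParams:
    k: int = 15
    min_score: float = 60.0
    max_seed_gap: int = 300
    xdrop: float = 30.0


def _xdrop_extend(eq: np.ndarray, lo: int, hi: int, xdrop: float) -> tuple[int, int]:
    """Extend [lo, hi) along a precomputed match/mismatch array with an
    X-drop rule (match +1, mismatch -1)."""
    best_drop = 0.0
    score = 0.0
    best_i = hi
    i = hi
    while i < len(eq):
        score += 1.0 if eq[i] else -1.0
        if score > best_drop:
            best_drop, best_i = score, i + 1
        if best_drop - score > xdrop:
            break
        i += 1
    hi = best_i
    best_drop = 0.0
    score = 0.0
    best_i = lo
    i = lo - 1
    while i >= 0:
        score += 1.0 if eq[i] else -1.0
        if score > best_drop:
            best_drop, best_i = score, i
        if best_drop - score > xdrop:
            break
        i -= 1
    return best_i, hi


def _contig_hsps(
    contig_a: str, seq_a: str, contig_b: str, seq_b: str, params: GbdpParams
) -> list[Hsp]:
    a_arr = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    a_codes = kmer_codes(seq_a, params.k)
    out: list[Hsp] = []
    for strand in ("+", "-"):
        sseq = seq_b if strand == "+" else reverse_complement(seq_b)
        s_arr = np.frombuffer(sseq.encode(), dtype=np.uint8)
        q_pos, s_pos = seed_matches(a_codes, kmer_codes(sseq, params.k))
        if len(q_pos) == 0:
            continue
        diag = q_pos - s_pos
        order = np.lexsort((q_pos, diag))
        q_pos, s_pos, diag = q_pos[order], s_pos[order], diag[order]
        run_break = np.nonzero(
            (np.diff(diag) != 0) | (np.diff(q_pos) > params.max_seed_gap)
        )[0] + 1
        for idx in np.split(np.arange(len(q_pos)), run_break):
            d = int(diag[idx[0]])
            qlo = int(q_pos[idx[0]])
            qhi = int(q_pos[idx[-1]]) + params.k
            # overlap of the two sequences along diagonal d
            lo_bound = max(0, d)
            hi_bound = min(len(seq_a), len(sseq) + d)
            eq = (
                (a_arr[lo_bound:hi_bound] == s_arr[lo_bound - d : hi_bound - d])
                & (a_arr[lo_bound:hi_bound] != ord("N"))
            )
            lo, hi = _xdrop_extend(eq, qlo - lo_bound, qhi - lo_bound, params.xdrop)
            a0, a1 = lo_bound + lo, lo_bound + hi  # 0-based half-open on a
            matches = int(eq[lo:hi].sum())
            length = a1 - a0
            if length <= 0:
                continue
            score = 2.0 * matches - length
            s0, s1 = a0 - d, a1 - d  # on the seeded strand of b
            if strand == "+":
                b0, b1 = s0, s1
            else:
                b0, b1 = len(seq_b) - s1, len(seq_b) - s0
            out.append(
                Hsp(
                    contig_a=contig_a,
                    a_start=a0 + 1,
                    a_end=a1,
                    contig_b=contig_b,
                    b_start=b0 + 1,
                    b_end=b1,
                    strand=strand,
                    length=length,
                    identities=matches,
                    score=score,
                )
            )
    return out


def _subtract(intervals: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Longest-run bookkeeping: remove covered [lo, hi) pieces from the
    candidate offset range; returns the remaining sub-intervals."""
    pieces = [(lo, hi)]
    return pieces if not intervals else _subtract_all(pieces, intervals)


def _subtract_all(pieces, covered):
    out = []
    for lo, hi in pieces:
        segs = [(lo, hi)]
        for c0, c1 in covered:
            nxt = []
            for s0, s1 in segs:
                if c1 <= s0 or c0 >= s1:
                    nxt.append((s0, s1))
                    continue
                if s0 < c0:
                    nxt.append((s0, c0))
                if c1 < s1:
                    nxt.append((c1, s1))
            segs = nxt
        out.extend(segs)
    return out


def gbdp_hsps(
    a: GenomeRecord, b: GenomeRecord, params: GbdpParams | None = None
) -> list[Hsp]:
    """Collect genome-vs-genome local alignments and greedily accept by
    descending score, trimming overlap with previously accepted HSPs on
    either genome; HSPs below min_score after trimming are discarded.

    HSPs here are ungapped diagonal segments (seed runs extended with an
    X-drop rule); identity counts are exact recounts of matching
    positions, with N never matching.
    """
    params = params or GbdpParams()
    raw: list[Hsp] = []
    seqs_a = dict(a.contigs)
    seqs_b = dict(b.contigs)
    for ca, sa in a.contigs:
        for cb, sb in b.contigs:
            raw.extend(_contig_hsps(ca, sa, cb, sb, params))
    raw.sort(key=lambda h: (-h.score, h.contig_a, h.a_start, h.contig_b, h.b_start))
    covered_a: dict[str, list[tuple[int, int]]] = {}
    covered_b: dict[str, list[tuple[int, int]]] = {}
    accepted: list[Hsp] = []
    for h in raw:
        a0, a1 = h.a_start - 1, h.a_end  # 0-based half-open
        # offsets within the HSP still free on the a-axis
        free = _subtract(covered_a.get(h.contig_a, []), a0, a1)
        # map b-axis coverage into a-axis offsets (linear along the diagonal)
        b_cov = covered_b.get(h.contig_b, [])
        mapped: list[tuple[int, int]] = []
        for c0, c1 in b_cov:
            o0 = max(c0, h.b_start - 1)
            o1 = min(c1, h.b_end)
            if o0 >= o1:
                continue
            if h.strand == "+":
                mapped.append((a0 + (o0 - (h.b_start - 1)), a0 + (o1 - (h.b_start - 1))))
            else:
                mapped.append((a0 + (h.b_end - o1), a0 + (h.b_end - o0)))
        free = _subtract_all(free, mapped)
        if not free:
            continue
        lo, hi = max(free, key=lambda seg: (seg[1] - seg[0], -seg[0]))
        if hi - lo <= 0:
            continue
        # recount matches on the trimmed run
        seq_a = seqs_a[h.contig_a]
        sb = seqs_b[h.contig_b]
        if h.strand == "+":
            b_lo = (h.b_start - 1) + (lo - a0)
            sub_b = sb[b_lo : b_lo + (hi - lo)]
        else:
            b_hi = h.b_end - (lo - a0)
            sub_b = reverse_complement(sb[b_hi - (hi - lo) : b_hi])
        sub_a = seq_a[lo:hi]
        arr_a = np.frombuffer(sub_a.encode(), dtype=np.uint8)
        arr_b = np.frombuffer(sub_b.encode(), dtype=np.uint8)
        eq = (arr_a == arr_b) & (arr_a != ord("N"))
        matches = int(eq.sum())
        length = hi - lo
        score = 2.0 * matches - length
        if score < params.min_score:
            continue
        if h.strand == "+":
            nb0, nb1 = (h.b_start - 1) + (lo - a0), (h.b_start - 1) + (hi - a0)
        else:
            nb0, nb1 = h.b_end - (hi - a0), h.b_end - (lo - a0)
        accepted.append(
            Hsp(
                contig_a=h.contig_a,
                a_start=lo + 1,
                a_end=hi,
                contig_b=h.contig_b,
                b_start=nb0 + 1,
                b_end=nb1,
                strand=h.strand,
                length=length,
                identities=matches,
                score=score,
            )
        )
        covered_a.setdefault(h.contig_a, []).append((lo, hi))
        covered_b.setdefault(h.contig_b, []).append((nb0, nb1))
    return accepted


# ---------------------------------------------------------------------------
# dDDH formula 2
# ---------------------------------------------------------------------------


@dataclass
class DdhModel:
    """Logistic map from formula-2 distance to the DDH scale:
    ddh = 100 / (1 + exp(-(intercept + slope * ln d)))."""

    model_id: str
    intercept: float
    slope_log_distance: float

    def ddh_percent(self, d2: float) -> float:
        if d2 <= 0.0:
            return 100.0
        z = self.intercept + self.slope_log_distance * math.log(d2)
        return 100.0 / (1.0 + math.exp(-z))


def load_ddh_model(name: str = "ggdc2-logitlog-synthetic-v1") -> DdhModel:
    payload = json.loads(
        resources.files("strainsort.data").joinpath("ddh_models.json").read_text()
    )
    try:
        entry = payload[name]
    except KeyError:
        raise SimilarityError(f"unknown dDDH coefficient set {name!r}") from None
    return DdhModel(
        model_id=name,
        intercept=entry["intercept"],
        slope_log_distance=entry["slope_log_distance"],
    )


@dataclass
class DdhResult:
    d2: float
    ddh: float
    model: DdhModel


def ddh_formula2(hsps: Sequence[Hsp], model: DdhModel | None = None) -> DdhResult:
    """Formula-2 genome distance d = 1 - (sum identities / sum aligned
    length) over the accepted HSPs, mapped to the DDH percent scale."""
    if not hsps:
        raise UndefinedResultError("no HSPs: dDDH undefined")
    model = model or load_ddh_model()
    total_len = sum(h.length for h in hsps)
    total_id = sum(h.identities for h in hsps)
    if total_len == 0:
        raise UndefinedResultError("zero aligned length: dDDH undefined")
    d2 = 1.0 - total_id / total_len
    return DdhResult(d2=d2, ddh=model.ddh_percent(d2), model=model)


def ddh(
    a: GenomeRecord,
    b: GenomeRecord,
    params: GbdpParams | None = None,
    model: DdhModel | None = None,
) -> DdhResult:
    return ddh_formula2(gbdp_hsps(a, b, params), model)


# ---------------------------------------------------------------------------
# species decision rule
# ---------------------------------------------------------------------------


@dataclass
class SpeciesThresholds:
    ani_min: float = 95.0
    ddh_min: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.ani_min < 100 and 0 < self.ddh_min < 100):
            raise SimilarityError("thresholds must be inside (0, 100)")


@dataclass
class SpeciesCall:
    same_species: bool
    rationale: str


def classify_species(
    ani: float, ddh_percent: float, t: SpeciesThresholds | None = None
) -> SpeciesCall:
    """Same species iff ANI >= ani_min AND dDDH >= ddh_min (inclusive)."""
    t = t or SpeciesThresholds()
    for name, v in (("ANI", ani), ("dDDH", ddh_percent)):
        if not (0.0 <= v <= 100.0):
            raise SimilarityError(f"{name} must be in [0, 100], got {v}")
    same = ani >= t.ani_min and ddh_percent >= t.ddh_min
    rationale = (
        f"ANI {ani:.1f}% {'>=' if ani >= t.ani_min else '<'} {t.ani_min:g}% and "
        f"dDDH {ddh_percent:.1f}% {'>=' if ddh_percent >= t.ddh_min else '<'} {t.ddh_min:g}%"
    )
    return SpeciesCall(same_species=same, rationale=rationale)
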