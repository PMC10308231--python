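"""Orthology and the diagnostic-gene screen.

Orthogroups are inferred as connected components of the union
reciprocal-best-hit (RBH) graph over all genome pairs — a deliberate
simplification of graph-clustering orthology tools that is adequate for
near-clonal in-groups.  The diagnostic screen then looks for groups
present in every in-group genome and absent from every out-group
genome, and verifies presence/absence by direct nucleotide search
(a two-stage design: orthology proposes, sequence search disposes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .align import LocalHit, local_best_hit
from .seqio import GenomeRecord

Proteome = Sequence[tuple[str, str]]  # (gene_id, protein sequence)


class OrthologyError(ValueError):
    pass


@dataclass
class RbhParams:
    min_identity: float = 30.0
    min_coverage: float = 0.5
    kmer: int = 5  # amino-acid seed for the candidate prefilter
    gap_open: float = -11.0
    gap_extend: float = -1.0


def _make_aligner(params: RbhParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _aa_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _sanitize(seq: str) -> str:
    # BLOSUM62 has no entry for '*'; simulated proteins mask stops as X
    return seq.replace("*", "X").replace("U", "X").replace("O", "X")


def _unique_best(scores_of: dict[str, dict[str, float]]) -> dict[str, str]:
    """gene -> unique best-scoring partner; a tie for the best score
    means no best hit for that gene."""
    out: dict[str, str] = {}
    for gid, partner_scores in scores_of.items():
        if not partner_scores:
            continue
        ranked = sorted(partner_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue
        out[gid] = ranked[0][0]
    return out


def protein_rbh(
    proteome_a: Proteome, proteome_b: Proteome, params: RbhParams | None = None
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two proteomes (BLOSUM62 local
    alignment; equal-best-score ties yield no pair).

    Candidate pairs are prefiltered to those sharing an exact
    amino-acid k-mer; local alignment scores are symmetric, so each
    candidate pair is scored once and both best-hit directions are read
    off the same table.  Reciprocal pairs must also pass the identity
    and coverage thresholds on their alignment.
    """
    if not proteome_a or not proteome_b:
        raise OrthologyError("proteomes must be non-empty")
    params = params or RbhParams()
    aligner = _make_aligner(params)
    a_prep = [(gid, _sanitize(seq)) for gid, seq in proteome_a]
    b_prep = [(gid, _sanitize(seq)) for gid, seq in proteome_b]
    a_kmers = {gid: _aa_kmers(seq, params.kmer) for gid, seq in a_prep}
    b_kmers = {gid: _aa_kmers(seq, params.kmer) for gid, seq in b_prep}
    b_seq = dict(b_prep)
    scores_a: dict[str, dict[str, float]] = {gid: {} for gid, _ in a_prep}
    scores_b: dict[str, dict[str, float]] = {gid: {} for gid, _ in b_prep}
    for ga, seq_a in a_prep:
        ka = a_kmers[ga]
        for gb, seq_b in b_prep:
            if ka.isdisjoint(b_kmers[gb]):
                continue
            s = float(aligner.score(seq_a, seq_b))
            scores_a[ga][gb] = s
            scores_b[gb][ga] = s
    fwd = _unique_best(scores_a)
    rev = _unique_best(scores_b)
    pairs: list[tuple[str, str]] = []
    for ga, gb in sorted(fwd.items()):
        if rev.get(gb) != ga:
            continue
        seq_a = dict(a_prep)[ga]
        seq_b = b_seq[gb]
        aln = next(iter(aligner.align(seq_a, seq_b)))
        counts = aln.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols == 0:
            continue
        identity = 100.0 * counts.identities / cols
        qa, ta = aln.aligned
        span_q = qa[-1][1] - qa[0][0]
        span_t = ta[-1][1] - ta[0][0]
        coverage = min(span_q / len(seq_a), span_t / len(seq_b))
        if identity >= params.min_identity and coverage >= params.min_coverage:
            pairs.append((ga, gb))
    return pairs


@dataclass
class OrthogroupSet:
    """Gene families over a stated genome panel; every (genome, gene)
    belongs to exactly one group (singletons included)."""

    genomes: list[str]
    groups: list[tuple[str, frozenset[tuple[str, str]]]]

    def group_of(self, genome_id: str, gene_id: str) -> str | None:
        for gid, members in self.groups:
            if (genome_id, gene_id) in members:
                return gid
        return None


def build_orthogroups(
    proteomes: Mapping[str, Proteome],
    rbh: Mapping[tuple[str, str], Sequence[tuple[str, str]]],
) -> OrthogroupSet:
    """Orthogroups as connected components of the union RBH graph.

    ``rbh`` must contain every unordered genome pair of the panel
    (either key order accepted); genes with no edges become singleton
    groups.  Group ids are assigned by decreasing size, ties by the
    lexicographically smallest member.
    """
    genomes = sorted(proteomes)
    missing = []
    normalized: dict[tuple[str, str], Sequence[tuple[str, str]]] = {}
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            if (ga, gb) in rbh:
                normalized[(ga, gb)] = rbh[(ga, gb)]
            elif (gb, ga) in rbh:
                normalized[(ga, gb)] = [(y, x) for x, y in rbh[(gb, ga)]]
            else:
                missing.append((ga, gb))
    if missing:
        raise OrthologyError(f"missing RBH results for genome pairs: {missing}")

    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for genome_id, proteome in proteomes.items():
        for gene_id, _ in proteome:
            parent[(genome_id, gene_id)] = (genome_id, gene_id)
    for (ga, gb), pairs in normalized.items():
        for gene_a, gene_b in pairs:
            union((ga, gene_a), (gb, gene_b))

    components: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for node in parent:
        components.setdefault(find(node), set()).add(node)
    ordered = sorted(components.values(), key=lambda c: (-len(c), min(c)))
    groups = [
        (f"OG{i:04d}", frozenset(members)) for i, members in enumerate(ordered, start=1)
    ]
    return OrthogroupSet(genomes=genomes, groups=groups)


@dataclass
class DiagnosticCandidate:
    group_id: str
    genome_id: str
    gene_id: str
    sequence: str
    present_in: list[str]
    absent_from: list[str]


def screen_core_unique(
    og: OrthogroupSet,
    ingroup: Sequence[str],
    outgroup: Sequence[str],
    gene_sequences: Mapping[tuple[str, str], str],
) -> list[DiagnosticCandidate]:
    """Groups with a member in EVERY in-group genome and none in ANY
    out-group genome; the representative is taken from the
    lexicographically smallest in-group genome."""
    in_set, out_set = set(ingroup), set(outgroup)
    if not in_set or not out_set:
        raise OrthologyError("ingroup and outgroup must both be non-empty")
    if in_set & out_set:
        raise OrthologyError(f"overlapping panels: {sorted(in_set & out_set)}")
    unknown = (in_set | out_set) - set(og.genomes)
    if unknown:
        raise OrthologyError(f"genomes not in the orthogroup panel: {sorted(unknown)}")
    candidates: list[DiagnosticCandidate] = []
    for group_id, members in og.groups:
        present = {g for g, _ in members}
        if in_set <= present and not (out_set & present):
            rep = min(m for m in members if m[0] in in_set)
            candidates.append(
                DiagnosticCandidate(
                    group_id=group_id,
                    genome_id=rep[0],
                    gene_id=rep[1],
                    sequence=gene_sequences[rep],
                    present_in=sorted(present),
                    absent_from=sorted(out_set),
                )
            )
    return candidates


@dataclass
class PresenceParams:
    min_identity: float = 80.0
    min_coverage: float = 0.8
    k: int = 13
    band: int = 16


@dataclass
class PresenceCall:
    present: bool
    hit: LocalHit | None
    contig_id: str | None = None


def presence_by_search(
    candidate_seq: str, genome: GenomeRecord, params: PresenceParams | None = None
) -> PresenceCall:
    """Nucleotide search of a candidate gene in a genome (both strands);
    present iff the best local hit passes the identity threshold with
    sufficient coverage of the candidate."""
    params = params or PresenceParams()
    best: LocalHit | None = None
    best_contig: str | None = None
    for contig_id, seq in genome.contigs:
        hit = local_best_hit(candidate_seq, seq, k=params.k, band=params.band)
        if hit is not None and (best is None or hit.score > best.score):
            best, best_contig = hit, contig_id
    if best is None:
        return PresenceCall(False, None)
    coverage = best.q_span / len(candidate_seq)
    ok = best.identity >= params.min_identity and coverage >= params.min_coverage
    return PresenceCall(ok, best, best_contig)


def conservation_filter(
    candidates: Sequence[DiagnosticCandidate],
    panel: Sequence[GenomeRecord],
    same_species: Mapping[str, bool],
    params: PresenceParams | None = None,
) -> list[DiagnosticCandidate]:
    """Keep candidates present in ALL same-species genomes of the
    extended panel and absent from all the others."""
    params = params or PresenceParams()
    surviving: list[DiagnosticCandidate] = []
    for cand in candidates:
        ok = True
        for genome in panel:
            call = presence_by_search(cand.sequence, genome, params)
            want = same_species[genome.strain_id]
            if call.present != want:
                ok = False
                break
        if ok:
            surviving.append(cand)
    return surviving
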