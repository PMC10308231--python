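"""Primer design on a diagnostic gene and in-silico PCR specificity.

Primer pairs are enumerated on windows that are 100% conserved across
the in-group homolog alignment (so every target strain is matched
perfectly), filtered on length, GC, melting temperature and a
self-complementarity heuristic, and ranked deterministically.  In-silico
PCR models amplification purely as sequence matching: a product is
reported for every inward-facing pair of primer sites within the product
window, with a configurable mismatch budget and a 3'-exactness
requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .seqio import GenomeRecord, gc_fraction, reverse_complement


class PrimerError(ValueError):
    pass


def melting_temp(
    seq: str,
    method: str = "nn",
    na_mM: float = 50.0,
    primer_nM: float = 500.0,
    enforce_length: bool = True,
) -> float:
    """Melting temperature in Celsius.

    ``wallace`` is the 2(A+T) + 4(G+C) rule; ``nn`` uses
    nearest-neighbor thermodynamics (the SantaLucia unified parameter
    table shipped with Biopython) at the stated salt and primer
    concentrations (defaults 50 mM Na+, 500 nM primer).
    """
    if set(seq) - set("ACGT"):
        raise PrimerError(f"primer contains non-ACGT characters: {seq!r}")
    if method == "wallace":
        if enforce_length and len(seq) < 8:
            raise PrimerError("wallace rule needs length >= 8")
        return float(_mt.Tm_Wallace(seq))
    if method == "nn":
        if enforce_length and len(seq) < 10:
            raise PrimerError("nearest-neighbor Tm needs length >= 10")
        return float(_mt.Tm_NN(seq, Na=na_mM, dnac1=primer_nM, dnac2=0))
    raise PrimerError(f"unknown Tm method {method!r}")


@dataclass
class Primer:
    name: str
    sequence: str
    tm: float = 0.0

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise PrimerError(f"primer {self.name!r} has non-ACGT characters")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class PrimerPair:
    forward: Primer
    reverse: Primer
    expected_product_range: tuple[int, int]
    designed_product: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.expected_product_range
        if lo > hi:
            raise PrimerError("product range min must be <= max")


@dataclass
class DesignConstraints:
    min_length: int = 18
    max_length: int = 28
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_target: float = 60.0
    max_tm_diff: float = 5.0
    product_min: int = 150
    product_max: int = 700
    max_self_complement_run: int = 6


def _self_complement_run(seq: str) -> int:
    """Longest common substring between a primer and its own reverse
    complement — a dimer/hairpin propensity heuristic."""
    rc = reverse_complement(seq)
    n = len(seq)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seq[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def conserved_runs(alignment: Sequence[str]) -> list[tuple[int, int]]:
    """Maximal runs of columns that are identical across all rows (and
    gap-free, ACGT only), as 0-based half-open intervals in the
    coordinates of the first row (the design target)."""
    if not alignment:
        raise PrimerError("empty homolog alignment")
    L = len(alignment[0])
    if any(len(row) != L for row in alignment):
        raise PrimerError("homolog alignment rows differ in length")
    target_pos = -1
    runs: list[tuple[int, int]] = []
    run_start: int | None = None
    for col in range(L):
        chars = {row[col] for row in alignment}
        in_target = alignment[0][col] != "-"
        if in_target:
            target_pos += 1
        conserved = len(chars) == 1 and chars <= set("ACGT")
        if conserved and in_target:
            if run_start is None:
                run_start = target_pos
        else:
            if run_start is not None:
                # a variable target column excludes the current position;
                # a target-row gap ends the run after the previous one
                runs.append((run_start, target_pos if in_target else target_pos + 1))
                run_start = None
    if run_start is not None:
        runs.append((run_start, target_pos + 1))
    return runs


@dataclass
class DesignResult:
    pairs: list[PrimerPair]
    diagnostics: dict[str, int] = field(default_factory=dict)


def _candidate_primers(
    target: str,
    runs: Sequence[tuple[int, int]],
    c: DesignConstraints,
    diag: dict[str, int],
) -> list[tuple[int, int]]:
    """(start, length) windows passing the single-primer constraints;
    one window per start position (the length with Tm closest to the
    target Tm), which keeps pair enumeration tractable."""
    chosen: list[tuple[int, int]] = []
    for lo, hi in runs:
        for start in range(lo, hi - c.min_length + 1):
            best: tuple[float, int] | None = None
            for length in range(c.min_length, min(c.max_length, hi - start) + 1):
                window = target[start : start + length]
                gc = gc_fraction(window)
                if not (c.gc_min <= gc <= c.gc_max):
                    diag["gc_failed"] = diag.get("gc_failed", 0) + 1
                    continue
                if _self_complement_run(window) > c.max_self_complement_run:
                    diag["self_complement_failed"] = diag.get("self_complement_failed", 0) + 1
                    continue
                tm = melting_temp(window, "nn")
                key = (abs(tm - c.tm_target), length)
                if best is None or key < best:
                    best = key
            if best is not None:
                chosen.append((start, best[1]))
    return chosen


def design_primers(
    target: str,
    homolog_alignment: Sequence[str] | None = None,
    constraints: DesignConstraints | None = None,
) -> DesignResult:
    """Enumerate and rank primer pairs on the conserved windows of a
    target gene.

    ``homolog_alignment`` holds the aligned in-group copies with the
    target as its first row; when omitted the whole target is treated as
    conserved.  Pairs are ranked by the Tm match between mates, then by
    product length closest to the midpoint of the allowed range; the
    order is deterministic.
    """
    c = constraints or DesignConstraints()
    if homolog_alignment is None:
        homolog_alignment = [target]
    if homolog_alignment[0].replace("-", "") != target:
        raise PrimerError("first alignment row must be the design target")
    if len(target) <= c.product_min:
        raise PrimerError(
            f"target ({len(target)} bp) is shorter than the minimum product "
            f"({c.product_min} bp)"
        )
    diag: dict[str, int] = {}
    runs = conserved_runs(homolog_alignment)
    diag["conserved_runs"] = len(runs)
    diag["conserved_bp"] = sum(hi - lo for lo, hi in runs)
    windows = _candidate_primers(target, runs, c, diag)
    diag["candidate_windows"] = len(windows)
    mid = (c.product_min + c.product_max) / 2.0
    scored: list[tuple[tuple, PrimerPair]] = []
    tm_cache: dict[tuple[int, int], float] = {}

    def tm_of(start: int, length: int) -> float:
        key = (start, length)
        if key not in tm_cache:
            tm_cache[key] = melting_temp(target[start : start + length], "nn")
        return tm_cache[key]

    for f_start, f_len in windows:
        for r_start, r_len in windows:
            r_end = r_start + r_len
            product = r_end - f_start
            if not (c.product_min <= product <= c.product_max):
                continue
            if r_start < f_start + f_len:  # overlapping footprints
                continue
            tmf = tm_of(f_start, f_len)
            tmr = tm_of(r_start, r_len)
            if abs(tmf - tmr) > c.max_tm_diff:
                diag["tm_mismatch_failed"] = diag.get("tm_mismatch_failed", 0) + 1
                continue
            fwd = Primer("F", target[f_start : f_start + f_len], tm=tmf)
            rev = Primer("R", reverse_complement(target[r_start:r_end]), tm=tmr)
            pair = PrimerPair(
                forward=fwd,
                reverse=rev,
                expected_product_range=(c.product_min, c.product_max),
                designed_product=product,
            )
            rank = (round(abs(tmf - tmr), 6), abs(product - mid), f_start, r_end)
            scored.append((rank, pair))
    scored.sort(key=lambda x: x[0])
    diag["pairs"] = len(scored)
    return DesignResult(pairs=[p for _, p in scored], diagnostics=diag)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


@dataclass
class PcrParams:
    max_mismatch: int = 1
    require_exact_3prime: int = 3


@dataclass
class PrimerSite:
    start: int  # 1-based position of the footprint's leftmost template base
    strand: str  # '+': primer extends rightward; '-': leftward
    mismatches: int
    primer_name: str


@dataclass
class AmpliconHit:
    genome_id: str
    contig_id: str
    forward_site: PrimerSite
    reverse_site: PrimerSite
    product_length: int  # distance between outer 5' ends, inclusive


def _site_positions(
    template: np.ndarray, primer: str, strand: str, params: PcrParams
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based) where the primer footprint matches with at
    most max_mismatch mismatches and an exact 3'-terminal block.

    On '+' the footprint equals the primer; on '-' it equals its reverse
    complement (the primer anneals to the forward strand and extends
    leftward).  Returns (positions, mismatch counts).
    """
    pat = primer if strand == "+" else reverse_complement(primer)
    m = len(pat)
    L = template.shape[0]
    if L < m:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    pat_arr = np.frombuffer(pat.encode(), dtype=np.uint8)
    n_win = L - m + 1
    mm = np.zeros(n_win, dtype=np.int32)
    for k in range(m):
        mm += template[k : k + n_win] != pat_arr[k]
    req = min(params.require_exact_3prime, m)
    if req > 0:
        mm3 = np.zeros(n_win, dtype=np.int32)
        three_prime = range(m - req, m) if strand == "+" else range(req)
        for k in three_prime:
            mm3 += template[k : k + n_win] != pat_arr[k]
        ok = (mm <= params.max_mismatch) & (mm3 == 0)
    else:
        ok = mm <= params.max_mismatch
    pos = np.nonzero(ok)[0]
    return pos, mm[pos]


def insilico_pcr(
    genome: GenomeRecord,
    pair: PrimerPair,
    params: PcrParams | None = None,
) -> list[AmpliconHit]:
    """Predict PCR products: every inward-facing forward/reverse site
    pair whose product length (both primer footprints included) falls in
    the pair's expected product range."""
    params = params or PcrParams()
    lo, hi = pair.expected_product_range
    hits: list[AmpliconHit] = []
    for contig_id, seq in genome.contigs:
        tpl = np.frombuffer(seq.encode(), dtype=np.uint8)
        # two chemistry-equivalent orientations: F rightward with R
        # leftward, and R rightward with F leftward
        for left, right in ((pair.forward, pair.reverse), (pair.reverse, pair.forward)):
            lpos, lmm = _site_positions(tpl, left.sequence, "+", params)
            rpos, rmm = _site_positions(tpl, right.sequence, "-", params)
            if len(lpos) == 0 or len(rpos) == 0:
                continue
            r_end = rpos + len(right.sequence)  # exclusive right edge
            for lp, lm in zip(lpos, lmm):
                sel = np.nonzero(
                    (rpos >= lp + len(left.sequence)) & (r_end - lp >= lo) & (r_end - lp <= hi)
                )[0]
                for idx in sel:
                    hits.append(
                        AmpliconHit(
                            genome_id=genome.strain_id,
                            contig_id=contig_id,
                            forward_site=PrimerSite(
                                start=int(lp) + 1, strand="+",
                                mismatches=int(lm), primer_name=left.name,
                            ),
                            reverse_site=PrimerSite(
                                start=int(rpos[idx]) + 1, strand="-",
                                mismatches=int(rmm[idx]), primer_name=right.name,
                            ),
                            product_length=int(r_end[idx] - lp),
                        )
                    )
    hits.sort(key=lambda h: (h.contig_id, h.forward_site.start, h.product_length))
    return hits


@dataclass
class SpecificityRow:
    genome_id: str
    product_lengths: list[int]

    @property
    def positive(self) -> bool:
        return bool(self.product_lengths)

    @property
    def multi_band(self) -> bool:
        return len(self.product_lengths) > 1


def specificity_matrix(
    panel: Sequence[GenomeRecord],
    pair: PrimerPair,
    params: PcrParams | None = None,
) -> list[SpecificityRow]:
    """In-silico PCR across a genome panel, one row per genome in input
    order; multi-product genomes keep every predicted band."""
    if not panel:
        raise PrimerError("empty genome panel")
    rows: list[SpecificityRow] = []
    for genome in panel:
        hits = insilico_pcr(genome, pair, params)
        rows.append(
            SpecificityRow(
                genome_id=genome.strain_id,
                product_lengths=[h.product_length for h in hits],
            )
        )
    return rows
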