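"""Synthetic strain panels with known ground truth.

A single ancestor genome is simulated (i.i.d. background at a target GC
with codon-structured gene loci and two marker loci), then evolved into
an in-group (low substitution rate, carrying a planted diagnostic gene)
and an out-group (higher rate, diagnostic gene deleted).  Substitution
follows the Jukes–Cantor model, whose closed form provides the expected
identity between any two strains — the recovery oracle used throughout
the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import (
    GeneRecord,
    GenomeRecord,
    MarkerProfile,
    reverse_complement,
    translate_cds,
    write_annotation,
    write_fasta,
    write_marker_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Panel-generation parameters.

    Defaults emulate a culture-collection reclassification panel: a
    small near-clonal in-group around a type strain (pairwise ANI > 95%)
    and a more divergent out-group (ANI roughly 85–94%), desk-scale
    200 kb genomes, Pseudomonas-like GC, and one 639-bp diagnostic gene
    carried only by the in-group.
    """

    seed: int = 0
    n_ingroup: int = 4
    n_outgroup: int = 10
    genome_length: int = 200_000
    gc: float = 0.62
    n_genes: int = 40
    gene_length: int = 900
    subst_rate_ingroup: float = 0.01
    subst_rate_outgroup: float = 0.08
    indel_rate: float = 0.0
    marker_16s_length: int = 1500
    marker_rpod_length: int = 760
    planted_marker_length: int = 639
    planted_marker_ingroup_only: bool = True

    def validate(self) -> None:
        if self.n_ingroup < 2:
            raise SimulationError("need at least 2 in-group strains")
        if min(self.subst_rate_ingroup, self.subst_rate_outgroup, self.indel_rate) < 0:
            raise SimulationError("rates must be non-negative")
        if not 0.0 < self.gc < 1.0:
            raise SimulationError("gc must be in (0, 1)")
        occupied = (
            self.n_genes * self.gene_length
            + self.planted_marker_length
            + self.marker_16s_length
            + self.marker_rpod_length
        )
        if occupied > self.genome_length:
            raise SimulationError(
                f"loci need {occupied} bp but genome_length is {self.genome_length}"
            )
        for name in ("gene_length", "planted_marker_length"):
            if getattr(self, name) % 3 != 0:
                raise SimulationError(f"{name} must be a multiple of 3")


@dataclass
class PanelTruth:
    labels: dict[str, str]  # strain -> "ingroup" | "outgroup"
    rates: dict[str, float]  # strain -> substitutions/site from the ancestor
    expected_identity: dict[str, dict[str, float]]
    planted_gene_id: str
    carriers: list[str]


@dataclass
class SimPanel:
    config: SimConfig
    genomes: list[GenomeRecord]
    annotations: dict[str, list[GeneRecord]]
    marker_profiles: list[MarkerProfile]
    truth: PanelTruth

    def genome(self, strain_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.strain_id == strain_id:
                return g
        raise KeyError(strain_id)

    def proteome(self, strain_id: str) -> list[tuple[str, str]]:
        return [
            (g.gene_id, translate_cds(g.sequence)) for g in self.annotations[strain_id]
        ]

    @property
    def type_strain_id(self) -> str:
        return self.genomes[0].strain_id


def expected_identity(t: float) -> float:
    """Expected percent identity after one lineage evolves for t
    substitutions/site under Jukes–Cantor (use the summed path length,
    t_a + t_b, for two lineages diverging from a common ancestor)."""
    if t < 0:
        raise SimulationError("t must be non-negative")
    p = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
    return 100.0 * (1.0 - p)


def substitution_probability(t: float) -> float:
    if t < 0:
        raise SimulationError("t must be non-negative")
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.arange(4, dtype=np.uint8), size=length, p=probs)


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + random non-stop codons + TAA, sampled near the target GC."""
    n_codons = length // 3 - 2
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codons: list[str] = []
    while len(codons) < n_codons:
        draw = rng.choice(np.arange(4, dtype=np.uint8), size=3, p=probs)
        codon = "".join("ACGT"[b] for b in draw)
        if codon not in _STOPS:
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


@dataclass
class _Locus:
    locus_id: str
    kind: str  # "gene" | "marker16s" | "markerrpod" | "diag"
    start: int  # 1-based inclusive
    end: int
    strand: str


def _place_loci(
    rng: np.random.Generator, genome_length: int, lengths: list[tuple[str, str, int]]
) -> list[_Locus]:
    """Place non-overlapping loci at seeded random positions."""
    placed: list[_Locus] = []
    intervals: list[tuple[int, int]] = []
    for locus_id, kind, length in lengths:
        ok = False
        for _ in range(10_000):
            start = int(rng.integers(1, genome_length - length + 2))
            end = start + length - 1
            if all(end < s or start > e for s, e in intervals):
                ok = True
                break
        if not ok:
            raise SimulationError(f"could not place locus {locus_id!r} (genome too full)")
        strand = "+" if kind.startswith("marker") else ("+", "-")[int(rng.integers(2))]
        intervals.append((start, end))
        placed.append(_Locus(locus_id, kind, start, end, strand))
    placed.sort(key=lambda l: l.start)
    return placed


@dataclass
class Ancestor:
    genome: GenomeRecord
    loci: list[_Locus]
    config: SimConfig


def simulate_ancestor(cfg: SimConfig) -> Ancestor:
    """Build the ancestral genome: i.i.d. background at the target GC
    with codon-structured gene loci, two marker loci and the planted
    diagnostic gene, fully reproducible from the seed."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA5CE]))
    arr = _random_background(rng, cfg.genome_length, cfg.gc)
    wanted: list[tuple[str, str, int]] = [
        ("marker_16s", "marker16s", cfg.marker_16s_length),
        ("marker_rpod", "markerrpod", cfg.marker_rpod_length),
        ("diag0001", "diag", cfg.planted_marker_length),
    ]
    wanted += [
        (f"core{i:04d}", "gene", cfg.gene_length) for i in range(1, cfg.n_genes + 1)
    ]
    loci = _place_loci(rng, cfg.genome_length, wanted)
    code = {b: i for i, b in enumerate("ACGT")}
    for locus in loci:
        if locus.kind in ("gene", "diag"):
            cds = _random_cds(rng, locus.end - locus.start + 1, cfg.gc)
            genomic = cds if locus.strand == "+" else reverse_complement(cds)
            arr[locus.start - 1 : locus.end] = [code[c] for c in genomic]
    seq = _decode(arr)
    genome = GenomeRecord(
        strain_id="ancestor", contigs=[("chr", seq)], metadata={"role": "ancestor"}
    )
    return Ancestor(genome=genome, loci=loci, config=cfg)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.encode(), dtype=np.uint8)]


def evolve_genome(
    ancestor: Ancestor,
    strain_id: str,
    t: float,
    deletions: Sequence[str] = (),
    seed: int = 0,
) -> tuple[GenomeRecord, list[GeneRecord], MarkerProfile]:
    """Evolve one descendant: per-site Jukes–Cantor substitution at
    divergence t, then clean excision of the listed gene loci with all
    downstream coordinates shifted.

    Optional indels (geometric lengths, mean 3 bp) are restricted to
    unannotated background so annotations and marker columns stay exact;
    they never touch the planted diagnostic gene.
    """
    cfg = ancestor.config
    known = {l.locus_id for l in ancestor.loci}
    for d in deletions:
        if d not in known:
            raise SimulationError(f"unknown gene id in deletions: {d!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed, 0xE01E]))
    arr = _encode(ancestor.genome.contigs[0][1]).copy()
    p = substitution_probability(t)
    if p > 0:
        mask = rng.random(arr.shape[0]) < p
        n_sub = int(mask.sum())
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=n_sub).astype(np.uint8)) % 4

    events: list[tuple[int, int]] = []  # (position after which to cut, signed length)
    if cfg.indel_rate > 0:
        n_events = rng.binomial(arr.shape[0], cfg.indel_rate)
        occupied = [(l.start, l.end) for l in ancestor.loci]
        for _ in range(n_events):
            pos = int(rng.integers(1, arr.shape[0] + 1))
            if any(s <= pos <= e for s, e in occupied):
                continue
            length = int(rng.geometric(1.0 / 3.0))
            if rng.random() < 0.5:
                events.append((pos, length))  # insertion
            else:
                events.append((pos, -length))  # deletion

    # apply deletions of whole loci plus background indels, high to low
    cuts: list[tuple[int, int, np.ndarray | None]] = []
    for locus in ancestor.loci:
        if locus.locus_id in deletions:
            cuts.append((locus.start, locus.end, None))
    for pos, length in events:
        if length < 0:
            cuts.append((pos, min(pos - length - 1, arr.shape[0]), None))
        else:
            ins = _random_background(rng, length, cfg.gc)
            cuts.append((pos, pos - 1, ins))  # pure insertion before pos
    cuts.sort(key=lambda c: c[0], reverse=True)
    pieces = arr
    shift_at: list[tuple[int, int]] = []  # (original position, cumulative delta)
    for start, end, ins in cuts:
        left = pieces[: start - 1]
        right = pieces[end:]
        mid = ins if ins is not None else np.empty(0, dtype=np.uint8)
        delta = len(mid) - (end - start + 1)
        pieces = np.concatenate([left, mid, right])
        shift_at.append((start, delta))

    def new_coord(pos: int) -> int:
        delta = sum(d for s, d in shift_at if s <= pos)
        return pos + delta

    seq = _decode(pieces)
    genome = GenomeRecord(
        strain_id=strain_id,
        contigs=[("chr", seq)],
        metadata={"divergence": f"{t:g}"},
    )
    genes: list[GeneRecord] = []
    markers: dict[str, str] = {}
    for locus in ancestor.loci:
        if locus.locus_id in deletions:
            continue
        s, e = new_coord(locus.start), new_coord(locus.end)
        sub = genome.slice("chr", s, e, locus.strand)
        if locus.kind in ("gene", "diag"):
            genes.append(
                GeneRecord(
                    gene_id=locus.locus_id,
                    genome_id=strain_id,
                    contig_id="chr",
                    start=s,
                    end=e,
                    strand=locus.strand,
                    sequence=sub,
                    protein=translate_cds(sub),
                )
            )
        elif locus.kind == "marker16s":
            markers["16s"] = sub
        else:
            markers["rpod"] = sub
    profile = MarkerProfile(strain_id, markers["16s"], markers["rpod"])
    return genome, genes, profile


def simulate_panel(cfg: SimConfig) -> SimPanel:
    """Evolve the full panel from one ancestor.

    Strain ids are IN01.. for the in-group (IN01 is the designated type
    strain) and OUT01.. for the out-group.  When the planted marker is
    in-group-only it is deleted from every out-group genome.
    """
    cfg.validate()
    ancestor = simulate_ancestor(cfg)
    strains: list[tuple[str, float, list[str]]] = []
    for i in range(cfg.n_ingroup):
        strains.append((f"IN{i + 1:02d}", cfg.subst_rate_ingroup, []))
    out_deletions = ["diag0001"] if cfg.planted_marker_ingroup_only else []
    for i in range(cfg.n_outgroup):
        strains.append((f"OUT{i + 1:02d}", cfg.subst_rate_outgroup, out_deletions))

    genomes: list[GenomeRecord] = []
    annotations: dict[str, list[GeneRecord]] = {}
    profiles: list[MarkerProfile] = []
    rates: dict[str, float] = {}
    for k, (sid, t, dels) in enumerate(strains):
        genome, genes, profile = evolve_genome(ancestor, sid, t, dels, seed=k + 1)
        genomes.append(genome)
        annotations[sid] = genes
        profiles.append(profile)
        rates[sid] = t

    labels = {
        sid: ("ingroup" if sid.startswith("IN") else "outgroup") for sid, _, _ in strains
    }
    exp: dict[str, dict[str, float]] = {}
    for sid_a, ta, _ in strains:
        exp[sid_a] = {}
        for sid_b, tb, _ in strains:
            exp[sid_a][sid_b] = 100.0 if sid_a == sid_b else expected_identity(ta + tb)
    carriers = [sid for sid, _, dels in strains if "diag0001" not in dels]
    truth = PanelTruth(
        labels=labels,
        rates=rates,
        expected_identity=exp,
        planted_gene_id="diag0001",
        carriers=carriers,
    )
    return SimPanel(
        config=cfg,
        genomes=genomes,
        annotations=annotations,
        marker_profiles=profiles,
        truth=truth,
    )


def write_panel(panel: SimPanel, outdir: str | Path) -> None:
    """Persist a panel as FASTA + GFF-style annotation + markers.tsv +
    truth.json (all plain text)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in panel.genomes:
        write_fasta(genome.contigs, outdir / f"{genome.strain_id}.fasta")
        write_annotation(
            panel.annotations[genome.strain_id], outdir / f"{genome.strain_id}.gff"
        )
        prot = [
            (g.gene_id, g.protein or translate_cds(g.sequence))
            for g in panel.annotations[genome.strain_id]
        ]
        write_fasta(prot, outdir / f"{genome.strain_id}.faa")
        write_fasta(
            [(g.gene_id, g.sequence) for g in panel.annotations[genome.strain_id]],
            outdir / f"{genome.strain_id}.ffn",
        )
    write_marker_table(panel.marker_profiles, outdir / "markers.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(asdict(panel.truth), fh, indent=1)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(panel.config), fh, indent=1)
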