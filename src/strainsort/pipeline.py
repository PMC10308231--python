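"""End-to-end reclassification study.

Orchestrates the full workflow over a strain panel: marker-gene OTU
clustering and tree, whole-genome similarity of every strain against the
designated type strain, species calls, the core-unique diagnostic-gene
funnel, primer design and the in-silico PCR specificity matrix — and
persists the study report tables.

The in-group for the diagnostic screen is defined by the genome
similarity calls (same species as the type strain), not by OTU
membership: marker-gene OTUs can contain strains that fail the
whole-genome criterion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import genome_similarity as gs
from . import markers as mk
from . import orthologs as og
from . import primers as pr
from .phylo import PhyloTree
from .seqio import GeneRecord, GenomeRecord, MarkerProfile, reverse_complement
from .synthetic import SimPanel


class PipelineError(ValueError):
    pass


@dataclass
class StageToggles:
    markers: bool = True
    tree: bool = True
    genomes: bool = True
    orthologs: bool = True
    primers: bool = True


@dataclass
class RunConfig:
    type_strain_id: str
    otu_threshold: float = 98.0
    otu_linkage: str = "complete"
    marker_mode: str = "concat"
    bootstrap_reps: int = 500
    seed: int = 17
    species_thresholds: gs.SpeciesThresholds = field(default_factory=gs.SpeciesThresholds)
    ani_params: gs.AniParams = field(default_factory=gs.AniParams)
    gbdp_params: gs.GbdpParams = field(default_factory=gs.GbdpParams)
    ddh_model: str = "ggdc2-logitlog-synthetic-v1"
    rbh_params: og.RbhParams = field(default_factory=og.RbhParams)
    presence_params: og.PresenceParams = field(default_factory=og.PresenceParams)
    design_constraints: pr.DesignConstraints = field(default_factory=pr.DesignConstraints)
    pcr_params: pr.PcrParams = field(default_factory=pr.PcrParams)
    stages: StageToggles = field(default_factory=StageToggles)
    outdir: str | None = None


@dataclass
class PanelInputs:
    genomes: list[GenomeRecord]
    marker_profiles: list[MarkerProfile]
    annotations: Mapping[str, Sequence[GeneRecord]]
    proteomes: Mapping[str, Sequence[tuple[str, str]]]

    @classmethod
    def from_sim_panel(cls, panel: SimPanel) -> "PanelInputs":
        proteomes = {g.strain_id: panel.proteome(g.strain_id) for g in panel.genomes}
        return cls(
            genomes=panel.genomes,
            marker_profiles=panel.marker_profiles,
            annotations=panel.annotations,
            proteomes=proteomes,
        )

    def strain_ids(self) -> list[str]:
        return [g.strain_id for g in self.genomes]


@dataclass
class StudyReport:
    otu_table: pd.DataFrame
    tree: PhyloTree | None
    newick: str | None
    similarity: pd.DataFrame | None
    candidates: pd.DataFrame | None
    specificity: pd.DataFrame | None
    primer_pair: pr.PrimerPair | None
    funnel: dict[str, int]
    log: list[str]

    def write(self, outdir: str | Path, config: RunConfig | None = None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.otu_table.to_csv(out / "otus.tsv", sep="\t", index=False)
        if self.newick is not None:
            (out / "tree.nwk").write_text(self.newick + "\n")
        if self.similarity is not None:
            self.similarity.to_csv(
                out / "similarity.tsv", sep="\t", index=False, float_format="%.2f"
            )
        if self.candidates is not None:
            self.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        if self.specificity is not None:
            self.specificity.to_csv(out / "specificity.tsv", sep="\t", index=False)
        with open(out / "funnel.json", "w") as fh:
            json.dump(self.funnel, fh, indent=1, sort_keys=True)
        (out / "run.log").write_text("\n".join(self.log) + "\n")
        if config is not None:
            with open(out / "resolved_config.yaml", "w") as fh:
                yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def run_reclassification(inputs: PanelInputs, cfg: RunConfig) -> StudyReport:
    """Execute the study stages in order; identical config and inputs
    produce an identical report."""
    strains = inputs.strain_ids()
    log: list[str] = []
    if cfg.stages.genomes and cfg.type_strain_id not in strains:
        raise PipelineError(
            f"type strain {cfg.type_strain_id!r} not among genomes {strains}"
        )
    log.append(
        f"panel: {len(strains)} strains; type strain {cfg.type_strain_id}; "
        f"otu threshold {cfg.otu_threshold}% ({cfg.otu_linkage} linkage); "
        f"species rule ANI>={cfg.species_thresholds.ani_min} & "
        f"dDDH>={cfg.species_thresholds.ddh_min}; bootstrap {cfg.bootstrap_reps} "
        f"reps seed {cfg.seed}"
    )

    # ---- markers: OTU clustering -------------------------------------
    otu: mk.OtuAssignment | None = None
    ident: mk.IdentityMatrix | None = None
    otu_rows = []
    if cfg.stages.markers:
        ident = mk.identity_matrix(inputs.marker_profiles, mode=cfg.marker_mode)
        otu = mk.cluster_otus(ident, threshold=cfg.otu_threshold, linkage=cfg.otu_linkage)
        for p in inputs.marker_profiles:
            otu_rows.append({"strain": p.strain_id, "otu": otu.mapping[p.strain_id]})
        log.append(
            f"markers: {otu.n_otus()} OTUs and {otu.n_singletons()} singletons "
            f"at >={cfg.otu_threshold}% identity"
        )
    otu_table = pd.DataFrame(otu_rows, columns=["strain", "otu"])

    # ---- markers: NJ tree with bootstrap -----------------------------
    tree = newick = None
    if cfg.stages.tree:
        labels = [p.strain_id for p in inputs.marker_profiles]
        seqs = [p.concat for p in inputs.marker_profiles]
        guide = None
        if ident is not None and cfg.marker_mode == "concat":
            guide = (100.0 - ident.values) / 100.0
        aligned = mk.progressive_align(labels, seqs, guide_distances=guide)
        tree = mk.bootstrap_supports(labels, aligned, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
        newick = tree.newick()
        log.append(f"tree: NJ with {cfg.bootstrap_reps} bootstrap replicates")

    # ---- genome similarity vs the type strain ------------------------
    similarity = None
    same_species: dict[str, bool] = {}
    if cfg.stages.genomes:
        type_genome = next(g for g in inputs.genomes if g.strain_id == cfg.type_strain_id)
        model = gs.load_ddh_model(cfg.ddh_model)
        sim_rows = []
        otu_map = otu.mapping if otu else {}
        for genome in inputs.genomes:
            if genome.strain_id == cfg.type_strain_id:
                ani_v, ddh_v = 100.0, 100.0
            else:
                ani_v = gs.orthoani(genome, type_genome, cfg.ani_params).ani
                ddh_v = gs.ddh(genome, type_genome, cfg.gbdp_params, model).ddh
            call = gs.classify_species(ani_v, ddh_v, cfg.species_thresholds)
            same_species[genome.strain_id] = call.same_species
            sim_rows.append(
                {
                    "strain": genome.strain_id,
                    "otu": otu_map.get(genome.strain_id, ""),
                    "ani": round(ani_v, 2),
                    "ddh": round(ddh_v, 2),
                    "genome_size_bp": genome.total_size,
                    "gc_percent": round(100 * genome.gc, 1),
                    "cds_count": len(inputs.annotations.get(genome.strain_id, [])),
                    "same_species": call.same_species,
                }
            )
        similarity = pd.DataFrame(sim_rows)
        log.append(
            f"genomes: {sum(same_species.values())} strains same species as "
            f"{cfg.type_strain_id}"
        )

    # ---- diagnostic-gene funnel --------------------------------------
    candidates_df = None
    conserved: list[og.DiagnosticCandidate] = []
    n_candidates = 0
    if cfg.stages.orthologs:
        if not cfg.stages.genomes:
            raise PipelineError("orthologs stage requires the genomes stage")
        ingroup = sorted(s for s in strains if same_species[s])
        outgroup = sorted(s for s in strains if not same_species[s])
        if not outgroup:
            log.append("orthologs: no out-group strains; screen skipped")
        else:
            rbh: dict[tuple[str, str], list[tuple[str, str]]] = {}
            ordered = sorted(strains)
            for i, ga in enumerate(ordered):
                for gb in ordered[i + 1 :]:
                    rbh[(ga, gb)] = og.protein_rbh(
                        inputs.proteomes[ga], inputs.proteomes[gb], cfg.rbh_params
                    )
            groups = og.build_orthogroups(inputs.proteomes, rbh)
            gene_seqs = {
                (sid, g.gene_id): g.sequence
                for sid, genes in inputs.annotations.items()
                for g in genes
            }
            screened = og.screen_core_unique(groups, ingroup, outgroup, gene_seqs)
            n_candidates = len(screened)
            conserved = og.conservation_filter(
                screened, inputs.genomes, same_species, cfg.presence_params
            )
            candidates_df = pd.DataFrame(
                [
                    {
                        "group_id": c.group_id,
                        "representative": f"{c.genome_id}:{c.gene_id}",
                        "length_bp": len(c.sequence),
                        "present_in": ",".join(c.present_in),
                        "conserved": c in conserved,
                    }
                    for c in screened
                ],
                columns=["group_id", "representative", "length_bp", "present_in", "conserved"],
            )
            log.append(
                f"orthologs: {n_candidates} core-unique candidates, "
                f"{len(conserved)} conserved after sequence verification"
            )

    # ---- primers and specificity -------------------------------------
    specificity_df = None
    pair = None
    if cfg.stages.primers and conserved:
        target_cand = sorted(conserved, key=lambda c: c.group_id)[0]
        ingroup = sorted(s for s in strains if same_species[s])
        # homolog copies in the other in-group genomes, located by the
        # same nucleotide search that verified conservation
        homolog_rows = [target_cand.sequence]
        for sid in ingroup:
            if sid == target_cand.genome_id:
                continue
            call = og.presence_by_search(
                target_cand.sequence, next(g for g in inputs.genomes if g.strain_id == sid),
                cfg.presence_params,
            )
            if call.present and call.hit is not None:
                contig_seq = next(
                    seq for cid, seq in next(
                        g for g in inputs.genomes if g.strain_id == sid
                    ).contigs if cid == call.contig_id
                )
                sub = contig_seq[call.hit.s_start : call.hit.s_end]
                if call.hit.strand == "-":
                    sub = reverse_complement(sub)
                homolog_rows.append(sub)
        aligned = mk.progressive_align(
            [str(i) for i in range(len(homolog_rows))], homolog_rows
        )
        design = pr.design_primers(target_cand.sequence, aligned, cfg.design_constraints)
        if design.pairs:
            pair = design.pairs[0]
            rows = pr.specificity_matrix(inputs.genomes, pair, cfg.pcr_params)
            specificity_df = pd.DataFrame(
                [
                    {
                        "strain": r.genome_id,
                        "positive": r.positive,
                        "n_products": len(r.product_lengths),
                        "product_lengths": ",".join(map(str, r.product_lengths)),
                    }
                    for r in rows
                ]
            )
            log.append(
                f"primers: pair F={pair.forward.sequence} R={pair.reverse.sequence} "
                f"designed product {pair.designed_product} bp; "
                f"{int(specificity_df['positive'].sum())} positive genomes"
            )
        else:
            log.append(
                "primers: no constraint-passing pair; diagnostics "
                + json.dumps(design.diagnostics, sort_keys=True)
            )

    funnel = {
        "n_strains": len(strains),
        "n_otus": otu.n_otus() if otu else 0,
        "n_singletons": otu.n_singletons() if otu else 0,
        "n_same_species": int(sum(same_species.values())) if same_species else 0,
        "n_candidates": n_candidates,
        "n_conserved": len(conserved),
        "n_pcr_positive": int(specificity_df["positive"].sum())
        if specificity_df is not None
        else 0,
    }
    report = StudyReport(
        otu_table=otu_table,
        tree=tree,
        newick=newick,
        similarity=similarity,
        candidates=candidates_df,
        specificity=specificity_df,
        primer_pair=pair,
        funnel=funnel,
        log=log,
    )
    if cfg.outdir:
        report.write(cfg.outdir, cfg)
    return report


def funnel_summary(report: StudyReport) -> dict[str, int]:
    """Pure aggregation of the report tables."""
    return dict(report.funnel)
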