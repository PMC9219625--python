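"""End-to-end pipeline: simulate -> mine -> annotate -> distances -> HT ->
landscape, with a checksummed manifest for reproducibility.

The bundled demo scenario plants one recent horizontal transfer between
the two most divergent of a handful of species, builds genomes with aged
element copies, and must re-discover exactly that event from sequence
alone.  Rerunning with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotate, distmod, htdetect, landscape, mining, synth

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and scenario knobs in one validated place."""

    out_dir: str = "pipeline_out"
    seed: int = 1

    # scenario
    n_species: int = 3
    tree_height: float = 0.25
    genome_length: int = 60000
    copies_per_species: int = 8
    copy_classes: Tuple[str, ...] = (
        "intact",
        "intact",
        "intact",
        "intact",
        "intact",
        "intact",
        "full",
        "truncated",
    )
    copy_age_max: float = 0.04
    ht_scenario: str = "most_divergent"  # or "none"
    ht_time: float = 0.005
    host_gene_length: int = 10000
    secondary_gene_length: int = 3000

    # mining
    min_hit_score: float = 60.0
    top_k: int = 10
    flank: int = 2000
    census_min_len: int = 1000
    census_min_cov: float = 0.40
    census_min_id: float = 0.80

    # annotation
    tir_min_len: int = 8
    tir_max_len: int = 40
    consensus_min_copies: int = 6
    intact_min_aa: int = 301

    # HT filters
    identity_threshold: float = 0.70
    ratio_factor: float = 1.2
    alpha: float = 0.01

    # landscape
    bin_width: float = 1.0
    recent_cut: float = 2.0
    old_cut: float = 10.0

    def validate(self) -> None:
        if not 0.0 <= self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in [0,1]")
        if self.ratio_factor < 1.0:
            raise ValueError("ratio_factor must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.tir_min_len > self.tir_max_len:
            raise ValueError("tir_min_len must not exceed tir_max_len")
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        if len(self.copy_classes) != self.copies_per_species:
            raise ValueError("copy_classes must list one class per copy")
        if self.ht_scenario not in ("most_divergent", "none"):
            raise ValueError(f"unknown ht_scenario {self.ht_scenario!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "copy_classes" in data:
            data["copy_classes"] = tuple(data["copy_classes"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["copy_classes"] = list(d["copy_classes"])
        return d


@dataclass
class RunReport:
    out_dir: Path
    manifest: Dict[str, str]
    n_called_events: int
    called_members: List[List[str]]
    truth_ht: List[Tuple[str, str, float]]


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in sorted(records):
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    for sub in ("genomes", "genes", "truth", "mining", "annotate", "dist", "ht", "landscape"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- stage 1: simulate --------------------------------------------
    element0 = synth.make_te_element(int(rng.integers(2**31)))
    study = synth.simulate_ht_study(
        config.n_species,
        seed=int(rng.integers(2**31)),
        tree_height=config.tree_height,
        te_element=element0,
        host_gene_lengths={
            "RPL3": config.host_gene_length,
            "RPL4": config.host_gene_length,
        },
        secondary_gene_lengths={
            "RAG1": config.secondary_gene_length,
            "tub3": config.secondary_gene_length,
        },
        ht=None if config.ht_scenario == "none" else "most_divergent",
        ht_time=config.ht_time,
        preserve_orf=True,  # an active family keeps its transposase open
    )
    species = study.tree.leaf_labels
    # per-species element: the species' evolved copy of the ancestral element
    # (the HT scenario already decided who inherited whose element)
    per_species_element = {
        sp: synth.TEElement(
            study.te_seqs[sp], element0.tir_len, element0.orf_start, element0.orf_end
        )
        for sp in species
    }
    genomes: Dict[str, str] = {}
    truth_all = synth.SimulationTruth()
    ages = np.linspace(0.0, config.copy_age_max, config.copies_per_species)
    for sp in species:
        background = synth.random_sequence(
            config.genome_length, np.random.default_rng(int(rng.integers(2**31)))
        )
        genome, truth = synth.plant_te_copies(
            background,
            per_species_element[sp],
            config.copies_per_species,
            ages=ages,
            class_plan=list(config.copy_classes),
            seed=int(rng.integers(2**31)),
            species=sp,
        )
        genomes[sp] = genome
        truth_all.insertions.extend(truth.insertions)
    truth_all.ht_events = list(study.truth.ht_events)
    _write_fasta(out / "genomes" / "genomes.fasta", genomes)
    for gene, seqs in sorted(study.gene_seqs.items()):
        _write_fasta(out / "genes" / f"{gene}.fasta", seqs)
    truth_all.insertions_to_tsv(out / "truth" / "insertions.tsv")
    truth_all.ht_to_tsv(out / "truth" / "ht.tsv")
    with open(out / "truth" / "tree.nwk", "w") as fh:
        fh.write(study.tree.newick() + "\n")

    # ---- stage 2: mine -------------------------------------------------
    query = element0.transposase
    copies_by_species: Dict[str, List[annotate.ElementCopy]] = {}
    hit_rows = []
    for sp in species:
        hits = mining.translated_search(
            query,
            genomes[sp],
            query_id="transposase",
            contig=sp,
            min_score=config.min_hit_score,
        )
        loci = mining.cluster_hits(hits)
        loci = mining.select_top_nonoverlapping(loci, k=max(config.top_k, len(loci)))
        for h in loci:
            hit_rows.append(
                dict(
                    species=sp,
                    contig=h.contig,
                    start=h.start,
                    end=h.end,
                    strand=h.strand,
                    identity=round(h.identity, 3),
                    score=h.score,
                )
            )
        regions = [
            mining.extract_flanked(genomes[sp], h, flank=config.flank) for h in loci
        ]
        ref = per_species_element[sp]
        copies = []
        for reg in regions:
            copy = annotate.annotate_region(
                reg.sequence,
                ref,
                species=sp,
                contig=reg.contig,
                region_offset=reg.genome_start,
                strand=reg.strand,
            )
            copies.append(copy)
        copies_by_species[sp] = copies
    pd.DataFrame(
        hit_rows,
        columns=["species", "contig", "start", "end", "strand", "identity", "score"],
    ).to_csv(out / "mining" / "hits.tsv", sep="\t", index=False)

    # ---- stage 3: annotate + census ------------------------------------
    copy_rows = []
    consensi: Dict[str, str] = {}
    census_rows = []
    for sp in species:
        copies = copies_by_species[sp]
        for c in copies:
            copy_rows.append(
                dict(
                    species=sp,
                    contig=c.contig,
                    start=c.start,
                    end=c.end,
                    strand=c.strand,
                    te_class=c.te_class,
                    tir_len=c.tir.length if c.tir else 0,
                    tir_mismatches=c.tir.mismatches if c.tir else -1,
                    tsd=str(c.tsd),
                    orf_aa=c.orf.protein_aa if c.orf else 0,
                )
            )
        seqs = [c.sequence for c in copies if c.sequence]
        classes = [c.te_class for c in copies if c.sequence]
        ref_seq = per_species_element[sp].sequence
        rows = annotate.align_copies_to_reference(seqs, ref_seq)
        cons = annotate.build_consensus(
            rows, min_copies=config.consensus_min_copies, classes=classes
        )
        consensi[sp] = cons.sequence
        census = mining.count_copies(
            seqs,
            ref_seq,
            element_id="element",
            species=sp,
            min_len=config.census_min_len,
            min_cov=config.census_min_cov,
            min_id=config.census_min_id,
        )
        n_intact = sum(1 for c in copies if c.te_class == "intact")
        n_full = sum(1 for c in copies if c.te_class in ("full", "intact"))
        census_rows.append(
            dict(
                species=sp,
                element="element",
                copies=census.count,
                intact=n_intact,
                full=n_full,
            )
        )
    pd.DataFrame(
        copy_rows,
        columns=[
            "species",
            "contig",
            "start",
            "end",
            "strand",
            "te_class",
            "tir_len",
            "tir_mismatches",
            "tsd",
            "orf_aa",
        ],
    ).to_csv(out / "annotate" / "copies.tsv", sep="\t", index=False)
    pd.DataFrame(
        census_rows, columns=["species", "element", "copies", "intact", "full"]
    ).to_csv(out / "mining" / "census.tsv", sep="\t", index=False)
    _write_fasta(out / "annotate" / "consensus.fasta", consensi)

    # ---- stage 4: distances --------------------------------------------
    # consensi are indel-free simulations projected on reference columns,
    # hence already on a common column space
    ref_len = min(len(s) for s in consensi.values())
    aligned_cons = {sp: s[:ref_len] for sp, s in sorted(consensi.items())}
    identity = distmod.identity_matrix(aligned_cons)
    d_te = distmod.mcl_distance_matrix(aligned_cons)
    d_hosts = {
        g: distmod.mcl_distance_matrix(study.gene_seqs[g])
        for g in ("RPL3", "RPL4")
    }
    d_secondary = {
        g: distmod.mcl_distance_matrix(study.gene_seqs[g])
        for g in ("RAG1", "tub3")
    }
    identity.to_tsv(out / "dist" / "te_identity.tsv")
    d_te.to_tsv(out / "dist" / "te_mcl.tsv")
    for g, m in {**d_hosts, **d_secondary}.items():
        m.to_tsv(out / "dist" / f"{g}.tsv")

    # ---- stage 5: horizontal transfer ----------------------------------
    result = htdetect.detect_ht(
        identity,
        d_te,
        d_hosts,
        identity_threshold=config.identity_threshold,
        ratio_factor=config.ratio_factor,
        alpha=config.alpha,
        te_seqs=aligned_cons,
        host_seqs={g: study.gene_seqs[g] for g in ("RPL3", "RPL4")},
    )
    htdetect.confirm_events(
        result.events,
        d_secondary,
        study.vertebrate,
        ratio_factor=config.ratio_factor,
        alpha=config.alpha,
        te_seqs=aligned_cons,
        secondary_seqs={g: study.gene_seqs[g] for g in ("RAG1", "tub3")},
    )
    result.candidates_frame().to_csv(
        out / "ht" / "ht_candidates.tsv", sep="\t", index=False, float_format="%.6g"
    )
    result.events_frame().to_csv(
        out / "ht" / "ht_events.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # ---- stage 6: landscape --------------------------------------------
    activity = {}
    for sp in species:
        seqs = [c.sequence for c in copies_by_species[sp] if c.sequence]
        prof = landscape.divergence_profile(
            seqs, consensi[sp], bin_width=config.bin_width, species=sp
        )
        prof.to_tsv(out / "landscape" / f"{sp}.tsv")
        if prof.total_kb > 0:
            rep = landscape.activity_assessment(
                prof, recent_cut=config.recent_cut, old_cut=config.old_cut
            )
            activity[sp] = json.loads(rep.to_json())
    with open(out / "landscape" / "activity.json", "w") as fh:
        json.dump(activity, fh, sort_keys=True, indent=1)

    # ---- manifest -------------------------------------------------------
    manifest: Dict[str, str] = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(out))] = _sha256(p)
    payload = {"config": config.to_dict(), "files": manifest}
    with open(out / "manifest.json", "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    called = [e.members for e in result.called_events]
    return RunReport(
        out_dir=out,
        manifest=manifest,
        n_called_events=len(called),
        called_members=called,
        truth_ht=truth_all.ht_events,
    )
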