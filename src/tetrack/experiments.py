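"""Replicate-level horizontal-transfer experiments over simulated truth.

These drivers wire the simulation bundle through the distance and filter
stages exactly as the analysis scripts do: element identity and
composite-likelihood TN93 distances from the per-species element
sequences, host-gene distances from RPL3/RPL4, the three-filter screen,
and optional secondary-gene confirmation.  Simulated sequences are
indel-free and therefore already on a common alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import distmod, htdetect, synth

__all__ = [
    "HTReplicate",
    "run_ht_replicate",
    "null_event_rate",
    "power_recovery",
]


@dataclass
class HTReplicate:
    study: synth.HTStudy
    result: htdetect.HTResult

    @property
    def called_events(self) -> List[htdetect.HTEvent]:
        return self.result.called_events

    def planted_pair_recovered(self) -> bool:
        """True when the planted donor/recipient pair sits inside one called
        event."""
        for donor, recipient, _ in self.study.truth.ht_events:
            hit = any(
                donor in ev.members and recipient in ev.members
                for ev in self.called_events
            )
            if not hit:
                return False
        return bool(self.study.truth.ht_events)

    def planted_pair_confirmed(self) -> bool:
        for donor, recipient, _ in self.study.truth.ht_events:
            hit = any(
                donor in ev.members
                and recipient in ev.members
                and ev.confirmed
                for ev in self.called_events
            )
            if not hit:
                return False
        return bool(self.study.truth.ht_events)


def run_ht_replicate(
    seed: int,
    *,
    n_species: int = 20,
    tree_height: float = 0.5,
    te_rate: float = 1.0,
    ht: Optional[str] = None,
    ht_time: float = 0.01,
    te_length_element: Optional[synth.TEElement] = None,
    host_gene_length: int = 10000,
    identity_threshold: float = 0.70,
    ratio_factor: float = 1.2,
    alpha: float = 0.01,
    confirm: bool = False,
) -> HTReplicate:
    """One simulated replicate pushed through the full HT screen."""
    study = synth.simulate_ht_study(
        n_species,
        seed=seed,
        tree_height=tree_height,
        te_rate=te_rate,
        te_element=te_length_element,
        host_gene_lengths={"RPL3": host_gene_length, "RPL4": host_gene_length},
        ht=ht,
        ht_time=ht_time,
    )
    identity = distmod.identity_matrix(study.te_seqs)
    d_te = distmod.mcl_distance_matrix(study.te_seqs)
    d_hosts = {
        g: distmod.mcl_distance_matrix(study.gene_seqs[g]) for g in ("RPL3", "RPL4")
    }
    host_seqs = {g: study.gene_seqs[g] for g in ("RPL3", "RPL4")}
    result = htdetect.detect_ht(
        identity,
        d_te,
        d_hosts,
        identity_threshold=identity_threshold,
        ratio_factor=ratio_factor,
        alpha=alpha,
        te_seqs=study.te_seqs,
        host_seqs=host_seqs,
    )
    if confirm:
        secondary = {
            g: distmod.mcl_distance_matrix(study.gene_seqs[g])
            for g in ("RAG1", "tub3")
            if g in study.gene_seqs
        }
        htdetect.confirm_events(
            result.events,
            secondary,
            study.vertebrate,
            ratio_factor=ratio_factor,
            alpha=alpha,
            te_seqs=study.te_seqs,
            secondary_seqs={
                g: study.gene_seqs[g] for g in ("RAG1", "tub3")
                if g in study.gene_seqs
            },
        )
    return HTReplicate(study=study, result=result)


@dataclass
class CensusExperiment:
    """Plant -> mine -> annotate -> census round trip with truth."""

    planted: Dict[str, int]  # class -> planted count
    recovered: Dict[str, int]  # class -> annotated count
    n_loci: int
    n_matched: int
    n_class_correct: int
    census_count: int
    expected_census_count: int

    @property
    def class_accuracy(self) -> float:
        return self.n_class_correct / max(self.n_matched, 1)

    @property
    def exact(self) -> bool:
        return (
            self.planted == self.recovered
            and self.n_matched == sum(self.planted.values())
            and self.census_count == self.expected_census_count
        )


def census_experiment(
    seed: int,
    *,
    age: float = 0.0,
    n_truncated: int = 30,
    n_full: int = 12,
    n_intact: int = 8,
    genome_length: int = 400000,
    min_score: float = 60.0,
    flank: int = 2000,
) -> CensusExperiment:
    """Plant a known copy census, re-locate it by translated search, and
    annotate every locus against the reference element."""
    from . import annotate, mining

    element = synth.make_te_element(seed)
    rng = np.random.default_rng(seed + 1)
    genome = synth.random_sequence(genome_length, rng)
    plan = (
        ["truncated"] * n_truncated + ["full"] * n_full + ["intact"] * n_intact
    )
    plan = [plan[i] for i in rng.permutation(len(plan))]
    g2, truth = synth.plant_te_copies(
        genome, element, len(plan), ages=age, class_plan=plan, seed=seed + 2
    )
    hits = mining.cluster_hits(
        mining.translated_search(element.transposase, g2, min_score=min_score)
    )
    recovered: Dict[str, int] = {"truncated": 0, "full": 0, "intact": 0}
    matched = correct = 0
    copy_seqs = []
    for h in hits:
        reg = mining.extract_flanked(g2, h, flank=flank)
        copy = annotate.annotate_region(
            reg.sequence,
            element,
            region_offset=reg.genome_start,
            strand=reg.strand,
        )
        recovered[copy.te_class] += 1
        copy_seqs.append(copy.sequence)
        for ins in truth.insertions:
            if max(ins.start, copy.start) < min(ins.end, copy.end):
                matched += 1
                correct += copy.te_class == ins.te_class
                break
    census = mining.count_copies(copy_seqs, element.sequence)
    # at age 0 extracted copies match the reference exactly, so the census
    # outcome is predictable from the planted lengths alone
    expected = sum(
        1
        for ins in truth.insertions
        if (ins.end - ins.start) > max(1000, 0.40 * element.length)
    )
    return CensusExperiment(
        planted={
            "truncated": n_truncated,
            "full": n_full,
            "intact": n_intact,
        },
        recovered=recovered,
        n_loci=len(hits),
        n_matched=matched,
        n_class_correct=correct,
        census_count=census.count,
        expected_census_count=expected,
    )


def null_event_rate(
    n_replicates: int = 100,
    base_seed: int = 0,
    **kwargs,
) -> Tuple[float, List[int]]:
    """Fraction of vertical-only replicates with at least one called event
    (the screen's empirical false-positive rate), plus per-replicate event
    counts."""
    counts = []
    for r in range(n_replicates):
        rep = run_ht_replicate(base_seed + r, ht=None, **kwargs)
        counts.append(len(rep.called_events))
    rate = sum(1 for c in counts if c > 0) / n_replicates
    return rate, counts


def power_recovery(
    n_replicates: int = 100,
    base_seed: int = 0,
    *,
    confirm: bool = True,
    **kwargs,
) -> Tuple[float, float]:
    """Recovery of one planted recent transfer between the two most
    divergent lineages: (fraction of replicates where the planted pair is
    inside a called event, fraction where that event is also confirmed)."""
    recovered = confirmed = 0
    for r in range(n_replicates):
        rep = run_ht_replicate(
            base_seed + r, ht="most_divergent", confirm=confirm, **kwargs
        )
        recovered += rep.planted_pair_recovered()
        if confirm:
            confirmed += rep.planted_pair_confirmed()
    return recovered / n_replicates, confirmed / n_replicates
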