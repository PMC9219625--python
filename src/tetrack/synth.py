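"""Synthetic genomes, host genes, and transposon histories with known truth.

The generator emulates the study design behind transposon horizontal-
transfer (HT) surveys: a host species tree, neutrally evolving single-copy
host genes (ribosomal-protein analogues), and a cut-and-paste DNA
transposon with terminal inverted repeats (TIRs), a TA target-site
duplication (TSD), and an internal transposase ORF.  Copies are planted at
chosen ages and truncation states; transfer histories are either purely
vertical or carry injected HT directives between chosen lineages.

Every routine is a pure function of its parameters and seed.  Coordinates
are 0-based half-open throughout.  Copy ages are expressed directly as
expected substitutions per site applied to the copy, not as years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

__all__ = [
    "SpeciesTree",
    "SubstitutionModel",
    "TEElement",
    "TEHistorySpec",
    "Insertion",
    "SimulationTruth",
    "simulate_yule_tree",
    "evolve_along_tree",
    "evolve_sequence",
    "random_sequence",
    "make_te_element",
    "plant_te_copies",
    "apply_ht_scenario",
    "simulate_ht_study",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_STOPS = ("TAA", "TAG", "TGA")


class InvalidScenarioError(ValueError):
    """An HT directive is inconsistent with the species tree."""


# ---------------------------------------------------------------------------
# species tree


@dataclass
class SpeciesTree:
    """Rooted binary tree with branch lengths in expected substitutions/site.

    ``age`` is time before present (leaves are at age 0 for ultrametric
    trees); ``blen[v]`` is the branch above node v (root branch is 0).
    """

    parent: Dict[int, Optional[int]]
    children: Dict[int, List[int]]
    blen: Dict[int, float]
    age: Dict[int, float]
    label: Dict[int, str]  # leaves only
    root: int

    def __post_init__(self) -> None:
        labels = list(self.label.values())
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        if any(b < 0 for b in self.blen.values()):
            raise ValueError("branch lengths must be non-negative")

    @property
    def leaves(self) -> List[int]:
        return sorted(self.label)

    @property
    def leaf_labels(self) -> List[str]:
        return [self.label[v] for v in self.leaves]

    @property
    def height(self) -> float:
        return self.age[self.root]

    def node_of(self, label: str) -> int:
        for v, lab in self.label.items():
            if lab == label:
                return v
        raise KeyError(label)

    def ancestors(self, v: int) -> List[int]:
        out = []
        while v is not None:
            out.append(v)
            v = self.parent[v]
        return out

    def mrca(self, a: int, b: int) -> int:
        anc = set(self.ancestors(a))
        v = b
        while v not in anc:
            v = self.parent[v]  # type: ignore[assignment]
        return v

    def patristic(self, a: str, b: str) -> float:
        va, vb = self.node_of(a), self.node_of(b)
        m = self.mrca(va, vb)
        return 2.0 * self.age[m] - self.age[va] - self.age[vb]

    def patristic_matrix(self) -> Tuple[List[str], np.ndarray]:
        labs = self.leaf_labels
        n = len(labs)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = self.patristic(labs[i], labs[j])
        return labs, out

    def most_divergent_pair(self) -> Tuple[str, str]:
        labs, d = self.patristic_matrix()
        i, j = np.unravel_index(int(np.argmax(d)), d.shape)
        return labs[min(i, j)], labs[max(i, j)]

    def scaled(self, factor: float) -> "SpeciesTree":
        return SpeciesTree(
            parent=dict(self.parent),
            children={k: list(v) for k, v in self.children.items()},
            blen={k: v * factor for k, v in self.blen.items()},
            age={k: v * factor for k, v in self.age.items()},
            label=dict(self.label),
            root=self.root,
        )

    def copy(self) -> "SpeciesTree":
        return self.scaled(1.0)

    def newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                return f"{self.label[v]}:{self.blen[v]:.10g}"
            inner = ",".join(fmt(c) for c in self.children[v])
            return f"({inner}):{self.blen[v]:.10g}"

        return fmt(self.root) + ";"

    def n_internal(self) -> int:
        return sum(1 for v in self.children if self.children[v])


def simulate_yule_tree(
    n_leaves: int,
    birth_rate: float,
    seed: int,
    *,
    height: Optional[float] = None,
) -> SpeciesTree:
    """Pure-birth (Yule) species tree with ``n_leaves`` extant species.

    Lineages split at rate ``birth_rate`` each; the process is stopped one
    exponential waiting time after the last split so leaves do not sit on a
    split instant.  ``height`` optionally rescales the tree to a fixed root
    age (expected substitutions/site).
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    parent: Dict[int, Optional[int]] = {0: None, 1: 0, 2: 0}
    children: Dict[int, List[int]] = {0: [1, 2], 1: [], 2: []}
    start: Dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    end: Dict[int, float] = {0: 0.0}
    active = [1, 2]
    t = 0.0
    next_id = 3
    while len(active) < n_leaves:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        v = active.pop(idx)
        end[v] = t
        c1, c2 = next_id, next_id + 1
        next_id += 2
        for c in (c1, c2):
            parent[c] = v
            children[c] = []
            start[c] = t
        children[v] = [c1, c2]
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / (n_leaves * birth_rate))
    for v in active:
        end[v] = t_end
    blen = {v: end[v] - start[v] for v in children}
    blen[0] = 0.0
    age = {v: t_end - end[v] for v in children}
    leaves = sorted(v for v in children if not children[v])
    width = max(2, len(str(n_leaves)))
    label = {v: f"S{i+1:0{width}d}" for i, v in enumerate(leaves)}
    tree = SpeciesTree(parent, children, blen, age, label, root=0)
    if height is not None:
        if tree.height <= 0:
            raise ValueError("degenerate tree height")
        tree = tree.scaled(height / tree.height)
    return tree


# ---------------------------------------------------------------------------
# substitution models and sequence evolution


@dataclass
class SubstitutionModel:
    """K2P or TN93 nucleotide model, normalized to ``rate`` expected
    substitutions/site per unit branch length.

    ``kappa`` is the transition/transversion *rate* ratio (alpha/beta); for
    TN93 ``kappa`` applies to pyrimidine (C<->T) and ``kappa2`` to purine
    (A<->G) transitions.  Base order is A, C, G, T.
    """

    kind: str = "K2P"
    kappa: float = 2.0
    kappa2: Optional[float] = None
    freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0 or (self.kappa2 is not None and self.kappa2 <= 0):
            raise ValueError("kappa must be positive")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.kind not in ("K2P", "TN93"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "K2P":
            self.freqs = (0.25, 0.25, 0.25, 0.25)

    def rate_matrix(self) -> np.ndarray:
        """Normalized rate matrix Q (rows sum to 0; -sum_i pi_i Q_ii = rate)."""
        k1 = self.kappa  # C<->T
        k2 = self.kappa2 if self.kappa2 is not None else self.kappa  # A<->G
        pi = np.asarray(self.freqs)
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                purines = {0, 2}
                if {i, j} == {0, 2}:
                    r = k2
                elif {i, j} == {1, 3}:
                    r = k1
                else:
                    r = 1.0
                q[i, j] = r * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q * (self.rate / mu)

    def transition_probs(self, distance: float) -> np.ndarray:
        """P(t) for a branch of ``distance`` expected substitutions/site."""
        if distance == 0:
            return np.eye(4)
        return expm(self.rate_matrix() * (distance / self.rate))


def random_sequence(length: int, rng: np.random.Generator, freqs=None) -> str:
    p = np.asarray(freqs) if freqs is not None else np.full(4, 0.25)
    draws = rng.choice(4, size=length, p=p / p.sum())
    return "".join(_BASES[i] for i in draws)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[i] for i in codes)


def _evolve_codes(
    codes: np.ndarray, p_matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = codes.copy()
    cum = np.cumsum(p_matrix, axis=1)
    u = rng.random(codes.shape[0])
    for b in range(4):
        idx = np.nonzero(codes == b)[0]
        if idx.size:
            out[idx] = np.searchsorted(cum[b], u[idx], side="right")
    np.clip(out, 0, 3, out=out)
    return out


def evolve_sequence(
    seq: str, distance: float, model: SubstitutionModel, rng: np.random.Generator
) -> str:
    """Mutate a sequence by an expected ``distance`` substitutions/site."""
    if distance == 0:
        return seq
    p = model.transition_probs(distance)
    return _decode(_evolve_codes(_encode(seq), p, rng))


_STOP_CODES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


def _repair_orf(
    child: np.ndarray, parent: np.ndarray, orf: Tuple[int, int]
) -> None:
    """Veto substitutions that would kill an ORF kept under purifying
    selection: revert the start codon, the terminal stop, and any codon a
    substitution turned into a premature stop (in place)."""
    start, end = orf
    child[start : start + 3] = parent[start : start + 3]
    child[end - 3 : end] = parent[end - 3 : end]
    for pos in range(start + 3, end - 3, 3):
        if tuple(child[pos : pos + 3]) in _STOP_CODES:
            child[pos : pos + 3] = parent[pos : pos + 3]


def evolve_along_tree(
    root_seq: str,
    tree: SpeciesTree,
    model: SubstitutionModel,
    seed: int,
    *,
    protect_orf: Optional[Tuple[int, int]] = None,
) -> Dict[str, str]:
    """Simulate the root sequence down every branch; returns leaf label ->
    ungapped sequence (all the same length as the root).

    ``protect_orf=(start, end)`` keeps that reading frame open on every
    branch (premature stops reverted), modelling purifying selection on a
    functional ORF.
    """
    if not root_seq:
        raise ValueError("root sequence must be non-empty")
    rng = np.random.default_rng(seed)
    codes = _encode(root_seq)
    states: Dict[int, np.ndarray] = {tree.root: codes}
    out: Dict[str, str] = {}
    # deterministic pre-order traversal
    stack = [tree.root]
    while stack:
        v = stack.pop()
        for c in sorted(tree.children[v]):
            d = tree.blen[c] * model.rate
            if d == 0:
                child_state = states[v].copy()
            else:
                child_state = _evolve_codes(
                    states[v], model.transition_probs(d), rng
                )
                if protect_orf is not None:
                    _repair_orf(child_state, states[v], protect_orf)
            if tree.children[c]:
                states[c] = child_state
                stack.append(c)
            else:
                out[tree.label[c]] = _decode(child_state)
    return out


# ---------------------------------------------------------------------------
# transposon element construction


@dataclass
class TEElement:
    """An ancestral cut-and-paste element: TIRs at both termini and a single
    transposase ORF on the plus strand."""

    sequence: str
    tir_len: int
    orf_start: int  # 0-based, ATG
    orf_end: int  # half-open, past the stop codon

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def protein_aa(self) -> int:
        return (self.orf_end - self.orf_start) // 3 - 1

    @property
    def tir_left(self) -> str:
        return self.sequence[: self.tir_len]

    @property
    def tir_right(self) -> str:
        return self.sequence[-self.tir_len :]

    @property
    def transposase(self) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.sequence[self.orf_start : self.orf_end - 3]).translate())


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def _random_codons(n: int, rng: np.random.Generator) -> str:
    sense = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    sense = [c for c in sense if c not in _STOPS]
    return "".join(sense[i] for i in rng.integers(len(sense), size=n))


def make_te_element(
    seed: int,
    *,
    tir_len: int = 23,
    orf_aa: int = 492,
    utr5: int = 600,
    utr3: int = 700,
) -> TEElement:
    """Build a synthetic element with exact TIRs and one transposase ORF.

    Defaults follow the family's typical architecture: ~2.8 kb element,
    20-ish bp TIRs, a ~492 aa transposase.  The internal filler is drawn
    without in-frame ATGs near the 5' end so the planted ORF is the longest
    by a wide margin.
    """
    if not 8 <= tir_len <= 40:
        raise ValueError("tir_len outside the supported 8-40 bp range")
    if utr5 < 3 or utr3 < 1:
        raise ValueError("UTRs too short")
    rng = np.random.default_rng(seed)
    tir = random_sequence(tir_len, rng)
    filler5 = random_sequence(utr5, rng)
    # in-frame stop guard so no upstream ATG extends the transposase ORF
    filler5 = filler5[:-3] + "TAA"
    orf = "ATG" + _random_codons(orf_aa - 1, rng) + "TAA"
    filler3 = random_sequence(utr3, rng)
    # keep the TIRs maximal: the bases just inside them must not pair
    if filler3[-1] == _revcomp(filler5[0]):
        repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[filler3[-1]]
        filler3 = filler3[:-1] + repl
    seq = tir + filler5 + orf + filler3 + _revcomp(tir)
    orf_start = tir_len + utr5
    return TEElement(seq, tir_len, orf_start, orf_start + len(orf))


def make_tir_region(
    seed: int,
    *,
    tir_len: int = 20,
    n_mismatches: int = 0,
    interior: int = 800,
    flank: int = 40,
) -> Tuple[str, Tuple[int, int]]:
    """A TSD-flanked element region for boundary-recovery experiments.

    Returns (region, (element_start, element_end)).  The element carries an
    exact terminal inverted repeat of ``tir_len`` (with ``n_mismatches``
    substitutions planted into the right copy), sits between TA target-site
    duplications, and is built so the planted repeat is the unique maximal
    inverted-repeat pair: the bases just inside the TIRs do not pair, and
    no chance TA immediately outside the TSDs can extend the boundary.
    """
    if tir_len < 8:
        raise ValueError("tir_len must be >= 8")
    if n_mismatches >= tir_len:
        raise ValueError("cannot plant that many mismatches")
    rng = np.random.default_rng(seed)
    tir = random_sequence(tir_len, rng)
    mid = random_sequence(interior, rng)
    # block inward extension of the repeat
    if mid[-1] == _revcomp(mid[0]):
        repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[mid[-1]]
        mid = mid[:-1] + repl
    right = list(_revcomp(tir))
    for pos in rng.choice(tir_len, size=n_mismatches, replace=False):
        alternatives = [b for b in _BASES if b != right[pos]]
        right[pos] = alternatives[int(rng.integers(3))]
    element = tir + mid + "".join(right)

    def clean_flank(length: int, leading: bool) -> str:
        while True:
            f = random_sequence(length, rng)
            # no TA directly against the TSD, which could shift the boundary
            if leading and f.endswith("TA"):
                continue
            if not leading and f.startswith("TA"):
                continue
            return f

    left_flank = clean_flank(flank, leading=True)
    right_flank = clean_flank(flank, leading=False)
    region = left_flank + "TA" + element + "TA" + right_flank
    start = len(left_flank) + 2
    return region, (start, start + len(element))


def disrupt_orf(element: TEElement, rng: np.random.Generator, every: int = 80) -> str:
    """Return the element sequence with premature stops planted through the
    ORF so no reading frame retains a >300 aa product (a dead 'full-only'
    copy)."""
    seq = list(element.sequence)
    n_codons = (element.orf_end - element.orf_start) // 3
    for c in range(every, n_codons - 1, every):
        pos = element.orf_start + 3 * c
        seq[pos : pos + 3] = _STOPS[int(rng.integers(3))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# planting copies


@dataclass
class Insertion:
    """Truth record for one planted copy (0-based half-open interval on the
    final, post-insertion genome)."""

    contig: str
    start: int
    end: int
    strand: str
    age: float
    te_class: str  # truncated | full | intact
    tsd: bool
    species: str = ""


@dataclass
class SimulationTruth:
    insertions: List[Insertion] = field(default_factory=list)
    ht_events: List[Tuple[str, str, float]] = field(default_factory=list)

    def insertions_to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            dict(
                species=i.species,
                contig=i.contig,
                start=i.start,
                end=i.end,
                strand=i.strand,
                age=i.age,
                te_class=i.te_class,
                tsd=i.tsd,
            )
            for i in self.insertions
        ]
        pd.DataFrame(
            rows,
            columns=[
                "species",
                "contig",
                "start",
                "end",
                "strand",
                "age",
                "te_class",
                "tsd",
            ],
        ).to_csv(path, sep="\t", index=False)

    def ht_to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.ht_events, columns=["donor", "recipient", "time"]
        ).to_csv(path, sep="\t", index=False)


def _mutate_preserving_orf(
    seq: str,
    age: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
    orf_start: int,
    orf_end: int,
) -> str:
    """Age a copy by ``age`` substitutions/site but keep the transposase ORF
    open: the start codon, terminal stop, and any codon that a substitution
    turned into a premature stop are reverted.  This is how genuinely intact
    old copies look — purifying selection has vetoed the killing changes."""
    mutated = list(evolve_sequence(seq, age, model, rng))
    orig = seq
    # restore start and terminal stop codons
    mutated[orf_start : orf_start + 3] = orig[orf_start : orf_start + 3]
    mutated[orf_end - 3 : orf_end] = orig[orf_end - 3 : orf_end]
    for pos in range(orf_start + 3, orf_end - 3, 3):
        codon = "".join(mutated[pos : pos + 3])
        if codon in _STOPS:
            mutated[pos : pos + 3] = orig[pos : pos + 3]
    return "".join(mutated)


def _truncate(seq: str, rng: np.random.Generator) -> str:
    """Remove a uniformly drawn prefix and/or suffix (each 10-40% of the
    element) so at least one terminus — and its TIR — is lost."""
    n = len(seq)
    mode = ("prefix", "suffix", "both")[int(rng.integers(3))]
    lo, hi = 0.10, 0.40
    left = int(n * rng.uniform(lo, hi)) if mode in ("prefix", "both") else 0
    right = int(n * rng.uniform(lo, hi)) if mode in ("suffix", "both") else 0
    out = seq[left : n - right]
    return out if out else seq[: max(1, n // 10)]


def plant_te_copies(
    genome: str,
    element: TEElement,
    n_copies: int,
    *,
    ages: float | Sequence[float] = 0.0,
    truncation_prob: float = 0.0,
    class_plan: Optional[Sequence[str]] = None,
    model: Optional[SubstitutionModel] = None,
    seed: int = 0,
    contig: str = "chr1",
    species: str = "",
    random_strand: bool = True,
    min_spacing: int = 2600,
) -> Tuple[str, SimulationTruth]:
    """Insert aged copies of ``element`` into ``genome`` at TA dinucleotides.

    Each insertion duplicates the TA target, so every copy is flanked by a
    TA TSD.  ``class_plan`` fixes the per-copy class ('intact', 'full',
    'truncated'); otherwise each copy is truncated with ``truncation_prob``
    and intact otherwise.  'full' copies carry a transposase killed by
    premature stops; 'intact' copies are aged with the ORF held open.
    Returns the modified genome and the truth table (coordinates on the
    final genome).
    """
    if not 0.0 <= truncation_prob <= 1.0:
        raise ValueError("truncation_prob must be in [0,1]")
    if len(genome) < element.length:
        raise ValueError("genome shorter than the element")
    if class_plan is not None and len(class_plan) != n_copies:
        raise ValueError("class_plan length must equal n_copies")
    truth = SimulationTruth()
    if n_copies == 0:
        return genome, truth
    rng = np.random.default_rng(seed)
    model = model or SubstitutionModel()
    age_list = (
        [float(ages)] * n_copies
        if np.isscalar(ages)
        else [float(a) for a in ages]
    )
    if len(age_list) != n_copies:
        raise ValueError("ages length must equal n_copies")

    # candidate TA sites, spaced so neighbouring loci stay separable after
    # flank extraction (spacing is preserved by the insertions themselves)
    sites = [
        i
        for i in range(len(genome) - 1)
        if genome[i : i + 2] == "TA"
    ]
    spaced: List[int] = []
    order = rng.permutation(len(sites))
    for k in order:
        p = sites[k]
        if all(abs(p - q) >= max(min_spacing, 4) for q in spaced):
            spaced.append(p)
        if len(spaced) == n_copies:
            break
    if len(spaced) < n_copies:
        raise ValueError("not enough TA target sites in the genome")
    spaced.sort()

    disrupted_cache: Optional[str] = None
    pieces: List[str] = []
    prev = 0
    offset = 0
    records: List[Insertion] = []
    for i, p in enumerate(spaced):
        if class_plan is not None:
            te_class = class_plan[i]
        else:
            te_class = (
                "truncated"
                if rng.random() < truncation_prob
                else ("intact" if element.protein_aa > 300 else "full")
            )
        if te_class not in ("truncated", "full", "intact"):
            raise ValueError(f"unknown class {te_class!r}")
        age = age_list[i]
        if te_class == "intact":
            copy = _mutate_preserving_orf(
                element.sequence, age, model, rng, element.orf_start, element.orf_end
            )
        elif te_class == "full":
            if disrupted_cache is None:
                disrupted_cache = disrupt_orf(element, rng)
            copy = evolve_sequence(disrupted_cache, age, model, rng)
        else:
            copy = evolve_sequence(element.sequence, age, model, rng)
            copy = _truncate(copy, rng)
        strand = "+"
        if random_strand and rng.random() < 0.5:
            strand = "-"
            copy = _revcomp(copy)
        # ...TA | copy TA ... : the TA at [p,p+2) is duplicated after copy
        pieces.append(genome[prev : p + 2])
        pieces.append(copy + "TA")
        start = p + 2 + offset
        records.append(
            Insertion(
                contig=contig,
                start=start,
                end=start + len(copy),
                strand=strand,
                age=age,
                te_class=te_class,
                tsd=True,
                species=species,
            )
        )
        offset += len(copy) + 2
        prev = p + 2
    pieces.append(genome[prev:])
    truth.insertions = records
    return "".join(pieces), truth


# ---------------------------------------------------------------------------
# horizontal-transfer scenarios


@dataclass
class TEHistorySpec:
    """Transfer history for the element across the species tree.

    ``ht_directives`` entries are (donor leaf label, recipient leaf label,
    time before present); an empty list is pure vertical descent.
    ``te_rate`` scales the element's substitution rate relative to the tree's
    branch-length units.
    """

    element: TEElement
    te_rate: float = 1.0
    ht_directives: List[Tuple[str, str, float]] = field(default_factory=list)
    model: SubstitutionModel = field(default_factory=SubstitutionModel)
    # keep the transposase ORF open along every lineage (an active family
    # under purifying selection); off for neutral fossil-like descent
    preserve_orf: bool = False


def _regraft_leaf(
    tree: SpeciesTree, recipient: str, donor: str, t: float
) -> SpeciesTree:
    """Re-attach the recipient leaf onto the donor's lineage at age ``t``,
    producing the genealogy a horizontal transfer imposes on the element."""
    tr = tree.copy()
    r = tr.node_of(recipient)
    d = tr.node_of(donor)
    if t < 0:
        raise InvalidScenarioError("HT time must be non-negative")
    mrca_age = tr.age[tr.mrca(r, d)]
    if t >= mrca_age:
        raise InvalidScenarioError(
            f"HT at {t} is older than the {donor}/{recipient} divergence ({mrca_age})"
        )
    # detach r; suppress its now-degree-2 parent
    p = tr.parent[r]
    assert p is not None
    sib = [c for c in tr.children[p] if c != r][0]
    gp = tr.parent[p]
    if gp is None:
        # parent is the root: sibling becomes the new root
        tr.children[p] = []
        tr.root = sib
        tr.parent[sib] = None
        tr.blen[sib] = 0.0
    else:
        tr.children[gp] = [sib if c == p else c for c in tr.children[gp]]
        tr.parent[sib] = gp
        tr.blen[sib] = tr.blen[sib] + tr.blen[p]
    for k in (p,):
        tr.parent.pop(k, None)
        tr.children.pop(k, None)
        tr.blen.pop(k, None)
        tr.age.pop(k, None)
    # find the edge on the donor path spanning age t
    u = tr.node_of(donor)
    while tr.parent[u] is not None and tr.age[tr.parent[u]] <= t:
        u = tr.parent[u]
    pu = tr.parent[u]
    w = max(tr.children) + 1  # fresh id
    if pu is None:
        # attaching above the current root of the element genealogy
        tr.root = w
        tr.parent[w] = None
        tr.blen[w] = 0.0
    else:
        tr.parent[w] = pu
        tr.children[pu] = [w if c == u else c for c in tr.children[pu]]
        tr.blen[w] = tr.age[pu] - t
    tr.children[w] = [u, r]
    tr.parent[u] = w
    tr.parent[r] = w
    tr.age[w] = t
    tr.blen[u] = t - tr.age[u]
    tr.blen[r] = t - tr.age[r]
    return tr


def apply_ht_scenario(
    tree: SpeciesTree, spec: TEHistorySpec, seed: int
) -> Tuple[Dict[str, str], SimulationTruth, SpeciesTree]:
    """Per-species element sequences under the given transfer history.

    Vertical descent follows the species tree (scaled by ``te_rate``); each
    HT directive re-roots the recipient's element lineage on the donor's at
    the transfer time, so donor/recipient element divergence reflects the
    transfer, not the species split.  Returns (leaf -> sequence, truth,
    element genealogy).
    """
    te_tree = tree.copy()
    truth = SimulationTruth()
    for donor, recipient, t in spec.ht_directives:
        te_tree = _regraft_leaf(te_tree, recipient, donor, t)
        truth.ht_events.append((donor, recipient, t))
    te_tree = te_tree.scaled(spec.te_rate)
    seqs = evolve_along_tree(
        spec.element.sequence,
        te_tree,
        spec.model,
        seed,
        protect_orf=(
            (spec.element.orf_start, spec.element.orf_end)
            if spec.preserve_orf
            else None
        ),
    )
    return seqs, truth, te_tree


# ---------------------------------------------------------------------------
# full study bundle (drives the HT null / power experiments)


@dataclass
class HTStudy:
    tree: SpeciesTree
    te_seqs: Dict[str, str]
    gene_seqs: Dict[str, Dict[str, str]]  # gene -> species -> sequence
    truth: SimulationTruth
    vertebrate: Dict[str, bool]


def simulate_ht_study(
    n_species: int = 20,
    *,
    seed: int = 0,
    tree_height: float = 0.5,
    birth_rate: float = 1.0,
    host_gene_lengths: Mapping[str, int] = None,  # type: ignore[assignment]
    secondary_gene_lengths: Mapping[str, int] = None,  # type: ignore[assignment]
    te_rate: float = 1.0,
    te_element: Optional[TEElement] = None,
    ht: Optional[str | Sequence[Tuple[str, str, float]]] = None,
    ht_time: float = 0.01,
    kappa: float = 2.0,
    preserve_orf: bool = False,
) -> HTStudy:
    """One replicate of the horizontal-transfer study design.

    A Yule tree of ``n_species`` is rescaled to ``tree_height`` expected
    substitutions/site (root-to-tip, host-gene scale).  Host and secondary
    genes evolve vertically from random roots; the element follows the
    transfer history.  ``ht='most_divergent'`` plants one transfer from the
    first to the second member of the most divergent leaf pair at
    ``ht_time``; an explicit directive list may be given instead; ``None``
    is vertical-only.  All species are flagged vertebrate (the secondary
    genes then exercise the RAG1 path; flip flags downstream to exercise
    tub3).
    """
    if host_gene_lengths is None:
        host_gene_lengths = {"RPL3": 10000, "RPL4": 10000}
    if secondary_gene_lengths is None:
        secondary_gene_lengths = {"RAG1": 3000, "tub3": 3000}
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(
        n_species, birth_rate, int(rng.integers(2**31)), height=tree_height
    )
    model = SubstitutionModel(kind="K2P", kappa=kappa)
    gene_seqs: Dict[str, Dict[str, str]] = {}
    for gene, length in {**host_gene_lengths, **secondary_gene_lengths}.items():
        root = random_sequence(length, rng)
        gene_seqs[gene] = evolve_along_tree(
            root, tree, model, int(rng.integers(2**31))
        )
    element = te_element or make_te_element(int(rng.integers(2**31)))
    if ht == "most_divergent":
        donor, recipient = tree.most_divergent_pair()
        directives = [(donor, recipient, ht_time)]
    elif ht is None:
        directives = []
    else:
        directives = [tuple(d) for d in ht]  # type: ignore[list-item]
    spec = TEHistorySpec(
        element=element,
        te_rate=te_rate,
        ht_directives=directives,
        model=model,
        preserve_orf=preserve_orf,
    )
    te_seqs, truth, _ = apply_ht_scenario(tree, spec, int(rng.integers(2**31)))
    vertebrate = {lab: True for lab in tree.leaf_labels}
    return HTStudy(tree, te_seqs, gene_seqs, truth, vertebrate)
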