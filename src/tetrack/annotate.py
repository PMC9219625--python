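"""Element boundary annotation, ORF finding, classification, consensus.

A copy is *full* when both terminal inverted repeats (TIRs) are present and
*intact* when, in addition, its transposase ORF encodes more than 300 aa;
anything without a TIR pair is *truncated*.  Cut-and-paste insertion into a
TA target leaves a TA target-site duplication (TSD) immediately flanking
the element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from . import distmod

__all__ = [
    "TIRPair",
    "OrfAnnotation",
    "ElementCopy",
    "UNDETERMINED",
    "find_tir_pair",
    "check_tsd",
    "find_longest_orf",
    "classify_copy",
    "build_consensus",
    "ConsensusResult",
    "align_copies_to_reference",
    "annotate_region",
    "discover_element_boundaries",
]


class _Undetermined:
    """TSD status when a flank is clipped at a contig edge (distinct from
    'no TSD')."""

    def __repr__(self) -> str:  # pragma: no cover
        return "UNDETERMINED"

    def __bool__(self) -> bool:
        return False


UNDETERMINED = _Undetermined()


@dataclass
class TIRPair:
    left: Tuple[int, int]  # element-relative, 0-based half-open
    right: Tuple[int, int]
    length: int
    mismatches: int

    def __post_init__(self) -> None:
        if not 8 <= self.length <= 741:
            raise ValueError("TIR length out of plausible range")


@dataclass
class OrfAnnotation:
    start: int  # 0-based on the element, includes the stop codon
    end: int
    strand: str
    protein_aa: int  # excludes the stop


@dataclass
class ElementCopy:
    species: str = ""
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    sequence: str = ""
    tir: Optional[TIRPair] = None
    tsd: object = None  # "TA" | None | UNDETERMINED
    orf: Optional[OrfAnnotation] = None
    te_class: str = ""


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# TIR search


def find_tir_pair(
    region: str,
    min_len: int = 8,
    max_len: int = 40,
    max_mismatch: Optional[int] = None,
    end_window: int = 50,
    left_candidates: Optional[Sequence[int]] = None,
    right_candidates: Optional[Sequence[int]] = None,
) -> Optional[TIRPair]:
    """Best terminal inverted repeat pair in ``region``, or None.

    The left copy must start within ``end_window`` of the region start and
    the right copy end within ``end_window`` of the region end (or at the
    supplied candidate positions).  Candidates are ranked longest first,
    then fewest mismatches, then leftmost/outermost.  The default mismatch
    allowance is ceil(10% of the TIR length).
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    n = len(region)
    if n < 2 * min_len:
        return None
    codes = _codes(region)
    rc = _codes(_revcomp(region))
    if left_candidates is None:
        left_candidates = range(0, min(end_window, n))
    if right_candidates is None:
        right_candidates = range(max(n - end_window, 0) + 1, n + 1)
    l0 = np.asarray(sorted(set(left_candidates)), dtype=np.intp)
    r1 = np.asarray(sorted(set(right_candidates)), dtype=np.intp)
    if l0.size == 0 or r1.size == 0:
        return None
    for length in range(min(max_len, n // 2), min_len - 1, -1):
        allow = (
            max_mismatch if max_mismatch is not None else math.ceil(0.1 * length)
        )
        lv = l0[l0 + length <= n]
        rv = r1[r1 - length >= 0]
        if lv.size == 0 or rv.size == 0:
            continue
        offs = np.arange(length)
        left_mat = codes[lv[:, None] + offs[None, :]]
        # region[r1-length:r1] reverse-complemented == rc[n-r1 : n-r1+length]
        right_mat = rc[(n - rv)[:, None] + offs[None, :]]
        mism = (left_mat[:, None, :] != right_mat[None, :, :]).sum(axis=2)
        # TIRs must not overlap each other
        valid = (lv[:, None] + length) <= (rv[None, :] - length)
        ok = (mism <= allow) & valid
        if not ok.any():
            continue
        mm = np.where(ok, mism, np.iinfo(np.int64).max)
        best_mm = mm.min()
        li, ri = np.nonzero(mm == best_mm)
        # leftmost left start, then outermost (largest) right end
        order = np.lexsort((-rv[ri], lv[li]))
        i, j = li[order[0]], ri[order[0]]
        return TIRPair(
            left=(int(lv[i]), int(lv[i]) + length),
            right=(int(rv[j]) - length, int(rv[j])),
            length=length,
            mismatches=int(best_mm),
        )
    return None


def check_tsd(genome: str, interval: Tuple[int, int]):
    """TA target-site duplication check for an element interval.

    Returns "TA" when the 2 bp immediately flanking both sides are TA,
    None when they are not, and UNDETERMINED when a flank is clipped at a
    contig edge.
    """
    start, end = interval
    if start < 0 or end > len(genome) or start >= end:
        raise ValueError("interval outside the contig")
    if start < 2 or end + 2 > len(genome):
        return UNDETERMINED
    left = genome[start - 2 : start].upper()
    right = genome[end : end + 2].upper()
    return "TA" if left == "TA" and right == "TA" else None


# ---------------------------------------------------------------------------
# ORF finding

_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_in_frame(seq: str, frame: int) -> List[Tuple[int, int]]:
    """ATG-to-stop ORFs (start, end half-open incl. stop) in one plus-strand
    frame of ``seq``."""
    out = []
    i = frame
    n = len(seq)
    start = None
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if start is None and codon == "ATG":
            start = i
        elif start is not None and codon in _STOPS:
            out.append((start, i + 3))
            start = None
        i += 3
    return out


def find_longest_orf(seq: str) -> Optional[OrfAnnotation]:
    """Longest ATG-to-stop ORF over all six frames.

    Ties prefer the plus strand, then the 5'-most start.  Coordinates are
    on the input sequence; for minus-strand ORFs they cover the region
    whose reverse complement encodes the protein.
    """
    seq = seq.upper()
    n = len(seq)
    best: Optional[Tuple[int, int, str, int]] = None  # start, end, strand, aa

    def consider(start: int, end: int, strand: str) -> None:
        nonlocal best
        aa = (end - start) // 3 - 1
        if best is None:
            best = (start, end, strand, aa)
            return
        b_aa = best[3]
        if aa > b_aa:
            best = (start, end, strand, aa)
        elif aa == b_aa:
            s_rank = 0 if strand == "+" else 1
            b_rank = 0 if best[2] == "+" else 1
            if (s_rank, start) < (b_rank, best[0]):
                best = (start, end, strand, aa)

    for f in range(3):
        for s, e in _orfs_in_frame(seq, f):
            consider(s, e, "+")
    rc = _revcomp(seq)
    for f in range(3):
        for s, e in _orfs_in_frame(rc, f):
            consider(n - e, n - s, "-")
    if best is None:
        return None
    return OrfAnnotation(start=best[0], end=best[1], strand=best[2], protein_aa=best[3])


# ---------------------------------------------------------------------------
# classification


def classify_copy(copy: ElementCopy) -> str:
    """'intact' with a TIR pair and a >300 aa transposase, 'full' with a TIR
    pair only, 'truncated' otherwise."""
    if copy.tir is None:
        return "truncated"
    if copy.orf is not None and copy.orf.protein_aa > 300:
        return "intact"
    return "full"


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusResult:
    sequence: str
    is_consensus: bool
    n_copies: int


def align_copies_to_reference(
    copies: Sequence[str], reference: str
) -> List[str]:
    """Project each copy onto the reference column space via overlap
    alignment (insertions relative to the reference are dropped)."""
    rows = []
    for copy in copies:
        aln = distmod.align_pair(reference, copy, mode="overlap")
        row = []
        for a, b in zip(aln.seq_a, aln.seq_b):
            if a != "-":
                row.append(b if b != "-" else "-")
        rows.append("".join(row))
    return rows


def build_consensus(
    aligned: Sequence[str],
    min_copies: int = 6,
    classes: Optional[Sequence[str]] = None,
) -> ConsensusResult:
    """Majority-rule consensus over pre-aligned rows.

    Columns are emitted when non-gap in at least 50% of rows; the majority
    base among non-gap characters wins (alphabetical tie-break).  With
    fewer than ``min_copies`` rows the longest copy — preferring intact
    ones when ``classes`` is given — is returned as a representative
    instead, flagged ``is_consensus=False``.
    """
    if not aligned:
        raise ValueError("no copies supplied")
    n = len(aligned)
    if len({len(r) for r in aligned}) != 1:
        raise ValueError("rows must share a common column space")
    if n < min_copies:
        idx = range(n)
        if classes is not None:
            intact = [i for i in idx if classes[i] == "intact"]
            idx = intact or list(range(n))
        best = max(idx, key=lambda i: (len(aligned[i].replace("-", "")), -i))
        return ConsensusResult(aligned[best].replace("-", ""), False, n)
    arr = np.array([list(r.upper()) for r in aligned])
    out = []
    for col in arr.T:
        non_gap = col[col != "-"]
        if len(non_gap) * 2 < n:
            continue
        bases, counts = np.unique(non_gap, return_counts=True)
        out.append(sorted(zip(-counts, bases))[0][1])
    return ConsensusResult("".join(out), True, n)


# ---------------------------------------------------------------------------
# reference-guided copy annotation


def _aligned_span(aln: distmod.PairAlignment) -> Tuple[int, int, np.ndarray]:
    """Map reference columns to copy positions.  Returns (copy_start,
    copy_end, ref_to_copy) where ref_to_copy[i] is the copy position aligned
    to reference position i, or -1."""
    ref_pos = -1
    cpy_pos = -1
    n_ref = len(aln.seq_a.replace("-", ""))
    mapping = np.full(n_ref, -1, dtype=np.intp)
    first = last = -1
    for a, b in zip(aln.seq_a, aln.seq_b):
        if a != "-":
            ref_pos += 1
        if b != "-":
            cpy_pos += 1
        if a != "-" and b != "-":
            mapping[ref_pos] = cpy_pos
            if first < 0:
                first = cpy_pos
            last = cpy_pos
    return first, last + 1, mapping


def annotate_region(
    region: str,
    reference,
    *,
    species: str = "",
    contig: str = "",
    region_offset: int = 0,
    strand: str = "+",
    tir_min_identity: float = 0.80,
    tir_min_coverage: float = 0.80,
    flanks_available: Tuple[bool, bool] = (True, True),
) -> ElementCopy:
    """Annotate one extracted region against a reference element.

    The copy's extent is the span aligned to the reference (overlap
    alignment, so flanking sequence stays unaligned).  The TIR pair is
    called when the copy covers each terminal reference TIR at
    ``tir_min_coverage`` with identity above ``tir_min_identity`` — the
    consensus-guided boundary call used once a family reference exists.
    ``reference`` is a :class:`~tetrack.synth.TEElement` or any object with
    ``sequence`` and ``tir_len`` attributes.
    """
    ref_seq = reference.sequence
    tir_len = reference.tir_len
    aln = distmod.align_pair(ref_seq, region, mode="overlap")
    c_start, c_end, mapping = _aligned_span(aln)
    if c_start < 0:
        return ElementCopy(
            species=species, contig=contig, strand=strand, te_class="truncated"
        )
    element_seq = region[c_start:c_end]
    ref_codes = _codes(ref_seq)
    reg_codes = _codes(region)

    def _end_match(ref_slice: slice) -> Tuple[bool, int]:
        idx = np.arange(*ref_slice.indices(len(ref_seq)))
        tgt = mapping[idx]
        covered = tgt >= 0
        if covered.sum() < tir_min_coverage * len(idx):
            return False, 0
        matches = (
            ref_codes[idx[covered]] == reg_codes[tgt[covered]]
        ).sum()
        ident = matches / covered.sum()
        return ident > tir_min_identity, int(covered.sum() - matches)

    left_ok, left_mm = _end_match(slice(0, tir_len))
    right_ok, right_mm = _end_match(slice(len(ref_seq) - tir_len, len(ref_seq)))
    tir = None
    if left_ok and right_ok:
        n_el = len(element_seq)
        tir = TIRPair(
            left=(0, tir_len),
            right=(n_el - tir_len, n_el),
            length=tir_len,
            mismatches=left_mm + right_mm,
        )
    # TSD on the region, unless a flank was clipped during extraction
    if c_start >= 2 and c_end + 2 <= len(region) and all(flanks_available):
        tsd = check_tsd(region, (c_start, c_end))
    else:
        tsd = UNDETERMINED
    orf = find_longest_orf(element_seq)
    if strand == "-":
        # the region arrives reverse-complemented; map back to genome coords
        g_start = region_offset + (len(region) - c_end)
        g_end = region_offset + (len(region) - c_start)
    else:
        g_start = region_offset + c_start
        g_end = region_offset + c_end
    copy = ElementCopy(
        species=species,
        contig=contig,
        start=g_start,
        end=g_end,
        strand=strand,
        sequence=element_seq,
        tir=tir,
        tsd=tsd,
        orf=orf,
    )
    copy.te_class = classify_copy(copy)
    return copy


def discover_element_boundaries(
    region: str,
    *,
    min_len: int = 8,
    max_len: int = 40,
    max_mismatch: Optional[int] = None,
    require_tsd: bool = True,
) -> Optional[Tuple[int, int, TIRPair]]:
    """De novo element boundaries inside a hit+flank region.

    Candidate boundaries are positions immediately inside a TA dinucleotide
    (the TSD signature), over which the best TIR pair is selected.  Returns
    (start, end, tir) in region coordinates, or None.
    """
    n = len(region)
    upper = region.upper()
    if require_tsd:
        lefts = [p + 2 for p in range(n - 1) if upper[p : p + 2] == "TA"]
        rights = [p for p in range(n - 1) if upper[p : p + 2] == "TA"]
    else:
        lefts = list(range(n))
        rights = list(range(n + 1))
    tir = find_tir_pair(
        region,
        min_len=min_len,
        max_len=max_len,
        max_mismatch=max_mismatch,
        left_candidates=lefts,
        right_candidates=rights,
    )
    if tir is None:
        return None
    return tir.left[0], tir.right[1], tir
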