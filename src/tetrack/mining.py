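"""Transposase homology mining: hit ingestion, a desk-scale translated
search, hit consolidation, flank extraction, and the copy census.

The built-in translated search substitutes for a full TBLASTN run at small
scale: six-frame translation, exact amino-acid word seeding, and ungapped
X-drop extension under BLOSUM62.  Its significance control is an empirical
score threshold (optionally calibrated from shuffled genomes), not a true
E-value, which is all a simulation-backed pipeline needs.

Census thresholds follow the copy-count convention for this family:
a hit is a countable copy only with >1000 bp length, >40% reference
coverage, and >80% identity — all strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from . import distmod

__all__ = [
    "HomologyHit",
    "CopyCensus",
    "FlankedRegion",
    "parse_hit_table",
    "translated_search",
    "empirical_score_threshold",
    "select_top_nonoverlapping",
    "cluster_hits",
    "extract_flanked",
    "count_copies",
]


@dataclass
class HomologyHit:
    """One translated-homology match on a genome (0-based half-open)."""

    query_id: str
    contig: str
    start: int
    end: int
    strand: str
    identity: float  # percent, 0-100
    length: int  # alignment columns
    score: float
    evalue: float = math.nan

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit interval must satisfy start < end")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be in [0, 100]")

    def overlaps(self, other: "HomologyHit") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


_TABULAR_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def parse_hit_table(
    stream: TextIO | Iterable[str],
    dialect: Optional[Sequence[str]] = None,
) -> List[HomologyHit]:
    """Parse a tab-separated hit table (standard 12-column dialect).

    Subject coordinates arrive 1-based inclusive; rows with subject start >
    end are minus-strand and are normalized to a 0-based half-open interval
    with strand "-".
    """
    cols = list(dialect) if dialect is not None else _TABULAR_COLUMNS
    idx = {name: i for i, name in enumerate(cols)}
    required = {"qseqid", "sseqid", "pident", "length", "sstart", "send"}
    missing = required - set(idx)
    if missing:
        raise ValueError(f"dialect lacks required columns: {sorted(missing)}")
    hits = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise ValueError(
                f"line {lineno}: expected {len(cols)} columns, got {len(fields)}"
            )
        try:
            pident = float(fields[idx["pident"]])
            length = int(fields[idx["length"]])
            sstart = int(fields[idx["sstart"]])
            send = int(fields[idx["send"]])
            evalue = float(fields[idx["evalue"]]) if "evalue" in idx else math.nan
            score = float(fields[idx["bitscore"]]) if "bitscore" in idx else math.nan
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})")
        strand = "+" if sstart <= send else "-"
        lo, hi = (sstart, send) if sstart <= send else (send, sstart)
        hits.append(
            HomologyHit(
                query_id=fields[idx["qseqid"]],
                contig=fields[idx["sseqid"]],
                start=lo - 1,
                end=hi,
                strand=strand,
                identity=pident,
                length=length,
                score=score,
                evalue=evalue,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# translated search

_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA = _BLOSUM.alphabet
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_SCORE = np.array(_BLOSUM, dtype=np.int32)


def _aa_codes(protein: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in protein.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc}")


def _six_frames(genome: str) -> List[Tuple[str, int, str]]:
    """(strand, frame, protein) for the six reading frames."""
    out = []
    rc = str(Seq(genome).reverse_complement())
    for strand, seq in (("+", genome), ("-", rc)):
        for f in range(3):
            sub = seq[f : f + ((len(seq) - f) // 3) * 3]
            if sub:
                out.append((strand, f, str(Seq(sub).translate())))
    return out


def _extend_seed(
    q: np.ndarray, s: np.ndarray, qi: int, si: int, word: int, xdrop: int
) -> Tuple[int, int, int, int, int, int]:
    """Ungapped X-drop extension around an exact word seed.  Returns
    (qstart, qend, sstart, send, score, matches) in protein coordinates."""
    score = int(_SCORE[q[qi : qi + word], s[si : si + word]].sum())
    best = score
    best_r = word
    cur = score
    k = word
    while qi + k < len(q) and si + k < len(s):
        cur += int(_SCORE[q[qi + k], s[si + k]])
        k += 1
        if cur > best:
            best, best_r = cur, k
        elif best - cur > xdrop:
            break
    cur = best
    best_l = 0
    run = cur
    k = 1
    while qi - k >= 0 and si - k >= 0:
        run += int(_SCORE[q[qi - k], s[si - k]])
        if run > cur:
            cur, best_l = run, k
        elif cur - run > xdrop:
            break
        k += 1
    q0, q1 = qi - best_l, qi + best_r
    s0, s1 = si - best_l, si + best_r
    matches = int((q[q0:q1] == s[s0:s1]).sum())
    return q0, q1, s0, s1, cur, matches


def translated_search(
    query_protein: str,
    genome: str,
    *,
    query_id: str = "query",
    contig: str = "contig",
    word_size: int = 4,
    xdrop: int = 18,
    min_score: float = 60.0,
) -> List[HomologyHit]:
    """Search a protein query against all six frames of a genome.

    Returns hits on both strands with genome-nucleotide coordinates; hits
    scoring below ``min_score`` are suppressed.  A genome shorter than three
    times the query yields whatever still fits (possibly nothing).
    """
    if len(query_protein) < 50:
        raise ValueError("query must be at least 50 aa")
    if len(genome) < 3 * word_size:
        return []
    q = _aa_codes(query_protein.upper())
    words: Dict[str, List[int]] = {}
    for i in range(len(query_protein) - word_size + 1):
        words.setdefault(query_protein[i : i + word_size].upper(), []).append(i)
    n = len(genome)
    raw: List[HomologyHit] = []
    for strand, frame, protein in _six_frames(genome):
        s = _aa_codes(protein)
        seen: Dict[int, Tuple[int, int]] = {}  # diagonal -> covered q-range
        for j in range(len(protein) - word_size + 1):
            w = protein[j : j + word_size]
            if w not in words:
                continue
            for qi in words[w]:
                diag = j - qi
                cov = seen.get(diag)
                if cov and cov[0] <= qi < cov[1]:
                    continue
                q0, q1, s0, s1, score, matches = _extend_seed(
                    q, s, qi, j, word_size, xdrop
                )
                seen[diag] = (q0, q1)
                if score < min_score:
                    continue
                if strand == "+":
                    nt0, nt1 = frame + 3 * s0, frame + 3 * s1
                else:
                    nt0, nt1 = n - (frame + 3 * s1), n - (frame + 3 * s0)
                raw.append(
                    HomologyHit(
                        query_id=query_id,
                        contig=contig,
                        start=nt0,
                        end=nt1,
                        strand=strand,
                        identity=100.0 * matches / (q1 - q0),
                        length=q1 - q0,
                        score=float(score),
                    )
                )
    # suppress lower-scoring hits nested in or duplicating a better one
    raw.sort(key=lambda h: (-h.score, h.start, h.end))
    kept: List[HomologyHit] = []
    for h in raw:
        if any(
            k.strand == h.strand and k.start <= h.start and h.end <= k.end
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.start, -h.score))
    return kept


def empirical_score_threshold(
    query_protein: str,
    genome: str,
    *,
    n_shuffles: int = 20,
    seed: int = 0,
    word_size: int = 4,
    xdrop: int = 18,
) -> float:
    """Highest extension score reached against shuffled copies of the
    genome — an empirical null for choosing ``min_score``."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    best = 0.0
    for _ in range(n_shuffles):
        shuf = arr[rng.permutation(arr.size)].tobytes().decode("ascii")
        hits = translated_search(
            query_protein,
            shuf,
            word_size=word_size,
            xdrop=xdrop,
            min_score=-math.inf,
        )
        if hits:
            best = max(best, max(h.score for h in hits))
    return best


# ---------------------------------------------------------------------------
# hit consolidation


def select_top_nonoverlapping(
    hits: Sequence[HomologyHit], k: int = 10
) -> List[HomologyHit]:
    """Greedy top-k by descending score, discarding any hit sharing subject
    bases with an already-selected one.  Score ties keep the smaller start
    (then the smaller end), so the result is independent of input order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(hits, key=lambda h: (-h.score, h.contig, h.start, h.end))
    out: List[HomologyHit] = []
    for h in ranked:
        if len(out) == k:
            break
        if not any(h.overlaps(o) for o in out):
            out.append(h)
    return out


def cluster_hits(
    hits: Sequence[HomologyHit], max_gap: int = 600
) -> List[HomologyHit]:
    """Merge same-contig, same-strand hits separated by at most ``max_gap``
    bp into locus-level hits (a decayed copy often yields several broken
    segments of the one transposase)."""
    groups: Dict[Tuple[str, str], List[HomologyHit]] = {}
    for h in hits:
        groups.setdefault((h.contig, h.strand), []).append(h)
    merged: List[HomologyHit] = []
    for (contig, strand), hs in groups.items():
        hs.sort(key=lambda h: h.start)
        cur = hs[0]
        acc = [cur]
        for h in hs[1:]:
            if h.start - cur.end <= max_gap:
                acc.append(h)
                if h.end > cur.end:
                    cur = HomologyHit(
                        query_id=cur.query_id,
                        contig=contig,
                        start=acc[0].start,
                        end=h.end,
                        strand=strand,
                        identity=_weighted_identity(acc),
                        length=sum(a.length for a in acc),
                        score=sum(a.score for a in acc),
                    )
            else:
                merged.append(cur if len(acc) == 1 else _merge(acc))
                cur = h
                acc = [h]
        merged.append(cur if len(acc) == 1 else _merge(acc))
    merged.sort(key=lambda h: (h.contig, h.start))
    return merged


def _weighted_identity(hits: Sequence[HomologyHit]) -> float:
    tot = sum(h.length for h in hits)
    return sum(h.identity * h.length for h in hits) / tot if tot else 0.0


def _merge(hits: Sequence[HomologyHit]) -> HomologyHit:
    return HomologyHit(
        query_id=hits[0].query_id,
        contig=hits[0].contig,
        start=min(h.start for h in hits),
        end=max(h.end for h in hits),
        strand=hits[0].strand,
        identity=_weighted_identity(hits),
        length=sum(h.length for h in hits),
        score=sum(h.score for h in hits),
    )


# ---------------------------------------------------------------------------
# flank extraction


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class FlankedRegion:
    """A hit plus flanking sequence, in hit orientation (minus-strand hits
    are reverse-complemented)."""

    sequence: str
    contig: str
    genome_start: int  # genome coordinates of the extracted window
    genome_end: int
    strand: str
    left_flank: int  # flank lengths in the *returned* orientation
    right_flank: int
    left_clipped: bool
    right_clipped: bool
    hit: Optional[HomologyHit] = None


def extract_flanked(
    genome: str, hit: HomologyHit, flank: int = 2000
) -> FlankedRegion:
    """Hit sequence with up to ``flank`` bp on each side, clipped (and
    recorded as clipped) at contig ends."""
    if hit.start < 0 or hit.end > len(genome):
        raise ValueError("hit lies outside the contig")
    g0 = max(hit.start - flank, 0)
    g1 = min(hit.end + flank, len(genome))
    left = hit.start - g0
    right = g1 - hit.end
    seq = genome[g0:g1]
    left_clip = left < flank
    right_clip = right < flank
    if hit.strand == "-":
        seq = seq.translate(_RC)[::-1]
        left, right = right, left
        left_clip, right_clip = right_clip, left_clip
    return FlankedRegion(
        sequence=seq,
        contig=hit.contig,
        genome_start=g0,
        genome_end=g1,
        strand=hit.strand,
        left_flank=left,
        right_flank=right,
        left_clipped=left_clip,
        right_clipped=right_clip,
        hit=hit,
    )


# ---------------------------------------------------------------------------
# copy census


@dataclass
class CopyRecord:
    length: int
    coverage: float  # aligned fraction of the reference
    identity: float  # over gap-free aligned columns
    counted: bool


@dataclass
class CopyCensus:
    element_id: str
    species: str
    count: int
    records: List[CopyRecord]
    thresholds: Tuple[int, float, float]  # min_len, min_cov, min_id

    @property
    def total(self) -> int:
        return len(self.records)


def count_copies(
    copies: Sequence[str],
    reference: str,
    *,
    element_id: str = "element",
    species: str = "",
    min_len: int = 1000,
    min_cov: float = 0.40,
    min_id: float = 0.80,
) -> CopyCensus:
    """Census of copies against a reference element.

    Coverage is measured on the reference (fraction of reference positions
    aligned to a copy base); identity over gap-free aligned columns.  A copy
    counts iff length > min_len AND coverage > min_cov AND identity >
    min_id, all strict.
    """
    if not reference:
        raise ValueError("reference element must be non-empty")
    records = []
    n_ref = len(reference)
    for copy in copies:
        if not copy:
            records.append(CopyRecord(0, 0.0, 0.0, False))
            continue
        aln = distmod.align_pair(reference, copy, mode="overlap")
        both = [
            (a, b)
            for a, b in zip(aln.seq_a, aln.seq_b)
            if a != "-" and b != "-"
        ]
        cov = len(both) / n_ref
        ident = (
            sum(1 for a, b in both if a.upper() == b.upper()) / len(both)
            if both
            else 0.0
        )
        counted = len(copy) > min_len and cov > min_cov and ident > min_id
        records.append(CopyRecord(len(copy), cov, ident, counted))
    return CopyCensus(
        element_id=element_id,
        species=species,
        count=sum(r.counted for r in records),
        records=records,
        thresholds=(min_len, min_cov, min_id),
    )
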