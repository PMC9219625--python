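"""Pairwise alignment, sequence identity, and genetic-distance estimation.

Distances implemented here:

* ``p`` — raw proportion of differing sites (pairwise deletion).
* ``K2P`` — Kimura two-parameter correction separating transition and
  transversion fractions.
* ``MCL-TN93`` — a composite-likelihood matrix under the Tamura–Nei (1993)
  model: substitution parameters (two transition/transversion rate ratios
  and base frequencies) are estimated once from site-pattern counts pooled
  over *all* sequence pairs, and each pair's divergence is then the maximum
  of its own multinomial likelihood with those shared parameters held
  fixed.  With exactly two sequences the pooled counts are the pair's own
  counts and the estimate reduces to the closed-form TN93 distance.

All distance routines use pairwise deletion: an alignment column counts
for a pair iff both members are unambiguous A/C/G/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from scipy.optimize import brentq

__all__ = [
    "PairAlignment",
    "DistanceMatrix",
    "align_pair",
    "percent_identity",
    "p_distance",
    "k2p_distance",
    "k2p_from_counts",
    "tn93_distance",
    "mcl_distance_matrix",
    "identity_matrix",
    "nj_tree",
    "encode",
    "pair_site_counts",
]

# base encoding: A=0, C=1, G=2, T=3, anything else (gaps, N) = -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

SATURATION_CAP = 40.0  # rate-units ceiling when solving for divergence


def encode(seq: str) -> np.ndarray:
    """Encode a (possibly gapped) sequence as int8 codes; non-ACGT -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass
class PairAlignment:
    """A global alignment of two nucleotide sequences.

    ``seq_a``/``seq_b`` are the gapped rows (equal length); removing "-"
    recovers the inputs.
    """

    seq_a: str
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.seq_a)

    @property
    def gap_columns(self) -> int:
        return sum(1 for a, b in zip(self.seq_a, self.seq_b) if a == "-" or b == "-")

    @property
    def aligned_columns(self) -> int:
        return self.length - self.gap_columns


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float, mode: str
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # biopython scores the first gap position with open_gap_score; we define
    # a length-g gap to cost gap_open + g*gap_extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    if mode == "overlap":  # free end gaps on both sequences
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older biopython naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    elif mode != "global":
        raise ValueError(f"unknown alignment mode {mode!r}")
    return aligner


def align_pair(
    a: str,
    b: str,
    *,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    mode: str = "global",
) -> PairAlignment:
    """Optimal global affine-gap alignment of two nucleotide sequences.

    A gap of length g costs ``gap_open + g * gap_extend`` (both negative).
    ``mode="overlap"`` leaves terminal gaps free on both sequences, which
    suits fragment-vs-reference comparisons.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, mode)
    aln = aligner.align(a, b)[0]
    rows = str(aln).splitlines()
    # biopython's str() layout varies; rebuild rows from coordinates instead
    ga, gb = _gapped_rows(a, b, aln.coordinates)
    return PairAlignment(ga, gb, float(aln.score))


def _gapped_rows(a: str, b: str, coords: np.ndarray) -> Tuple[str, str]:
    ra: List[str] = []
    rb: List[str] = []
    for k in range(coords.shape[1] - 1):
        a0, a1 = coords[0, k], coords[0, k + 1]
        b0, b1 = coords[1, k], coords[1, k + 1]
        if a1 > a0 and b1 > b0:
            ra.append(a[a0:a1])
            rb.append(b[b0:b1])
        elif a1 > a0:
            ra.append(a[a0:a1])
            rb.append("-" * (a1 - a0))
        else:
            ra.append("-" * (b1 - b0))
            rb.append(b[b0:b1])
    return "".join(ra), "".join(rb)


def percent_identity(aln: PairAlignment) -> float:
    """Fraction of matching bases over gap-free alignment columns."""
    ca = encode(aln.seq_a)
    cb = encode(aln.seq_b)
    use = (ca >= 0) & (cb >= 0)
    n = int(use.sum())
    if n == 0:
        raise ValueError("identity undefined: no gap-free columns")
    return float((ca[use] == cb[use]).sum() / n)


# ---------------------------------------------------------------------------
# site-pattern counts and closed-form distances

_PURINE = (0, 2)  # A, G
_PYRIMIDINE = (1, 3)  # C, T


def pair_site_counts(a: str | np.ndarray, b: str | np.ndarray) -> Dict[str, int]:
    """Pairwise-deleted site-pattern counts for one sequence pair.

    Returns counts of identical sites, pyrimidine transitions (C<->T),
    purine transitions (A<->G), and transversions.
    """
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise ValueError("sequences must be on a common alignment")
    use = (ca >= 0) & (cb >= 0)
    xa, xb = ca[use], cb[use]
    same = xa == xb
    purine_a = (xa == 0) | (xa == 2)
    purine_b = (xb == 0) | (xb == 2)
    ts = ~same & (purine_a == purine_b)
    n_same = int(same.sum())
    n_ts_pur = int((ts & purine_a).sum())
    n_ts_pyr = int((ts & ~purine_a).sum())
    n_tv = int((~same & (purine_a != purine_b)).sum())
    base_counts = np.bincount(np.concatenate([xa, xb]), minlength=4).astype(float)
    return {
        "sites": int(use.sum()),
        "same": n_same,
        "ts_pyrimidine": n_ts_pyr,
        "ts_purine": n_ts_pur,
        "tv": n_tv,
        "base_counts": base_counts,  # type: ignore[dict-item]
    }


@dataclass
class DistanceEstimate:
    distance: float
    saturated: bool = False
    sites: int = 0

    def __float__(self) -> float:
        return self.distance


def p_distance(a, b) -> DistanceEstimate:
    c = pair_site_counts(a, b)
    if c["sites"] == 0:
        raise ValueError("p-distance undefined: zero comparable sites")
    return DistanceEstimate(1.0 - c["same"] / c["sites"], False, c["sites"])


def k2p_from_counts(p: float, q: float) -> DistanceEstimate:
    """Kimura (1980) two-parameter distance from transition fraction ``p``
    and transversion fraction ``q``: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return DistanceEstimate(math.inf, True)
    return DistanceEstimate(-0.5 * math.log(w1) - 0.25 * math.log(w2), False)


def k2p_distance(a, b) -> DistanceEstimate:
    """K2P distance between two sequences on a common alignment
    (pairwise deletion)."""
    c = pair_site_counts(a, b)
    n = c["sites"]
    if n == 0:
        raise ValueError("K2P distance undefined: zero comparable sites")
    p = (c["ts_pyrimidine"] + c["ts_purine"]) / n
    q = c["tv"] / n
    est = k2p_from_counts(p, q)
    est.sites = n
    return est


def _tn93_from_props(
    p1: float, p2: float, q: float, freqs: np.ndarray
) -> Tuple[float, float, float, bool]:
    """Closed-form TN93 branch-length components (a1*t, a2*t, b*t summed over
    both lineages).  p1 = C<->T fraction, p2 = A<->G fraction, q =
    transversion fraction.  Returns (s_a1, s_a2, s_b, saturated)."""
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    w3 = 1.0 - q / (2.0 * pr * py)
    w1 = 1.0 - pr * p2 / (2.0 * pa * pg) - q / (2.0 * pr)
    w2 = 1.0 - py * p1 / (2.0 * pt * pc) - q / (2.0 * py)
    if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
        return math.nan, math.nan, math.nan, True
    s_b = -0.5 * math.log(w3)  # = b*2t with b scaled out
    s_a2 = (-0.5 * math.log(w1) - py * s_b) / pr
    s_a1 = (-0.5 * math.log(w2) - pr * s_b) / py
    return s_a1, s_a2, s_b, False


def tn93_distance(a, b) -> DistanceEstimate:
    """Standard two-sequence Tamura–Nei (1993) distance, pairwise deletion,
    base frequencies taken from the pair itself."""
    c = pair_site_counts(a, b)
    n = c["sites"]
    if n == 0:
        raise ValueError("TN93 distance undefined: zero comparable sites")
    freqs = np.asarray(c["base_counts"], dtype=float)
    freqs = freqs / freqs.sum()
    p1, p2, q = c["ts_pyrimidine"] / n, c["ts_purine"] / n, c["tv"] / n
    s_a1, s_a2, s_b, sat = _tn93_from_props(p1, p2, q, freqs)
    if sat:
        return DistanceEstimate(math.inf, True, n)
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    # components are per lineage (a*t, b*t); the distance covers both
    d = 4.0 * (pt * pc * s_a1 + pa * pg * s_a2 + pr * py * s_b)
    return DistanceEstimate(d, False, n)


# ---------------------------------------------------------------------------
# composite-likelihood TN93 matrix


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with method metadata.

    ``saturated`` marks entries whose estimate hit the model's saturation
    boundary; their value is the cap, and downstream filters treat them as
    automatic failures rather than numbers to trust.
    """

    labels: List[str]
    values: np.ndarray
    method: str = "unknown"
    deletion: str = "pairwise"
    saturated: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def is_saturated(self, a: str, b: str) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return bool(self.saturated[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="label")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")


def _as_seq_dict(seqs, labels=None) -> Dict[str, str]:
    if isinstance(seqs, Mapping):
        return dict(seqs)
    labels = labels or [f"seq{i+1}" for i in range(len(seqs))]
    return dict(zip(labels, seqs))


def identity_matrix(seqs, labels=None) -> "DistanceMatrix":
    """Pairwise identity fractions over gap-free columns, as a labelled
    symmetric matrix (diagonal = 1)."""
    d = _as_seq_dict(seqs, labels)
    labs = list(d)
    codes = [encode(d[l]) for l in labs]
    n = len(labs)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            use = (codes[i] >= 0) & (codes[j] >= 0)
            tot = int(use.sum())
            if tot == 0:
                raise ValueError(f"no comparable sites for {labs[i]}/{labs[j]}")
            out[i, j] = out[j, i] = float((codes[i][use] == codes[j][use]).sum() / tot)
    return DistanceMatrix(labs, out, method="identity", deletion="pairwise")


class _TN93Probs:
    """Expected site-pattern probabilities under TN93 with transversion rate
    fixed at 1, transition/transversion ratios k1 (pyrimidine) and k2
    (purine), as a function of the combined path length s = 2*b*t."""

    def __init__(self, k1: float, k2: float, freqs: np.ndarray):
        self.k1, self.k2 = k1, k2
        pa, pc, pg, pt = freqs
        self.freqs = freqs
        self.pr, self.py = pa + pg, pc + pt
        self.c1 = 2.0 * pt * pc / self.py
        self.c2 = 2.0 * pa * pg / self.pr
        self.cq = 2.0 * self.pr * self.py
        self.e1 = self.py * k1 + self.pr  # exponent rate for pyrimidine ts
        self.e2 = self.pr * k2 + self.py
        # s is the *combined* 2t path in transversion-rate units: d = mu_s * s
        self.mu_s = 2.0 * (pt * pc * k1 + pa * pg * k2 + self.pr * self.py)

    def probs(self, s: float) -> Tuple[float, float, float, float]:
        es = math.exp(-s)
        p1 = self.c1 * (self.py + self.pr * es - math.exp(-self.e1 * s))
        p2 = self.c2 * (self.pr + self.py * es - math.exp(-self.e2 * s))
        q = self.cq * (1.0 - es)
        return 1.0 - p1 - p2 - q, p1, p2, q

    def dprobs(self, s: float) -> Tuple[float, float, float, float]:
        es = math.exp(-s)
        dp1 = self.c1 * (-self.pr * es + self.e1 * math.exp(-self.e1 * s))
        dp2 = self.c2 * (-self.py * es + self.e2 * math.exp(-self.e2 * s))
        dq = self.cq * es
        return -(dp1 + dp2 + dq), dp1, dp2, dq

    def score(self, s: float, counts: Sequence[float]) -> float:
        p = self.probs(s)
        dp = self.dprobs(s)
        tot = 0.0
        for n, pi, dpi in zip(counts, p, dp):
            if n > 0:
                tot += n * dpi / pi
        return tot

    def distance(self, s: float) -> float:
        return self.mu_s * s


def mcl_distance_matrix(seqs, labels=None) -> DistanceMatrix:
    """TN93 distance matrix by composite likelihood with shared parameters.

    Rate ratios and base frequencies come from pooled pair counts; each
    pair's divergence is then its own 1-D maximum-likelihood path length
    under those shared parameters (solved on the likelihood score to
    bracketing precision).  Saturated pairs are flagged, not dropped.
    """
    d = _as_seq_dict(seqs, labels)
    labs = list(d)
    n = len(labs)
    if n < 2:
        raise ValueError("need at least two sequences")
    codes = [encode(d[l]) for l in labs]
    counts = {}
    pooled = np.zeros(4)  # same, ts_pyr, ts_pur, tv
    pooled_bases = np.zeros(4)
    for i in range(n):
        for j in range(i + 1, n):
            c = pair_site_counts(codes[i], codes[j])
            if c["sites"] == 0:
                raise ValueError(f"no comparable sites for {labs[i]}/{labs[j]}")
            counts[(i, j)] = c
            pooled += (c["same"], c["ts_pyrimidine"], c["ts_purine"], c["tv"])
            pooled_bases += c["base_counts"]
    freqs = pooled_bases / pooled_bases.sum()
    tot = pooled.sum()
    s_a1, s_a2, s_b, sat = _tn93_from_props(
        pooled[1] / tot, pooled[2] / tot, pooled[3] / tot, freqs
    )
    if sat:
        # pooled signal saturated: fall back to equal-rate ratios; per-pair
        # estimates may still be finite or get flagged individually
        k1 = k2 = 1.0
    else:
        s_b_eff = max(s_b, 1e-9)  # transversion-free pools need a floor
        k1 = max(s_a1 / s_b_eff, 1e-9)
        k2 = max(s_a2 / s_b_eff, 1e-9)
    model = _TN93Probs(k1, k2, freqs)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for (i, j), c in counts.items():
        ns = c["sites"]
        obs = (c["same"], c["ts_pyrimidine"], c["ts_purine"], c["tv"])
        if obs[0] == ns:
            continue  # identical pair -> distance 0
        lo, hi = 1e-12, SATURATION_CAP
        f_hi = model.score(hi, obs)
        if f_hi > 0.0:  # likelihood still increasing at the cap
            values[i, j] = values[j, i] = model.distance(hi)
            saturated[i, j] = saturated[j, i] = True
            continue
        s_hat = brentq(model.score, lo, hi, args=(obs,), xtol=1e-15, rtol=1e-15)
        values[i, j] = values[j, i] = model.distance(s_hat)
    return DistanceMatrix(labs, values, method="MCL-TN93", saturated=saturated)


def k2p_matrix(seqs, labels=None) -> DistanceMatrix:
    d = _as_seq_dict(seqs, labels)
    labs = list(d)
    n = len(labs)
    codes = [encode(d[l]) for l in labs]
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            est = k2p_distance(codes[i], codes[j])
            if est.saturated:
                values[i, j] = values[j, i] = SATURATION_CAP
                saturated[i, j] = saturated[j, i] = True
            else:
                values[i, j] = values[j, i] = est.distance
    return DistanceMatrix(labs, values, method="K2P", saturated=saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick, unrooted) from a distance matrix.

    Ties in the Q criterion are broken by the lowest index pair.  Negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch, the usual NJ post-hoc fix.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(dm.values, dm.values.T):
        raise ValueError("distance matrix must be symmetric")
    D = dm.values.astype(float).copy()
    nodes: List[str] = [_quote(l) for l in dm.labels]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin scans row-major
        k = int(np.argmin(np.round(q, 12)))
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += -li
            li = 0.0
        if lj < 0.0:
            li += -lj
            lj = 0.0
        ai, aj = active[i], active[j]
        new = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        # distances from the new node to the rest
        d_new = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, d_new])
        D = np.hstack([D, np.append(d_new, 0.0)[:, None]])
        nodes.append(new)
        idx = len(nodes) - 1
        active = [a for a in active if a not in (ai, aj)] + [idx]
    a, b = active
    d_ab = max(D[a, b], 0.0)
    return f"({nodes[a]}:{d_ab / 2.0:.10g},{nodes[b]}:{d_ab / 2.0:.10g});"


def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
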