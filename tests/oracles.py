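"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (explicit
loops, textbook formulas) and kept independent of the package's code
paths, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

NEG = float("-inf")


def affine_dp_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Gotoh three-state global alignment score; a gap of length g costs
    gap_open + g*gap_extend."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def k2p_closed_form(p: float, q: float) -> float:
    return -0.5 * math.log(1.0 - 2.0 * p - q) - 0.25 * math.log(1.0 - 2.0 * q)


_PUR = {"A", "G"}


def pair_props(a: str, b: str) -> Tuple[int, float, float, float, np.ndarray]:
    """(n, P1 C<->T, P2 A<->G, Q, base freqs) over gap-free columns."""
    n = p1 = p2 = q = 0
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for x, y in zip(a.upper(), b.upper()):
        if x not in counts or y not in counts:
            continue
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x == y:
            continue
        if {x, y} == {"C", "T"}:
            p1 += 1
        elif {x, y} == {"A", "G"}:
            p2 += 1
        else:
            q += 1
    freqs = np.array([counts[b] for b in "ACGT"], dtype=float)
    freqs /= freqs.sum()
    return n, p1 / n, p2 / n, q / n, freqs


def tn93_closed_form(a: str, b: str) -> float:
    """Tamura & Nei (1993) distance, textbook formula."""
    n, p1, p2, q, f = pair_props(a, b)
    pa, pc, pg, pt = f
    pr, py = pa + pg, pc + pt
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pt * pc / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    w1 = 1.0 - p2 / k1 - q / (2.0 * pr)
    w2 = 1.0 - p1 / k2 - q / (2.0 * py)
    w3 = 1.0 - q / (2.0 * pr * py)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def brute_force_tir(
    region: str,
    lefts: Sequence[int],
    rights: Sequence[int],
    min_len: int,
    max_len: int,
    allow,
) -> Optional[Tuple[int, int, int, int]]:
    """Exhaustive inverted-repeat search over all (left start, right end,
    length) triples.  ``allow`` maps length -> allowed mismatches.  Returns
    (l0, r1, length, mismatches) ranked longest, fewest mismatches,
    leftmost, outermost — or None."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    best = None
    for length in range(max_len, min_len - 1, -1):
        cand = []
        for l0 in lefts:
            if l0 + length > len(region):
                continue
            left = region[l0 : l0 + length]
            for r1 in rights:
                if r1 - length < 0 or l0 + length > r1 - length:
                    continue
                right = region[r1 - length : r1]
                rc = "".join(comp[c] for c in reversed(right))
                mm = sum(1 for x, y in zip(left, rc) if x != y)
                if mm <= allow(length):
                    cand.append((mm, l0, -r1, length))
        if cand:
            mm, l0, negr1, length = min(cand)
            return l0, -negr1, length, mm
    return None


def enumerate_orfs(seq: str) -> List[Tuple[int, int, str, int]]:
    """All ATG-to-stop ORFs on both strands: (start, end, strand, aa)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    stops = {"TAA", "TAG", "TGA"}
    out = []

    def scan(s: str):
        found = []
        for f in range(3):
            i = f
            start = None
            while i + 3 <= len(s):
                c = s[i : i + 3]
                if start is None and c == "ATG":
                    start = i
                elif start is not None and c in stops:
                    found.append((start, i + 3))
                    start = None
                i += 3
        return found

    for s, e in scan(seq):
        out.append((s, e, "+", (e - s) // 3 - 1))
    rc = "".join(comp[c] for c in reversed(seq))
    for s, e in scan(rc):
        out.append((len(seq) - e, len(seq) - s, "-", (e - s) // 3 - 1))
    return out


def anova_f_direct(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Textbook one-factor ANOVA: F = MSB/MSW and its p-value."""
    from scipy.stats import f as fdist

    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (math.inf, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return F, float(fdist.sf(F, dfb, dfw))


def anova_p_permutation(
    groups: Sequence[Sequence[float]], n_perm: int = 10000, seed: int = 0
) -> float:
    """Permutation p-value for the one-factor ANOVA F statistic."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.array([x for g in groups for x in g], dtype=float)
    f_obs, _ = anova_f_direct(groups)
    count = 0
    for _ in range(n_perm):
        perm = pooled[rng.permutation(pooled.size)]
        out = []
        i = 0
        for s in sizes:
            out.append(perm[i : i + s])
            i += s
        f_p, _ = anova_f_direct(out)
        if f_p >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def anova_p_permutation_fast(
    groups: Sequence[Sequence[float]], n_perm: int = 10000, seed: int = 0
) -> float:
    """Vectorized permutation p for the one-factor F statistic, using the
    computational sum-of-squares formulas (independent of the package's
    mean-centred implementation)."""
    rng = np.random.default_rng(seed)
    sizes = np.array([len(g) for g in groups])
    v = np.concatenate([np.asarray(g, float) for g in groups])
    N = v.size
    k = len(groups)
    starts = np.concatenate([[0], np.cumsum(sizes)])

    def f_rows(mat: np.ndarray) -> np.ndarray:
        total = mat.sum(axis=1)
        ss_total = (mat**2).sum(axis=1) - total**2 / N
        ss_groups = np.zeros(mat.shape[0])
        for g in range(k):
            t = mat[:, starts[g] : starts[g + 1]].sum(axis=1)
            ss_groups += t**2 / sizes[g]
        ssb = ss_groups - total**2 / N
        ssw = ss_total - ssb
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / (k - 1)) / (ssw / (N - k))
        f[np.isnan(f)] = np.inf
        return f

    f_obs = f_rows(v[None, :])[0]
    mat = np.tile(v, (n_perm, 1))
    # column-wise independent shuffles
    idx = np.argsort(rng.random(mat.shape), axis=1)
    mat = np.take_along_axis(mat, idx, axis=1)
    f = f_rows(mat)
    return float((np.sum(f >= f_obs - 1e-12) + 1) / (n_perm + 1))


def unrooted_splits(newick: str, taxa: Sequence[str]) -> frozenset:
    """Non-trivial bipartitions of an unrooted tree, canonicalized so the
    first taxon is never in the reported side."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa_set = set(taxa)
    anchor = sorted(taxa_set)[0]
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(taxa_set - side)
        if 1 < len(side) < len(taxa_set) - 1:
            out.add(side)
    return frozenset(out)
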