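"""Horizontal-transfer inference from transposon vs host-gene distances.

The screen applies the survey's filters in order:

1. *Identity*: only species pairs whose element identity exceeds 70% enter
   the analysis.
2. *Distance ratio*: a pair is kept only when its element distance is "1.2
   times smaller" than the host-gene distance, read as
   ``d_te * 1.2 <= d_host`` for every host gene (configurable to any-gene).
3. *Significance*: candidate events (connected components of passing
   pairs) are accepted only when a one-factor ANOVA across the member
   pairs' element and host-gene distances gives p < 0.01 with the element
   group mean the smallest.

Confirmed status comes from re-running filters 2-3 with a secondary gene:
RAG1 for vertebrate pairs, tub3 for pairs involving an invertebrate.

Replication for the ANOVA comes from independent alignment blocks: each
member pair contributes one distance per marker per block, so even a
single-pair candidate yields a properly replicated one-factor layout.
When sequences are not supplied the groups fall back to one point
distance per member pair, and single-pair candidates are then untestable
and never called.  Saturated or missing distances fail filters instead of
being imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .distmod import DistanceMatrix

__all__ = [
    "HTCandidate",
    "HTEvent",
    "HTResult",
    "identity_filter",
    "distance_ratio_filter",
    "anova_significance",
    "call_ht_events",
    "detect_ht",
    "confirm_events",
]

Pair = Tuple[str, str]


def _norm_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass
class HTCandidate:
    pair: Pair
    identity: float
    d_te: float
    d_hosts: Dict[str, float]
    ratio_pass: bool
    reason: str = ""
    event_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be a fraction in [0,1]")


@dataclass
class HTEvent:
    event_id: int
    members: List[str]
    member_pairs: List[HTCandidate]
    f_stat: float = math.nan
    p_value: float = math.nan
    called: bool = False
    note: str = ""
    confirmed: Optional[bool] = None
    confirmation_note: str = ""


@dataclass
class HTResult:
    candidates: List[HTCandidate]
    events: List[HTEvent]

    @property
    def called_events(self) -> List[HTEvent]:
        return [e for e in self.events if e.called]

    def candidates_frame(self):
        import pandas as pd

        rows = []
        for c in self.candidates:
            row = dict(
                species_a=c.pair[0],
                species_b=c.pair[1],
                identity=c.identity,
                d_te=c.d_te,
                ratio_pass=c.ratio_pass,
                reason=c.reason,
                event_id=c.event_id,
            )
            for g, d in c.d_hosts.items():
                row[f"d_{g}"] = d
            rows.append(row)
        return pd.DataFrame(rows)

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(
                    event_id=e.event_id,
                    members=",".join(e.members),
                    n_pairs=len(e.member_pairs),
                    f_stat=e.f_stat,
                    p_value=e.p_value,
                    called=e.called,
                    confirmed=e.confirmed,
                    note=e.note,
                )
                for e in self.events
            ]
        )


# ---------------------------------------------------------------------------
# filters


def identity_filter(
    identity: DistanceMatrix, threshold: float = 0.70
) -> List[Pair]:
    """Species pairs with element identity strictly above the threshold."""
    pairs = []
    labs = identity.labels
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            if identity.values[i, j] > threshold:
                pairs.append(_norm_pair(labs[i], labs[j]))
    return sorted(pairs)


def distance_ratio_filter(
    d_te: float,
    d_hosts: Mapping[str, float],
    factor: float = 1.2,
    mode: str = "all",
    saturated_te: bool = False,
    saturated_hosts: Optional[Mapping[str, bool]] = None,
) -> Tuple[bool, str]:
    """Element-vs-host distance ratio test for one pair.

    Passes when ``d_te * factor <= d_host`` for every host gene ("all"
    mode) or for at least one ("any").  Saturated or missing distances
    fail with a logged reason.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    if not d_hosts:
        return False, "no host distances"
    if saturated_te or not math.isfinite(d_te):
        return False, "element distance saturated"
    checks = []
    for gene, dh in d_hosts.items():
        if (
            dh is None
            or not math.isfinite(dh)
            or (saturated_hosts or {}).get(gene, False)
        ):
            return False, f"host distance missing/saturated ({gene})"
        # a distance cannot be 1.2 times smaller than a zero host distance
        checks.append(dh > 0.0 and d_te * factor <= dh)
    ok = all(checks) if mode == "all" else any(checks)
    return ok, "" if ok else "ratio"


def _f_stats(mat: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Row-wise one-factor ANOVA F statistics for (R, N) value matrices
    whose columns are grouped by ``sizes``."""
    grand = mat.mean(axis=1)
    ssb = np.zeros(mat.shape[0])
    ssw = np.zeros(mat.shape[0])
    i = 0
    for s in sizes:
        g = mat[:, i : i + s]
        m = g.mean(axis=1)
        ssb += s * (m - grand) ** 2
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
        i += s
    dfb = len(sizes) - 1
    dfw = mat.shape[1] - len(sizes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    f[np.isnan(f)] = np.inf
    return f


def permutation_p(
    groups: Sequence[Sequence[float]], n_perm: int = 4999, seed: int = 0
) -> float:
    """Permutation p-value for the one-factor ANOVA F statistic.

    Robust where the parametric F p-value is anti-conservative — distances
    built from a handful of substitutions give discrete, far-from-normal
    group values.  Deterministic for given data (fixed seed).
    """
    sizes = [len(g) for g in groups]
    v = np.concatenate([np.asarray(g, float) for g in groups])
    f_obs = _f_stats(v[None, :], sizes)[0]
    rng = np.random.default_rng(seed)
    mat = np.tile(v, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    f = _f_stats(mat, sizes)
    return float((np.sum(f >= f_obs - 1e-12) + 1) / (n_perm + 1))


def anova_significance(
    te_dists: Sequence[float],
    host_dist_groups: Mapping[str, Sequence[float]],
) -> Tuple[float, float]:
    """One-factor ANOVA across the element group and each host-gene group.

    Returns (F, p).  When every value in every group is identical there is
    no between-group variance to test and the convention (F=0, p=1)
    applies.
    """
    groups = [list(te_dists)] + [list(v) for v in host_dist_groups.values()]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    flat = [x for g in groups for x in g]
    if max(flat) == min(flat):
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    if math.isnan(f):  # zero within-group variance with distinct means
        f, p = math.inf, 0.0
    return float(f), float(p)


# ---------------------------------------------------------------------------
# event construction


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def call_ht_events(passing: Sequence[HTCandidate]) -> List[HTEvent]:
    """Group passing pairs into events = connected components of the pass
    graph, ordered by smallest member label."""
    uf = _UnionFind()
    for c in passing:
        uf.union(*c.pair)
    comps: Dict[str, List[HTCandidate]] = {}
    for c in passing:
        comps.setdefault(uf.find(c.pair[0]), []).append(c)
    events = []
    for k, (root, pairs) in enumerate(
        sorted(comps.items(), key=lambda kv: kv[0])
    ):
        members = sorted({s for c in pairs for s in c.pair})
        for c in pairs:
            c.event_id = k
        events.append(
            HTEvent(event_id=k, members=members, member_pairs=sorted(pairs, key=lambda c: c.pair))
        )
    return events


def block_distances(
    a: str, b: str, n_blocks: int = 6
) -> List[float]:
    """Per-block K2P distances between two co-aligned sequences (the
    replicate values feeding the event ANOVA).  Saturated or undefined
    blocks are dropped."""
    from . import distmod as _dm

    n = min(len(a), len(b))
    if n_blocks < 2 or n < 2 * n_blocks:
        raise ValueError("need at least 2 usable blocks")
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        try:
            est = _dm.k2p_distance(a[lo:hi], b[lo:hi])
        except ValueError:
            continue
        if not est.saturated:
            out.append(est.distance)
    return out


def _event_groups(
    ev: "HTEvent",
    markers: Sequence[str],
    te_seqs: Optional[Mapping[str, str]],
    host_seqs: Optional[Mapping[str, Mapping[str, str]]],
    n_blocks: int,
) -> Optional[Tuple[List[float], Dict[str, List[float]]]]:
    """ANOVA groups for one candidate event.

    With sequences available each member pair contributes per-block
    distances (replication even for single-pair events); otherwise each
    pair contributes its point distance and >=2 pairs are required.
    """
    if te_seqs is not None and host_seqs is not None:
        te_group: List[float] = []
        host_groups: Dict[str, List[float]] = {g: [] for g in markers}
        for c in ev.member_pairs:
            a, b = c.pair
            te_group.extend(block_distances(te_seqs[a], te_seqs[b], n_blocks))
            for g in markers:
                host_groups[g].extend(
                    block_distances(host_seqs[g][a], host_seqs[g][b], n_blocks)
                )
        if len(te_group) < 2 or any(len(v) < 2 for v in host_groups.values()):
            return None
        return te_group, host_groups
    if len(ev.member_pairs) < 2:
        return None
    te_group = [c.d_te for c in ev.member_pairs]
    host_groups = {
        g: [c.d_hosts[g] for c in ev.member_pairs] for g in markers
    }
    return te_group, host_groups


def detect_ht(
    identity: DistanceMatrix,
    d_te: DistanceMatrix,
    d_hosts: Mapping[str, DistanceMatrix],
    *,
    identity_threshold: float = 0.70,
    ratio_factor: float = 1.2,
    ratio_mode: str = "all",
    alpha: float = 0.01,
    te_seqs: Optional[Mapping[str, str]] = None,
    host_seqs: Optional[Mapping[str, Mapping[str, str]]] = None,
    n_blocks: int = 6,
) -> HTResult:
    """Run the full three-filter screen and return candidates + events."""
    if not 0.0 <= identity_threshold <= 1.0:
        raise ValueError("identity threshold must be a fraction")
    candidates: List[HTCandidate] = []
    passing: List[HTCandidate] = []
    for a, b in identity_filter(identity, identity_threshold):
        dh = {g: m.get(a, b) for g, m in d_hosts.items()}
        sat_h = {g: m.is_saturated(a, b) for g, m in d_hosts.items()}
        ok, reason = distance_ratio_filter(
            d_te.get(a, b),
            dh,
            factor=ratio_factor,
            mode=ratio_mode,
            saturated_te=d_te.is_saturated(a, b),
            saturated_hosts=sat_h,
        )
        cand = HTCandidate(
            pair=(a, b),
            identity=identity.get(a, b),
            d_te=d_te.get(a, b),
            d_hosts=dh,
            ratio_pass=ok,
            reason=reason,
        )
        candidates.append(cand)
        if ok:
            passing.append(cand)
    events = call_ht_events(passing)
    markers = list(d_hosts)
    for ev in events:
        groups = _event_groups(ev, markers, te_seqs, host_seqs, n_blocks)
        if groups is None:
            ev.note = "untestable: single member pair"
            continue
        te_group, host_groups = groups
        f, p = anova_significance(te_group, host_groups)
        all_groups = [te_group] + list(host_groups.values())
        if p < alpha and sum(map(len, all_groups)) >= 12:
            # decide on the permutation p-value: the parametric one is
            # anti-conservative for sparse, discrete distance values (with
            # fewer values the permutation test cannot resolve alpha)
            p = permutation_p(all_groups)
        ev.f_stat, ev.p_value = f, p
        te_mean = float(np.mean(te_group))
        smallest = all(te_mean < np.mean(v) for v in host_groups.values())
        ev.called = p < alpha and smallest
        if not ev.called:
            ev.note = "not significant" if p >= alpha else "element mean not smallest"
    return HTResult(candidates=candidates, events=events)


def confirm_events(
    events: Sequence[HTEvent],
    secondary: Mapping[str, DistanceMatrix],
    vertebrate: Mapping[str, bool],
    *,
    ratio_factor: float = 1.2,
    alpha: float = 0.01,
    te_seqs: Optional[Mapping[str, str]] = None,
    secondary_seqs: Optional[Mapping[str, Mapping[str, str]]] = None,
    n_blocks: int = 6,
) -> List[HTEvent]:
    """Secondary-gene confirmation of called events.

    Pairs of vertebrates are re-tested against RAG1, pairs involving an
    invertebrate against tub3; an event is confirmed when every member
    pair passes the ratio filter with its secondary gene and the
    element-vs-secondary ANOVA over member pairs stays significant with the
    element mean smaller.  Pairs whose secondary gene is unavailable are
    unconfirmable and flag the event as partial.
    """
    for ev in events:
        if not ev.called:
            ev.confirmed = None
            continue
        te_group: List[float] = []
        sec_group: List[float] = []
        all_pass = True
        partial = False
        for c in ev.member_pairs:
            a, b = c.pair
            gene = "RAG1" if vertebrate.get(a) and vertebrate.get(b) else "tub3"
            dmat = secondary.get(gene)
            if dmat is None or a not in dmat.labels or b not in dmat.labels:
                partial = True
                continue
            d_sec = dmat.get(a, b)
            ok, _ = distance_ratio_filter(
                c.d_te,
                {gene: d_sec},
                factor=ratio_factor,
                saturated_te=False,
                saturated_hosts={gene: dmat.is_saturated(a, b)},
            )
            all_pass = all_pass and ok
            if te_seqs is not None and secondary_seqs is not None:
                te_group.extend(
                    block_distances(te_seqs[a], te_seqs[b], n_blocks)
                )
                sec_group.extend(
                    block_distances(
                        secondary_seqs[gene][a], secondary_seqs[gene][b], n_blocks
                    )
                )
            else:
                te_group.append(c.d_te)
                sec_group.append(d_sec)
        if partial and not te_group:
            ev.confirmed = None
            ev.confirmation_note = "unconfirmable: secondary gene missing"
            continue
        if len(te_group) < 2:
            ev.confirmed = None
            ev.confirmation_note = "unconfirmable: too few testable pairs"
            continue
        f, p = anova_significance(te_group, {"secondary": sec_group})
        if p < alpha and len(te_group) + len(sec_group) >= 12:
            p = permutation_p([te_group, sec_group])
        sig = p < alpha and float(np.mean(te_group)) < float(np.mean(sec_group))
        ev.confirmed = bool(all_pass and sig)
        if partial:
            ev.confirmation_note = "partial: some pairs lacked the secondary gene"
    return list(events)
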