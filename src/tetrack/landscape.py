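"""Divergence landscapes: copy-to-consensus Kimura divergence histograms.

Each copy contributes its aligned length (in kb) to the histogram bin
containing its K2P divergence from the family consensus; the x-axis is
percent divergence from 0 in fixed-width bins, the y-axis summed coverage.
Low-divergence mass (<2%) marks recent activity; a landscape with most of
its mass past 10% is fossil-dominated.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import distmod

__all__ = [
    "DivergenceProfile",
    "ActivityReport",
    "divergence_profile",
    "activity_assessment",
]

log = logging.getLogger(__name__)


@dataclass
class DivergenceProfile:
    element_id: str
    species: str
    bin_width: float  # percent
    coverage_kb: np.ndarray  # contiguous bins from 0%
    n_copies: int
    n_excluded: int = 0

    @property
    def total_kb(self) -> float:
        return float(self.coverage_kb.sum())

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.coverage_kb) + 1) * self.bin_width

    def mass_below(self, cut_percent: float) -> float:
        """Fraction of coverage in bins entirely below the cut."""
        if self.total_kb == 0:
            return 0.0
        edges = self.bin_edges
        full = edges[1:] <= cut_percent
        return float(self.coverage_kb[full].sum() / self.total_kb)

    def to_rows(self) -> List[Tuple[float, float]]:
        return [
            (float(e), float(c))
            for e, c in zip(self.bin_edges[:-1], self.coverage_kb)
        ]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_rows(), columns=["bin_lower_pct", "coverage_kb"]).to_csv(
            path, sep="\t", index=False
        )

    def local_maxima(self) -> List[int]:
        """Indices of strict local maxima in the histogram (plateau-aware)."""
        c = self.coverage_kb
        out = []
        for i in range(len(c)):
            if c[i] == 0:
                continue
            left = c[i - 1] if i > 0 else -math.inf
            right = c[i + 1] if i < len(c) - 1 else -math.inf
            if c[i] >= left and c[i] > right or (c[i] > left and c[i] >= right):
                out.append(i)
        return out


def divergence_profile(
    copies: Sequence[str],
    consensus: str,
    *,
    bin_width: float = 1.0,
    element_id: str = "element",
    species: str = "",
    pre_aligned: bool = False,
) -> DivergenceProfile:
    """Histogram of copy coverage (kb) by K2P divergence from the consensus.

    Copies are aligned to the consensus (overlap alignment) unless
    ``pre_aligned``; a copy with an undefined or saturated distance is
    excluded and logged.  An empty copy list yields an empty profile.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    masses: List[Tuple[int, float]] = []  # (bin index, kb)
    excluded = 0
    for i, copy in enumerate(copies):
        try:
            if pre_aligned:
                a, b = consensus, copy
            else:
                aln = distmod.align_pair(consensus, copy, mode="overlap")
                a, b = aln.seq_a, aln.seq_b
            est = distmod.k2p_distance(a, b)
        except ValueError:
            log.warning("copy %d excluded: undefined divergence", i)
            excluded += 1
            continue
        if est.saturated:
            log.warning("copy %d excluded: saturated divergence", i)
            excluded += 1
            continue
        pct = est.distance * 100.0
        masses.append((int(pct // bin_width), est.sites / 1000.0))
    n_bins = max((b for b, _ in masses), default=-1) + 1
    cov = np.zeros(max(n_bins, 1))
    for b, kb in masses:
        cov[b] += kb
    if not masses:
        cov = np.zeros(0)
    return DivergenceProfile(
        element_id=element_id,
        species=species,
        bin_width=bin_width,
        coverage_kb=cov,
        n_copies=len(masses),
        n_excluded=excluded,
    )


@dataclass
class ActivityReport:
    recent_activity: bool
    fossil_dominated: bool
    recent_fraction: float  # coverage mass below the recent cut
    old_fraction: float  # coverage mass above the old cut
    recent_cut: float
    old_cut: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


def activity_assessment(
    profile: DivergenceProfile,
    recent_cut: float = 2.0,
    old_cut: float = 10.0,
) -> ActivityReport:
    """Recent-vs-fossil activity flags from a divergence profile.

    ``recent_activity`` when any coverage mass lies below ``recent_cut``
    percent; ``fossil_dominated`` when more than half the mass lies above
    ``old_cut``.
    """
    if profile.total_kb == 0:
        raise ValueError("assessment undefined for an empty profile")
    recent = profile.mass_below(recent_cut)
    old = 1.0 - profile.mass_below(old_cut)
    return ActivityReport(
        recent_activity=recent > 0.0,
        fossil_dominated=old > 0.5,
        recent_fraction=recent,
        old_fraction=old,
        recent_cut=recent_cut,
        old_cut=old_cut,
    )
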