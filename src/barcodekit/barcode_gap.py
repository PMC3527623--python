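"""Barcoding-gap analysis.

The barcoding gap is the separation between within-species (intraspecific)
and between-species (interspecific) genetic distances.  Following common
practice, the interspecific side of the gap statistic is restricted to
congeneric pairs (same genus, different species): the gap is

    gap = min(interspecific-but-intrageneric) - max(intraspecific)

and may be negative when the two distributions overlap.  Two ranges are
reported: the ``total`` range uses every defined pair; the ``trimmed90``
(90% overlapping) range first discards the largest 5% of intraspecific and
the smallest 5% of congeneric interspecific observations.

Distances are held as proportions internally; report exports multiply by
100 to match the percent scale conventional in gap plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from barcodekit.distmat import DistanceMatrix

GapMode = Literal["total", "trimmed90"]

TRIM_FRACTION = 0.05


@dataclass(frozen=True)
class DivergenceDistributions:
    """Defined pairwise distances split by label relation.

    ``intra`` and ``inter`` partition the defined off-diagonal pairs;
    ``inter_congeneric`` is the subset of ``inter`` with both genera equal.
    """

    intra: tuple[float, ...]
    inter: tuple[float, ...]
    inter_congeneric: tuple[float, ...]
    model: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = (
            [{"class": "intraspecific", "distance": d} for d in self.intra]
            + [{"class": "interspecific", "distance": d} for d in self.inter]
            + [
                {"class": "interspecific_congeneric", "distance": d}
                for d in self.inter_congeneric
            ]
        )
        return pd.DataFrame(rows, columns=["class", "distance"])


@dataclass(frozen=True)
class GapSummary:
    """Max-intra / min-inter(congeneric) / gap for one range mode."""

    max_intra: float
    min_inter_congeneric: float
    gap: float
    mode: GapMode
    n_affected: int
    model: str

    def as_percent(self) -> dict[str, float]:
        return {
            "max_intra_pct": self.max_intra * 100.0,
            "min_inter_congeneric_pct": self.min_inter_congeneric * 100.0,
            "gap_pct": self.gap * 100.0,
        }

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "model": self.model,
            "max_intra": self.max_intra,
            "min_inter_congeneric": self.min_inter_congeneric,
            "gap": self.gap,
            "n_affected": self.n_affected,
            **self.as_percent(),
        }


def split_distributions(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    genera: Mapping[str, str],
) -> DivergenceDistributions:
    """Partition defined pairs into intra / inter / congeneric-inter sets.

    A pair is intraspecific iff the two effective labels are equal.
    Undefined pairs (below the overlap floor or saturated) appear nowhere.
    """
    unlabeled = [i for i in matrix.ids if i not in labels or i not in genera]
    if unlabeled:
        raise KeyError(f"ids without labels: {unlabeled}")
    intra: list[float] = []
    inter: list[float] = []
    inter_cg: list[float] = []
    for p in matrix.defined_pairs():
        assert p.d is not None
        if labels[p.id_a] == labels[p.id_b]:
            intra.append(p.d)
        else:
            inter.append(p.d)
            if genera[p.id_a] == genera[p.id_b]:
                inter_cg.append(p.d)
    return DivergenceDistributions(
        intra=tuple(intra),
        inter=tuple(inter),
        inter_congeneric=tuple(inter_cg),
        model=matrix.model,
    )


def _trim_count(n: int) -> int:
    return math.ceil(TRIM_FRACTION * n)


def gap_summary(dists: DivergenceDistributions, mode: GapMode = "total") -> GapSummary:
    """Compute the gap statistic for the total or 90%-overlap range.

    ``trimmed90`` removes the top ceil(5%) of intraspecific values and the
    bottom ceil(5%) of congeneric interspecific values before taking the
    max/min; ties at the cut are resolved by removing the most extreme
    values first in sorted order.
    """
    if not dists.intra:
        raise ValueError("empty intraspecific distribution")
    if not dists.inter_congeneric:
        raise ValueError("empty congeneric interspecific distribution")
    intra = sorted(dists.intra)
    inter = sorted(dists.inter_congeneric)
    n_affected = 0
    if mode == "trimmed90":
        k_intra = _trim_count(len(intra))
        k_inter = _trim_count(len(inter))
        if k_intra >= len(intra) or k_inter >= len(inter):
            raise ValueError("trimming would empty a distribution")
        intra = intra[: len(intra) - k_intra]
        inter = inter[k_inter:]
        n_affected = k_intra + k_inter
    elif mode != "total":
        raise ValueError(f"unknown mode {mode!r}")
    max_intra = intra[-1]
    min_inter = inter[0]
    return GapSummary(
        max_intra=max_intra,
        min_inter_congeneric=min_inter,
        gap=min_inter - max_intra,
        mode=mode,
        n_affected=n_affected,
        model=dists.model,
    )


def histogram(
    dists: DivergenceDistributions, bin_width_pct: float = 0.25
) -> pd.DataFrame:
    """Bin intra and inter distributions on the percent scale for plotting."""
    all_vals = np.array(dists.intra + dists.inter) * 100.0
    if all_vals.size == 0:
        return pd.DataFrame(columns=["bin_left_pct", "intra", "inter"])
    top = float(all_vals.max())
    edges = np.arange(0.0, top + 2 * bin_width_pct, bin_width_pct)
    intra_counts, _ = np.histogram(np.array(dists.intra) * 100.0, bins=edges)
    inter_counts, _ = np.histogram(np.array(dists.inter) * 100.0, bins=edges)
    return pd.DataFrame(
        {
            "bin_left_pct": edges[:-1],
            "intra": intra_counts,
            "inter": inter_counts,
        }
    )
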