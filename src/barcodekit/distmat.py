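"""Pairwise distances under pairwise deletion.

Two distance models are supported:

* ``uncorrected`` — the p-distance, the raw proportion of differing sites
  among the compared (both-ungapped, unambiguous) columns;
* ``k2p`` — the Kimura 2-parameter correction, which distinguishes the
  transition proportion P (A<->G, C<->T) from the transversion proportion Q:

      d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Pairwise deletion means each pair is compared only on the columns where
*both* sequences carry a plain base (A/C/G/T); gaps and IUPAC ambiguity
codes are excluded.  Pairs sharing fewer than ``min_overlap`` such columns
(300 by default) carry an explicitly *undefined* distance and are excluded
from every downstream summary — never a sentinel number.  The K2P distance
is likewise undefined when the logarithm argument is non-positive
(saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from barcodekit.seqio import AlignedRecord

Model = Literal["uncorrected", "k2p"]

DEFAULT_MIN_OVERLAP = 300

# Byte codes for the four plain bases; everything else is missing.
_A, _C, _G, _T = (ord(c) for c in "ACGT")
_PURINES = frozenset({_A, _G})


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _base_mask(arr: np.ndarray) -> np.ndarray:
    return (arr == _A) | (arr == _C) | (arr == _G) | (arr == _T)


def compare_sites(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """Count compared sites, transitions and transversions for one pair.

    A column is compared only when both characters are in {A,C,G,T}.
    Transitions are A<->G and C<->T; every other mismatch is a transversion.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = _encode(seq_a.upper()), _encode(seq_b.upper())
    both = _base_mask(a) & _base_mask(b)
    a, b = a[both], b[both]
    diff = a != b
    # Transition iff both are purines or both are pyrimidines.
    a_pur = (a == _A) | (a == _G)
    b_pur = (b == _A) | (b == _G)
    transitions = int(np.count_nonzero(diff & (a_pur == b_pur)))
    transversions = int(np.count_nonzero(diff & (a_pur != b_pur)))
    return int(both.sum()), transitions, transversions


def k2p(P: float, Q: float) -> float | None:
    """Kimura 2-parameter distance from transition/transversion proportions.

    Returns ``None`` (undefined) at saturation, i.e. when ``1-2P-Q <= 0`` or
    ``1-2Q <= 0``.
    """
    if not (math.isfinite(P) and math.isfinite(Q)):
        raise ValueError("P and Q must be finite")
    if P < 0 or Q < 0 or P + Q > 1 + 1e-12:
        raise ValueError(f"invalid proportions P={P}, Q={Q}")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 normalizes -0.0


@dataclass(frozen=True)
class PairDistance:
    """Distance between one unordered pair of sequences.

    ``d`` is ``None`` when the pair is undefined: fewer than ``min_overlap``
    compared sites, or K2P saturation.
    """

    id_a: str
    id_b: str
    model: Model
    n_sites: int
    n_transitions: int
    n_transversions: int
    d: float | None

    @property
    def p_transition(self) -> float:
        return self.n_transitions / self.n_sites if self.n_sites else 0.0

    @property
    def q_transversion(self) -> float:
        return self.n_transversions / self.n_sites if self.n_sites else 0.0

    @property
    def defined(self) -> bool:
        return self.d is not None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair overlap bookkeeping."""

    ids: list[str]
    model: Model
    min_overlap: int
    entries: dict[frozenset[str], PairDistance]
    n_saturated: int = 0
    n_below_overlap: int = 0

    def pair(self, id_a: str, id_b: str) -> PairDistance:
        return self.entries[frozenset((id_a, id_b))]

    def distance(self, id_a: str, id_b: str) -> float | None:
        if id_a == id_b:
            return 0.0
        return self.pair(id_a, id_b).d

    def iter_pairs(self) -> Iterable[PairDistance]:
        ids = self.ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                yield self.pair(ids[i], ids[j])

    def defined_pairs(self) -> Iterable[PairDistance]:
        return (p for p in self.iter_pairs() if p.defined)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table: id_a, id_b, model, d, n_sites."""
        rows = [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "model": p.model,
                "d": p.d if p.defined else float("nan"),
                "n_sites": p.n_sites,
            }
            for p in self.iter_pairs()
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "model", "d", "n_sites"])

    def to_square(self) -> pd.DataFrame:
        """Square matrix with NaN for undefined pairs (diagonal 0)."""
        n = len(self.ids)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = self.pair(self.ids[i], self.ids[j]).d
                mat[i, j] = mat[j, i] = d if d is not None else float("nan")
        return pd.DataFrame(mat, index=self.ids, columns=self.ids)

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance format; undefined entries written as -1."""
        sq = self.to_square().fillna(-1.0)
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid in self.ids:
                row = " ".join(f"{v:.8f}" for v in sq.loc[sid])
                fh.write(f"{sid:<10s} {row}\n")


def build_matrix(
    records: Sequence[AlignedRecord],
    model: Model = "k2p",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Assemble the pairwise distance matrix for an aligned dataset.

    Every pair with fewer than ``min_overlap`` compared sites is stored with
    an undefined distance, as is every K2P-saturated pair; both are counted
    in the matrix diagnostics.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
    if model not in ("uncorrected", "k2p"):
        raise ValueError(f"unknown model {model!r}")

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")

    encoded = [_encode(r.seq) for r in records]
    masks = [_base_mask(a) for a in encoded]
    purine = [(a == _A) | (a == _G) for a in encoded]

    entries: dict[frozenset[str], PairDistance] = {}
    n_sat = 0
    n_short = 0
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            both = masks[i] & masks[j]
            n = int(both.sum())
            diff = (encoded[i] != encoded[j]) & both
            ts = int(np.count_nonzero(diff & (purine[i] == purine[j])))
            tv = int(np.count_nonzero(diff & (purine[i] != purine[j])))
            d: float | None
            if n < min_overlap:
                d = None
                n_short += 1
            elif model == "uncorrected":
                d = (ts + tv) / n
            else:
                d = k2p(ts / n, tv / n)
                if d is None:
                    n_sat += 1
            entries[frozenset((ids[i], ids[j]))] = PairDistance(
                id_a=ids[i],
                id_b=ids[j],
                model=model,
                n_sites=n,
                n_transitions=ts,
                n_transversions=tv,
                d=d,
            )
    return DistanceMatrix(
        ids=ids,
        model=model,
        min_overlap=min_overlap,
        entries=entries,
        n_saturated=n_sat,
        n_below_overlap=n_short,
    )
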