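"""Distance-based species identification.

Every sequence in the dataset serves once as a query against all remaining
sequences (leave-one-out).  Three criteria are implemented:

* Best Match (BM): the query takes the label of its nearest reference(s),
  regardless of the distance magnitude.  Ties at the minimal distance with
  mixed labels are ambiguous; a single wrong label is a misidentification.
* Best Close Match (BCM): as BM, but only when the nearest reference lies
  strictly below a dataset-derived threshold; otherwise "no match".
* All Species Barcodes (ASB): considers *all* references strictly below the
  threshold.  Identification succeeds only when these are >= 2 conspecific
  barcodes comprising every conspecific reference comparable to the query;
  a single conspecific barcode, or an incomplete portion of them, is
  ambiguous; any allospecific barcode in the set is a misidentification;
  an empty set is "no match".

The threshold is the smallest defined interspecific distance in the matrix
under the active label mode.  Comparison against the threshold is strict
(match iff d < threshold): the threshold is itself realised by an
allospecific pair, so an inclusive comparison would admit a guaranteed
wrong match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import pandas as pd

from barcodekit.distmat import DistanceMatrix

Method = Literal["BM", "BCM", "ASB"]
Outcome = Literal["correct", "ambiguous", "misidentified", "no_match"]


@dataclass(frozen=True)
class Threshold:
    """Dataset-derived distance threshold for BCM/ASB."""

    value: float
    model: str
    provenance: str = "smallest_interspecific"


@dataclass(frozen=True)
class IdentOutcome:
    """Per-query classification under one criterion."""

    query_id: str
    method: Method
    outcome: Outcome
    best_ids: tuple[str, ...]
    best_distance: float | None


def derive_threshold(matrix: DistanceMatrix, labels: Mapping[str, str]) -> Threshold:
    """Smallest defined interspecific distance under the given labels."""
    best = math.inf
    found = False
    for p in matrix.defined_pairs():
        if labels[p.id_a] != labels[p.id_b]:
            assert p.d is not None
            found = True
            if p.d < best:
                best = p.d
    if not found:
        raise ValueError("no defined interspecific pairs; cannot derive threshold")
    return Threshold(value=best, model=matrix.model)


def _neighbours(
    query_id: str, matrix: DistanceMatrix, labels: Mapping[str, str]
) -> list[tuple[str, float]]:
    """Defined (reference id, distance) pairs for a query, others only."""
    out = []
    for other in matrix.ids:
        if other == query_id:
            continue
        d = matrix.pair(query_id, other).d
        if d is not None:
            out.append((other, d))
    return out


def _classify_best(
    query_label: str, candidates: list[str], labels: Mapping[str, str]
) -> Outcome:
    cand_labels = {labels[c] for c in candidates}
    if cand_labels == {query_label}:
        return "correct"
    if query_label in cand_labels:
        return "ambiguous"
    if len(cand_labels) == 1:
        return "misidentified"
    return "ambiguous"


def best_match(
    query_id: str, matrix: DistanceMatrix, labels: Mapping[str, str]
) -> IdentOutcome:
    """Best Match: label of the nearest reference(s), unconditionally."""
    neigh = _neighbours(query_id, matrix, labels)
    if not neigh:
        raise ValueError(f"query {query_id!r} has no defined comparisons")
    best_d = min(d for _, d in neigh)
    candidates = sorted(c for c, d in neigh if d == best_d)
    return IdentOutcome(
        query_id=query_id,
        method="BM",
        outcome=_classify_best(labels[query_id], candidates, labels),
        best_ids=tuple(candidates),
        best_distance=best_d,
    )


def best_close_match(
    query_id: str,
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: Threshold,
) -> IdentOutcome:
    """Best Close Match: BM gated on best distance < threshold, else no_match."""
    bm = best_match(query_id, matrix, labels)
    assert bm.best_distance is not None
    if bm.best_distance >= threshold.value:
        return IdentOutcome(
            query_id=query_id,
            method="BCM",
            outcome="no_match",
            best_ids=bm.best_ids,
            best_distance=bm.best_distance,
        )
    return IdentOutcome(
        query_id=query_id,
        method="BCM",
        outcome=bm.outcome,
        best_ids=bm.best_ids,
        best_distance=bm.best_distance,
    )


def all_species_barcodes(
    query_id: str,
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: Threshold,
) -> IdentOutcome:
    """All Species Barcodes: judge the full sub-threshold reference set."""
    neigh = _neighbours(query_id, matrix, labels)
    if not neigh:
        raise ValueError(f"query {query_id!r} has no defined comparisons")
    close = [(c, d) for c, d in neigh if d < threshold.value]
    if not close:
        return IdentOutcome(
            query_id=query_id,
            method="ASB",
            outcome="no_match",
            best_ids=(),
            best_distance=min(d for _, d in neigh),
        )
    best_d = min(d for _, d in close)
    cand_ids = tuple(sorted(c for c, _ in close))
    qlabel = labels[query_id]
    if any(labels[c] != qlabel for c, _ in close):
        outcome: Outcome = "misidentified"
    else:
        # Every comparable conspecific reference must be inside the threshold,
        # and there must be at least two of them.
        conspecific_refs = {c for c, _ in neigh if labels[c] == qlabel}
        if len(close) >= 2 and {c for c, _ in close} == conspecific_refs:
            outcome = "correct"
        else:
            outcome = "ambiguous"
    return IdentOutcome(
        query_id=query_id,
        method="ASB",
        outcome=outcome,
        best_ids=cand_ids,
        best_distance=best_d,
    )


def identify_all(
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: Threshold | None = None,
) -> dict[Method, list[IdentOutcome]]:
    """Leave-one-out identification of every sequence under BM, BCM and ASB.

    Queries without any defined comparison are skipped (and reported by
    :func:`excluded_queries`).
    """
    if threshold is None:
        threshold = derive_threshold(matrix, labels)
    results: dict[Method, list[IdentOutcome]] = {"BM": [], "BCM": [], "ASB": []}
    for qid in matrix.ids:
        if not _neighbours(qid, matrix, labels):
            continue
        results["BM"].append(best_match(qid, matrix, labels))
        results["BCM"].append(best_close_match(qid, matrix, labels, threshold))
        results["ASB"].append(all_species_barcodes(qid, matrix, labels, threshold))
    return results


def excluded_queries(matrix: DistanceMatrix, labels: Mapping[str, str]) -> list[str]:
    """Ids with no defined comparison at all (excluded from percentages)."""
    return [q for q in matrix.ids if not _neighbours(q, matrix, labels)]


def summarize(outcomes: list[IdentOutcome]) -> dict:
    """Counts and percentages per outcome category for one method."""
    n = len(outcomes)
    counts = {k: 0 for k in ("correct", "ambiguous", "misidentified", "no_match")}
    for o in outcomes:
        counts[o.outcome] += 1
    return {
        "n_queries": n,
        "counts": counts,
        "percent": {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()},
    }


def outcomes_table(results: dict[Method, list[IdentOutcome]]) -> pd.DataFrame:
    rows = [
        {
            "query_id": o.query_id,
            "method": o.method,
            "outcome": o.outcome,
            "best_distance": o.best_distance,
            "best_ids": ",".join(o.best_ids),
        }
        for method in ("BM", "BCM", "ASB")
        for o in results.get(method, [])
    ]
    return pd.DataFrame(
        rows, columns=["query_id", "method", "outcome", "best_distance", "best_ids"]
    )
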