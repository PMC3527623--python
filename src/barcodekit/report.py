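"""End-to-end marker assessment and reporting.

``run_assessment`` executes the full workflow for one aligned marker
dataset under one label mode: distance matrix -> barcoding-gap summaries
(total and 90%-overlap ranges, both distance models) -> leave-one-out
distance identification (BM, BCM, ASB) -> NJ tree with bootstrap supports
-> tree identification (Hebert-style and Meier-style criteria on the
collapsed, rooted tree).  ``compare_modes`` repeats the classification
stages under both the OTU and taxonomy labelings of the same matrix and
tree, re-deriving the threshold per mode.

All percentages in the report derive from the per-query outcome tables the
run also writes, so every number is re-checkable from the emitted TSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from barcodekit._version import __version__ as _version
from barcodekit.barcode_gap import gap_summary, split_distributions
from barcodekit.distmat import DEFAULT_MIN_OVERLAP, Model, build_matrix
from barcodekit.ident_distance import (
    derive_threshold,
    excluded_queries,
    identify_all,
    outcomes_table,
    summarize,
)
from barcodekit.ident_tree import (
    identify_all_tree,
    summarize_tree,
    tree_outcomes_table,
)
from barcodekit.njtree import (
    DEFAULT_COLLAPSE_EPSILON,
    bootstrap_supports,
    collapse,
    prune_leaves,
    root_tree,
)
from barcodekit.seqio import AlignedRecord, LabelMode, effective_labels, genus_map

logger = logging.getLogger("barcodekit")

REPORT_SCHEMA_VERSION = 1


@dataclass
class AssessmentConfig:
    """Declarative description of one assessment run."""

    marker: str = "marker"
    label_mode: LabelMode | str = LabelMode.TAXONOMY
    model: Model = "k2p"
    min_overlap: int = DEFAULT_MIN_OVERLAP
    bootstrap: int = 1000
    seed: int = 0
    collapse_epsilon: float = DEFAULT_COLLAPSE_EPSILON
    outgroup: str | None = None
    out_dir: str | Path | None = None


@dataclass
class AssessmentReport:
    """Structured results of one marker x label-mode assessment."""

    marker: str
    label_mode: str
    model: str
    n_sequences: int
    n_queries_scored: int
    threshold: float
    gap: dict
    distance_methods: dict
    tree_methods: dict
    excluded_queries: list[str]
    newick: str
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "marker": self.marker,
            "label_mode": self.label_mode,
            "model": self.model,
            "n_sequences": self.n_sequences,
            "n_queries_scored": self.n_queries_scored,
            "threshold": self.threshold,
            "gap": self.gap,
            "distance_methods": self.distance_methods,
            "tree_methods": self.tree_methods,
            "excluded_queries": self.excluded_queries,
            "newick": self.newick,
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def _gap_block(records, labels, genera, min_overlap) -> dict:
    """Gap summaries for both models and both range modes."""
    out: dict = {}
    for model in ("uncorrected", "k2p"):
        matrix = build_matrix(records, model=model, min_overlap=min_overlap)
        dists = split_distributions(matrix, labels, genera)
        block = {}
        for mode in ("total", "trimmed90"):
            try:
                block[mode] = gap_summary(dists, mode).to_dict()
            except ValueError as exc:
                block[mode] = {"error": str(exc)}
        out[model] = block
    return out


def run_assessment(
    records: list[AlignedRecord], config: AssessmentConfig
) -> AssessmentReport:
    """Run the full assessment for one marker dataset and label mode."""
    if len(records) < 3:
        raise ValueError("assessment needs at least 3 sequences (NJ requires >= 3)")
    mode = LabelMode(config.label_mode)
    labels = effective_labels(records, mode)
    genera = genus_map(records)
    logger.info(
        "assessment start: marker=%s mode=%s n=%d", config.marker, mode.value,
        len(records),
    )

    matrix = build_matrix(records, model=config.model, min_overlap=config.min_overlap)
    logger.info(
        "distance matrix: %d pairs, %d below overlap floor, %d saturated",
        len(matrix.entries), matrix.n_below_overlap, matrix.n_saturated,
    )

    gap = _gap_block(records, labels, genera, config.min_overlap)

    threshold = derive_threshold(matrix, labels)
    dist_results = identify_all(matrix, labels, threshold)
    excluded = excluded_queries(matrix, labels)
    dist_summary = {m: summarize(v) for m, v in dist_results.items()}
    logger.info(
        "distance identification: threshold=%.6f excluded=%d",
        threshold.value, len(excluded),
    )

    stree = bootstrap_supports(
        records,
        model=config.model,
        B=config.bootstrap,
        seed=config.seed,
        min_overlap=config.min_overlap,
    )
    scored_tree = collapse(stree, config.collapse_epsilon)
    if config.outgroup is not None:
        scored_tree = root_tree(scored_tree, outgroup=config.outgroup)
        scored_tree = prune_leaves(scored_tree, [config.outgroup])
    else:
        scored_tree = root_tree(scored_tree)
    tree_labels = {k: v for k, v in labels.items() if k != config.outgroup}
    tree_results = identify_all_tree(scored_tree, tree_labels)
    tree_summary = {c: summarize_tree(v) for c, v in tree_results.items()}

    n_scored = len(dist_results["BM"])
    report = AssessmentReport(
        marker=config.marker,
        label_mode=mode.value,
        model=config.model,
        n_sequences=len(records),
        n_queries_scored=n_scored,
        threshold=threshold.value,
        gap=gap,
        distance_methods=dist_summary,
        tree_methods=tree_summary,
        excluded_queries=excluded,
        newick=stree.as_newick(),
        metadata={
            "tool": "barcodekit",
            "version": _version,
            "seed": config.seed,
            "bootstrap": config.bootstrap,
            "min_overlap": config.min_overlap,
            "collapse_epsilon": config.collapse_epsilon,
            "outgroup": config.outgroup,
        },
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        matrix.to_dataframe().to_csv(out / "distances.tsv", sep="\t", index=False)
        outcomes_table(dist_results).to_csv(
            out / "outcomes_distance.tsv", sep="\t", index=False
        )
        tree_outcomes_table(tree_results).to_csv(
            out / "outcomes_tree.tsv", sep="\t", index=False
        )
        (out / "gap.json").write_text(json.dumps(gap, indent=2, sort_keys=True) + "\n")
        stree.write_newick(out / "tree.nwk")
    return report


def compare_modes(
    records: list[AlignedRecord], config: AssessmentConfig
) -> dict[str, AssessmentReport]:
    """Run both label modes on the identical dataset; threshold per mode."""
    missing_otu = [r.id for r in records if not r.otu]
    if missing_otu:
        raise ValueError(f"records without otu codes: {missing_otu}")
    reports = {}
    for mode in (LabelMode.OTU, LabelMode.TAXONOMY):
        cfg = AssessmentConfig(
            marker=config.marker,
            label_mode=mode,
            model=config.model,
            min_overlap=config.min_overlap,
            bootstrap=config.bootstrap,
            seed=config.seed,
            collapse_epsilon=config.collapse_epsilon,
            outgroup=config.outgroup,
            out_dir=(
                Path(config.out_dir) / mode.value
                if config.out_dir is not None
                else None
            ),
        )
        reports[mode.value] = run_assessment(records, cfg)
    return reports


def mode_delta_table(reports: dict[str, AssessmentReport]) -> list[dict]:
    """Side-by-side outcome percentages for the two label modes."""
    rows = []
    for method in ("BM", "BCM", "ASB"):
        for outcome in ("correct", "ambiguous", "misidentified", "no_match"):
            rows.append(
                {
                    "method": method,
                    "outcome": outcome,
                    "otu_pct": reports["otu"].distance_methods[method]["percent"][outcome],
                    "taxonomy_pct": reports["taxonomy"].distance_methods[method][
                        "percent"
                    ][outcome],
                }
            )
    for crit in ("hebert", "meier"):
        for outcome in ("correct", "ambiguous", "misidentified"):
            rows.append(
                {
                    "method": f"tree-{crit}",
                    "outcome": outcome,
                    "otu_pct": reports["otu"].tree_methods[crit]["percent"][outcome],
                    "taxonomy_pct": reports["taxonomy"].tree_methods[crit]["percent"][
                        outcome
                    ],
                }
            )
    return rows
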