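"""Tree-based species identification.

Two rule sets, both applied leaf-by-leaf to a rooted, polytomy-collapsed
NJ tree with species-level labels:

* Hebert-style: identification succeeds when the query clusters with *all*
  conspecific sequences, i.e. the label's full leaf set is monophyletic;
  it fails (misidentified) when conspecifics occur in multiple clusters;
  singletons — sole representatives of their label — are ambiguous.

* Meier-style (stricter): the query is judged by its local context.  It is
  correct when in polytomy with conspecifics or at least one node inside a
  clade of conspecifics; ambiguous when it has no conspecifics at all or is
  sister to the complete set of its conspecifics; misidentified when its
  context is purely allospecific.  A mixed sibling context is conservatively
  scored ambiguous.

The central interpretive point for the Meier rules is the distinction
between a query *inside* a conspecific clade (its siblings are a proper
subset of its conspecifics — correct) and a query *sister to* all of its
conspecifics (siblings exactly equal the conspecific set — ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import dendropy
import pandas as pd

from barcodekit.njtree import SupportTree

Criteria = Literal["hebert", "meier"]
TreeOutcome = Literal["correct", "ambiguous", "misidentified"]
Evidence = Literal[
    "singleton",
    "monophyletic_conspecifics",
    "conspecifics_split",
    "polytomy_conspecific",
    "nested_in_conspecific_clade",
    "sister_to_all_conspecifics",
    "no_conspecifics",
    "allospecific_context",
    "mixed_context",
]


@dataclass(frozen=True)
class TreeIdentOutcome:
    query_id: str
    criteria: Criteria
    outcome: TreeOutcome
    evidence: Evidence


def _leaf(tree: dendropy.Tree, query_id: str) -> dendropy.Node:
    node = tree.find_node_with_taxon_label(query_id)
    if node is None or not node.is_leaf():
        raise KeyError(f"query {query_id!r} is not a leaf of the tree")
    return node


def hebert_identify(
    stree: SupportTree, labels: Mapping[str, str], query_id: str
) -> TreeIdentOutcome:
    """Monophyly-of-all-conspecifics rule; singletons are ambiguous."""
    tree = stree.tree
    _leaf(tree, query_id)
    qlabel = labels[query_id]
    members = [
        lf for lf in tree.leaf_node_iter() if labels[lf.taxon.label] == qlabel
    ]
    if len(members) == 1:
        return TreeIdentOutcome(query_id, "hebert", "ambiguous", "singleton")
    taxa = [lf.taxon for lf in members]
    mrca = tree.mrca(taxa=taxa)
    clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
    if clade_leaves == {lf.taxon.label for lf in members}:
        return TreeIdentOutcome(
            query_id, "hebert", "correct", "monophyletic_conspecifics"
        )
    return TreeIdentOutcome(query_id, "hebert", "misidentified", "conspecifics_split")


def meier_identify(
    stree: SupportTree, labels: Mapping[str, str], query_id: str
) -> TreeIdentOutcome:
    """Local-context rule on the collapsed tree; see module docstring.

    Rule order: (1) no conspecifics -> ambiguous; (2) all-conspecific
    polytomy siblings -> correct; (3) all-conspecific binary sibling:
    proper subset of conspecifics -> correct, the complete set -> ambiguous
    (sister); (4) all-allospecific siblings -> misidentified; (5) mixed ->
    ambiguous.
    """
    tree = stree.tree
    query = _leaf(tree, query_id)
    qlabel = labels[query_id]
    conspecifics = {
        lf.taxon.label
        for lf in tree.leaf_node_iter()
        if labels[lf.taxon.label] == qlabel and lf.taxon.label != query_id
    }
    if not conspecifics:
        return TreeIdentOutcome(query_id, "meier", "ambiguous", "no_conspecifics")

    parent = query.parent_node
    if parent is None:
        # Degenerate: query is the root; treat all other leaves as siblings.
        siblings = {
            lf.taxon.label
            for lf in tree.leaf_node_iter()
            if lf.taxon.label != query_id
        }
        n_children = len(tree.seed_node.child_nodes())
    else:
        siblings = {
            lf.taxon.label
            for child in parent.child_nodes()
            if child is not query
            for lf in child.leaf_iter()
        }
        n_children = len(parent.child_nodes())

    sib_labels = {labels[s] for s in siblings}
    if sib_labels == {qlabel}:
        if n_children >= 3:
            return TreeIdentOutcome(
                query_id, "meier", "correct", "polytomy_conspecific"
            )
        if siblings < conspecifics:
            return TreeIdentOutcome(
                query_id, "meier", "correct", "nested_in_conspecific_clade"
            )
        return TreeIdentOutcome(
            query_id, "meier", "ambiguous", "sister_to_all_conspecifics"
        )
    if qlabel not in sib_labels:
        return TreeIdentOutcome(
            query_id, "meier", "misidentified", "allospecific_context"
        )
    return TreeIdentOutcome(query_id, "meier", "ambiguous", "mixed_context")


def identify_all_tree(
    stree: SupportTree, labels: Mapping[str, str]
) -> dict[Criteria, list[TreeIdentOutcome]]:
    """Score every leaf under both criteria sets."""
    leaves = sorted(lf.taxon.label for lf in stree.tree.leaf_node_iter())
    return {
        "hebert": [hebert_identify(stree, labels, q) for q in leaves],
        "meier": [meier_identify(stree, labels, q) for q in leaves],
    }


def summarize_tree(outcomes: list[TreeIdentOutcome]) -> dict:
    n = len(outcomes)
    counts = {k: 0 for k in ("correct", "ambiguous", "misidentified")}
    for o in outcomes:
        counts[o.outcome] += 1
    return {
        "n_queries": n,
        "counts": counts,
        "percent": {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()},
    }


def tree_outcomes_table(
    results: dict[Criteria, list[TreeIdentOutcome]]
) -> pd.DataFrame:
    rows = [
        {
            "query_id": o.query_id,
            "criteria": o.criteria,
            "outcome": o.outcome,
            "evidence": o.evidence,
        }
        for crit in ("hebert", "meier")
        for o in results.get(crit, [])
    ]
    return pd.DataFrame(rows, columns=["query_id", "criteria", "outcome", "evidence"])
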