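"""Synthetic labeled alignments with controlled divergence.

Generates multi-species aligned datasets with known ground truth so every
downstream stage (distances, gap, identification, trees) can be validated
without downloading any sequences.  The generative model:

* a species tree drawn from a Yule (pure-birth) process and rescaled to a
  chosen root-to-tip height (expected substitutions/site);
* within each species, a star genealogy: each specimen hangs off the
  species tip on its own terminal branch, with branch length drawn
  Exponential(mean = ``intra_height``).  Exponential depths (rather than a
  single fixed depth) give the intraspecific distances realistic spread,
  which is what allows designed *overlapping* (negative-gap) scenarios:
  with a fixed shared depth the expected minimum interspecific distance
  could never fall below the expected maximum intraspecific distance.
* sites evolve independently under the two-rate Kimura substitution
  process with transition/transversion rate ratio ``kappa``, using the
  exact closed-form transition probabilities per branch (no event-level
  simulation), from a root sequence drawn uniformly over {A,C,G,T}.

Everything is reproducible from ``seed``.  The generator emits the same
FASTA/TSV dialects that :mod:`barcodekit.seqio` reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from barcodekit.seqio import AlignedRecord

_BASES = "ACGT"
# Index layout: A=0, C=1, G=2, T=3.  Transitions: A<->G (0,2), C<->T (1,3).
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults mirror a small, well-separated barcoding study: a handful of
    congeneric species, a few specimens each, marker-length sequences, and
    intraspecific variation well below interspecific divergence
    (0.005 vs 0.20 expected substitutions/site, 1,000 sites).
    """

    n_species: int = 5
    n_per_species: int | tuple[int, ...] = 4
    seq_len: int = 1000
    species_tree_height: float = 0.20
    intra_height: float = 0.005
    kappa: float = 2.0
    seed: int = 0
    singleton_fraction: float = 0.0
    genus: str = "Genus"
    marker: str = "sim"

    def per_species_counts(self) -> list[int]:
        if isinstance(self.n_per_species, int):
            return [self.n_per_species] * self.n_species
        counts = list(self.n_per_species)
        if len(counts) != self.n_species:
            raise ValueError("n_per_species list length must equal n_species")
        return counts

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if any(c < 1 for c in self.per_species_counts()):
            raise ValueError("every species needs >= 1 sequence")
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.species_tree_height < 0 or self.intra_height < 0:
            raise ValueError("heights must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for a simulated dataset: labels, genealogy, path lengths."""

    labels: dict[str, str]
    genealogy_newick: str
    path_lengths: dict[frozenset[str], float]

    def path(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 0.0
        return self.path_lengths[frozenset((id_a, id_b))]


def k2p_rates(kappa: float) -> tuple[float, float]:
    """(alpha, beta): transition/transversion rates normalized to 1 sub/site.

    Total substitution rate per site is alpha + 2*beta = 1, so branch
    lengths are in expected substitutions per site; kappa = alpha/beta.
    """
    beta = 1.0 / (kappa + 2.0)
    return kappa * beta, beta


def k2p_transition_matrix(t: float, kappa: float) -> np.ndarray:
    """Exact 4x4 substitution probability matrix after branch length t."""
    alpha, beta = k2p_rates(kappa)
    e4 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4  # each of the two transversion targets
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    for i in range(4):
        P[i, _TRANSITION_PARTNER[i]] = p_ts
    return P


def _evolve(
    seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an encoded sequence along one branch, site-wise."""
    if t <= 0.0:
        return seq.copy()
    P = k2p_transition_matrix(t, kappa)
    cum = np.cumsum(P, axis=1)
    u = rng.random(seq.shape[0])
    # Inverse-CDF draw per site from its row of the transition matrix.
    out = (u[:, None] > cum[seq]).sum(axis=1)
    return out.astype(seq.dtype)


class _SimNode:
    """Minimal genealogy node: children with branch lengths to them."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[_SimNode] = []
        self.length = length  # branch length to parent

    def add(self, child: "_SimNode") -> None:
        self.children.append(child)

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.8f}"
        inner = ",".join(c.newick() for c in self.children)
        name = self.name or ""
        return f"({inner}){name}:{self.length:.8f}"


# Shallowest-split floor, as a fraction of tree height.  A raw Yule draw
# concentrates late splits near the present, so the most recent divergence
# can be arbitrarily small; that would decouple the between-species
# divergence from species_tree_height, which exists precisely to control
# it.  Draws violating the floor are rejected and redrawn from the same
# stream (deterministic given the seed).
MIN_SPLIT_FRACTION = 0.25
_MAX_TREE_REDRAWS = 10_000


def _yule_species_tree(
    n_species: int, height: float, rng: np.random.Generator
) -> tuple[_SimNode, dict[str, _SimNode]]:
    """Pure-birth species tree rescaled to root-to-tip height ``height``.

    Returns the root and a map species-name -> tip node.  All tips are
    contemporaneous (ultrametric).  Trees whose shallowest split is below
    ``MIN_SPLIT_FRACTION`` of the height are redrawn.
    """
    for _ in range(_MAX_TREE_REDRAWS):
        root, tip_map, min_split_frac = _draw_yule(n_species, height, rng)
        if min_split_frac >= MIN_SPLIT_FRACTION:
            return root, tip_map
    raise RuntimeError("could not draw a Yule tree satisfying the split floor")


def _draw_yule(
    n_species: int, height: float, rng: np.random.Generator
) -> tuple[_SimNode, dict[str, _SimNode], float]:
    root = _SimNode()
    if n_species == 1:
        tip = _SimNode(length=height)
        root.add(tip)
        return root, {"sp1": tip}, 1.0

    # Forward simulation with explicit split times: each active lineage
    # records its start time; at each exponential waiting time a uniformly
    # chosen lineage splits.
    start: dict[int, float] = {}
    tips: list[_SimNode] = []
    t_now = 0.0
    for _ in range(2):
        nd = _SimNode()
        root.add(nd)
        start[id(nd)] = 0.0
        tips.append(nd)
    while len(tips) < n_species:
        t_now += rng.exponential(1.0 / len(tips))
        parent = tips.pop(int(rng.integers(len(tips))))
        parent.length = t_now - start[id(parent)]
        for _ in range(2):
            child = _SimNode()
            parent.add(child)
            start[id(child)] = t_now
            tips.append(child)
    t_end = t_now + rng.exponential(1.0 / len(tips))
    for nd in tips:
        nd.length = t_end - start[id(nd)]
    # Shallowest split depth relative to height; t_now is the last split
    # time (0 for n=2, where the only split is the root).
    min_split_frac = (t_end - t_now) / t_end if t_end > 0 else 1.0

    scale = height / t_end if t_end > 0 else 0.0

    def rescale(node: _SimNode) -> None:
        node.length *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    tip_map = {}
    for k, nd in enumerate(tips):
        nd.name = f"sp{k+1}"
        tip_map[nd.name] = nd
    return root, tip_map, min_split_frac


def _depths(root: _SimNode) -> dict[int, float]:
    """Root-to-node path length for every node."""
    out: dict[int, float] = {}

    def walk(node: _SimNode, acc: float) -> None:
        out[id(node)] = acc
        for c in node.children:
            walk(c, acc + c.length)

    walk(root, 0.0)
    return out


def _path_lengths(root: _SimNode, leaves: dict[str, _SimNode]) -> dict[frozenset[str], float]:
    """Patristic distances between named leaves via ancestor chains."""
    depth = _depths(root)
    parent: dict[int, _SimNode] = {}

    def walk(node: _SimNode) -> None:
        for c in node.children:
            parent[id(c)] = node
            walk(c)

    walk(root)

    def ancestors(node: _SimNode) -> list[_SimNode]:
        chain = [node]
        while id(node) in parent:
            node = parent[id(node)]
            chain.append(node)
        return chain

    names = sorted(leaves)
    anc = {name: ancestors(leaves[name]) for name in names}
    anc_sets = {name: {id(a) for a in anc[name]} for name in names}
    out: dict[frozenset[str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            mrca = next(nd for nd in anc[a] if id(nd) in anc_sets[b])
            out[frozenset((a, b))] = (
                depth[id(leaves[a])] + depth[id(leaves[b])] - 2 * depth[id(mrca)]
            )
    return out


def simulate(config: SimConfig) -> tuple[list[AlignedRecord], SimTruth]:
    """Generate one labeled alignment plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.per_species_counts()

    # Apply the singleton fraction: the first round(f * n_species) species
    # are reduced to one specimen each (deterministic given the config).
    n_singletons = int(round(config.singleton_fraction * config.n_species))
    counts = [1 if k < n_singletons else counts[k] for k in range(config.n_species)]

    root, species_tips = _yule_species_tree(
        config.n_species, config.species_tree_height, rng
    )

    # Attach specimen tips: a star of exponential terminal branches per species.
    specimen_leaves: dict[str, _SimNode] = {}
    labels: dict[str, str] = {}
    for k, sp in enumerate(sorted(species_tips, key=lambda s: int(s[2:]))):
        tip = species_tips[sp]
        tip.name = None
        for m in range(counts[k]):
            sid = f"{sp}_{m+1}"
            length = (
                float(rng.exponential(config.intra_height))
                if config.intra_height > 0
                else 0.0
            )
            leaf = _SimNode(name=sid, length=length)
            tip.add(leaf)
            specimen_leaves[sid] = leaf
            labels[sid] = sp

    # Evolve sequences down the genealogy (preorder, depth-first in child
    # order, so the draw sequence is fixed by the seed).
    root_seq = rng.integers(0, 4, size=config.seq_len).astype(np.int64)
    seqs: dict[str, str] = {}

    def recurse(node: _SimNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve(seq, child.length, config.kappa, rng)
            if child.children:
                recurse(child, child_seq)
            else:
                seqs[child.name] = "".join(_BASES[b] for b in child_seq)

    recurse(root, root_seq)

    path_lengths = _path_lengths(root, specimen_leaves)
    sids = sorted(specimen_leaves)
    records = [
        AlignedRecord(
            id=sid,
            species=labels[sid],
            genus=config.genus,
            otu=labels[sid].upper(),
            seq=seqs[sid],
            marker=config.marker,
        )
        for sid in sids
    ]
    truth = SimTruth(
        labels=dict(labels),
        genealogy_newick=root.newick() + ";",
        path_lengths=path_lengths,
    )
    return records, truth


# Calibration of scenario_gap: the gap statistic is approximately
# 2 * (shallowest species split) - (realized max intra), with the
# shallowest split of a 5-species Yule tree of height H around H/3 and the
# realized maximum of intraspecific distances (sums of two exponential tip
# depths, maximized over ~30 pairs) around 4 * intra_height.
_SHALLOW_SPLIT_FRACTION = 1.0 / 3.0
_MAX_INTRA_FACTOR = 4.0


def scenario_gap(
    width: float,
    intra_height: float = 0.005,
    seed: int = 0,
    singleton_fraction: float = 0.0,
) -> SimConfig:
    """Config whose expected barcoding gap is approximately ``width``.

    Negative widths design overlapping intra/inter distance distributions.
    """
    target_min_inter = width + _MAX_INTRA_FACTOR * intra_height
    height = max(target_min_inter / (2.0 * _SHALLOW_SPLIT_FRACTION), 1e-4)
    return SimConfig(
        n_species=5,
        n_per_species=4,
        seq_len=1000,
        species_tree_height=height,
        intra_height=intra_height,
        kappa=2.0,
        seed=seed,
        singleton_fraction=singleton_fraction,
    )
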