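"""Haplogroup assignment by Kulczynski set overlap against a reduced tree.

Each tree node is defined by the variants accumulated on its root-to-node
path.  A sample's filtered SNV set (restricted to positions that are
informative anywhere in the tree, so private variants do not dilute the
score) is compared to every node's cumulative set with the Kulczynski
measure

    score = 0.5 * (|S n E| / |E| + |S n E| / |S|)

and the best-scoring node wins (ties: deeper node, then lexicographic name).
Calls with confidence <= 0.5 are discarded, the regime typical of samples
presenting fewer than ~40 variants at this coverage.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .variants import SNV, MtVariant, VariantKey


@dataclass
class HaploNode:
    name: str
    parent: str | None
    variants: frozenset[tuple[int, str]]  # (pos, alt) defining this node
    depth: int = 0
    cumulative: frozenset[tuple[int, str]] = frozenset()


@dataclass
class HaploTree:
    """Rooted haplogroup tree with cached root-to-node cumulative variant sets."""

    nodes: dict[str, HaploNode]
    root: str
    informative_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.informative_positions = frozenset(
            pos for n in self.nodes.values() for pos, _ in n.variants
        )

    def cumulative(self, name: str) -> frozenset[tuple[int, str]]:
        if name not in self.nodes:
            raise KeyError(f"unknown haplogroup {name!r}")
        return self.nodes[name].cumulative


@dataclass
class HaplogroupCall:
    sample_id: str
    best_haplogroup: str
    confidence: float
    superclade: str
    n_sample_variants: int
    discarded: bool


def load_tree(path: str | Path) -> HaploTree:
    """Parse the TSV tree schema (name, parent, comma-separated POS+ALT tokens)."""
    raw: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            name = parts[0]
            parent = parts[1] if len(parts) > 1 else ""
            tokens = parts[2].split(",") if len(parts) > 2 and parts[2] else []
            variants = frozenset((int(t[:-1]), t[-1]) for t in tokens)
            if name in raw:
                raise ValueError(f"duplicate node {name!r}")
            raw[name] = (parent, variants)
    roots = [n for n, (p, _) in raw.items() if not p]
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {roots}")
    root = roots[0]
    nodes: dict[str, HaploNode] = {}

    def build(name: str, seen: tuple[str, ...]) -> HaploNode:
        if name in seen:
            raise ValueError(f"cycle in tree at {name!r}")
        if name in nodes:
            return nodes[name]
        parent, variants = raw[name]
        if parent:
            if parent not in raw:
                raise ValueError(f"node {name!r} references missing parent {parent!r}")
            pnode = build(parent, seen + (name,))
            node = HaploNode(name, parent, variants, pnode.depth + 1, pnode.cumulative | variants)
        else:
            node = HaploNode(name, None, variants, 0, frozenset(variants))
        nodes[name] = node
        return node

    for name in raw:
        build(name, ())
    return HaploTree(nodes=nodes, root=root)


def packaged_tree() -> HaploTree:
    """The packaged synthetic reduced haplogroup tree."""
    with importlib.resources.as_file(
        importlib.resources.files("cfmito") / "data" / "haplogroup_tree_synthetic.tsv"
    ) as p:
        return load_tree(p)


def _sample_set(variants, tree: HaploTree) -> set[tuple[int, str]]:
    """Sample SNVs restricted to tree-informative positions, as (pos, alt) pairs."""
    pairs = set()
    for v in variants:
        key = v.key if isinstance(v, MtVariant) else v
        if key.vtype == SNV and key.pos in tree.informative_positions:
            pairs.add((key.pos, key.alt))
    return pairs


def score_node(sample_pairs: set[tuple[int, str]], node_cumulative: frozenset) -> float:
    """Kulczynski similarity between a sample set and a node's cumulative set."""
    if not node_cumulative:
        raise ValueError("node cumulative variant set is empty")
    if not sample_pairs:
        warnings.warn("sample has no tree-informative variants; score is 0", stacklevel=2)
        return 0.0
    overlap = len(sample_pairs & node_cumulative)
    return 0.5 * (overlap / len(node_cumulative) + overlap / len(sample_pairs))


def collapse_to_superclade(name: str) -> str:
    """Leading clade letter of a haplogroup name: H1c4b -> H, J1c2 -> J."""
    if not name:
        raise ValueError("empty haplogroup name")
    if not name[0].isalpha():
        raise ValueError(f"haplogroup name {name!r} does not start with a clade letter")
    return name[0].upper()


def assign_haplogroup(
    sample_variants,
    tree: HaploTree,
    sample_id: str = "",
    discard_threshold: float = 0.5,
) -> HaplogroupCall:
    """Best-scoring haplogroup for a sample's filtered variant set.

    ``sample_variants`` may be :class:`MtVariant` objects or
    :class:`VariantKey` tuples.  Calls scoring <= ``discard_threshold`` are
    flagged as discarded.
    """
    scorable = [n for n in tree.nodes.values() if n.cumulative]
    if not scorable:
        raise ValueError("tree has no scorable nodes")
    sample_variants = list(sample_variants)
    pairs = _sample_set(sample_variants, tree)
    if pairs:
        best = max(scorable, key=lambda n: (score_node(pairs, n.cumulative), n.depth, [-ord(c) for c in n.name]))
        confidence = score_node(pairs, best.cumulative)
        name = best.name
    else:
        confidence, name = 0.0, tree.root
    return HaplogroupCall(
        sample_id=sample_id,
        best_haplogroup=name,
        confidence=confidence,
        superclade=collapse_to_superclade(name) if pairs else "",
        n_sample_variants=len(sample_variants),
        discarded=confidence <= discard_threshold,
    )
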