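"""Motif-based haplogroup classification and frequency tabulation.

A haplogroup is a clade of the mtDNA tree defined by a motif of diagnostic
variants relative to the rCRS.  Classification here is best-match scoring of
a haplotype against the cumulative motif of every node of a user-supplied
tree: the score of a node is

    matched motif variants  -  lambda * missing motif variants,

where a motif variant is *matched* when the sample carries a variant at the
same (position, insert index, kind) key with a compatible allele state, and
*missing* when it does not.  Motif sites in regions the sample was never
typed for (in practice: coding-region sites of samples without coding data)
are skipped entirely -- unobserved is not absent.  The deepest node wins
among equal scores on one ancestral path, but only when it actually matches
more motif variants than its ancestor; equal-scoring nodes on different
paths are reported as ties, never silently broken.

The packaged tree (``data/motif_tree.tsv``) is rooted at H* because the rCRS
itself belongs to haplogroup H2: a reference-like haplotype carries no
diagnostic variants and stays at the root.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .notation import (
    CODING,
    REGIONS,
    DistancePolicy,
    Haplotype,
    Variant,
    parse_region_string,
)

__all__ = [
    "HaplogroupNode",
    "MotifTree",
    "Assignment",
    "FrequencyTable",
    "DEFAULT_LAMBDA",
    "load_motif_tree",
    "load_default_tree",
    "classify",
    "classify_all",
    "macro_pool",
    "l_branch",
    "tabulate",
]

#: Penalty per missing (observed-region) motif variant.  Chosen below 1 so a
#: haplotype matching most of a deep motif still beats shallow generic nodes,
#: but above 1/2 so two missing diagnostics cost more than one extra match.
DEFAULT_LAMBDA = 0.75


@dataclass(frozen=True)
class HaplogroupNode:
    """One named clade with the motif variants added on its parent edge."""

    name: str
    parent: str | None
    motif: Mapping[str, frozenset[Variant]]

    def motif_items(self) -> Iterable[tuple[str, Variant]]:
        for region, variants in self.motif.items():
            for v in variants:
                yield region, v


class MotifTree:
    """A rooted tree of :class:`HaplogroupNode` with cumulative motifs."""

    def __init__(self, nodes: Sequence[HaplogroupNode]):
        if not nodes:
            raise ValueError("empty motif tree")
        self.nodes: dict[str, HaplogroupNode] = {}
        for n in nodes:
            if n.name in self.nodes:
                raise ValueError(f"duplicate haplogroup name {n.name!r}")
            self.nodes[n.name] = n
        roots = [n.name for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for n in nodes:
            if n.parent is not None and n.parent not in self.nodes:
                raise ValueError(f"node {n.name!r} has unknown parent {n.parent!r}")
        # precompute depth and cumulative motifs
        self.depth: dict[str, int] = {}
        self.cumulative: dict[str, list[tuple[str, Variant]]] = {}
        for name in self.nodes:
            path = self.path_to_root(name)
            self.depth[name] = len(path) - 1
            cum: dict[tuple, tuple[str, Variant]] = {}
            for anc in reversed(path):  # root first; children override ancestors
                for region, v in self.nodes[anc].motif_items():
                    cum[(region, v.key)] = (region, v)
            self.cumulative[name] = list(cum.values())

    def path_to_root(self, name: str) -> list[str]:
        path = [name]
        seen = {name}
        while (p := self.nodes[path[-1]].parent) is not None:
            if p in seen:
                raise ValueError(f"cycle in motif tree at {p!r}")
            path.append(p)
            seen.add(p)
        return path

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is an ancestor of ``b`` (or equal)."""
        return a in self.path_to_root(b)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def load_motif_tree(path_or_lines) -> MotifTree:
    """Read a motif tree from TSV: name, parent, HVRI, HVRII, CODING tokens."""
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines, newline="") as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    rdr = csv.DictReader((l for l in lines if not l.startswith("#")), delimiter="\t")
    nodes = []
    for row in rdr:
        motif = {}
        for region in REGIONS:
            text = (row.get(region) or "").strip()
            if text:
                motif[region] = parse_region_string(text, region)
        parent = (row.get("parent") or "").strip() or None
        nodes.append(HaplogroupNode(row["name"].strip(), parent, motif))
    return MotifTree(nodes)


def load_default_tree() -> MotifTree:
    """The packaged minimal tree covering the El Jadida haplogroups."""
    raw = resources.files("mthaplopop.data").joinpath("motif_tree.tsv").read_text()
    return load_motif_tree(raw.splitlines(keepends=True))


@dataclass(frozen=True)
class Assignment:
    """Result of classifying one sample."""

    sample_id: str
    best_node: str
    score: float
    matched: int
    mismatches: int
    ties: tuple[str, ...] = ()


def _motif_matches(sample_state: frozenset | None, motif: Variant) -> bool:
    if sample_state is None:
        return False
    ms = motif.state
    if not ms and not sample_state:
        return True  # both bare transitions
    return bool(ms & sample_state) or ms == sample_state


def _node_score(
    h: Haplotype, tree: MotifTree, name: str, lam: float
) -> tuple[float, int, int]:
    matched = missing = 0
    sample: dict[tuple[str, tuple], frozenset] = {}
    for region in REGIONS:
        for v in h.variants(region):
            sample[(region, v.key)] = v.state
    for region, mv in tree.cumulative[name]:
        if not h.is_typed(region):
            continue  # unobserved region: neither evidence for nor against
        if _motif_matches(sample.get((region, mv.key)), mv):
            matched += 1
        else:
            missing += 1
    return matched - lam * missing, matched, missing


def classify(
    h: Haplotype,
    tree: MotifTree | None = None,
    policy: DistancePolicy | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> Assignment:
    """Assign a haplotype to its best-matching haplogroup node.

    ``policy`` is accepted for interface symmetry with the distance-based
    operations; motif scoring itself uses all typed variants of the sample.
    """
    tree = tree or load_default_tree()
    scores = {name: _node_score(h, tree, name, lam) for name in tree.nodes}
    best_score = max(s for s, _, _ in scores.values())
    candidates = [n for n, (s, _, _) in scores.items() if s == best_score]

    # Along one ancestral path, depth only wins with strictly more matches:
    # a descendant whose extra motif sites were all unobserved adds nothing.
    drop = set()
    for a in candidates:
        for b in candidates:
            if a == b or a in drop or b in drop:
                continue
            if tree.is_ancestor(a, b):
                if scores[b][1] > scores[a][1]:
                    drop.add(a)
                else:
                    drop.add(b)
    final = sorted(
        (n for n in candidates if n not in drop),
        key=lambda n: (-scores[n][1], -tree.depth[n], n),
    )
    best = final[0]
    return Assignment(
        sample_id=h.sample_id,
        best_node=best,
        score=best_score,
        matched=scores[best][1],
        mismatches=scores[best][2],
        ties=tuple(n for n in final[1:]),
    )


def classify_all(
    haplotypes: Sequence[Haplotype],
    tree: MotifTree | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> list[Assignment]:
    tree = tree or load_default_tree()
    return [classify(h, tree, lam=lam) for h in haplotypes]


# ---------------------------------------------------------------------------
# Frequency tabulation
# ---------------------------------------------------------------------------

def macro_pool(label: str) -> str:
    """Macro-pool of a haplogroup label: sub-Saharan ``L`` vs West Eurasian."""
    return "L" if label.upper().startswith("L") else "West Eurasian"


def l_branch(label: str) -> str | None:
    """The L0..L6 branch of a label, or None for non-L haplogroups."""
    u = label.upper()
    if u.startswith("L") and len(u) >= 2 and u[1].isdigit():
        return u[:2]
    return None


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and proportions of haplogroup labels over a stated denominator."""

    grouping: str
    counts: Mapping[str, int]
    denominator: int

    @property
    def proportions(self) -> dict[str, float]:
        return {k: c / self.denominator for k, c in self.counts.items()}

    def percent(self, label: str) -> float:
        return 100.0 * self.counts.get(label, 0) / self.denominator


def tabulate(
    assignments: Sequence[Assignment], grouping: str = "total-population"
) -> FrequencyTable:
    """Tabulate haplogroup frequencies.

    ``grouping="total-population"`` counts every assigned label over the full
    sample; ``"macro"`` collapses labels into the L / West Eurasian pools;
    ``"within-L-pool"`` restricts to L samples and counts their L0..L6
    branches over the L-pool total.
    """
    if not assignments:
        raise ValueError("no assignments to tabulate")
    labels = [a.best_node for a in assignments]
    if grouping == "total-population":
        keys = labels
        denom = len(labels)
    elif grouping == "macro":
        keys = [macro_pool(l) for l in labels]
        denom = len(labels)
    elif grouping == "within-L-pool":
        keys = [b for b in (l_branch(l) for l in labels) if b is not None]
        denom = len(keys)
        if denom == 0:
            raise ValueError("no L-pool samples to tabulate")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return FrequencyTable(grouping=grouping, counts=dict(sorted(counts.items())), denominator=denom)
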