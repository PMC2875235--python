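"""Rho-statistic founder ages for mutation-annotated clades.

The rho statistic is the average number of mutations separating the
ancestral haplotype of a clade from each of its sampled tips.  Multiplied
by a clock calibration (years per mutation; 3624 for the whole molecule
under the calibration used here) it estimates the age of the clade's most
recent common ancestor.  The standard error follows the branch-weighted
Poisson variance: for branches b with n_b descendant tips and l_b
mutations, ``sigma^2 = sum_b (n_b / N)^2 l_b``, which reduces to
``sqrt(sum counts) / N`` on a star phylogeny.

A haplotype shared by several samples can either contribute its terminal
mutations once per carrier or once in total ("counted as one event if
shared by a few samples"); both modes are exposed via ``shared_tips_once``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "CladeCluster",
    "ClockCalibration",
    "rho",
    "sigma",
    "age",
    "read_cluster_tsv",
    "cluster_from_newick",
]


@dataclass(frozen=True)
class ClockCalibration:
    """Linear molecular-clock calibration in years per mutation."""

    years_per_mutation: float = 3624.0
    label: str = "whole-molecule, 1 mutation per 3624 years"

    def __post_init__(self) -> None:
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")


@dataclass(frozen=True)
class CladeCluster:
    """A clade with per-tip mutation counts from the cluster root.

    ``tips`` holds (tip id, mutation count from the root, multiplicity);
    ``branches`` optionally holds (descendant-tip count, length in
    mutations) for every branch of the within-cluster tree, enabling the
    non-star standard error.
    """

    name: str
    tips: tuple[tuple[str, int, int], ...]
    branches: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.tips:
            raise ValueError(f"cluster {self.name!r} has no tips")
        for tid, count, mult in self.tips:
            if count < 0 or mult < 1:
                raise ValueError(f"bad tip ({tid}, {count}, {mult})")
        if self.branches is not None:
            total_branch = sum(nb * lb for nb, lb in self.branches)
            total_tip = sum(c * m for _, c, m in self.tips)
            if total_branch != total_tip:
                raise ValueError(
                    f"branch bookkeeping inconsistent: sum n_b*l_b = {total_branch} "
                    f"but sum tip count*multiplicity = {total_tip}"
                )

    @property
    def n_tips(self) -> int:
        return sum(m for _, _, m in self.tips)


def rho(cluster: CladeCluster, shared_tips_once: bool = False) -> float:
    """Average mutation count from the cluster root to its tips.

    With ``shared_tips_once`` a haplotype shared by several samples
    contributes its mutations once while its carriers still enlarge N.
    """
    if shared_tips_once:
        total = sum(c for _, c, _ in cluster.tips)
    else:
        total = sum(c * m for _, c, m in cluster.tips)
    return total / cluster.n_tips


def sigma(cluster: CladeCluster, star: bool = True) -> float:
    """Standard error of rho from branch-weighted Poisson variance.

    ``sigma = sqrt(sum_b (n_b/N)^2 l_b)`` over the within-cluster branches;
    under a star phylogeny every tip is its own branch and this is
    ``sqrt(sum counts) / N``.
    """
    n = cluster.n_tips
    if cluster.branches is not None:
        var = sum((nb / n) ** 2 * lb for nb, lb in cluster.branches)
    elif star:
        var = sum(c * m for _, c, m in cluster.tips) / n**2
    else:
        raise ValueError(
            f"cluster {cluster.name!r} has no branch data and the star "
            "assumption is disabled"
        )
    return math.sqrt(var)


def age(
    rho_value: float, sigma_value: float, cal: ClockCalibration | None = None
) -> tuple[float, float]:
    """Clade age and its standard deviation in years, ``rho * calibration``."""
    cal = cal or ClockCalibration()
    return rho_value * cal.years_per_mutation, sigma_value * cal.years_per_mutation


def read_cluster_tsv(path, name: str | None = None) -> CladeCluster:
    """Read a cluster from TSV columns: tip_id, mutations, multiplicity."""
    path = Path(path)
    tips = []
    with open(path, newline="") as fh:
        rdr = csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        for row in rdr:
            tips.append(
                (
                    row["tip_id"],
                    int(row["mutations"]),
                    int(row.get("multiplicity", 1) or 1),
                )
            )
    return CladeCluster(name=name or path.stem, tips=tuple(tips))


def cluster_from_newick(newick: str, name: str = "newick-clade") -> CladeCluster:
    """Build a cluster from a newick tree whose branch lengths are mutation counts.

    Tip mutation counts are root-to-tip path sums; branch bookkeeping for the
    non-star standard error is taken from the tree's internal structure.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tips = []
    branches = []
    for leaf in tree.leaf_node_iter():
        count = 0
        node = leaf
        while node.parent_node is not None:
            count += int(round(node.edge.length or 0))
            node = node.parent_node
        tips.append((leaf.taxon.label if leaf.taxon else f"t{len(tips)+1}", count, 1))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or not edge.length:
            continue
        n_desc = sum(1 for _ in edge.head_node.leaf_iter())
        branches.append((n_desc, int(round(edge.length))))
    return CladeCluster(name=name, tips=tuple(tips), branches=tuple(branches))
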