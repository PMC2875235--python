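"""Synthetic data generators with the statistical structure the analyses assume.

Three families of generators:

* standard neutral (constant-size) coalescent haplotype samples under the
  infinite-sites model, with mutations placed either conditional on a fixed
  number of segregating sites S (multinomially on branches by length -- the
  conditioning used for neutrality-test p-values) or with a fixed scaled
  mutation rate theta (Poisson per branch, E[MPD] = theta);
* mutation-annotated clades of known true age for validating the rho clock:
  per-branch mutation counts are Poisson with mean branch-time divided by
  the calibration (years per mutation);
* clinal (or flat) haplogroup-frequency surfaces over a geographic grid,
  and single haplotypes sampled from a motif-tree node for classifier
  recall checks.

All generators are deterministic given a seed or Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .notation import (
    HVRI,
    Haplotype,
    Variant,
)
from .rho_clock import CladeCluster, ClockCalibration
from .geospatial import GeoPoint

__all__ = [
    "SimConfig",
    "coalescent_branches",
    "simulate_coalescent_counts",
    "simulate_coalescent_sample",
    "simulate_clade",
    "generate_clinal_populations",
    "sample_from_motif",
]

DEFAULT_WINDOW = (16024, 16365)


@dataclass(frozen=True)
class SimConfig:
    """Bundle of generator settings for the command-line ``simulate`` stage."""

    seed: int = 0
    n_samples: int = 50
    theta: float | None = 5.0
    fixed_S: int | None = None
    window: tuple[int, int] = DEFAULT_WINDOW
    clade_tips: int = 20
    clade_age_years: float = 10_000.0
    years_per_mutation: float = 3624.0
    grid_shape: tuple[int, int] = (6, 6)
    gradient: tuple[float, float] = (-0.015, 0.0)
    noise_sd: float = 0.05


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def coalescent_branches(n: int, rng) -> list[tuple[frozenset, float]]:
    """Branches of one Kingman coalescent genealogy of n tips.

    Returns (tip set, branch length) pairs in coalescent time units (2N
    generations).  While k lineages remain, the waiting time to the next
    coalescence is exponential with rate k(k-1)/2, and the joining pair is
    uniform.
    """
    rng = _rng(rng)
    if n < 2:
        raise ValueError("need n >= 2 tips")
    active: list[frozenset] = [frozenset([i]) for i in range(n)]
    elapsed = {fs: 0.0 for fs in active}
    branches: list[tuple[frozenset, float]] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        for fs in active:
            elapsed[fs] += t
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        branches.append((a, elapsed.pop(a)))
        branches.append((b, elapsed.pop(b)))
        merged = a | b
        active = [fs for fs in active if fs not in (a, b)] + [merged]
        elapsed[merged] = 0.0
        k -= 1
    return branches


def _mutation_carrier_sets(n: int, S: int | None, theta: float | None, rng) -> list[frozenset]:
    """Tip sets carrying each mutation, under fixed-S or fixed-theta placement."""
    rng = _rng(rng)
    branches = coalescent_branches(n, rng)
    lengths = np.array([l for _, l in branches])
    carriers: list[frozenset] = []
    if S is not None:
        if S < 0:
            raise ValueError("S must be >= 0")
        if S > 0:
            total = lengths.sum()
            counts = rng.multinomial(S, lengths / total)
            for (tips, _), c in zip(branches, counts):
                carriers.extend([tips] * int(c))
    elif theta is not None:
        if theta < 0:
            raise ValueError("theta must be >= 0")
        # theta = 2 N mu for the whole window; mutation rate theta/2 per
        # branch per coalescent time unit gives E[MPD] = theta.
        for tips, l in branches:
            carriers.extend([tips] * int(rng.poisson(theta / 2.0 * l)))
    else:
        raise ValueError("specify either fixed S or theta")
    return carriers


def simulate_coalescent_counts(
    n: int, S: int | None = None, theta: float | None = None, rng=0
) -> tuple[float, int]:
    """Fast path for null distributions: (MPD, distinct-haplotype count).

    Under infinite sites a mutation carried by c of n tips contributes
    c(n-c) differing pairs, so MPD needs no explicit haplotypes.
    """
    carriers = _mutation_carrier_sets(n, S, theta, rng)
    npairs = n * (n - 1) / 2
    mpd = sum(len(c) * (n - len(c)) for c in carriers) / npairs
    sigs: dict[int, list[int]] = {i: [] for i in range(n)}
    for m, tips in enumerate(carriers):
        for t in tips:
            sigs[t].append(m)
    k = len({tuple(v) for v in sigs.values()})
    return mpd, k


def simulate_coalescent_sample(
    n: int,
    S: int | None = None,
    theta: float | None = None,
    seed=0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    population: str = "sim",
) -> list[Haplotype]:
    """A neutral coalescent sample rendered as control-region haplotypes.

    Each mutation is a transition at a distinct position drawn uniformly
    from the window (collisions redrawn, keeping S interpretable); output
    haplotypes parse and render in the same dialect as the population
    tables.
    """
    rng = _rng(seed)
    carriers = _mutation_carrier_sets(n, S, theta, rng)
    lo, hi = window
    n_sites = hi - lo + 1
    if len(carriers) > n_sites:
        raise ValueError(f"{len(carriers)} mutations exceed window of {n_sites} sites")
    positions: list[int] = []
    used: set[int] = set()
    while len(positions) < len(carriers):
        p = int(rng.integers(lo, hi + 1))
        if p not in used:
            used.add(p)
            positions.append(p)
    per_tip: dict[int, set[Variant]] = {i: set() for i in range(n)}
    for pos, tips in zip(positions, carriers):
        v = Variant(pos)
        for t in tips:
            per_tip[t].add(v)
    return [
        Haplotype(
            sample_id=f"{population}{i + 1}",
            region_variants={HVRI: frozenset(per_tip[i])},
            population=population,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Clades of known age for the rho clock
# ---------------------------------------------------------------------------

def simulate_clade(
    n_tips: int,
    true_age_years: float,
    cal: ClockCalibration | None = None,
    topology: str = "star",
    seed=0,
    name: str = "sim-clade",
) -> CladeCluster:
    """A mutation-annotated clade whose root is ``true_age_years`` old.

    ``topology="star"`` hangs every tip directly from the root;
    ``"random"`` draws a Kingman topology rescaled so the root sits at the
    true age.  Mutation counts per branch are Poisson with mean
    branch-time / years-per-mutation, so the rho estimator is unbiased for
    the true age by construction.
    """
    cal = cal or ClockCalibration()
    rng = _rng(seed)
    if true_age_years < 0:
        raise ValueError("true_age_years must be >= 0")
    rate = 1.0 / cal.years_per_mutation
    if topology == "star":
        counts = rng.poisson(true_age_years * rate, size=n_tips)
        tips = [(f"t{i + 1}", int(c), 1) for i, c in enumerate(counts)]
        branches = [(1, int(c)) for c in counts]
    elif topology == "random":
        if n_tips < 2:
            raise ValueError("random topology needs >= 2 tips")
        raw = coalescent_branches(n_tips, rng)
        depth = {}
        for i in range(n_tips):
            depth[i] = sum(l for tips_, l in raw if i in tips_)
        # every tip's root-to-tip time equals the tree height; rescale it to
        # the requested age (the coalescent tree is ultrametric)
        height = depth[0]
        scale = true_age_years / height if height > 0 else 0.0
        branch_mut = [
            (tips_, int(rng.poisson(l * scale * rate))) for tips_, l in raw
        ]
        tip_counts = {i: 0 for i in range(n_tips)}
        for tips_, m in branch_mut:
            for t in tips_:
                tip_counts[t] += m
        tips = [(f"t{i + 1}", tip_counts[i], 1) for i in range(n_tips)]
        branches = [(len(tips_), m) for tips_, m in branch_mut]
    else:
        raise ValueError("topology must be 'star' or 'random'")
    return CladeCluster(name=name, tips=tuple(tips), branches=tuple(branches))


# ---------------------------------------------------------------------------
# Spatial surfaces and motif sampling
# ---------------------------------------------------------------------------

def generate_clinal_populations(
    lat_range: tuple[float, float] = (0.0, 35.0),
    lon_range: tuple[float, float] = (-15.0, 40.0),
    grid_shape: tuple[int, int] = (6, 6),
    intercept: float = 0.8,
    gradient: tuple[float, float] = (-0.02, 0.0),
    noise_sd: float = 0.05,
    seed=0,
) -> list[GeoPoint]:
    """Populations on a lat/lon grid with a linear frequency cline plus noise.

    The value at (lat, lon) is
    ``clip(intercept + g_lat (lat - lat0) + g_lon (lon - lon0) + N(0, sd))``
    measured from the grid's south-west corner; frequencies are clipped to
    [0, 1].
    """
    rng = _rng(seed)
    lats = np.linspace(*lat_range, grid_shape[0])
    lons = np.linspace(*lon_range, grid_shape[1])
    g_lat, g_lon = gradient
    out = []
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            v = (
                intercept
                + g_lat * (la - lat_range[0])
                + g_lon * (lo - lon_range[0])
                + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            )
            out.append(
                GeoPoint(
                    population=f"pop_{i}_{j}",
                    lat=float(la),
                    lon=float(lo),
                    value=float(np.clip(v, 0.0, 1.0)),
                )
            )
    return out


def sample_from_motif(
    tree,
    node: str,
    n_extra_mutations: int = 0,
    seed=0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    sample_id: str | None = None,
) -> Haplotype:
    """A haplotype carrying a node's cumulative motif plus random noise.

    Extra mutations are transitions at positions inside the window not
    already used by the motif; with zero extra noise the haplotype is the
    motif itself and must classify to the node (or an ancestor).
    """
    rng = _rng(seed)
    if node not in tree:
        raise KeyError(f"no node {node!r} in motif tree")
    regions: dict[str, set[Variant]] = {}
    for region, v in tree.cumulative[node]:
        regions.setdefault(region, set()).add(v)
    lo, hi = window
    used = {v.position for vs in regions.values() for v in vs}
    extra = regions.setdefault(HVRI, set())
    while n_extra_mutations > 0:
        p = int(rng.integers(lo, hi + 1))
        if p not in used:
            used.add(p)
            extra.add(Variant(p))
            n_extra_mutations -= 1
    return Haplotype(
        sample_id=sample_id or f"motif-{node}",
        region_variants={r: frozenset(vs) for r, vs in regions.items()},
        haplogroup_label=node,
    )
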