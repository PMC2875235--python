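"""Distance-based analysis of molecular variance (AMOVA) and Phi_ST.

A two-level AMOVA partitions the total sum of squared pairwise distances
between haplotypes into among-population and within-population variance
components (sigma_a^2, sigma_w^2).  With squared pairwise-difference
distances (the conventional choice for sequence haplotypes), the
among-population fraction sigma_a^2 / (sigma_a^2 + sigma_w^2) is the
Phi_ST fixation index.  Significance comes from permuting individuals
among populations; Bonferroni correction adjusts for multiple pairwise
comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .notation import HVRI, DistancePolicy, Haplotype, distance_matrix

__all__ = [
    "AmovaComponents",
    "StructureResult",
    "amova_from_distances",
    "amova",
    "pairwise_phist",
    "permutation_test",
    "bonferroni",
    "population_structure",
]


@dataclass(frozen=True)
class AmovaComponents:
    """Variance components of a two-level AMOVA."""

    sigma2_among: float
    sigma2_within: float
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    n_total: int
    n_populations: int

    @property
    def percent_among(self) -> float:
        """Among-population percentage; a negative component counts as zero."""
        sa = max(self.sigma2_among, 0.0)
        total = sa + self.sigma2_within
        return 100.0 * sa / total if total > 0 else 0.0

    @property
    def phi_st(self) -> float:
        total = self.sigma2_among + self.sigma2_within
        return self.sigma2_among / total if total > 0 else 0.0

    @property
    def negative_component(self) -> bool:
        return self.sigma2_among < 0


def _squared_distance_matrix(
    populations: Sequence[Sequence[Haplotype]],
    policy: DistancePolicy | None,
    region: str,
) -> tuple[np.ndarray, list[int]]:
    pooled = [h for pop in populations for h in pop]
    sizes = [len(pop) for pop in populations]
    policy = (policy or DistancePolicy()).for_dataset(pooled, region)
    d = distance_matrix(pooled, policy, region).astype(float)
    return d**2, sizes


def amova_from_distances(d2: np.ndarray, sizes: Sequence[int]) -> AmovaComponents:
    """Two-level AMOVA from a pooled squared-distance matrix.

    ``sizes`` gives the number of individuals per population, in the order
    the pooled matrix was assembled.
    """
    sizes = [s for s in sizes]
    n = int(sum(sizes))
    p = len(sizes)
    if p < 2:
        raise ValueError("AMOVA needs at least two populations")
    if d2.shape != (n, n):
        raise ValueError("distance matrix does not match population sizes")
    # SSD(total) = (1/n) * sum_{i<j} d2_ij ; SSD(within) analogous per group
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    start = 0
    for s in sizes:
        block = d2[start : start + s, start : start + s]
        bu = np.triu_indices(s, k=1)
        if s > 0:
            ss_within += float(block[bu].sum()) / s
        start += s
    ss_among = ss_total - ss_within
    df_among = p - 1
    df_within = n - p
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    # average sample size correcting for unequal n
    n_c = (n - sum(s * s for s in sizes) / n) / df_among
    sigma_w = ms_within
    sigma_a = (ms_among - sigma_w) / n_c if n_c > 0 else 0.0
    return AmovaComponents(
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        n_total=n,
        n_populations=p,
    )


def amova(
    populations: Sequence[Sequence[Haplotype]],
    policy: DistancePolicy | None = None,
    region: str = HVRI,
) -> AmovaComponents:
    """Two-level AMOVA over haplotype populations (squared differences).

    Populations of fewer than two samples carry no within-group information
    and are excluded with a warning.
    """
    kept = []
    for i, pop in enumerate(populations):
        if len(pop) < 2:
            warnings.warn(f"population {i} has <2 samples; excluded from AMOVA", stacklevel=2)
        else:
            kept.append(pop)
    d2, sizes = _squared_distance_matrix(kept, policy, region)
    return amova_from_distances(d2, sizes)


def pairwise_phist(
    pop_a: Sequence[Haplotype],
    pop_b: Sequence[Haplotype],
    policy: DistancePolicy | None = None,
    region: str = HVRI,
) -> float:
    """Phi_ST between two populations from the two-level AMOVA decomposition."""
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 samples")
    d2, sizes = _squared_distance_matrix([pop_a, pop_b], policy, region)
    if not d2.any():
        warnings.warn("all sequences identical; Phi_ST defined as 0", stacklevel=2)
        return 0.0
    return amova_from_distances(d2, sizes).phi_st


def permutation_test(
    pop_a: Sequence[Haplotype],
    pop_b: Sequence[Haplotype],
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    policy: DistancePolicy | None = None,
    region: str = HVRI,
) -> tuple[float, float, float]:
    """Permutation p-value for the pairwise Phi_ST.

    Individuals are shuffled among the two populations; p is the fraction
    of permutations with Phi_ST at least as large as observed, with
    binomial standard error sqrt(p(1-p)/reps).

    Returns (phi_st_observed, p, se).
    """
    if reps < 100:
        raise ValueError("use at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2, sizes = _squared_distance_matrix([pop_a, pop_b], policy, region)
    if not d2.any():
        return 0.0, 1.0, 0.0
    obs = amova_from_distances(d2, sizes).phi_st
    n = sum(sizes)
    count = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        d2p = d2[np.ix_(perm, perm)]
        if amova_from_distances(d2p, sizes).phi_st >= obs:
            count += 1
    p = count / reps
    return obs, p, math.sqrt(p * (1.0 - p) / reps)


def bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Significance flags after Bonferroni correction: p < alpha / m."""
    m = len(pvalues)
    if m == 0:
        return []
    return [p < alpha / m for p in pvalues]


@dataclass(frozen=True)
class StructureResult:
    """Global AMOVA plus the pairwise Phi_ST matrix with permutation tests."""

    components: AmovaComponents
    population_names: tuple[str, ...]
    phi_st: np.ndarray
    p_values: np.ndarray
    p_se: np.ndarray
    bonferroni_alpha: float
    significant: np.ndarray


def population_structure(
    populations: dict[str, Sequence[Haplotype]],
    policy: DistancePolicy | None = None,
    region: str = HVRI,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> StructureResult:
    """Global AMOVA and all pairwise Phi_ST with Bonferroni-corrected tests."""
    names = tuple(populations)
    pops = [list(populations[n]) for n in names]
    comp = amova(pops, policy, region)
    k = len(names)
    phi = np.zeros((k, k))
    pv = np.full((k, k), np.nan)
    pse = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    flat_p = []
    for i, j in pairs:
        obs, p, se = permutation_test(pops[i], pops[j], reps=reps, seed=rng, policy=policy, region=region)
        phi[i, j] = phi[j, i] = obs
        pv[i, j] = pv[j, i] = p
        pse[i, j] = pse[j, i] = se
        flat_p.append(p)
    flags = bonferroni(flat_p, alpha)
    sig = np.zeros((k, k), dtype=bool)
    for (i, j), f in zip(pairs, flags):
        sig[i, j] = sig[j, i] = f
    return StructureResult(
        components=comp,
        population_names=names,
        phi_st=phi,
        p_values=pv,
        p_se=pse,
        bonferroni_alpha=alpha / max(len(pairs), 1),
        significant=sig,
    )
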