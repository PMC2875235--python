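"""Molecular diversity and neutrality statistics for haplotype samples.

Implements the classical summary statistics for a sample of n mtDNA
control-region haplotypes:

* haplotype (gene) diversity ``H = n/(n-1) (1 - sum p_i^2)`` with Nei's
  sampling variance;
* mean number of pairwise differences (MPD) with the no-recombination total
  variance, and nucleotide diversity ``pi = MPD / L`` for a window of L
  sites;
* Tajima's D, contrasting the pairwise-difference and segregating-sites
  estimators of ``theta = 2 N mu``;
* Fu's Fs, based on the probability under the Ewens sampling formula of
  observing at least the sampled number of distinct haplotypes given
  ``theta`` estimated by MPD;
* one-tailed simulation p-values for D and Fs under the standard neutral
  coalescent conditioned on the observed number of segregating sites.

Fu's Fs needs the unsigned Stirling numbers of the first kind ``|s(n, k)|``,
which overflow double precision long before n = 81; they are computed
exactly as Python integers and the tail probability is assembled in
log-space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .notation import (
    HVRI,
    DistancePolicy,
    Haplotype,
    distance_matrix,
    distinct_haplotypes,
    segregating_sites,
)

__all__ = [
    "DiversityResult",
    "haplotype_diversity",
    "mean_pairwise_differences",
    "tajimas_d",
    "stirling1_unsigned",
    "fus_fs",
    "neutrality_pvalues",
    "compute_diversity",
]


def haplotype_diversity(counts: Sequence[int] | Mapping[object, int]) -> tuple[float, float]:
    """Unbiased gene diversity and its standard error.

    Parameters
    ----------
    counts : sequence of int, or mapping to int
        Multiplicity of each distinct haplotype; must sum to n >= 2.

    Returns
    -------
    (H, SE) with ``H = n/(n-1) (1 - sum p_i^2)`` and Nei's (1987) variance

    ``V = 2/(n(n-1)) {2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2}``
    """
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity needs a sample of at least 2")
    if any(c <= 0 for c in counts):
        raise ValueError("haplotype counts must be positive")
    p = np.sort(np.asarray(counts, dtype=float))[::-1] / n  # order-independent
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, math.sqrt(max(var, 0.0))


def _mpd_variance(mpd: float, n: int) -> float:
    # Total (sampling + evolutionary) variance of the mean number of pairwise
    # differences under no recombination (Tajima 1983, as reported alongside
    # MPD in standard population-genetics software).  The denominator
    # (n-1)(n-6) is non-positive below n = 7, where the approximation does
    # not apply; the SE is then undefined.
    denom = 11 * (n * n - 7 * n + 6)
    if denom <= 0:
        return math.nan
    return (3 * n * (n + 1) * mpd + 2 * (n * n + n + 3) * mpd * mpd) / denom


def mean_pairwise_differences(
    haplotypes: Sequence[Haplotype],
    policy: DistancePolicy | None = None,
    region: str = HVRI,
    apply_site_filter: bool = True,
) -> tuple[float, float, int]:
    """MPD with its standard error, and the number of segregating sites.

    The policy's dataset-level ambiguous-site filter is applied before
    counting (sites where more than the allowed fraction of samples carry an
    ambiguous call are excluded), unless ``apply_site_filter`` is False.
    """
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    policy = policy or DistancePolicy()
    if apply_site_filter:
        policy = policy.for_dataset(haplotypes, region)
    d = distance_matrix(haplotypes, policy, region)
    n = len(haplotypes)
    mpd = float(d[np.triu_indices(n, k=1)].sum()) / (n * (n - 1) / 2)
    s = segregating_sites(haplotypes, policy, region)
    return mpd, math.sqrt(_mpd_variance(mpd, n)), s


def tajimas_d(S: int, mpd: float, n: int) -> float:
    """Tajima's D from segregating sites and mean pairwise differences.

    ``D = (MPD - S/a1) / sqrt(e1 S + e2 S (S-1))`` with the standard
    constants a1, a2, b1, b2, c1, c2, e1, e2.  Undefined (NaN) when S = 0.
    """
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 0:
        raise ValueError("negative segregating-site count")
    if S == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (mpd - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


@lru_cache(maxsize=32)
def stirling1_unsigned(n: int) -> tuple[int, ...]:
    """Row n of the unsigned Stirling numbers of the first kind.

    ``|s(n, k)|`` counts permutations of n elements with k cycles; the
    numbers are exact Python integers (they overflow doubles for n ~ 81).
    """
    row = [1] + [0] * n
    for m in range(1, n + 1):
        new = [0] * (n + 1)
        for k in range(1, m + 1):
            new[k] = row[k - 1] + (m - 1) * row[k]
        row = new
    return tuple(row)


def _log_stirling_row(n: int) -> np.ndarray:
    row = stirling1_unsigned(n)
    out = np.full(n + 1, -np.inf)
    for k, v in enumerate(row):
        if v > 0:
            shift = max(0, v.bit_length() - 900)
            out[k] = math.log(v >> shift) + shift * math.log(2.0)
    return out


def fus_fs(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs statistic.

    ``S' = Pr(K >= k_obs)`` under the Ewens sampling formula,
    ``Pr(K = k) = |s(n,k)| theta^k / theta^(n)`` with the rising factorial
    ``theta^(n) = theta (theta+1) ... (theta+n-1)``, and
    ``Fs = ln(S' / (1 - S'))``.  ``theta`` is conventionally the MPD
    estimate.  Returns +/-inf when S' is numerically 1 or 0.
    """
    if n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must lie in 1..n")
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_row(n)
    ks = np.arange(n + 1)
    terms = log_s + ks * math.log(theta)
    log_all = _logsumexp(terms[1:])
    log_tail = _logsumexp(terms[k_obs:])
    log_sp = log_tail - log_all
    if log_sp >= 0.0:
        return math.inf
    # ln(1 - S') via the head of the distribution for numerical symmetry
    if k_obs == 1:
        return math.inf
    log_head = _logsumexp(terms[1:k_obs])
    log_one_minus = log_head - log_all
    fs = log_sp - log_one_minus
    if math.isinf(fs):
        return math.copysign(math.inf, fs)
    return fs


def _logsumexp(a: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    if a.size == 0:
        return -math.inf
    m = float(np.max(a))
    return m + math.log(float(np.sum(np.exp(a - m))))


@dataclass(frozen=True)
class NeutralityPValues:
    p_D: float
    p_Fs: float
    p_D_two_tailed: float
    p_Fs_two_tailed: float
    se_p_D: float
    se_p_Fs: float
    reps: int


def neutrality_pvalues(
    n: int,
    S: int,
    d_obs: float,
    fs_obs: float,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> NeutralityPValues:
    """Simulation p-values for Tajima's D and Fu's Fs.

    Null samples are standard neutral coalescent genealogies conditioned on
    the observed number of segregating sites (fixed-S mutation placement),
    the conditioning used by the classical analysis software.  The one-
    tailed p is the fraction of replicates at least as negative as the
    observation; a symmetric two-tailed version is also reported.
    """
    from .simulate import simulate_coalescent_counts

    if reps < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d_null = np.empty(reps)
    fs_null = np.empty(reps)
    for r in range(reps):
        mpd_r, k_r = simulate_coalescent_counts(n, S=S, rng=rng)
        d_null[r] = tajimas_d(S, mpd_r, n)
        fs_null[r] = fus_fs(n, k_r, mpd_r) if mpd_r > 0 else math.inf
    p_d = float(np.mean(d_null <= d_obs))
    p_fs = float(np.mean(fs_null <= fs_obs))
    med_d = float(np.median(d_null))
    med_fs = float(np.median(fs_null[np.isfinite(fs_null)]))
    p_d2 = float(np.mean(np.abs(d_null - med_d) >= abs(d_obs - med_d)))
    p_fs2 = float(np.mean(np.abs(fs_null - med_fs) >= abs(fs_obs - med_fs)))
    return NeutralityPValues(
        p_D=p_d,
        p_Fs=p_fs,
        p_D_two_tailed=p_d2,
        p_Fs_two_tailed=p_fs2,
        se_p_D=math.sqrt(p_d * (1 - p_d) / reps),
        se_p_Fs=math.sqrt(p_fs * (1 - p_fs) / reps),
        reps=reps,
    )


@dataclass(frozen=True)
class DiversityResult:
    """One population's row of diversity and neutrality statistics."""

    n: int
    k: int
    H: float
    H_se: float
    mpd: float
    mpd_se: float
    pi: float
    pi_se: float
    S: int
    window_length: int
    tajima_d: float
    fu_fs: float
    p_D: float | None = None
    p_Fs: float | None = None

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "distinct_haplotypes": self.k,
            "haplotype_diversity": self.H,
            "haplotype_diversity_se": self.H_se,
            "mean_pairwise_differences": self.mpd,
            "mean_pairwise_differences_se": self.mpd_se,
            "nucleotide_diversity": self.pi,
            "nucleotide_diversity_se": self.pi_se,
            "segregating_sites": self.S,
            "window_length": self.window_length,
            "tajimas_D": self.tajima_d,
            "fus_Fs": self.fu_fs,
            "p_tajimas_D": self.p_D,
            "p_fus_Fs": self.p_Fs,
        }


def compute_diversity(
    haplotypes: Sequence[Haplotype],
    policy: DistancePolicy | None = None,
    region: str = HVRI,
    pvalue_reps: int = 0,
    seed: int = 0,
) -> DiversityResult:
    """Full diversity/neutrality summary for one population sample.

    Nucleotide diversity divides MPD by the policy window length, which is
    reported alongside.  Set ``pvalue_reps`` > 0 to add coalescent p-values
    for D and Fs.
    """
    policy = (policy or DistancePolicy()).for_dataset(haplotypes, region)
    n = len(haplotypes)
    counts = distinct_haplotypes(haplotypes, policy, region)
    h, h_se = haplotype_diversity(list(counts.values()))
    mpd, mpd_se, s = mean_pairwise_differences(
        haplotypes, policy, region, apply_site_filter=False
    )
    L = policy.range_end - policy.range_start + 1
    d = tajimas_d(s, mpd, n) if s > 0 else math.nan
    fs = fus_fs(n, len(counts), mpd) if mpd > 0 else math.nan
    p_d = p_fs = None
    if pvalue_reps:
        pv = neutrality_pvalues(n, s, d, fs, reps=pvalue_reps, seed=seed)
        p_d, p_fs = pv.p_D, pv.p_Fs
    return DiversityResult(
        n=n,
        k=len(counts),
        H=h,
        H_se=h_se,
        mpd=mpd,
        mpd_se=mpd_se,
        pi=mpd / L,
        pi_se=mpd_se / L,
        S=s,
        window_length=L,
        tajima_d=d,
        fu_fs=fs,
        p_D=p_d,
        p_Fs=p_fs,
    )
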