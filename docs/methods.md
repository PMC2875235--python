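# Methods

## Input notation and the packaged data

Haplotypes are scored relative to the revised Cambridge Reference Sequence
(rCRS), positions 1–16569.  The parser accepts the dialect used in
published population tables: bare integers are transitions; an appended
base is a transversion (`184C`); `X/Y` is an ambiguous or heteroplasmic
call whose two bases are both retained (`318A/C`); `309.1`, `309.2`,
`315.1` are C-tract insertions indexed by inserted base (an explicit base
may follow, and `196insT` is normalized to `196.1T`); `193del`/`193d` are
deletions.  HVRI positions are conventionally printed minus 16000 and are
restored on parsing; the parser accepts restored HVRI positions in
16001–16569 (published tables occasionally carry variants slightly
upstream of the classical 16024 start, e.g. 16017, and these are parsed
but excluded from windowed counting).

The packaged El Jadida table (81 samples, HVRI + HVRII + four coding
segments typed in possible-H samples, with published haplogroup labels)
is shipped as TSV and guarded by a SHA-256 checksum; `load_eljadida_fixture`
refuses to return silently corrupted data.  An empty coding column means
*not typed*, which the classifier treats differently from
typed-and-reference-identical.

## Distance policy

All pairwise-difference counting runs under an explicit `DistancePolicy`:

* **window** — default 16024–16365.  The classical HVRI reading frame;
  with the data's own variant range this is equivalent to any end point up
  to 16383.  Window length L = 342 is used for nucleotide diversity
  π = MPD/L and is always reported alongside.
* **position exclusions** — 16519, a mutational hotspot, is always
  excluded (it is also excluded upstream of any clade-dating input).
* **indels** — not counted by default (the common sequence-data
  convention); `count_indels=True` includes them as presence/absence
  characters keyed by (position, insert index).
* **ambiguity handling** — three modes.  `state` (default): an ambiguous
  call is its own character state, so `265A/T` differs from `265A/C` but
  `280G/C` equals `280C/G`; `overlap`: calls agree when their base sets
  intersect; `missing`: ambiguous calls contribute no differences.
* **ambiguous-site filter** — dataset-level: sites at which more than 5%
  of samples carry an ambiguous call (in the El Jadida data, 16183, with
  6/81) are excluded before counting, mirroring the allowed-missing-
  per-site threshold of standard software.  The filter is applied by
  `DistancePolicy.for_dataset`; pairwise distance itself stays a pure
  two-sequence function.

The default combination (window 16024–16365, no indels, `state`
ambiguity, 5% site filter) is the policy under which the package
reproduces the published El Jadida diversity row exactly: 59 distinct
haplotypes, H = 0.982, MPD = 5.945, S = 64, Tajima's D = −1.777.  The
alternative modes remain available for sensitivity analysis.

## Haplogroup classification

A haplogroup motif tree is data, not code: TSV rows of (name, parent,
motif tokens per region), cumulative along the path from the root.  The
packaged tree is *minimally diagnostic* for the haplogroups present in
the El Jadida sample; it is not a reference phylogeny.  Two deliberate
choices follow from scoring considerations rather than phylogenetics:
the tree is rooted at H\* (the rCRS is itself an H2 lineage, so a
reference-like haplotype belongs at the root), and some motifs are
trimmed to the sites that discriminate within this data set (e.g. U4
keeps only 16356 under U = 7028, because its fuller control-region motif
would capture coding-untyped U\* samples).

Scoring: `score = matched − λ·missing` over the node's cumulative motif,
with λ = 0.75 by default.  Motif sites in regions the sample was never
typed for are skipped — unobserved is not absent, which matters for
coding-defined clades such as H1 (3010) when only control-region data
exist.  Among equal scores on one ancestral path the deeper node wins
*only if it matches strictly more motif variants*; otherwise the
ancestor is kept (a descendant whose extra motif sites were all
unobserved adds no evidence).  Equal scores on different paths are
reported as ties and never silently broken.  λ sits below 1 so that a
deep, largely matched motif outranks shallow generic nodes, and above
1/2 so that two missing diagnostics cost more than one extra match; with
the packaged tree the 81 El Jadida samples classify uniquely to their
published labels with zero ties.

Frequency tables are computed over three denominators: the whole sample,
the macro-pools (sub-Saharan L0–L6 vs West Eurasian), and the L pool
itself (branch shares L1/L2/L3…), the denominator under which
trans-Saharan geographic gradients are most visible.

## Diversity and neutrality statistics

* **Gene diversity** `H = n/(n−1)(1 − Σpᵢ²)` with Nei's variance
  `V = 2/(n(n−1)) {2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}`.
* **MPD** is the average of `haplotype_distance` over all C(n,2) pairs;
  its reported SE uses the no-recombination total variance
  `[3n(n+1)π̂ + 2(n²+n+3)π̂²] / [11(n²−7n+6)]`, undefined below n = 7
  where the denominator changes sign.  The per-site version of this SE
  (0.0087 → 0.009 at L = 342) matches the published nucleotide-diversity
  SE for El Jadida; the published MPD SE itself (2.866) follows some
  other convention we could not identify and is not reproduced.
* **Tajima's D** uses the textbook constants (a₁, a₂, b₁, b₂, c₁, c₂,
  e₁, e₂); S = 0 yields NaN rather than a number.
* **Fu's Fs**: `S′ = Pr(K ≥ k_obs) = Σ_{k≥k_obs} |s(n,k)| θᵏ / θ^(n̄)`
  with θ the MPD estimate, evaluated from exact integer Stirling numbers
  assembled in log-space (`ln(1−S′)` comes from the complementary head
  sum, so both tails stay accurate).  k_obs = 1 gives +∞ by construction.

  A numerical caution learned from the El Jadida comparison: legacy
  software saturates near Fs ≈ −25 when S′ falls below ~1e-11.  Our
  implementation reproduces published values to the printed 3 decimals
  whenever |Fs| < 20 (verified against nine independent North/East
  African samples), while samples reported in the −24.8…−25.7 band have
  true values as low as −72.  For El Jadida (n = 81, k = 59, θ = 5.945)
  the exact value is −64.916.
* **p-values** for D and Fs are one-tailed (toward negative) fractions of
  fixed-S neutral coalescent replicates at least as extreme as the
  observation; a symmetric two-tailed variant around the null median is
  also returned, since published tables rarely state the convention.
  Fixed-S conditioning (mutations placed multinomially on branches by
  length) matches the conditioning of the classical analysis software.

## AMOVA and Φ_ST

Distances are squared pairwise differences (the Φ-statistics convention).
The two-level decomposition uses sums of squares
`SSD(total) = (1/N)Σ_{i<j} d²ᵢⱼ` and its within-population analogue,
mean squares over P−1 and N−P degrees of freedom, and the unequal-size
coefficient `n_c = (N − Σn_p²/N)/(P−1)`; Φ_ST = σ²ₐ/(σ²ₐ+σ²w).  Negative
among-population components are reported as computed (and flagged) but
truncated to zero only inside `percent_among`, the conventional
presentation.  Pairwise Φ_ST is exactly the two-population AMOVA, and the
permutation test shuffles individuals between the pair, reporting
`p = #(Φ* ≥ Φ_obs)/reps ± √(p(1−p)/reps)`.  Populations of size one are
excluded with a warning.  Bonferroni correction compares each p to α/m.

## Rho clock

ρ is the average mutation count from the clade's ancestral haplotype to
its tips (multiplicity-weighted).  The standard error is the
branch-weighted Poisson form `σ² = Σ_b (n_b/N)² l_b`, which reduces to
`√(Σ counts)/N` on a star phylogeny; when branch structure is unknown the
star form is used unless explicitly disabled.  Ages are linear:
`years = ρ × 3624` (whole-molecule calibration), `sd = σ × 3624`.  A
haplotype shared by several samples can contribute its terminal
mutations once per carrier (default) or once in total
(`shared_tips_once=True`); the published phrasing is ambiguous, so both
are exposed.  No purifying-selection correction is applied — the
calibration is a plain linear clock, and a user-supplied transform can
be layered on the returned ages.  Clusters can be read from TSV
(tip, mutations, multiplicity) or from newick trees whose branch lengths
are mutation counts.

## Geospatial analysis

Great-circle (haversine) distances on a 6371-km sphere; no map
projection, since frequencies are interpolated on a plain lat/lon
lattice.  IDW uses power 2 by default; a grid node coinciding with a
sample takes the sample's value exactly, and the surface is bounded by
the data range.  Moran's I follows the standard double-sum definition;
zero-variance inputs are NaN (undefined), and the correlogram bins the
C(n,2) pair distances into 14 equal-count classes by rank (exhaustive
and disjoint even under ties; PASSAGE-style default, stabilizing
per-class power versus equal-width bins).  Class significance is a
permutation test of the values over locations, two-sided around the null
expectation E[I] = −1/(n−1).  A cline is declared when the first class
is positive and significant, Spearman rank correlation of I against
class index is negative and significant, and at least one of the last
three classes is negative — each clause configurable, since published
usage ("a continuous decline trend composed of significant points") is
informal.

## Synthetic data: what it does and does not emulate

The coalescent generator is a constant-size Kingman genealogy with
infinite-sites mutations at distinct positions drawn uniformly from the
analysis window (collisions redrawn, so fixed-S output has exactly S
segregating sites).  It emulates the *null* used by the neutrality
tests; it does not model growth, bottlenecks, recurrent mutation, or the
strong site-rate heterogeneity of real control-region data, so passing
calibration tests validates the statistics' null behaviour, not any
demographic inference about real populations.  Clade simulation hangs
Poisson mutation counts on star or rescaled-coalescent topologies of
known age, making the rho estimator unbiased by construction — it tests
estimator algebra and coverage, not clock validity.  Clinal surfaces are
linear gradients plus Gaussian noise clipped to [0,1] on a regular grid;
real sampling is irregular and autocorrelated in more complex ways.
Validation scales: 500 clades of 20 tips at 10 kyr for age recovery
(coverage ≥ 90%); 5000 + 2000 fixed-S replicates at n = 30, S = 15 for
the D test's type-I error; 50 + 50 seeded surfaces (6×6 grid, 99
permutations) for cline sensitivity/specificity — sizes chosen to hold
Monte-Carlo error well below the tested margins.

## Determinism

Every stochastic routine takes a seed or `numpy.random.Generator`; the
pipeline splits one root seed across stages, stamps all outputs with a
provenance header (package version, input, policy, reps, seed), and
re-runs are byte-identical.

## Known limitations

* The classifier's packaged tree only resolves the haplogroups present
  in the packaged data; finer placement (e.g. sub-K resolution of the
  16287 K haplotypes) needs a richer user-supplied tree.
* Fu's Fs p-values inherit the fixed-S conditioning; fixed-θ p-values
  would differ slightly.
* FASTA export of patched reference subsequences is not provided: the
  package deliberately does not bundle the rCRS sequence, and variant
  strings are the interchange format.
* AMOVA is two-level only (no regional grouping level).
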