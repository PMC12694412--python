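# Methods

This note documents the statistical models behind `viralphenology`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate about real data.

## Input model and normalization

The pipeline consumes a taxa × samples matrix of trimmed-mean read
coverage with per-sample metadata (ISO-8601 date, library read count,
size-fraction label). Coverage is normalized to *coverage per 10⁷ reads*
(`a = c / reads × 10⁷`); the scale constant is arbitrary (every downstream
statistic is scale-free or rank-based) and is chosen to keep normalized
values near raw-coverage magnitudes. Samples are assigned to calendar
months by (year, month) only; multiple samples in one month are averaged
with a warning. Interior missing months are filled by linear interpolation
on the month index; leading/trailing months are never extrapolated, so a
series runs from its first to its last observed month. Periodicity testing
requires ≥ 24 months.

## Periodicity tests

**Periodogram.** For a mean-centered monthly series of length *n*,
ordinates are computed on the Fourier grid `f_j = 12·j/n` cycles/year,
`j = 1..⌊(n−1)/2⌋`; the "extended" grid oversamples the same band
five-fold. Oversampling reduces the scalloping loss when a true frequency
falls between Fourier bins — relevant because real series lengths are not
multiples of 12.

**Exact Fisher's g.** `g = max I_j / Σ I_j` with the classical closed-form
null (iid exponential ordinates under Gaussian white noise). The closed
form is validated against a 10⁶-series Monte-Carlo null in the test suite.

**Rank-robust variant.** The series is replaced by its average-ranks,
centered, and `g` is computed on the extended grid; the null distribution
comes from *B* seeded iid standard-normal series processed identically,
with `p = (1 + #{g_b ≥ g_obs}) / (B + 1)`. Because the ranks of any iid
continuous noise are a uniform random permutation, this null is
distribution-free, and the test is invariant to any strictly monotone
transform of the data — which is what rescues power under uneven peak
heights, heavy-tailed noise and gap years. The null depends only on
`(n, B, seed)` and is cached per length. This is an independent design in
the same spirit as published "robust" periodogram tests, not a clone of
any particular implementation.

**Choice of B.** The default is **B = 1999**. With B = 999 the smallest
attainable Monte-Carlo p is exactly 1/1000 = 0.001, which can never fall
*below* the screening cutoff α = 0.001; B = 1999 makes the minimum
p = 0.0005. Any B ≥ 999 is accepted.

**Harmonic LRT.** OLS of the series on an intercept plus cosine/sine pairs
for the requested periods (12 months by default; 12+6 optionally).
`Λ = n·ln(RSS₀/RSS₁)` is referred to χ² with 2 df per pair; the F test is
reported alongside and agrees with the LRT to rank correlation > 0.99 at
n = 60. The 12-month-only default reflects that the screen targets annual
structure; biannual structure is picked up by the periodogram instead.

**Classification.** A taxon with robust p < α (default 0.001, matching the
strict screening convention for multiple testing across hundreds of taxa)
is labeled *annual* if its dominant frequency is nearer 1 than 2 cycles/yr
and *biannual* if nearer 2; dominant frequencies outside [0.5, 2.5]
cycles/yr are treated as nonseasonal, since the Fourier resolution of a
60-month series is 0.2 cycles/yr and frequencies beyond that band do not
correspond to annual or semiannual phenology. Classification uses the
periodogram's dominant frequency rather than the 6-month harmonic fit; the
two agree for clean signals and the periodogram requires no extra model.

## Seasonal profiles and clustering

A seasonal profile is the vector of mean normalized abundance per calendar
month, z-scored across the 12 months (population sd); flat profiles are
flagged degenerate and excluded from clustering. Clustering is PAM
(k-medoids, BUILD then SWAP to convergence) under Euclidean distance on
z-profiles. Euclidean on z-scores is the conventional pairing for
seasonal-profile representations; the medoid is always a member profile,
which keeps cluster exemplars interpretable as actual taxa. PAM here is
deterministic given the input set (ties break toward lower index), so
repeated runs agree and partitions are invariant to input order.

The number of clusters minimizes a **medoid-based Davies–Bouldin index**
(S_i = mean member–medoid distance; M_ij = medoid–medoid distance), scanned
over k = 2..10 by default, ties toward smaller k. Note a structural
property of this index: on *unstructured* profile sets (no planted groups)
DB tends to decrease with k, so the selected k is only meaningful when the
data have real cluster structure; the package records the whole DB-by-k
curve so users can see whether the minimum is a genuine elbow. By default
only taxa classified annual or biannual are clustered; a flag admits all
taxa. A cluster's peak month is the calendar month of its medoid's maximum,
binned into meteorological seasons (Dec–Feb winter, Mar–May spring,
Jun–Aug summer, Sep–Nov fall).

## Community seasonality

Bray–Curtis similarity (1 − dissimilarity) is computed for all unordered
sample pairs on normalized abundances; lag-0 pairs are excluded (distinct
size fractions are analyzed separately). The 12-month harmonic regression
of similarity on lag is fit twice — on all pairs and on per-lag means —
because the two weight lags differently; both are reported. The all-pairs
p-value is flagged *nominal*: pair similarities sharing a sample are not
independent, so its F test is calibrated only for independent
observations (verified on independent draws in the tests).

## Phylogenetic signal

Patristic distances come from the input newick tree (path sums of branch
lengths). Temporal agreement is Kendall tau-b on the overlapping monthly
grid of each pair (≥ 12 shared months), computed on interpolated grids so
that pairs align. The Mantel statistic is the Spearman correlation of the
vectorized upper triangles (Pearson available); the null is B seeded
simultaneous row/column permutations of the agreement matrix, one-sided
for negative association. The contingency test cross-tabulates cluster
membership against a user-supplied grouping (taxonomy or clades cut at a
configurable depth) and reports both the parametric χ² upper tail — the
regularized upper incomplete gamma Q(df/2, x/2) — and a permutation p from
cluster-label shuffles; the permutation version is preferred when expected
cell counts are small.

**Power caveat.** Mantel-type permutation tests have intrinsically modest
power for Brownian-motion traits on phylogenies: in this package's
replicate simulations (Yule trees, wrapped-BM phenology, 150 taxa,
decade-long monthly series) detection rates at α = 0.05 plateau around
80–85%, and the ceiling — testing the true phase distances directly, with
no abundance noise at all — is ≈ 78% at 150 taxa and only reaches ~90% by
300 taxa. Replicates fail when the BM realization itself produces
phase-convergent deep clades, i.e. when the signal is genuinely absent
from the draw. Interpret a nonsignificant Mantel result on real data as
weak evidence of absence.

## Synthetic data generator

The generator emulates a multi-year monthly metagenomic survey:

* **Tree:** Yule pure-birth (default birth rate 1/unit time), sampled by
  the GSA method so terminal branches have positive length.
* **Phenology:** root peak phase ~ Uniform[0, 12); each branch adds a
  wrapped-normal increment with variance σ²ℓ (default σ² = 1 month²/unit);
  K ~ Poisson(λℓ) host-switch jumps (default λ = 0.1) resample the phase
  uniformly — the simplest exchangeable model of phenology reassignment
  after a switch.
* **Dynamics classes:** annual/biannual/erratic with default shares
  0.17/0.02/0.81, the composition reported for the field system this
  emulates. Seasonal signal is an exponential-cosine bump
  `b + A·exp(κ(cos(2π(t−φ)/P) − 1))` (P = 12 or 6; defaults A = 10, b = 1,
  κ = 2), which produces localized one-to-two-month peaks while keeping the
  fundamental Fourier component dominant. Erratic taxa place
  Poisson-distributed spikes (default 1/year in expectation, height A) at
  uniform months. Gap years (default probability 0.1 per taxon-year) zero
  the seasonal component but keep the baseline.
* **Observation layer:** observed = signal × LogNormal(0, σ_noise = 0.3) ×
  (library/median library); library sizes ~ LogNormal(ln 10⁷, 0.5) rounded
  to ≥ 1; whole months unsampled with probability 0.15 (matching a ~5-year
  survey with 53 of ~64 monthly slots sampled).
* **Genomes:** each host gets a random order-2 Markov chain
  (Dirichlet-sampled rows); virus genomes (default 100 kb) are emitted
  position-wise from the host chain with probability α (amelioration,
  default 0.75) and otherwise from a shared global chain.

Everything is bit-reproducible from `(SimConfig, seed)`.

What passing the synthetic benchmarks does **not** show: real NCLDV series
have autocorrelated environmental drivers, trends, compositional coupling
between taxa, and library-preparation artifacts that the independent
lognormal noise model does not emulate; real genomes are not order-2
Markov. Recovery rates on this generator are therefore upper bounds on
field performance, and the gap-year/missing-month "study" mode (reported
separately by the acceptance script) is the more honest benchmark for the
classifier: recovery there drops from 100% to roughly 85–95% depending on
the draw, because gap years move rank-periodogram power into very low
frequencies (0.2–0.36 cycles/yr) and the strict α = 0.001 cutoff turns
marginal peaks away.

## d2\* host prediction

K-mer counts (default k = 6) are accumulated over forward and
reverse-complement strands of every record, skipping windows containing
non-ACGT characters, so profiles are exactly invariant to
reverse-complementing the input. Expected counts come from the genome's
own order-m chain (default m = 2) fit to both-strand (m+1)-mer counts with
pseudocount 1 — the pseudocount guarantees E_w > 0 where d2\* would
otherwise be undefined. Then

    D2* = Σ_w X̃_w Ỹ_w / √(E^x_w E^y_w),   d2* = ½(1 − D2*/(‖X̃‖_E ‖Ỹ‖_E))

clamped to [0, 1]. k = 6, m = 2 follow common alignment-free host-range
practice; both are configurable. Predictions are reported below d2\* = 0.4
(strict) and tiered "high" below 0.2; the co-occurrence edge filter, by
contrast, retains |weight| ≥ cutoff inclusively. These boundary conventions
are recorded in output metadata.

A subtlety documented by the tests: under both-strand counting, the
"null" value d2\* = 0.5 between unrelated sequences holds exactly only
when the generating composition is strand-symmetric. Sequences from a
strand-*asymmetric* chain share a systematic order-2 lack-of-fit residual
(observed counts are strand-symmetrized, the fitted chain's expectations
are not), which drags same-chain d2\* far below 0.5 (≈ 0.17 in
simulation). The null benchmarks therefore use a reverse-complement
symmetric chain, built by symmetrizing the stationary 3-mer joint of a
random chain. For host prediction this bias is harmless — it affects all
candidate hosts of a virus similarly — but absolute d2\* values should not
be compared across datasets with different strand biases.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the
whole suite completes in minutes on one CPU: 200 planted taxa for
classifier recovery, 10⁶ Monte-Carlo series for the Fisher's g null,
50 replicates for Mantel power and null-uniformity checks (150 and 40
taxa respectively), 20 seeds for cluster-number selection, 100 sequence
pairs of 100 kb for the d2\* null, and 20 viruses × 5 hosts for host
recovery.

## Known limitations

* No Lomb–Scargle handling of uneven sampling: series are interpolated to
  a monthly grid first, which mildly smooths and can bias periodogram
  ordinates when many consecutive months are missing.
* The classifier assigns one label per taxon; mixed annual+biannual
  dynamics are labeled by the dominant component only.
* FlashWeave-style network inference is out of scope; only the edge-weight
  filter on precomputed edges is provided.
* The Mantel power caveat above: absence of phylogenetic signal cannot be
  concluded from a nonsignificant test at these sample sizes.
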