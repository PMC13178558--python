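# Methods

## Observation model

Per-cell mRNA counts are modelled as a zero-inflated negative binomial
(ZINB). A cell is transcriptionally repressed with probability ω and then
contributes a structural zero; otherwise its count follows NB(r, p) with

    P(k) = C(k + r − 1, k) · p^k · (1 − p)^r ,

so the full pmf is P(0) = ω + (1 − ω)(1 − p)^r and
P(k>0) = (1 − ω)·NB(k; r, p). The NB convention matters: here p is the
per-trial "success" (mRNA) probability, under which NB(r, p) is the
stationary distribution of a gene producing geometric bursts with mean size
b = p/(1 − p) at rate f = r per mRNA lifetime. The burst mapping is therefore

    repression = ω,  burst size b = p/(1 − p),  burst frequency f = r ,

with f reported dimensionless (per mRNA lifetime). p = 1 (infinite bursts)
is outside the domain. Useful closed forms used throughout the tests:
mean = (1 − ω)·m and variance = (1 − ω)·m·(1 + b + ω·m), with m = r·p/(1 − p).

## Priors, sampler, and summaries

Priors: Uniform(0, 1) on ω and on p, half-normal (location 0, scale 20,
positively truncated) on r. The posterior is sampled by Metropolis–Hastings
with a diagonal Gaussian proposal whose per-coordinate standard deviation is
5% of the current parameter value, floored at `min_proposal_sd = 1e−4` so a
coordinate drifting toward 0 cannot freeze the chain. Defaults: 500,000
iterations, 100,000 burn-in, thinning by 100 (4,000 retained samples),
single chain.

Because the proposal scale depends on the current state, the kernel is
asymmetric; by default the Hastings ratio q(θ|θ′)/q(θ′|θ) is included in the
acceptance probability, which preserves detailed balance exactly (verified
against a brute-force grid posterior: total variation of each marginal
< 0.05 on a 20-cell dataset). The `hastings_correction=False` flag gives the
plain-Metropolis variant. Proposals outside the prior support are rejected
through a −∞ posterior. The chain is initialised by method of moments
(p₀ = 1 − mean/var for overdispersed samples, ω₀ from the excess zero
fraction, each clipped to the interior of the support) with a fallback of
θ₀ = [0.5, 1, 0.5].

Point estimate: the retained sample with maximal log-posterior (no kernel
density bandwidth to choose, fully reproducible). Uncertainty: equal-tailed
2.5th–97.5th percentile intervals of the per-sample derived quantities ω, b,
f. Both choices are conventions; an HPD interval or KDE mode would differ
slightly on skewed marginals.

Numerical notes: the iid likelihood is evaluated on the unique counts and
their multiplicities (log-gamma form), which makes a 500k-iteration chain on
thousands of cells take seconds; P(0) combines the point mass and the NB
zero through `logaddexp`. Identifiability: an all-zero dataset is explained
equally well by ω → 1 and by r → 0 (both send P(0) → 1), so only the implied
mean (1 − ω)·m is pinned near zero, not ω itself. Similarly r and p trade
off along a ridge at fixed mean, which is why mixing in r is the slowest
direction; coverage experiments use proportionally longer chains.

## Spot-intensity calibration

False positives are removed at the 99.9th percentile of the negative-control
(no-target strain) spot intensities, computed with the linear-interpolation
percentile convention (position (n − 1)·q on the sorted sample) and applied
to the integrated intensity; peak height is carried as metadata only. The
surviving intensity distribution is fitted with a Gaussian mixture by EM on
the raw intensities (bin-free; scikit-learn's `GaussianMixture`, k-means++
initialisation, fixed seed, tolerance 1e−8, 500-iteration cap; 3 components
by default, configurable, with component means left free rather than pinned
to integer multiples). The mean of the lowest-mean component is the
single-molecule unit intensity. Each cell's copy number is
round(Σ surviving intensities / unit intensity): counts are integers and
symmetric rounding is unbiased under symmetric intensity noise (the division
rule alone leaves rounding open).

## Noise statistics

CV² = σ²/μ² and Fano = σ²/μ use the sample (n − 1) standard deviation;
groups with μ = 0 report NaN (undefined), never 0/0. "Silent" is count 0 and
"on" is count ≥ 1. The Spearman test enumerates all n! rank permutations for
n ≤ 8 and counts |ρ_perm| ≥ |ρ_obs| (two-sided, ≥ convention), which gives
p = 2/24 ≈ 0.08 for perfectly monotone n = 4 ladders; larger n falls back to
the usual t-approximation with a logged notice. The one-phase exponential
decay y(x) = (y₀ − plateau)e^(−kx) + plateau is fitted by bounded
least-squares (k ≥ 0) initialised with plateau₀ = min(y), y₀₀ = max(y), and
k₀ from a log-linear regression of y − plateau₀; constant y returns
plateau = y with R² = 1 by the zero-SS_tot convention.

## Synthetic data

The generators define the study conditions the tests run under.

* **ZINB counts**: drawn via a Bernoulli(ω) repression mask and numpy's
  negative-binomial sampler (whose success probability is 1 − p under our
  convention). The default condition ladder is 0/5/50/100 μM tryptophan with
  two strain archetypes: a dual-layer-regulation archetype starting near 86%
  silent cells at 0 μM with a modest expressing tail, and a single-layer
  archetype starting near 45% silent with a larger tail (counts into the
  tens) that shrinks gradually along the ladder. 1,000 cells per group by
  default, commensurate with segmented-cell counts in smFISH experiments.
* **Telegraph model**: the ON/OFF promoter path is simulated exactly
  (exponential holding times, stationary initial state); conditional on the
  path, transcription is a Poisson process at k_tx during ON intervals and
  transcripts decay independently at k_deg, so the count at t_end is Poisson
  with mean k_tx·∫_ON e^(−k_deg(t_end − s)) ds. This conditional-Poisson
  draw has exactly the law of a full event-by-event simulation read out at
  t_end at a fraction of the cost (one event per promoter switch). Cells
  start with zero mRNA, so t_end must be ≫ 1/k_deg; tests use ≥ 15 mRNA
  lifetimes. The simulator shares no code with the ZINB path and serves as
  the mechanistic oracle: always-ON gives Fano = 1, and the bursty limit
  k_off ≫ k_on with k_tx ≫ k_off gives mean k_on·k_tx/(k_deg·k_off) and
  burst size ≈ k_tx/k_off.
* **Spot tables**: molecules co-localize sequentially with probability 0.15
  (default), so a spot holding m molecules draws its intensity from
  N(m·unit, m·(cv·unit)²) — the quantal multi-Gaussian structure the
  calibration step assumes, with per-cell total intensity sd = cv·unit·√k.
  The default unit intensity is 100 a.u. with 5% CV; control intensities are
  half-normal with scale 12 a.u. (99.9th percentile ≈ 39 a.u., safely below
  half a unit). The generator does not model point-spread functions, cell
  geometry, out-of-focus loss, or intensity drift, so passing recovery tests
  demonstrate correctness of the calibration arithmetic, not robustness to
  optical artefacts in real images.

## Pipeline determinism

A single global seed fans out to per-stage, per-group seeds via
`SeedSequence((seed, stage_index, group_index))` (all derived seeds < 2³¹),
groups are processed in sorted (strain, condition) order, and JSON/CSV
output formatting is canonical, so re-running an identical config reproduces
every output byte-for-byte.

## Validation problem sizes

The test suite checks moments of 10⁵-draw samples against closed forms, the
pmf normalisation by tail-truncated summation (tail < 1e−12), the exact
Spearman p against full enumeration for n ≤ 6, the sampler against a dense
grid posterior on a 20-cell dataset (marginal total variation < 0.08, three
seeds), parameter recovery on 20 replicate datasets of 2,000 cells (truth
inside the 95% CI in ≥ 17/20 per parameter), CI coverage across 50
prior-drawn datasets of 1,000 cells (≥ 90% per parameter), and end-to-end
spot-to-count recovery on 1,000 cells (≥ 99% exact at 5% intensity CV).

## Known limitations

* Burst frequency is reported per mRNA lifetime (f = r, dimensionless);
  converting to absolute time requires an independent mRNA half-life
  estimate.
* Single-chain sampling by default mirrors the minimal workflow; no R-hat
  diagnostics are computed unless multiple estimators with different seeds
  are run by hand.
* The ZINB is phenomenological: it cannot distinguish a genuinely locked-off
  subpopulation (ω) from extreme burst-interval statistics, and fitting it
  to mechanistic telegraph data recovers burst size only up to the
  model-misspecification band (~25% in the bursty regime).
* Intensity calibration assumes the first mixture component is the
  single-molecule class; in data where monomer spots are rare (very high
  co-localization), the first component could capture a multimer class and
  bias counts downward.
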