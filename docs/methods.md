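# Methods

This note documents the models and procedures implemented in `methylqc`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Quantification

β = M/(M+U) with no offset constant; a zero denominator (or missing input)
yields a missing value rather than 0, so degenerate probes never masquerade
as unmethylated. β is invariant under any common positive rescaling of
(U, M).

## Dye-bias correction

Two-color arrays show a systematic intensity difference between channels.
The correction regresses log green on log red over matched internal control
pairs and applies the fitted power-law map `red → exp(a)·red^b` to every
red-channel intensity of the sample (green untouched), preserving ranks.

Pairing: control probes of the staining and extension categories are
assigned to a channel side by their dominant channel (mean across samples at
least twice the other channel's); each side is sorted by its own-channel
mean and paired rank-wise. This emulates duplicate control designs that
measure the same target once per channel, without hard-coding a vendor
probe list. The regression slope is shrunk toward 1 with one pseudo-pair of
unit leverage (λ = 1 in squared log units): with a handful of noisy pairs
the map stays near-linear instead of amplifying noise into a wildly
nonlinear transform, while with many pairs the data dominate. Samples with
fewer than 3 usable pairs are skipped and flagged
(`samples["dye_bias_skipped"]`).

## Detection p-values

p(i, n) is the upper-tail normal probability of total intensity U+M under a
background estimated from negative-control probes: type I probes (both
signals in one channel) against twice that channel's negative mean with
doubled variance; type II probes against the sum of the two channel
backgrounds. The conventional screen fails a sample when more than 1% of
probes have p > 0.01. The one-sided normal-tail form is a documented
stand-in for the various proprietary formulations; only the 0.01/1% rule is
treated as canonical.

## Control metrics

Seventeen metrics, each (mean foreground-group intensity)/(mean
background-group intensity) in a designated channel, with flagging strictly
below threshold (a sample exactly at threshold passes). Metrics whose probe
groups are absent report "n.a." and never flag. The default policy
(`src/methylqc/data/control_policy.yaml`) encodes the groupings as
probe-identifier regexes and ships thresholds of 5.0 for
staining/extension/non-polymorphic, 0.0 for restoration and 1.0 otherwise,
following the manufacturer's controls-reporter conventions. The exact probe
groupings of commercial manifests are not reproduced; the policy is an
editable approximation the user can replace wholesale.

## SNP-probe mixture model

Pooled SNP β-values (all samples × all SNP probes) are fitted with a
four-component mixture: Beta(a_k, b_k) for genotypes AA/AB/BB plus a fixed
uniform density on [0, 1] whose weight absorbs outliers. Fitting is EM:

* **Initialization.** Components moment-matched to β in [0, 0.25],
  (0.25, 0.75], (0.75, 1]; outlier weight 0.01. A second start uses tight
  clusters (means 0.05/0.5/0.95) with outlier weight 0.1 — on heavily
  contaminated cohorts the bin-based start can converge to a poor local
  optimum that inflates the homozygote variances; the higher final
  log-likelihood wins.
* **M-step.** Beta shapes by weighted maximum likelihood (L-BFGS-B on the
  exact weighted log-likelihood with digamma gradients, warm-started from
  the previous parameters and never accepted if worse), so the
  log-likelihood trace is monotone non-decreasing by construction. Moment
  matching would not guarantee this.
* **Termination.** Log-likelihood gain < 1e-6 or 500 iterations. β-values
  are clipped into [1e-6, 1−1e-6] for density evaluation. Components are
  relabeled by ascending mean; a fit whose means are not strictly ordered,
  or that empties a genotype component, is rejected (one fallback
  initialization is tried before raising).

Posterior genotype calls follow Bayes' rule per (sample, SNP); missing
β-values propagate as missing posterior slices.

## Fingerprint agreement

For samples a, b: agreement = Σ_j Σ_k q_jk^a q_jk^b / Σ_j w_j^a w_j^b with q
the genotype posteriors and w = 1 − p(outlier). The denominator uses the
*product* of the two samples' non-outlier masses — one concrete reading of
"partially excluded" (min or average were alternatives); it makes a probe's
exclusion symmetric and exactly complements the numerator, keeping scores in
[0, 1]. Under Hardy-Weinberg at allele frequency p, unrelated pairs score
around Σ_k HWE(k)² (= 0.375 at p = 0.5) while duplicates score near 1, so
the two populations separate cleanly. The conflict threshold defaults to
0.90 — far above observed unrelated scores and below duplicate scores.
Conflicts are reported, not adjudicated: deciding *which* sample of a pair
is mislabeled needs outside evidence.

## Outlier log-odds O_n

O_n = mean over non-missing SNPs of log₂ p(outlier)/(1 − p(outlier)),
clipped at ±40 to guard degenerate posteriors. The default flagging cutoff
is −4. Two caveats, both visible in the synthetic studies: O_n conflates the
contamination degree with the number of SNPs at which the contaminating
source happens to differ in genotype, and a 50:50 mix of opposite
homozygotes lands on the heterozygote cluster and looks clean. Consequently
O_n is a reliable *screen* and a good rank proxy for moderate contamination,
but its rank agreement with the true mixing degree degrades as γ approaches
0.5 (on 100-sample cohorts with γ spanning [0, 0.5], even an oracle mixture
caps the Spearman correlation near 0.89, versus ≈0.94 when γ stays below
0.4).

## Sex check

T̄ˣ and T̄ʸ are means of total intensity over X / Y probes normalized by the
autosomal mean (cancels per-sample DNA concentration; all calls are scale
invariant). Cutoffs: Hodges-Lehmann estimator — the exact median of all
pairwise (male, female) cross-averages, computed by full enumeration (even
pair counts take the midpoint of the central two). It is used because the
recorded labels may be partly wrong; the median of cross-pair averages moves
little until a large minority of labels are wrong. Calls: male iff
T̄ˣ < cutoff_x and T̄ʸ > cutoff_y; female in the opposite quadrant; the other
two quadrants (including exact ties on a cutoff) are "unclear" — the
upper-right region is where an XXY karyotype would fall — and unclear
samples are never counted as mismatches.

## Contamination model

β_nj ~ N((1−γ_n)·μ_k + γ_n·c_j, (1−γ_n)·σ_k) with genotypes k_nj ∈
{AA, AB, BB}; the spread shrinks with γ because a mixed signal averages
over beads. Inference is Metropolis-within-Gibbs over the whole cohort
jointly:

* random-walk proposals, reflected at the bounds, for γ_n (vectorized over
  samples; uniform prior on [0, 0.99] — the 0.99 cap keeps the sd positive),
  c_j (vectorized over SNPs; uniform on [0, 1]), μ_k (flat prior constrained
  to μ_AA < μ_AB < μ_BB in [0, 1]) and σ_k (half-normal(0.1) prior, reflected
  at 1e-4);
* discrete Gibbs updates of every k_nj proportional to the three component
  likelihoods (genotypes stay free so the model, not the caller, explains
  outliers);
* proposal scales adapt every 50 burn-in iterations toward ≈0.3 acceptance;
  final acceptance rates outside [0.05, 0.95] raise a warning.

Defaults: 10,000 iterations, 5,000 burn-in, chain thinned by 10 for the
retained γ draws; point estimates are posterior means, genotype estimates
posterior modes, intervals the 2.5/97.5 chain percentiles. Initialization
comes from the mixture model's hard calls (or β thresholds at 0.25/0.75
without them). Everything is reproducible from one integer seed. No
measurement-noise floor is added to the (1−γ)σ scale. The model assumes a
*single* foreign source; multi-source mixtures are out of scope.

## Synthetic-data generator

`SimulationConfig` fully determines a cohort given its seed (identical seeds
give identical output). Defaults describe a realistic mid-size study:
100 samples, balanced sexes, 65 SNP probes at allele frequency 0.5
(maximizing fingerprint entropy, as with real high-frequency SNP panels),
genotype β means 0.05/0.5/0.95 with Beta-distributed noise of sd 0.05
(typical cluster tightness for SNP probes), intensity scale 5000 with 10%
log-normal measurement noise, 300/60/30 autosomal/X/Y methylation probes
(a down-scaled but structurally faithful array).

Emulated: Hardy-Weinberg genotypes; trimodal SNP β; sex-dependent allosome
doses (X: 1.0 female / 0.5 male; Y: 0.8 male / 0.1 female residual
background); the full control-probe layout matching the default policy,
including graded two-channel normalization pairs anchoring the dye-bias
regression; per-category control failures (signal collapses to half
background, or for target-removal, rises to signal level); detection
failures (methylation probes collapse to background); single-source
contamination acting on both SNP β (convex mixing toward the source's
expected β) and, for a male source in female hosts, on allosome doses;
recorded-sex and donor-label corruption; technical replicates.

Not emulated: probe cross-reactivity, batch/position effects, copy-number
aberrations beyond allosome dosage, between-array intensity drift, or
channel-specific β noise (β noise is drawn directly, so U and M share one
intensity draw). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative assumptions, not
robustness to every artifact of real arrays.

## Problem sizes and numerical choices

The shipped studies use cohorts of 100–2000 samples with the down-scaled
probe complement above; these sizes give stable statistics while keeping a
full test run to a couple of minutes. EM tolerance 1e-6 (≤500 iterations);
density clipping at 1e-6; log-odds clipping at ±40; MCMC 10,000 iterations.
Ties exactly on a sex cutoff are unclear (conservative); a metric exactly at
threshold passes (strict less-than); missing values propagate everywhere
rather than defaulting to zero.

## Known limitations

* The control-metric probe groupings are a self-consistent approximation,
  not a vendor manifest transcription.
* The detection p-value formula is a stated convention, not a reimplementation
  of any specific scanner software.
* O_n saturates at high contamination (see above); the MCMC γ estimate does
  not and should be preferred when a single-source model is plausible.
* The IDAT reader handles only the fields needed for mean intensities and
  requires address columns in the manifest.
* Fingerprinting is uninformative for cohorts with one sample per donor (no
  pairs to compare), and the sex check needs at least one recorded male and
  one recorded female to learn cutoffs.
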