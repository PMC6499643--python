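# Methods

## Model and rationale

The package estimates, for every recurrent somatic single-nucleotide variant
in a tumor cohort, the intensity of somatic selection that drove it to its
observed prevalence.

**Variant hygiene.** Input is a MAF-dialect table (1-based, fully closed
coordinates). Non-SNV rows go to a side channel; rows whose reference allele
disagrees with the FASTA base are rejected to a report, never silently
corrected. Adjacent same-sample SNVs (|Δpos| = 1 on one chromosome) are
re-designated as dinucleotide events and removed whole — including runs of
three or more, the conservative reading, since a single mutational event
would otherwise masquerade as multiple independent point mutations. Variant
identity for recurrence is nucleotide-level (chrom, pos, ref, alt);
amino-acid labels are reporting metadata. Splice-site records are retained
(recurrent splice-site substitutions are legitimate selection targets);
consequence only controls which records count as silent for rate
calibration.

**HPV stratification.** A tumor is HPV-positive iff it has strictly more
than 100 viral transcript reads per hundred million (ties negative, reading
"greater than" literally). Optional clinical p16/ISH overrides supersede the
read rule, with provenance recorded. TP53 mutation status is cross-tabulated
as a descriptive check only.

**Signature refitting.** Per-tumor 96-channel spectra (pyrimidine-strand
folding) are refit against a fixed 30-signature catalogue for tumors with
more than 50 SNVs (strict). The fitter is a from-scratch re-implementation
of the forward-selection scheme: each round, every candidate signature's
weight is optimized on its feasible interval by golden-section search with
the others held fixed; the best-improving candidate is accepted; selection
stops when the residual-norm improvement falls below 1e-3. The stop
threshold is applied on the residual norm (not squared error) because
channel fractions are O(1/96): on the squared scale the same threshold would
never admit flat signatures carrying ~10% of mutations. Weights below 0.06
are zeroed and the survivors re-optimized once (then re-thresholded, so no
reported weight sits under the cutoff). Weights are non-negative with sum at
most 1; the residual is reported per tumor. APOBEC presence means any
positive weight on signatures 2 or 13 — effectively ≥ 0.06 given the cutoff.
Tumor clustering uses complete linkage on Euclidean distances between weight
rows, rows pre-sorted by sample id so the tree is input-order independent.

**Context profile and abundance normalization.** The tissue context profile
c is the mean, over eligible tumors, of the signature-reconstructed
(denoised) channel distributions, renormalized; a raw pooled-spectrum
fallback is a config switch (and the automatic fallback when no tumor is
eligible). c is a distribution over *mutations*. To convert it into a
per-site propensity the default divides by the exome-wide count of
(site, alt) pairs per channel (`abundance: exome`): a channel's mutation
share is spread across however many sites can produce it. This choice makes
the rate model the exact inverse of the simulator's generative process —
without it, neutral selection intensities acquire a per-channel bias equal
to the ratio of channel site counts. The literal un-normalized weighting
(`abundance: none`) is retained for comparison.

**Gene-level silent rates.** Silent counts per gene across N tumors follow
count_g ~ Poisson(N·θ·O_g·u_g), u_g ~ Gamma(shape k, mean 1), where O_g is
the gene's synonymous propensity mass under the context profile. θ and k are
fit by method of moments (θ from pooled counts per unit opportunity; 1/k
from excess-Poisson dispersion, truncated at zero to full pooling). The
reported rate is the posterior mean r_g = θO_g(k + count_g)/(k + NθO_g),
always between the pooled prior mean and the per-gene MLE. With zero silent
counts cohort-wide, θ falls back to a configured floor (default 1e-8 per
unit opportunity). Externally computed gene rates (e.g. from a covariate
regression) can be injected verbatim through a TSV. This deliberately
replaces full covariate machinery: on a toy exome there are no covariates to
regress on, and the estimator preserves the property that matters
downstream — shrunken, strictly positive gene-level silent rates.

**Per-site expected frequency.** μ(site, alt) = r_g · w(key) / Σ_syn w(key)
with w the (abundance-normalized) channel propensity; the synonymous changes
anchor the denominator, so Σ_synonymous μ = r_g to machine precision, and
non-synonymous sites inherit the calibration. μ is interpreted per tumor
over the average evolutionary span from tumor initiation to resection; no
separate time parameter exists because it cancels in γ rankings.

**Selection intensity.** Prevalence is computed per stratum (HPV−, HPV+,
pooled over labelled samples), with recurrence (n ≥ 2) evaluated within the
stratum being reported. λ = −ln(1 − p) is the exact inversion of
presence/absence observation of a Poisson mutation stream; λ ≥ p with
equality only at 0, and p = 1 is reported NA (unbounded). γ = λ/μ. The
TCW→TKW comparison (amino-acid-replacement variants only) is a one-sided
Welch t-test on log₁₀ γ — γ spans orders of magnitude, so the raw-scale
option exists but is not the default.

**Attribution and net realized intensity.** For a variant in channel key,
tumor-level attribution is α_j ∝ w_j P_j(key), normalized; the variant-level
α is the componentwise median over carrier tumors with eligible fits,
renormalized to sum 1. Net realized selection intensity uses the pooled γ
with stratum prevalences, exactly the printed weighted-mean formula; per-
signature values for groups {1, 2, 13, 4, 16} plus the remaining 25 sum to
the all-signature total by construction. Note the formula is *not* monotone
in a single stratum's prevalence (it is a p-weighted mean of αγp, so raising
a negligible stratum's prevalence can lower it); it is monotone in α, γ and
under joint prevalence scaling, and the tests pin both facts.

**Cohort-level tests.** Fisher's exact test is computed by full
hypergeometric enumeration (scipy's implementation serves as an independent
cross-check in the tests, not as the implementation); the Wilcoxon rank-sum
test uses the tie-corrected normal approximation; the logistic regression of
HPV status on total APOBEC weight is an IRLS GLM fit with Wald p-values,
with (quasi-)separation detected and reported as NA.

**Kinetics.** Deaminase time courses are fit to
% product = A(1 − e^(−k_obs t)) by nonlinear least squares, initialized
deterministically (A₀ = max product; k₀ from regressing
−ln(1 − product/A₀) on t through the origin over the early phase,
product < 0.9·A₀). Rate uncertainty is the asymptotic standard error from
the curvature of the loss. Estimates are invariant to timepoint order; an
all-zero course or fewer than three timepoints is an error.

## The simulator: what it emulates and what it does not

`simulate_cohort` is the generative inverse of the model above. Per tumor:
signature weights are a Dirichlet draw around the stratum mean
(concentration 30; 0 disables jitter); a passenger count is lognormal;
channels are drawn from the weight-mixed signature distribution (channels
with no matching exome site are dropped and renormalized, with the lost mass
logged); each mutation lands uniformly among exome sites carrying its
channel, at most one substitution per site per tumor. Planted driver sites
are carried independently with probability 1 − e^(−μγ), μ being the site's
true expected frequency under the passenger process. DNV contamination adds
one adjacent SNV pair per affected tumor. Identical seeds give
byte-identical MAF output.

Defaults state the cohort the analysis was designed around: 451 HPV-negative
and 69 HPV-positive tumors; mean APOBEC weights (signatures 2/13) of
0.11/0.13 in HPV-negative and 0.30/0.19 in HPV-positive tumors, with the
rest on the aging, tobacco and 16-like signatures; lognormal passenger
counts with median 150 (σ_log = 0.5), so most tumors clear the >50
eligibility threshold, as in the real cohort. The toy exome is 20 synthetic
genes (ATG + stop, no internal stops, 300–3000 nt), deterministic under its
seed.

Not emulated: clonal structure and subclonal allele fractions, sequencing
error, copy-number and indel events, strand-asymmetric or regional mutation
rate variation, and real human loci (gene names are synthetic). A green
recovery test therefore establishes internal consistency of the estimator
chain under the stated model — not robustness to the artifacts of real
exome data.

The bundled 30-signature catalogue is likewise a synthetic stand-in: its
designed members (1, 2, 13, 4, 16) carry the qualitative character the
analysis relies on (NCG-focused C>T aging; TCW-focused C>T and C>G APOBEC;
broad C>A tobacco; ATN T>C), and the rest are seeded Dirichlet draws. Real
catalogues are sparser and more collinear; refitting error against the real
catalogue will be somewhat larger than the recovery tests suggest.

## Numerical choices and degenerate inputs

* Golden-section search runs 34 bracket contractions (argmin to ~1e-7 of
  the unit interval); the per-candidate objective is an exact quadratic in
  the candidate weight, evaluated in closed form.
* Gamma–Poisson moment estimate of 1/k at or below zero ⇒ k = ∞ (full
  pooling), logged.
* Genes with zero synonymous propensity mass are excluded from rate
  estimation with a warning; μ for their sites is undefined by design.
* A stratum with zero labelled samples reports NaN prevalence/λ/γ rather
  than failing; saturated prevalence (n = N) reports NaN λ with the variant
  excluded from rankings.
* Fisher enumeration treats probability ties with a 1e-7 relative guard,
  matching the convention of standard implementations.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global state.

## Known limitations

* Selection intensities carry no confidence intervals; calibration is
  demonstrated by simulation (neutral cohorts give median γ ≈ 1 at
  recurrent sites; planted drivers with ≥5 expected carriers are recovered
  within ~25% median relative error at N = 1000).
* Recurrence conditioning inflates neutral γ slightly above 1 (winner's
  curse); the effect shrinks with cohort size.
* The empirical-Bayes rate model shares one dispersion parameter across all
  genes and ignores covariates; inject external rates where a richer model
  is available.
* Attribution α is a median over carriers and is undefined for variants
  whose carriers all lack eligible signature fits; such variants are absent
  from the net-realized table.
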