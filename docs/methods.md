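# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic studies, and the numerical and design
choices made where more than one reasonable option existed.

## Dominance scoring

Every free-association response is classified by up to two raters against
a word's 2–5 candidate senses, or marked OTHER when it fits multiple,
undifferentiable, or none of them. The tally counts *ratings*, not
responses: a response both raters assign to sense A contributes 2 to A,
and a disagreement contributes 1 to each rater's sense. OTHER ratings are
excluded from both the counts and the denominator, so percentages are
taken over ratings aligned with some selected sense. When one rater
assigns a sense and the other marks OTHER, the sense rating counts and the
OTHER does not — the tally-of-ratings reading applied consistently; this
is the one place the counting rule is genuinely underdetermined, and the
choice is worth a sensitivity check on real data.

With p₁ ≥ p₂ the top-two sense proportions, D = (p₁ − p₂)/p₁. D = 0 iff
p₁ = p₂ and D = 1 iff p₂ = 0; ties between equally frequent senses break
toward the lower sense index, which cannot change D. Words with no
classified ratings raise an explicit empty-tally signal and are skipped by
the table builder rather than scored. Reported proportions and scores are
rounded half-up to 3 decimals.

Dual-rater reliability reports coverage (share of responses with a
non-OTHER label from both raters) and consistency (share of double-labeled
responses whose labels match); consistency is undefined, and signaled,
when nothing is double-labeled. The procedure assumes exactly two raters
and refuses more.

## Similarity analysis

Participant exclusion interprets the flatness rule as an absolute
difference: a rater is dropped when |mean(Homonym) − mean(Unambiguous)| ≤
0.5. With only two values, a literal variance would halve the scale of the
rule while measuring the same thing; the spread reading matches the rule's
purpose of catching raters who ignore item type. Incompleteness and
externally adjudicated exclusions are configurable because no formula
defines them.

Item statistics use the sample SD (n − 1) and SEM = SD/√n. Condition
statistics are computed across item means, not pooled ratings — the
within-item rating SDs are far larger than the published condition SDs, so
the across-item reading is the only consistent one — and the pairwise
contrasts are two-sided Welch t tests (unequal variances across conditions
are the norm here), Bonferroni-corrected by the number of pairs, flagged
at α = 0.01. Whether such contrasts should run on item means or raw
ratings is not fully determined; item means were chosen to match the
across-item condition SDs.

Leave-one-out agreement computes, per participant, Spearman's ρ (average
ranks for ties) between their ratings and the mean rating of the remaining
participants over the items both sides cover; participants with fewer than
3 usable items are dropped from the summary with a warning.

## Encoder metrics

Cosine distance d = 1 − u·v/(‖u‖‖v‖) is computed per layer between the
target word's vector and the anaphor's vector, where a word split into
several subtokens is represented by the unweighted mean of its subtoken
vectors. Surprisal is −log p of the anaphor token at its masked position;
the log base is natural by default with a base-2 option, recorded in the
run manifest (s_e = ln 2 · s₂). Items whose anaphoric expression contains
internal whitespace are filtered out before surprisal is computed, since a
multiword anaphor has no single maskable position. Layer indexing is 1..L;
a static layer 0 is not part of the encoder contract. Per-layer Pearson
correlations with human item means carry 95% CIs from the Fisher z
transform (z ± 1.96/√(n−3)); at |r| ≈ 1 the bounds are clamped to contain
r, which floating-point tanh/arctanh round-tripping does not otherwise
guarantee.

## Mixed-model inference

All models are linear mixed models with a single random intercept for the
anaphoric expression, fitted by maximum likelihood — not REML, because
REML likelihoods are not comparable between models that differ in fixed
effects, and every fit here feeds a likelihood-ratio test. The condition
factor is treatment-coded with the alphabetically first level (Homonym) as
reference, so the intercept estimates that condition's adjusted mean.
Nested models are compared with χ² = 2Δloglik (floored at 0 when optimizer
noise produces a tiny negative difference; tolerance 1e-6) on df equal to
the difference in fixed-effect parameter counts — the 4-level condition
factor contributes 3. p values are Bonferroni-adjusted over the family of
encoder metrics (m = 2 by default). Comparing a model with itself is
defined as the degenerate null result (χ² = 0, df = 0, p = 1); genuinely
non-nested specifications raise.

Numerics: the optimizer tries Powell first, then L-BFGS, then CG,
accepting the first converged fit with a finite likelihood — gradient
methods are unreliable exactly where these analyses often live, at the
zero-variance boundary of the random intercept. Boundary fits are retained
with a "singular fit" warning. A constant response makes the Gaussian ML
likelihood degenerate, so that case returns the closed-form fit (all
coefficients zero apart from an intercept at the constant) with loglik
reported as 0.

## Synthetic studies

The generators exist so the full pipeline is testable end to end; their
defaults are the conditions of the studies they emulate.

*Associate studies.* Each participant contributes two responses per word,
each response's latent sense drawn i.i.d. from the word's mixture. Rater 1
always matches the latent sense; a response is double-labeled with
probability 0.757 (the observed both-rater coverage), and the second rater
agrees with probability 0.949 (the observed consistency), otherwise
picking uniformly among the other senses — the studies report only these
aggregates, so the uniform-disagreement model is the minimal one
consistent with them.

*Rating studies.* True item means are drawn per condition from
Normal(μ_c, σ_c) clamped to [1, 7], with defaults μ = (1.63, 2.57, 4.96,
6.28) and σ = (0.33, 1.14, 1.27, 0.44) for Homonym, Irregular Polyseme,
Regular Polyseme and Unambiguous; 80 items per condition and 88
participants. Individual ratings are integer discretizations
round(clamp(N(m, σ_w), 1, 7)) with within-item SD σ_w = 1.2 — a package
choice, as no per-condition within-item SD is published; it reproduces
single-item SDs near the published 0.9–1.6 range. The latent mean m is
calibrated by a 1-D root find so that the discretized rating's expectation
equals the item mean: naive clamping-and-rounding inflates means near the
scale floor by ~0.2 points, which would make the generator unfaithful to
its own condition means. Planted "flat" raters rate every item near the
scale midpoint (N(4, 0.2), discretized) and are added on top of the
genuine participants.

*Zeugma items and toy encoder.* Generated sentences carry one target-word
span and one anaphor span (0-based, half-open character offsets); the
anaphor is drawn from a small single-word pool, with a configurable
fraction receiving the multiword "a lot" to exercise the filter. Each item
carries a planted sense similarity (`sense_blend` ∈ [0, 1]) drawn from
disjoint per-condition ranges ordered Homonym < Irregular < Regular <
Unambiguous. The toy encoder assigns each (word, layer) a seeded unit
Gaussian vector; for known sentences the anaphor vector is the spherical
interpolation of the target vector toward an orthogonal direction at angle
(1 − blend)·π/2, making the cosine distance exactly 1 − cos(angle) in
every layer — 0 at blend 1, 1 at blend 0, strictly decreasing in blend —
and the masked probability of the planted anaphor rises linearly from 0.02
to 0.98 in the blend, so surprisal falls monotonically. Words longer than
8 characters split deterministically into two subtokens to exercise the
span-averaging path; unknown tokens raise an out-of-vocabulary error. Each
generator draws from its own tagged RNG stream, so adding one generator to
a script does not perturb another's output.

For the end-to-end pipeline, ratings for the zeugma items themselves are
generated with item mean 1 + 6·blend, so the human ratings and the encoder
geometry are driven by a single latent similarity.

*What the synthetic data does not emulate.* Responses are symbolic tokens
with no English semantics; rater errors are independent across responses;
rating noise is homoscedastic across conditions; and the toy encoder's
sense geometry is noiseless and perfectly monotone. Passing tests
therefore demonstrate that the analysis machinery recovers planted
structure at the studies' sample sizes — not that a pretrained encoder
reproduces the published effect sizes, which requires real model weights
and the deposited norms.

## Pipeline runs and problem sizes

A pipeline run writes every intermediate table plus a manifest (seed,
config hash, package version, exclusion counts) into a directory named by
the config hash. The name deliberately omits a timestamp: re-running an
identical configuration must reproduce the directory byte for byte, and a
timestamp would break that while adding nothing to immutability.

Default pipeline sizes (12 words × 60 norming participants, 20 items per
condition × 40 raters, a 6-layer/48-dimension toy encoder) are chosen so a
full run completes in a few seconds while every statistic retains enough
data to be stable; the statistical conclusions of the synthetic pipeline
are unchanged at the full study sizes, which remain available through the
configs. The null-calibration check of the likelihood-ratio test uses
1000 simulated datasets of 80 observations in 8 groups.

## Known limitations

- No pretrained-encoder adapter ships with the package; any encoder
  implementing the three-method interface can be plugged in, and the
  published encoder-side correlations can only be reproduced with real
  weights and the deposited sentences.
- The mixed models support exactly one random intercept — no random
  slopes or crossed random effects.
- The deposit summarisation (`similarity.summarize_deposit`) expects the
  study's deposited tables to be supplied locally; nothing is downloaded.
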