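# Methods

## The measurement model

`netagree` quantifies how well an inter-agency service network is integrated
by the *agreement* between two parallel surveys: each responding agency rates,
on a 5-point ordinal involvement scale, both its current (**perceived**) and
its ideal (**expected**) level of involvement with every other agency.  The
responses form two square matrices with a fixed orientation: column *j* holds
agency *j*'s own ratings (*self-ratings*), row *i* holds everyone else's
ratings about agency *i* (*group-ratings*), so cell `[i, j]` is agency *j*'s
rating about its involvement with agency *i*.  The diagonal is undefined.

For a target agency X and each partner j ≠ X, four perspectives pair the
ratings:

| perspective | pairing | cells compared |
|---|---|---|
| P1 | group-perceived vs group-expected | `(perceived[X,j], expected[X,j])` |
| P2 | self-perceived vs group-expected | `(perceived[j,X], expected[X,j])` |
| P3 | group-perceived vs self-expected | `(perceived[X,j], expected[j,X])` |
| P4 | self-perceived vs self-expected | `(perceived[j,X], expected[j,X])` |

A pair is *valid* when both members are observed and *agreed* when they are
exactly equal; the integration score is agreed/valid.  Missing members are
dropped pairwise — no imputation — which reproduces the survey's structural
asymmetry: an agency that returned no questionnaire has no self-ratings
(empty column) and therefore no P2–P4, but keeps a P1 computed from the
respondents' ratings about it.

### Modelling choices

* **Exact ordinal equality** defines agreement; no partial credit for
  adjacent categories.  An ordinal tolerance (|difference| ≤ k) is exposed on
  every scoring entry point but defaults to 0.  Exact matching is what makes
  "8 of 10 raters agree" translate literally into an 80% score.
* **Ties in representative averaging** round half away from zero (3.5 → 4);
  "round to the nearest integer" does not pin down the tie rule, so the
  choice is explicit and configurable (`ties="to_even"` gives the IEEE
  alternative).
* **Scale bounds are configurable** (`RatingScale(low, high)`); some
  instruments code the same 5 anchors 0..4 rather than 1..5, and validation
  follows the configured bounds.
* Note one consequence of the pairing rules: if the perceived matrix equals
  the expected matrix cell-for-cell, P1 and P4 are 100% everywhere, but P2
  and P3 compare cell `[j,X]` with cell `[X,j]` and reach 100% only when
  ratings are additionally reciprocal (the matrix equals its transpose).

## Global scores

The network-level score for one perspective summarises the defined agency
scores s₁,…,sₙ (for P2–P4 this is automatically the respondents only):

* **mean** — the arithmetic mean with a normal-approximation interval
  x̄ ± z·sd/√n, clipped to [0, 1].  A t-quantile would be defensible at small
  n; z is used with the quantile configurable through `confidence`.
* **weighted** — inverse-variance weights from a binomial model of each
  score: varᵢ = p̃ᵢ(1−p̃ᵢ)/validᵢ with the shrunken p̃ᵢ = (agreedᵢ+0.5)/(validᵢ+1),
  wᵢ = 1/varᵢ, estimate Σwᵢsᵢ/Σwᵢ, interval ± z·√(1/Σwᵢ).  The shrinkage
  (add 0.5/1, a Jeffreys-style correction) exists only to keep boundary
  scores (0 or 1) from receiving infinite weight; the reported scores
  themselves are never shrunk.  Because the weighted interval reflects the
  modelled within-agency binomial variance rather than the observed
  between-agency spread, it can be narrower or wider than the mean's.
* **bootstrap** — three resampling schemes over the agency scores (the
  agency, not the rating pair, is the unit of analysis):
  * *standard*: B i.i.d. resamples of size n; bias-corrected point
    2x̄ − mean(replicate means); BCa interval.
  * *balanced*: B copies of the score vector concatenated, permuted once,
    split into B consecutive resamples, so each score appears exactly B
    times; this removes the Monte-Carlo part of the bias estimate, and its
    bias-corrected point equals x̄ up to floating-point summation.  BCa
    interval as for the standard scheme.
  * *Bayesian*: flat-Dirichlet weights per replicate, drawn by the
    sorted-uniform-spacings construction; the replicate distribution is a
    posterior for the global score, summarised by its mean and a central
    credibility interval.

  The default B = 40,000; B ≥ 100 is enforced because shorter runs make the
  interval quantiles unstable.  The bias-corrected point is defined as
  2θ̂ − mean(θ*) (not the BCa-median-adjusted value).  All three point
  estimates converge to the sample mean, which is the method's core
  robustness claim and is what the estimator-concordance test verifies.

### BCa construction

z₀ = Φ⁻¹(share of replicate means strictly below the sample mean); the
acceleration a comes from the jackknife over the original agency scores,
a = Σ(m̄−mᵢ)³ / (6·[Σ(m̄−mᵢ)²]^{3/2}) with mᵢ the leave-one-out means.  The
interval endpoints are the empirical (linear-interpolation) quantiles of the
replicate means at Φ(z₀ + (z₀+z_k)/(1−a(z₀+z_k))), z_k = ±Φ⁻¹((1+c)/2).
Degenerate cases: a constant replicate set returns a point interval; when
every replicate mean falls strictly on one side of the sample mean, z₀ is
unidentified and the central percentile interval is returned with a logged
warning.  Seeds feed `numpy.random.default_rng`; identical seed and input
give bit-identical replicate vectors, and the multi-method table spawns
independent child seeds per (perspective, method) via `SeedSequence`.

## Synthetic networks

Because real involvement surveys of this kind are confidential, estimators
are validated on generated networks with known truth.

* **independent** model: each off-diagonal cell's expected rating is drawn
  from `rating_distribution` (default uniform over the 5 categories); with
  probability θ (`agreement_prob`) the perceived rating equals it, otherwise
  it is uniform over the remaining categories (no ordinal-distance
  weighting — the simplest null).  Cells are independent, so same-cell
  agreement (P1, P4) is exactly θ and cross-cell agreement (P2, P3) is
  Σₖ q_k p_k with q the perceived marginal q_k = θp_k + (1−θ)(1−p_k)/4.
* **consensus** model: each unordered dyad carries a latent true rating; all
  four observed values touching the dyad report it with probability
  1 − `consensus_noise`, else a uniform other category.  Every perspective
  then has agreement (1−ε)² + ε²/4.
* **non-response** is independent Bernoulli per agency at 1 − `response_rate`
  (not informative); presets 0.89 and 0.64 mirror response rates observed in
  the motivating two-county survey.  Defaults (n = 30 agencies, θ = 0.6,
  uniform categories) match the scale and the mid-range agreement levels of
  those surveys.

`expected_scores` enumerates the generative joint distribution on the 5×5
category lattice and returns the exact per-perspective agreement — the
oracle for parameter-recovery tests.  What the generator does **not**
emulate: sector structure, reciprocity correlation between the two sides of
a dyad (independent model), informative non-response, halo/end-aversion
response styles.  Passing recovery tests therefore show the estimators are
correct under the stated sampling model, not that real surveys satisfy it.

## Presentation

Tables print whole-number percentages (half away from zero) per the field's
reporting convention; JSON/CSV global tables carry one decimal.  Figures are
strict views of computed scores.  The integration-area diagram sorts
agencies by score into equal-width bars inside the unit box, so the filled
fraction equals the mean score *exactly* — this is checked by a polygon-area
oracle — and the blank remainder is the integration gap.  The spider plot
draws P1–P4 on four radial axes (0–100%); undefined perspectives appear as
gaps, and a fully integrated agency draws the complete diamond.

## Problem sizes in the test suite

The suite runs desk-scale: worked examples at n = 4 and n = 11, oracle
equivalence on 200 random 3–6 agency networks, estimator concordance on one
30-agency network at B = 40,000 versus B = 500, and interval coverage over
100 seeded repetitions at B = 10,000 — sizes chosen so the full suite
completes in seconds while still exercising every estimator at its default
or published replicate count.

## Known limitations

* Percentage agreement is not chance-corrected (no kappa); two networks with
  different rating-marginal entropy are not directly comparable on chance
  grounds.
* Normal-approximation intervals on small networks (n < ~15 defined scores)
  are rough; prefer the bootstrap intervals there.
* The weighted estimator assumes within-agency binomial sampling of
  agreement counts, which ignores any dependence between an agency's pairs.
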