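# Methods

## Scope

`sociorank` analyses the social dynamics of a confined cattle herd observed
over two periods (pre- and post-castration). The raw material is a
long-format log of dyadic interactions coded against a four-behavior
ethogram — three agonistic behaviors (mount, fight, headbutt) and one
affiliative behavior (head-play) — each event naming an author and a
receptor. From these logs the package builds directed weighted interaction
networks, extracts a graph- and node-level parameter panel, ranks animals
by the balance index, quantifies pre/post rank changes, and runs the
inferential layer (Wilcoxon tests, logistic regression, Spearman
correlation, PCA). A synthetic-herd generator with a planted dominance
hierarchy makes every stage testable without animal data.

## Networks

One simple directed graph is built per behavioral category and period.
Repeated events between the same ordered pair collapse onto a single edge
whose weight is the interaction count. Two counting conventions coexist by
design:

* **graph-level structure** (connections, density, the
  mutual/asymmetric/null dyad census, reciprocity = 2·mutual/E) counts
  distinct ordered pairs — these quantities obey the exact identities
  mutual + asym + null = n(n−1)/2 and 2·mutual + asym = E, which the test
  suite asserts on every generated graph;
* **node-level degrees** are weighted strengths — total interaction counts
  received (IN), authored (OUT) and both (ALL).

**Active-node convention.** A network contains only animals with at least
one event in that category × period; density is E/(n(n−1)) over the active
count n. This is how edge-list-driven graph construction behaves, and it is
the only convention under which a published panel with 51 affiliative edges
and density 0.39 on a 14-animal roster is internally consistent (12 active
animals). Full-roster graphs are available via `active_only=False`; the
pipeline re-expands node metrics over the full roster (inactive animals
score 0) when pairing periods.

**Path metrics.** Betweenness is unnormalised Brandes accumulation (all
shortest paths counted); closeness(v) = 1/Σ_u d(v,u) with every unreachable
target contributing a substitute distance of n, the legacy convention of
common network toolkits on disconnected digraphs (configurable); the
diameter is the longest finite directed shortest-path length. The default
edge distance is the raw count (`weight_as_distance`), because fractional
betweenness values in herd panels indicate weighted shortest paths;
`unweighted` and `inverse_weight` (more interactions = closer) modes are
exposed, since count-as-distance is semantically debatable. All three are
checked against a brute-force min-plus/path-counting oracle.

**Hub and authority scores** ("Authors"/"Receptors") come from a
mutually-reinforcing power iteration on the weighted adjacency A:
authority ∝ Aᵀ·hub, hub ∝ A·authority, each vector rescaled so its maximum
is 1, iterated to tolerance 1e−12 (cap 1000 iterations, error on
non-convergence). Scores are invariant to uniform rescaling of all weights;
values below 1e−15 are reported as 0 in display output (they are numerical
zeros of the iteration). The fixed point equals the dominant eigenvector of
A·Aᵀ (hub) / Aᵀ·A (authority) whenever that eigenvalue is simple; with a
degenerate dominant eigenvalue (possible in small symmetric components) the
iterate depends on the uniform start, which the tests respect by filtering
degenerate draws.

## Hierarchy

The **balance index** of an animal is

    BI = [(IN_aff + F1) / (IN_ag + F2)] / [(OUT_aff + F1) / (OUT_ag + F2)],

with correction factors F1 = 0.005 and F2 = 0.001 keeping the ratio finite
when a behavior never occurred (an animal with no interactions scores
exactly F1/F2 / (F1/F2) = 1). The IN/OUT terms are weighted strengths
(interaction frequencies) taken from the full-roster count matrices, so
inactive animals are still scored and ranked. A classically dominant animal
— authoring agonistic acts, receiving affiliative ones — obtains a large
BI; **rank 1 therefore goes to the largest BI**. Ties are broken by stable
animal-id order and flagged rather than silently resolved.

The **rank delta** is rank_pre − rank_post, so an animal that ascends the
hierarchy has a positive delta. Delta = 0 is grouped with the negative sign
("did not ascend") for the dichotomous outcome, and its occurrence is
logged. Note one consequence: an animal that holds rank 1 in both periods
cannot ascend and is coded as a non-ascender.

Average daily gain is ADG = (Wf − Wi)/d in kg/day (negative values are
legitimate: the study herd lost weight on a maintenance diet before
surgery). Plasma testosterone below the assay sensitivity of 3.9 pg/mL is
reported at the floor; all post-castration samples are non-detects, so the
censored post-period median is exactly 3.90.

## Inference

All variables are treated as non-normal. Conventions:

* **paired Wilcoxon** (pre vs post): zero differences dropped (count
  reported), tied |differences| mid-ranked. The null distribution is exact
  — by the standard tie-free recursion up to n = 25, or by full enumeration
  of all 2ⁿ sign patterns of the midranks up to n = 14 when ties are
  present — otherwise a continuity-corrected normal approximation is used.
* **unpaired Wilcoxon** (rank-sum): exact enumeration for tie-free pooled
  samples up to 50 observations, otherwise the tie- and
  continuity-corrected normal approximation.
* **Spearman**: mid-ranks for ties, p from the t approximation on n − 2
  degrees of freedom.
* **logistic regression**: binomial GLM with logit link fitted by IRLS
  (deviance tolerance 1e−8, 25-iteration cap; statsmodels backend), Wald
  standard errors from the inverse information. Outcome coding: 1 =
  downgraded (delta non-positive), 0 = ascended — this makes a harmful
  inflammation effect a positive coefficient. A constant outcome or
  rank-deficient design raises an error naming the offending terms;
  quasi-complete separation (all fitted probabilities at 0/1) is flagged.
* **permutation score test**: at herd size n = 14 with five parameters, no
  asymptotic single-term test is calibrated — in Monte-Carlo null
  experiments the Wald test rejects ~0% (the Hauck–Donner effect: near
  separation the standard error outgrows the estimate), the likelihood
  ratio ~20% and the Rao score test ~10% at nominal 5%. The recovery
  report therefore decides significance by permuting the inflammation
  column and comparing Rao score statistics evaluated at the reduced-model
  fit (no refitting needed): under the null of joint independence the
  permutation distribution is exact at any sample size. The Wald summary
  is still reported, since it is what the standard GLM output prints.
* **PCA**: listwise deletion (reported), variables standardized to zero
  mean and unit variance before the eigen-decomposition (testosterone is
  measured in thousands of pg/mL and would otherwise own the first
  component; covariance mode is available behind a flag), loadings signed
  so each component's largest-magnitude loading is positive. Zero-variance
  variables raise an error naming them; the pipeline pre-drops constant
  columns with a log note.

**Pipeline order.** Aggregation → four networks → parameter panels → BI →
rankings → deltas → paired Wilcoxon period comparisons → per-period
logistic models (pre: weight, ADG, testosterone; post: weight, ADG,
inflammation score, surgery order; "weight" is the last weight of the
period) → Spearman(delta, inflammation) **only if** the inflammation term
is significant at α = 0.05 (gate overridable with `force_spearman`) →
unpaired Wilcoxon on post-ADG by delta sign → joint PCA over both periods
with period labels on the scores. α = 0.05 throughout, configurable. Every
default in effect is echoed to the run log; identical inputs and
configuration produce byte-identical output files.

## Synthetic herd

The generator emulates the study design: 14 bulls, 5 observation sessions
per period, two periods.

* latent dominance θᵢ ~ N(0, 1);
* agonistic counts per ordered pair ~ Poisson(λ_ag · logistic(β(θᵢ − θⱼ)))
  — dominants initiate; behavior labels (mount/fight/headbutt) drawn
  multinomially with proportions (0.15, 0.35, 0.50); downstream analysis
  sums them anyway;
* affiliative counts per unordered pair ~ Poisson(λ_af · exp(−|θᵢ − θⱼ|/τ))
  with a fair-coin direction per event — head-play carries no directional
  dominance meaning;
* post period: inflammation score sᵢ drawn from the prevalence vector
  (7, 4, 2, 1)/14 — seven animals clean, four mild, two moderate, one
  severe, the distribution observed in a 14-bull herd; θ′ᵢ = θᵢ − γ·sᵢ +
  N(0, σ); rates multiplied by ρ_ag, ρ_af.

Defaults: λ_ag = 1.5 and λ_af = 1.0 events/pair/period put the pre-period
networks at the scale of the study herd (agonistic density ≈ 0.5 with
~90–140 events; roughly half as many affiliative edges); ρ_ag = 0.6 and
ρ_af = 0.35 reproduce the observed post-castration reductions (connections
98→61 agonistic, 51→17 affiliative); β = 1.5 and τ = 1.0 give a clear but
not deterministic hierarchy; γ = 1.0 and σ = 0.5 are clear-signal test
values, not biological estimates (no effect-size data exist to calibrate
them). Covariates are drawn at the study herd's scale: last pre-period
weights ~ N(430, 25) kg, pre-period ADG ~ N(−1.8, 1.2) kg/day (maintenance
diet), post-period ADG ~ N(0.5, 0.4), pre-period testosterone
log-normal(8.1, 0.9) pg/mL with all post samples non-detect, surgery in
batches of three. Everything is reproducible bit-for-bit from the seed,
and the planted truth (θ per period, scores, γ) is retained.

**What the generator does not emulate:** within-session temporal dynamics,
winner–loser (Elo-style) rank updating, spatial/pen geometry, seasonal or
diet effects, correlation between testosterone and dominance, and any
feedback from weight or ADG onto behavior. Passing tests therefore
demonstrate that the pipeline recovers structure *of this generative form*;
they say nothing about observational biases of live focal sampling.

## Calibration results and a known limitation

With γ = 0 the permutation test holds its nominal size (≈ 4–5% rejections
over 200 herds). With a strong planted effect (γ = 1.5, σ = 0.2) the
inflammation coefficient is positive in roughly 80–90% of converging fits
— not more, even though substituting the *true* latent ranks for the
BI-derived ranks raises this to ≈ 98%. The shortfall is intrinsic
measurement noise of balance-index ranking at herd-scale interaction
counts: the BI separates hierarchy extremes sharply (the top animal's
IN_ag ≈ 0 and the bottom animal's OUT_ag ≈ 0 produce extreme ratios) but
discriminates mid-ranked animals weakly, because for an animal in the
middle of the hierarchy OUT_ag ≈ IN_ag and the affiliative ratio is
direction noise. Planted-order recovery saturates near Spearman ρ ≈ 0.75
even under a near-deterministic latent hierarchy (β = 8, λ_ag = 12). Users
ranking herds of this size by BI should treat mid-table positions, and
deltas built from them, as noisy.

## Numerical choices

* HITS: tolerance 1e−12, 1000-iteration cap, max-normalisation each sweep.
* Logistic IRLS: deviance tolerance 1e−8, 25 iterations; permutation test:
  999 resamples by default, p = (1 + #{perm ≥ obs})/(n_perm + 1).
* Exact-test size caps: signed-rank 25 (tie-free) / 14 (tied, full 2ⁿ
  enumeration); rank-sum 50 pooled tie-free observations.
* Rounding on export only: 2 decimals for panel/summary tables, 5 for
  model estimates; in-memory values keep full precision.
* Degenerate inputs fail loudly: all-zero count matrices, edgeless graphs,
  constant outcomes, zero-variance PCA variables and mismatched
  animal sets all raise informative errors rather than propagating NaNs.
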