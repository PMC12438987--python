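# Methods

## The model

Each visit yields nine ordinal symptom-domain scores (0–3), obtained from
the 16 QIDS items by taking the maximum over the items of the three
multi-item domains (sleep, appetite/weight, restlessness/agitation; default
item layout: sleep = items 1–4, appetite/weight = 6–9,
restlessness/agitation = 15–16, remaining domains single items — the layout
is configurable) and the single item elsewhere.  The total (0–27) is the sum
of the domains.  The Q-LES-Q-SF context total sums 14 of its 16 items (the
two general-life items, by default the last two, are excluded) and is split
into poor/good at a threshold that is either the sample median (pipeline
default, matching how such cuts are usually derived) or a fixed value
(45 by default when fixed).

A group's symptom network at a phase is a Gaussian graphical model: with
R the Spearman rank-correlation matrix of the n×9 domain matrix and
Ω = R⁻¹, the edge weight is the partial correlation
w_ij = −Ω_ij/√(Ω_ii Ω_jj).  Spearman input is used because the domains are
ordinal; ties get average ranks.  Global connectivity strength is
S = Σ_{i<j} |w_ij| — each unordered pair counted once (counting both
directions would double every S and change no comparison; the convention is
written into every network's output metadata).

Non-positive-definite Spearman matrices are repaired before inversion by
clipping eigenvalues at ε = 1e−6 and re-standardizing to unit diagonal; the
Frobenius repair distance is logged in the network metadata.  Missing data
default to pairwise-complete observations (per-pair effective n recorded);
listwise deletion is available.

Two sensitivity estimators mirror the primary one behind the same
interface: an EBIC-selected graphical lasso
(EBIC = −2ℓ(K) + E·log n + 4γE·log p with ℓ the Gaussian log-likelihood,
E the nonzero upper-triangle edge count, γ = 0.5, a 100-point log-spaced λ
grid from 0.01·λ_max to λ_max), and the nonparametric full (marginal)
Spearman correlation network.

## Trajectory phases

ΔQIDS at week w ∈ {4, 6, 9, 12} is baseline minus week-w total, so
improvement is positive.  The subject's maximum change is the Δ largest in
absolute value (ties broken toward the earliest week, which maximizes the
post-change observation window); the visit attaining it is the post-change
phase and its schedule predecessor (4→0, 6→4, 9→6, 12→9) the change phase.
A subject enters the analysis only with QIDS data at their change week.
Subjects are binned by |max Δ| into two-unit groups with ≥16 merged into the
top bin; worsening subjects are binned by magnitude unless
`improvement_only` excludes them.  Responders achieve ≥50% reduction from a
positive baseline at any visit.

## The permutation comparison test

The strength difference between two groups is tested by pooling subjects,
relabelling them at random n_perm times (default 1000) preserving group
sizes, re-estimating both networks with the same estimator as the observed
ones, and comparing |ΔS| to its permutation distribution with the add-one
two-sided p = (1 + #{|ΔS*| ≥ |ΔS|})/(1 + n_perm).  The pooled rows are
sorted canonically and the smaller group drawn first, so the p-value is
exactly invariant to the order of the two samples given the seed.

## Group-level statistics

The strength series (one row per group: strengths at the three phases, mean
ΔQIDS, mean severity per phase) feeds: Spearman correlations — exact
two-sided p by full enumeration of rank permutations when n ≤ 10 without
ties, the t-approximation otherwise; a one-way repeated-measures ANOVA of
strength with group as the repeated unit and phase as the within factor
(df = (t−1), (t−1)(g−1), i.e. (2, 14) for 8 groups × 3 phases); Bonferroni
paired t-tests for the three phase pairs; and the Fisher r-to-z comparison
of two correlations, implemented in its independent-samples form.  The two
compared correlations share the same groups, so they are in truth
dependent; the dependent-correlations correction needs cross-correlations
that a group-level summary does not carry, so the independent form is the
declared default and this limitation is noted here.  Phase severity is the
group mean QIDS total at each member's assigned phase week — the mean is a
declared choice, recorded in the report provenance.  Group-level
correlations are unweighted (each group one point).

## The synthetic cohort generator

The generator is the package's testbed: it emulates the structure of a
large naturalistic antidepressant cohort (≈8 groups × 350 subjects, visits
at weeks 0/4/6/9/12) with fully known ground truth.

**Ground-truth networks.**  A true network draws a random edge pattern at
density 0.25 (9 of 36 edges — sparse networks both match the psychometric
literature and keep per-edge weights above the sampling-noise floor at
n = 350), weights with 80% positive signs (symptom networks are
predominantly positive), rescaled so Σ|w| hits the target strength exactly;
the precision matrix is I − W, patterns that are not positive definite are
redrawn, and its standardized inverse is the latent correlation matrix, so
the partial correlations of the emitted matrix equal W to numerical
precision.

**Ordinal data.**  Visits are Gaussian copula draws: latent multivariate
normal with the phase network's correlation matrix, shifted by a severity
mean and cut at per-item thresholds (default −1, 0, 1) into 0–3 scores.
The severity mean for a target total is found by inverting
E[total](μ) = Σ_k Φ(μ − t_k)·9 on a grid.  Domain scores are emitted as
16-item responses whose max-consolidation reproduces them exactly (the
first item of each domain carries the score, the rest draw ≤ it).

**Study conditions (defaults).**  True baseline strengths decrease linearly
2.4 → 1.0 across the eight groups while intended change magnitudes increase
0.5 → 19 (bin centers; the top group spans its 16–24 bin with sd 2.8,
others sd 1.2) — the built-in plasticity gradient.  Baseline severity rises
with change magnitude (target totals 12.3 → 23.4), giving the larger-change
groups the headroom their change requires, as in the real cohort.
Change-phase and post-change networks are stronger than baseline by
0.2 + 1.2·(target/20), so the strength rise scales with change.  The latent
severity trajectory peaks at week 9 (fractions 0.45/0.7/1.0/0.8 of the
subject's change at weeks 4/6/9/12); week-0 and week-4 visits draw from the
baseline network, week-6 from the change network, weeks 9 and 12 from the
post-change network, so a subject peaking at the intended week contributes
change-network data at their change week.  A context class (good with
probability 0.5, consistent with the emitted Q-LES-Q-SF total around the
45 cut) multiplies the week-12 fraction by 1.15 (good) or divides it
(poor) — the context-by-plasticity moderation of the final outcome.  All
effects switch off in `null_config()` for null testing.

**Within-subject structure.**  Two mechanisms give scores realistic
within-subject stability without disturbing the cross-sectional networks:
(i) at baseline, a per-subject trait (a latent offset common to all nine
domains, variance τ² chosen per group as the largest value keeping
R − τ²·J positive definite, capped at 0.45) is added to the mean while the
visit noise uses R − τ²·J, so the between-subject covariance is exactly R;
(ii) follow-up severity targets anchor to the subject's *realized* baseline
total (clinical change is relative to one's own starting severity), which
makes ΔQIDS independent of the baseline measurement noise — re-binning
subjects by realized ΔQIDS then neither distorts the baseline networks by
selection nor leaks subjects across bins more than the follow-up noise
requires.  The anchored mean spread approximately replaces the trait
variance at follow-up visits.

**What the generator does not emulate.**  Real item-level heterogeneity
(all items share thresholds), dropout beyond complete schedules, treatment
arms, and individual-level network dynamics.  Passing tests therefore show
that the pipeline recovers structure *of this kind* — group-level
cross-sectional GGMs under ordinal thresholding — not that it would recover
every feature of clinical data.

## Numerical and scale notes

Ordinal thresholding attenuates Spearman correlations (more severely in
near-ceiling groups), and the absolute-value sum makes estimated strength
biased upward by roughly E|noise| per true-zero edge (≈ 1.1/√n per edge).
Consequently absolute strengths are not comparable to the generating
values, and group comparisons are meaningful as ranks; recovery checks in
the test suite are therefore rank- and monotonicity-based, with the
parameter-recovery benchmark aggregating per-group strengths as medians
over 20 generator seeds (problem size: 8 groups × 350 subjects per seed) to
average out the ≈0.2 sampling sd of a single strength estimate.  The same
small-sample bias varies with realized bin size when subjects are re-binned
by their observed change, which caps the achievable magnitude of the
bin-level strength-vs-change correlation in a single run; the end-to-end
checks assert the sign pattern of the full report and the quantitative
gradient at generator-group level.

Permutation-test simulations use 500 same-model replicates (n = 500 per
arm, 200 permutations) for type-I calibration and 25 replicates for power —
sizes chosen so the whole suite runs in a few minutes on one CPU.

Other numerical choices: eigenvalue-clip PD repair at 1e−6; glasso edges
below the solver tolerance (1e−6) treated as absent; strength-test p-values
have resolution 1/(n_perm + 1); exact Spearman p switches to asymptotic at
n > 10 or any tie; random substreams are spawned per group from the master
seed, so any group's data is reproducible in isolation.

## Known limitations

- The Fisher-Z comparison ignores the dependence of the two correlations
  (see above).
- Strength magnitudes are estimator- and n-dependent; only comparisons
  under a common estimator and similar n are interpretable.
- The unregularized GGM is the primary estimator; for small groups its
  strength is noticeably inflated, and the glasso variant trades that bias
  for selection variability.
- When the maximum change occurs at week 4 the change phase is baseline
  (week 0), making the group's change-phase network partly coincide with
  its baseline network; such subjects are a small minority under the
  default conditions but the coincidence is inherent to the phase
  definition.
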