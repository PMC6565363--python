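# Methods

This note records the models, the numerical choices, what the synthetic
data do and do not emulate, and the design decisions taken where more
than one reasonable implementation existed.

## Behavioral models and fitting

Subjective value is hyperbolic for delayed offers, `SV = R / (1 + k·t)`
(R in dollars, t in days, k in 1/days), and prospect-theoretic for risky
offers, `SV = P · R^α` (gains only; no probability weighting or loss
aversion).  Choice is softmax on the SV difference with inverse
temperature β ≥ 0 (inverse value units); β = 0 is random choice.  Each
family forms four variants: {1, 2} value parameters × {1, 2} noise
parameters, where "2" means separate self/other parameters selected by
each trial's agent condition.

Maximum likelihood minimizes the negative log likelihood with
Nelder–Mead over log-transformed parameters, which enforces positivity
without constrained optimization.  Settings and rationale:

- **Multi-start**: 10 restarts (default) from scrambled-Sobol points in
  log space over k ∈ [10⁻³, 1], α ∈ [0.2, 2], β ∈ [10⁻², 10] — wide
  enough to bracket human-plausible values; the lowest negLL wins.
- **Probability floor**: per-trial choice probabilities are clipped to
  [10⁻¹⁰, 1 − 10⁻¹⁰] before the log, so perfectly separated data (an
  agent who always takes a dominant option) yield a finite optimum.
- **β cap**: the inverse temperature is capped at 10³ inverse dollars.
  Note that at perfect separation the clipped likelihood plateaus (log p
  underflows to 0) at β well below the cap, so the fitted β lands on
  that plateau rather than exactly at the bound; the fitted choice rule
  is identical anywhere on the plateau.
- **Convergence**: simplex function/parameter tolerance 10⁻⁶, at most
  2000 iterations per restart.
- **BIC** uses the natural log and counts only usable trials (dummy and
  error trials excluded) as n.  The Bayes-factor approximation is
  `exp(ΔBIC/2)`, the standard BIC-based approximation; cohort-level
  selection sums BIC over subjects and breaks exact ties toward fewer
  free parameters.

## Value metrics

Relative subjective value (RSV) = SV(chosen) − SV(unchosen), computed
*online* (with the parameters of the agent being decided for) or
*offline* (with the opposite agent's parameters, the "chosen" option
redefined as that parameter set's argmax, so offline RSV ≥ 0; ties
designate the sooner/likelier option, a documented deterministic rule).
Offline values are undefined under shared-value variants and raise.

The median split labels trials strictly above/below the median as
high/low; records tied at the median are assigned in trial order,
first topping up whichever class is smaller and then alternating, which
bounds the class-size difference by one — important because the decoder
downsamples to the minority class.  SV ties are excluded from the
choice-consistency denominator (the proportion is then invariant to any
strictly monotone SV rescaling).  RT comparisons use raw response times
and the two-sided Wilcoxon signed-rank test (normal approximation,
zero-drop, mid-ranks; the z is signed so positive means the first
vector is larger); an exhaustive sign-flip oracle in the tests confirms
the approximation on small vectors.

## Trial-set engineering

The designer draws candidate option pairs on a discrete grid (cents,
whole days, whole percent; delays proposed log-uniformly because short
delays carry most of the discounting information) and rejection-samples
them into per-trial targets.  Each of the 240 trials is assigned to one
of four cells — (self-high, other-high), (self-high, other-low), (…) —
in equal quotas, and within its cell to an independent uniform target
pair (|ΔSV|_self, |ΔSV|_other) inside the low band (0.2–1.2 $) or high
band (6–14 $), matched within a tolerance that relaxes (never beyond
the band) as the candidate budget is consumed.  Independent targets
decorrelate the two agents' value differences both between and within
cells; the returned set is re-measured (Spearman |r| ≤ 0.2 by default,
consistent with realized correlations of ~0.15–0.19 in comparable
designs; high/low mean separation ≥ 400%, measured as
(mean_high − mean_low)/mean_low on a sorted-half split) and the
generator retries up to three times before failing with its best
diagnostics.  Identical self/other preferences make the cross cells
unreachable and correctly raise an infeasibility error.

Sessions are assembled as 8 single-condition blocks of 30 scored trials
(120 per agent), alternating Self/Other with the first condition
counterbalanced across subjects, each block opening with one dummy
trial excluded from analysis.  The "15/15 counterbalanced" phrasing of
block composition is resolved as single-condition blocks announced at
block start, consistent with the task structure.

## Decoding

Patterns are mean-centered per trial (across features) by default; a
per-feature-within-training-fold mode is exposed because the direction
of centering is ambiguous in the source description.  Training balances
labels by random downsampling, then fits a logistic model with a pure
quadratic (ridge) penalty chosen from 100 log-spaced strengths spanning
1/C ∈ [10⁻⁴, 10⁴] by stratified inner CV (5-fold by default; ties take
the strongest penalty).  The ridge path is an internal dual-space
Newton solver with an unpenalized intercept, batched across the penalty
grid; it matches scikit-learn's L2 logistic regression to ~10⁻⁷ (a
dual-route test keeps them honest) while being fast enough for
permutation nulls.  The lasso robustness variant (`penalty="lasso"`)
delegates to scikit-learn.

Cross-validation is leave-one-block-out over exactly four blocks (eight
scanner runs map to four CV blocks by consecutive pairing); a classifier
is never trained and tested on the same block.  Cross-agent decoding is
block-paired (train on three blocks of one condition, test on the
held-out block position of the other); cross-task decoding trains on
the full training session because no runs are shared across sessions.
`cv_accuracy(ds)` is literally `cross_decode(ds, ds)`, so the
degenerate call is consistent by construction.

**Empirical null.** Per subject, the full analysis is repeated n_perm
(default 100) times with labels permuted within block — preserving
block label counts so every permuted analysis respects the CV
structure — and the penalty grid is re-selected each time (the
conservative full-pipeline choice).  For a within-condition analysis
the relabeling applies to the session as a whole, i.e. training and
testing labels move together; permuting training labels only, while
testing against the original labels of the same session, breaks the
exchangeability of the observed and permuted accuracies across folds
and demonstrably overdisperses the observed statistic relative to the
null (we measured z-SD ≈ 1.4 on signal-free data before adopting the
coherent relabeling; ≈ 1.0 after).  For cross-decoding only the
training session is relabeled.  The group null draws one permutation
accuracy per subject uniformly and averages, n_boot = 10,000 times; the
one-sided p uses the add-one convention, p = (#{null ≥ obs} + 1)/(n_boot
+ 1), so it is never zero.  Signal-free simulations show the resulting
p-values are approximately uniform and the group null mean sits at 0.5.

## Attitudes

Questionnaire columns are z-scored before PCA (the five instruments
have incommensurate scales; covariance-mode is exposed as a switch).
PC1 loadings are unit-norm and sign-anchored so the psychopathy loading
is positive — higher scores read as more antisocial.  Cross-decoding
accuracies are averaged over directions, then sessions, with partial
availability flagged.  The Spearman correlation uses mid-ranks; its
permutation test shuffles one vector 10,000 times (default) and is
two-sided.

## Synthetic data

Generators are pure functions of (config, seed).  Choices are Bernoulli
draws from the softmax; optional response times follow
`max(0.1, c − d·|ΔSV| + noise)`, so low-RSV trials are slower.  Pattern
datasets plant a linear code: pattern = amplitude·s·w_c + ε with s = ±1
for high/low, amplitude = effect_size × noise SD, ε isotropic Gaussian,
and condition encoding vectors w_c built from a random orthonormal
basis through the PSD square root of the requested Gram matrix, so
pairwise cosine similarities ("code overlap") are exact to machine
precision, including the rank-deficient overlap = 1 case.  Questionnaire
totals follow a one-factor model (psychopathy +, altruism/empathy −,
autism quotient and social phobia near zero) mapped onto plausible
instrument scales.  Cohorts tie each subject's code overlap to the same
latent antisocial factor through a configurable slope (positive by
default, matching the observed direction), which is what makes the
attitude correlation recoverable in sign.

What the generator does **not** emulate: hemodynamics and temporal
autocorrelation (patterns are trial-level estimates by construction),
spatial noise correlations between features, session-to-session drift
in preferences, and questionnaire item-level structure.  Passing tests
therefore certify the statistical machinery — estimator consistency,
CV hygiene, null calibration, sign recovery — not performance on real
BOLD data.

One pragmatic deviation: a session-wide median split can leave a small
block with fewer than two trials of one label, which the decoder's
input contract forbids.  The cohort generator falls back to
per-(agent, block) median splits in that case; at study-scale block
sizes (30 trials) the fallback essentially never triggers.

## Desk-scale test sizes

Defaults everywhere are the study-scale settings (240-trial sessions,
500 features, 100 permutations, 10,000 bootstraps, grid of 100).  The
test suite exercises the same code paths at desk scale, chosen once for
statistical adequacy: parameter recovery uses 200 agents × 240 trials;
variant selection uses 50 cohorts × 20 subjects with 2 optimizer
restarts; null calibration uses 200 signal-free cohorts of 8 subjects
with 16–44 trials each (heterogeneous sizes keep group accuracies off a
coarse lattice and avoid tie inflation of the empirical p), 50
permutations and a degenerate penalty grid (penalty selection is
irrelevant on pure noise); power and attitude-recovery tests use 20
subjects with 16–40 trials per condition and small feature counts.

## Known limitations

- The simplex fit offers no standard errors or hierarchical pooling;
  variants are compared only by BIC.
- The empirical-p machinery is exact per subject but the group
  bootstrap is an approximation whose fidelity grows with the
  permutation count; very small permutation budgets (≲ 20 per subject)
  visibly distort the upper tail.
- The trial-set designer reconstructs the stated design goals; it is a
  search procedure meeting the published constraints, not a replication
  of the original (undescribed) generation code.
- Offline valuation requires agent-specific value parameters and is
  undefined (by design) for shared-parameter fits.
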