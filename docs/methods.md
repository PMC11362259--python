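# Methods

## The problem

Gesture repertoires of great apes are traditionally coded as discrete
*gesture actions* (object shake, big loud scratch, ...). Each observed
token additionally carries categorical *modifiers*: the signaller's body
part, the body part contacted, whether the movement is rhythmically
repeated, and laterality (one limb, both simultaneously, both
alternating). Whether two tokens of the same action but different
modifier profiles are "the same signal" is usually decided ad hoc. This
package implements a systematic split: within each action, latent class
analysis over the modifiers proposes sub-types ("morphs"), hard
constraints keep only sub-types a field worker could re-apply
deterministically, and information-theoretic follow-ups ask whether the
split is worth making — whether morphs predict the signaller's apparent
goal or community better than the undivided action.

## Preprocessing

Fixed order, each step logged in the table's provenance:

1. **Re-lumping pre-split actions.** Coding schemes sometimes encode a
   modifier in the action name (hit vs hitting). A lump map renames such
   actions to a common action and writes the induced modifier value; an
   explicitly coded contradictory value is an error rather than silently
   overwritten.
2. **Action filter** — actions with fewer than `min_action_n = 10` tokens
   are removed; latent class models are unstable below that.
3. **Rare-level consolidation** (within action, per modifier) — unknown
   codes become missing; levels with fewer than `min_level_n = 5` cases
   are pooled into an "other" level, which is itself demoted to missing
   if it stays under the threshold. "Not valid" (the modifier cannot
   apply, e.g. laterality of a head gesture) is kept as a regular level:
   it is informative, and published rule tables contain not-valid-defined
   morphs.
4. **Modifier selection** — a modifier is retained for an action only if
   at least two of its levels occur at least `min_level_n` times (missing
   never counts; not-valid does). Actions retaining no modifier are
   single-morph actions by construction.
5. **Complete cases** — tokens missing a retained modifier are dropped.
   Actions are *not* re-filtered against `min_action_n` afterwards (the
   analysis keeps per-action counts that may fall below 10 after
   removal); a stricter re-filter would only shrink the repertoire.

## Latent class analysis

The retained levels are one-hot coded (one indicator column per
(modifier, level) pair, including "other" and "not valid"). The model is
a K-class mixture of independent Bernoulli indicators. Fitting is EM to a
MAP estimate with symmetric Beta(a, a) smoothing on the indicator
probabilities and Dirichlet(a) on the weights, a = 1.01 — enough to keep
parameters off the 0/1 boundary, deterministic given the restart seed.
`prior_strength = 1.0` switches to plain maximum likelihood (used when
comparing against an independent numerical maximiser, where the MAP
offset would otherwise exceed the comparison tolerance). Convergence:
absolute change of the penalised objective below 1e-6, cap 1000
iterations. Identical rows are compressed to unique combinations with
counts, and all restarts of one K iterate as a single batched EM — both
exact reformulations, not approximations. Restart seeds derive from a
master seed via `SeedSequence([master, K, restart])`, folded to 31 bits.

Model choice: K runs from 1 to the number of distinct observed modifier
combinations, 10 restarts each, best restart by log-likelihood; a
candidate is *eligible* iff its modal assignment maps every observed
combination to exactly one class and every class holds at least
`min_cluster_n = 5` tokens; the eligible candidate with the lowest
BIC = −2 logL + ((K−1) + K·D) ln n wins. K = 1 is always eligible, so the
procedure cannot fail. With modal (argmax-posterior, ties to the lowest
index) assignment the determinism check cannot actually fire — identical
rows always share a class — but it is kept as a guard for any future
sampling-based assignment, and the candidate log records the outcome of
both checks for every K.

### What BIC can and cannot recover here

One-hot blocks are internally dependent (exactly one indicator per
modifier is 1), so the class-conditional independence model is
structurally misspecified — the same violation the original analysis
acknowledges for real modifiers. The practical consequence, visible in
simulation, is that the likelihood gain of an extra class contains a
term *linear in n* from re-absorbing that block dependence, so the BIC
choice is conservative only when the per-class penalty (1 + D) ln n is
large relative to the residual ("halo") noise mass. The synthetic
recovery design below takes this into account; on real data the analyst
should expect occasional "all other cases" classes — published tables
contain exactly such a morph.

## Rule extraction

For each class of an accepted solution we compute, per observed modifier
combination, its probability (share of the class's tokens) and
specificity (share of the combination's tokens in the class). A class
fully covered by combinations of specificity 1 becomes an *explained*
morph: a single combination gives a simple rule, several give a
disjunctive rule; otherwise the morph is *unexplained* ("all other
cases") — retained for entropy analyses, but it never captures new
tokens. Rules are minimised by greedily dropping modifiers whose value
never discriminates the morph from any other observed combination, then
merging alternatives that differ on a single modifier into level
disjunctions; replay of the training tokens verifies the induced
partition is unchanged. Morphs are named `action.index`, 1-based, by
descending support. Assignment of a new token returns the unique
matching explained morph, `UNASSIGNED` when none matches, and an
integrity error if two match (possible only for tokens outside the
observed combinations of a minimised ruleset).

## Value of morphs

* **Entropy + permutation null.** Within each action with ≥ 2 morphs and
  per target (goal, community — analysed independently, no
  multiple-testing correction by default; a Benjamini–Hochberg helper is
  available in `statsmodels` if wanted), tokens with unknown goals are
  removed, the plug-in Shannon entropy (natural log) of the target is
  computed per morph, and target labels are shuffled across the action's
  tokens 1000 times with morph sizes fixed. A morph is significant when
  its observed entropy is strictly below the permuted entropy in at
  least ⌈0.95 · n_perm⌉ permutations; ties count against significance,
  which makes the test slightly conservative (observed false-positive
  share ≈ 4–5% at nominal 5%).
* **Play exclusivity** — morphs whose every known-goal token is play.
* **Missingness check** — Pearson chi-square (no continuity correction)
  on the morphs × goal-known/unknown table, flagged invalid when any
  expected count is below 5, skipped for degenerate tables.
* **Classifier comparison.** A naive Bayes classifier with a single
  categorical predictor (action, or morph) and Laplace smoothing α = 1;
  with one predictor this is argmax over targets of prior × conditional.
  Optional upsampling (on by default for the goal analysis) resamples
  each training fold to target-class balance so minority goals are not
  swamped by the dominant play goal. Evaluation: stratified seeded
  10-fold CV, identical folds for both predictors; token-level accuracy
  (mean over folds) and goal-level accuracy (unweighted mean of pooled
  per-goal recalls). On training data without smoothing or upsampling,
  morph accuracy can never fall below action accuracy (morphs refine
  actions); under CV it can, which is the scientifically interesting
  comparison.

## Synthetic data

The generator emulates the structure of a multi-community chimpanzee
gesture table: per action a token count, applicable modifiers with level
sets, planted morphs (defining combination, mixing weight, goal and
community distributions), within-morph fidelity θ_def (probability of
expressing the defining level per modifier, independently — exactly the
LCA generative assumption; a correlated mode ties the flips together to
probe the independence violation), plus unknown/missing injection.

`paper_like_spec` produces a full-repertoire spec: 61 actions of which
19 are rare (< 10 tokens, removed by preprocessing), heavy-tailed counts
(lognormal, clipped to 10–871, total ≈ 7 900 at scale 1), 1–7 planted
morphs per action, 25 goals with a dominant play-like goal (≈ 31% of
tokens), 5 communities with skewed representation (62/20/7/6/5%).
Planted morphs whose expected support falls below 5 at the requested
scale are dropped from the truth and the weights renormalised.

`planted_action_spec` produces single-action recovery instances. Its
default design places morph j at level j of every modifier ("diagonal"
combinations — a k-ary repetition code, maximal Hamming separation), so
a token with one noisy modifier remains strictly closer to its source
morph than to any other. The modifier count per planted K — (7, 5, 3)
modifiers with (3, 3, 4) levels for K = (2, 3, 4) — sets the one-hot
dimensionality so that the BIC penalty per class dominates the
misspecification term described above; with markedly fewer columns the
criterion absorbs the ~1 − θ_def^M residual noise into a spurious extra
class regardless of how cleanly the true classes separate. This is a
property of the selection procedure worth knowing when interpreting real
splits, not an artefact of the generator. Recovery studies cap the
candidate class count at 10 (noise inflates the raw combination count,
and hence the default K range, far past any plausible solution; BIC
rises monotonically well before the cap).

What the generator does **not** emulate: signaller identity structure
(repeated measures / pseudoreplication), sequential dependencies between
gestures, correlated modifiers by default, or community-specific
repertoires. Passing recovery tests therefore show the estimator chain
is correct under its own assumptions, not that field data satisfy them.

## Numerical and design choices

* Entropy base: natural log everywhere.
* Assignment ties (equal posteriors): lowest class index, logged by the
  candidate record; BIC ties between eligible K: the smaller K.
* Deterministic byte-identical outputs for a fixed config: per-action
  independence, sorted action order, seeded permutations and folds.
* Reserved codes are configurable spellings in the schema; internally
  they are angle-bracketed sentinels disjoint from any field level. A
  declared level always wins over a reserved-code spelling when a cell
  is parsed (a coded body-part level "Other" is not the pooled-other
  category).
* The bundled morph-table transcription records rows whose count/accuracy
  boundary is typographically ambiguous in the printed source in its
  `note` column; tests avoid relying on those counts. Column placement
  of single body-part cells (signaller vs contact) was assigned per
  action by plausibility and is documented in the file header.

## Known limitations

* The LCA assumes class-conditional independence that one-hot blocks
  violate by construction (see above); interpret extra "all other cases"
  classes accordingly.
* Unexplained morphs cannot absorb new tokens; assignment coverage on new
  data is bounded by the explained share of the repertoire.
* No modelling of signaller identity; actions with few signallers can
  yield morphs that reflect individuals rather than signal types.
* Entropy comparisons use the plug-in estimator without small-sample bias
  correction; the permutation null shares the bias, which is why
  significance is assessed against permutations rather than absolute
  entropy values.
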