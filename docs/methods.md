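# Methods

This note documents the models, conventions and design choices behind
toxfunnel, in the spirit of a statistical software methods appendix.

## Descriptor panel

Seven 2D descriptors per molecule, in fixed column order: `logp`,
`drug_likeness`, `amines`, `ligand_efficiency`, `alkyl_amines`,
`aromatic_nitrogens`, `basic_nitrogens`.

**logP.** Crippen atom-contribution logP: every atom is typed against the
published contribution table and contributions are summed (RDKit's
implementation). The method is open and reproducible; other descriptor
packages ship different logP variants, so absolute values are comparable
only within one method. Molecules are renumbered to canonical atom order
before summation so that any SMILES of the same molecule yields a
bit-identical value.

**Drug-likeness.** A fragment-incidence score
S = (Σ scores of matched fragments) / √(number of matched fragments),
0 when nothing matches. Each fragment counts once regardless of
multiplicity. The score functional form is fixed; the fragment-score
table is pluggable. The bundled table has 15 hand-scored fragments and is
demonstrative — large empirical fragment tables used by commercial
descriptor software are proprietary, so absolute values here are not
comparable to theirs. Supply your own table to calibrate.

**Substructure counts.** SMARTS-defined, counting distinct atom sets
(symmetric duplicate matches collapsed), so counts are deterministic and
representation-invariant:

- `amines`: trivalent aliphatic N bonded only to carbon/hydrogen;
  amides, anilines, nitro and N–heteroatom nitrogens excluded.
- `alkyl_amines`: amines whose carbon substituents are all sp3. By
  construction a subset of `amines`.
- `aromatic_nitrogens`: any aromatic N (pyridine- and pyrrole-type).
- `basic_nitrogens`: amine N plus pyridine-type (lone-pair-bearing,
  H-free) aromatic N; pyrrole NH is not basic and is excluded.

The patterns ship as editable configuration because "amine-like" group
definitions differ between descriptor packages; the bundled definitions
are pinned by 20 hand-counted fixture molecules. Counts are of groups,
not of compounds containing them.

**Ligand efficiency.** LE = −ΔG / N_heavy (kcal/mol per heavy atom).
An affinity source is required; without one the cell is missing (NaN),
never zero-filled, and modeling code drops the column rather than impute.

## Feature selection

Point-biserial Pearson correlation (Pearson r of a descriptor against the
0/1 label) drives a two-stage gate with defaults t_target = 0.1 and
t_pair = 0.9:

1. drop descriptors with |r_target| ≤ 0.1 (absolute value: a strong
   negative correlate is informative); constant columns have undefined r
   and are dropped here too;
2. among survivors, process pairs with |r_pair| > 0.9 in descending
   |r_pair|, dropping the member with the lower |r_target| (ties drop the
   later descriptor in registry order) and re-evaluating after each drop.

Processing pairs in descending |r_pair| with re-evaluation makes the
procedure deterministic; a test verifies the kept set against an oracle
that enumerates every possible drop order. Selection is idempotent
(running it on its own output changes nothing).

## Classifier benchmark

Five endpoint datasets (arrhythmia, cardiac failure, heart block,
hypertension, myocardial infarction; label 1 = toxic = positive class
everywhere). Five classifier families with deliberately modest defaults,
all overridable and all recorded in reports:

| algorithm | defaults |
|---|---|
| random forest | 10 trees, √p features per split |
| kNN | k = 5, Euclidean |
| naive Bayes | Gaussian |
| AdaBoost | 50 depth-1 stumps |
| SVM | RBF kernel, C = 1, Platt-calibrated probabilities |

Evaluation is exact leave-one-out: n folds, each sample scored by a model
trained on the other n−1. Descriptors are z-scored with the scaler fitted
on the training fold only, preventing leakage. Held-out probabilities are
thresholded at 0.5 (configurable) into confusion counts; metrics with a
zero denominator are reported as undefined (NaN), never as 0. AUC is the
trapezoidal area under the threshold-swept ROC, which equals the
Mann–Whitney concordance probability with ties counted ½. Single-class
training folds (possible when a class has one member) are scored with the
degenerate class probability where the algorithm tolerates them and are
otherwise skipped with a warning and recorded.

Model suites serialize to a directory (JSON metadata + joblib per
endpoint) and reload bit-stably.

## Safety funnel

Three nested tiers; survivors of one tier enter the next, so survivor
sets satisfy tier3 ⊆ tier2 ⊆ tier1 ⊆ input by construction.

- **Tier 1 (cardiotoxicity).** Default rule: all endpoint models must
  predict non-toxic. This is the conservative reading of a single
  safe/unsafe call derived from five models; a majority rule is available
  in config.
- **Tier 2 (mutagenicity, tumorigenicity, reproductive toxicity)** and
  **Tier 3 (hepatotoxicity, immunotoxicity).** Per-category risk is the
  maximum level (none < low < high) over matched structural alerts. The
  default failure rule is any risk ≠ none; `high_only` is available.

The original tier-2/3 verdicts in this workflow's provenance came from
closed-source predictors. The funnel therefore exposes a predicate
interface: bundled demonstrative SMARTS alert lists (classic literature
toxicophores), user YAML lists, or an external per-compound verdict table
(CSV `compound_id,category,risk`) that replays exported verdicts exactly.
Published survivor counts obtained with those closed tools are not
reproducible with the bundled lists, and no attempt is made to imitate
them; the funnel's correctness is established by construction properties
(nestedness, monotonicity in the alert set, permutation invariance) and
an engineered fixture with known counts.

Compounds whose structures cannot be parsed auto-fail with reason
`uncomputable` and are counted separately from tier failures.

A reference-list evaluation computes the combined-verdict success rate
(percentage of known-toxic compounds flagged by either the cardiotoxicity
models or any auxiliary category, rounded to one decimal). On the bundled
39-compound known-cardiotoxin list the rate is 97.4% (38/39). The bundled
verdict table follows the printed per-compound calls; note the printed
source is internally inconsistent about whether one compound
(grayanotoxin III 6,14-diacetate) was caught by the cardiac models or
only by an auxiliary flag — the combined verdict, and hence the rate, is
the same either way.

## Docking post-processing

Replicate docking runs are aggregated per compound: mean and sample SD
(n−1; SD = 0 for a single run) of the lowest binding energy (LBE), and of
the per-run predicted inhibition constant. The conversion is the
Boltzmann relation Ki = exp(ΔG / RT) with R = 1.98719×10⁻³ kcal/(mol·K)
and T = 298.15 K — the AutoDock4 reporting convention. `ki_mean` is the
mean of per-run Ki values, not the Ki of the mean LBE; the two differ by
Jensen's inequality and the per-run convention is what replicate docking
reports print (it explains why two compounds with the same printed mean
LBE can print different mean Ki).

Because LBE values are typically printed to 3 decimals while Ki SDs can
be tiny, recomputing Ki from a printed mean LBE can land outside one
printed SD even when the arithmetic is exact (a 0.001 kcal/mol rounding
moves Ki by ≈0.17%). The bundled reference table has three such rows;
tests assert one-SD agreement only for the self-consistent rows and <1%
relative agreement for all.

Control ranking sorts by mean LBE descending (weakest binder first) and
calls a compound `weaker_than_positive` iff its mean LBE is strictly
greater than the cardiotoxic control's; ties are conservatively
`not_weaker`.

## Expression and in-vivo analyses

Fold-change tables are consumed as printed signed magnitudes (positive =
up), with no log transform and no magnitude cutoff by default (an
optional |fc| filter exists). Genes absent from any table are excluded
from intersection analyses; nothing is imputed. A gene is *reversely
deregulated* when treatments A and B move it in the same direction and
treatment C moves it oppositely: sign A = sign B = −sign C. The detector
is symmetric in A and B and invariant under a global sign flip.

Event-rate classification: rate = 100·events/n, reported rounded to one
decimal; `within_noise` compares the exact rate strictly against the
threshold (default 10%), the conventional bound below which in-vivo
death/adverse-event rates are attributed to experimental error.

## Synthetic data generator

The generator emulates a labeled descriptor table, not chemistry: each
descriptor gets a latent standard normal mapped through its marginal
(normal for logP ~ N(2.5, 1.5²), drug-likeness ~ N(0, 1), LE ~ N(0.3,
0.1²); Poisson with small rates for the four counts, via the Gaussian
quantile coupling). Requested pairwise collinearity r is injected on the
latent scale as z_b ← r·z_a + √(1−r²)·z_b, which reproduces r exactly for
normal–normal pairs and slightly attenuated through the Poisson map.
Labels are Bernoulli from a logistic model P(toxic) = σ(β₀ + Σ β_d·x_d)
on the raw descriptor values; independent label draws per endpoint. All
randomness flows from one seed through spawned child streams (one for
descriptors, one per endpoint), so adding endpoints never perturbs the
descriptor draw and identical specs are bit-reproducible.

Two named conditions are used throughout the tests: a *strong signal*
condition (β_logP = 2, intercept centring prevalence near ½) under which
feature selection must retain logP and leave-one-out random forest must
reach AUC ≥ 0.85, and a *null* condition (all β = 0) under which mean
LOO AUC over 20 seeds must stay in [0.4, 0.6]. Problem sizes in the test
suite and acceptance script (n = 20 for the fold-by-fold oracle
comparison, n = 300 for signal recovery, 20×n = 100 for null calibration,
100 random libraries for funnel properties) were chosen as the smallest
sizes at which these properties are stable across seeds.

What passing these tests shows — and does not. The generator's labels
come from a well-specified logistic model on exactly the descriptors the
models see; real cardiotoxicity labels are noisier, class-imbalanced and
driven by mechanisms the seven descriptors only partially capture.
Passing therefore validates the machinery (correct LOO accounting, no
leakage, correct rule implementations), not real-world predictive
performance.

## Known limitations

- The bundled drug-likeness fragment table and alert lists are small and
  demonstrative; production use should supply calibrated tables.
- Descriptor values are 2D only; no tautomer or protonation-state
  enumeration is performed before pattern matching.
- The classifier defaults are deliberately modest and not tuned; the
  benchmark reports what it measures rather than optimized performance.
- Fold-change inputs are taken verbatim; the magnitudes in the bundled
  reference table are far larger than typical microarray fold changes,
  which suggests a non-standard unit in the source — users comparing
  against their own data should check units before mixing tables.
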