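# Methods

## The screening model

`pmtscreen` implements a three-step, screening-level hazard assessment for
persistent-mobile-toxic (PMT) and very-persistent-very-mobile (vPvM)
substances.  It is deliberately *not* a weight-of-evidence assessment: each
criterion is decided from a single aggregated quantity against a fixed
regulatory cutoff, and every audit trail carries that caveat.  The steps are
strictly ordered (known list → rules → ML) and each compound is decided by
the first step able to resolve it, so results are independent of roster
order and reproducible from the config snapshot and seed alone.

### Rule engine

| parameter | default | meaning |
| --- | --- | --- |
| `persistence_P_days` | 40 | freshwater DT50 above which a compound is P (days) |
| `persistence_vP_days` | 60 | DT50 above which it is vP (days) |
| `logkoc_M` | 3.0 | log K_oc below which it is M (log10 L/kg) |
| `logkoc_vM` | 2.0 | log K_oc below which it is vM |
| `half_life_aggregation` | median | how multiple DT50 reports collapse to one value |

Cutoffs are exposed in `RuleConfig` so a regulatory update is a config
change, not a code change.  Boundary semantics are strict as the cutoffs are
printed: DT50 of exactly 40 d is not P, log K_oc of exactly 3.0 is not M.

Two aggregation choices were genuinely open and are design decisions of this
package:

* **Half-life aggregation = median** (robust against a single outlier study),
  configurable to `max` for a worst-case reading.
* **log K_oc aggregation = minimum over the reported pH 4–9 values** — the
  most mobile observed speciation.  For ionizable compounds sorption can vary
  by orders of magnitude across this pH window; taking the minimum is the
  water-protective choice for a screening scheme.

Tier combination: PMT requires P∧M∧T; vPvM requires vP∧vM and no toxicity
finding; both can hold at once (reported as `PMT_and_vPvM`).  A definitive
failure of persistence or mobility is negative regardless of the other
criteria.  Toxicity asymmetry matters: flags are presence-only, so "no flag"
is only `not_established` when experimental evidence exists at all, and a
P∧M compound with *unknown* toxicity stays unresolved (it could still be
PMT) while one with toxicity *not established* below the vP∧vM level is
negative.  Which partially-assessed compounds should fall through to the ML
step is not regulated anywhere; the routing rule above (route iff a needed
tier is unknown) is this package's decision.

### Machine-learning screen

A random forest (200 trees, ≤ 64 leaves each, single-threaded, seeded)
predicts one pooled binary outcome — PMT or vPvM or both — from ~210 open
RDKit 2D descriptors.  A pooled positive class was chosen over a multi-class
model because the downstream decision ("flag for follow-up") is the same for
every positive subclass.  Missing descriptor values are median-imputed with
medians fit on the training data and serialized in the model bundle.

Descriptor set notes: the proprietary descriptor packages common in this
literature are replaced by the open RDKit set plus three named descriptors
the analysis keys on: `logP_estimate` (Crippen atom-contribution log P,
standing in for consensus-log-P descriptors), `carbon_fraction` (carbon
atoms over all atoms including hydrogen — the C% convention of
constitutional descriptor families) and `halogen_count`.  Name mapping for
descriptor families referenced in screening work: consensus log P →
`logP_estimate`; C% → `carbon_fraction`; Geary/Moran-style topological
autocorrelations and information indices → the RDKit autocorrelation-flavored
blocks (Chi/Kappa/BCUT/EState/VSA).  Numeric equality with proprietary
implementations is explicitly not claimed.  Two RDKit descriptors are
excluded: `Ipc` (grows exponentially with size, overflows, and makes any
z-scored Euclidean distance meaningless) and `MolLogP` (identical to
`logP_estimate`; a duplicated column would split its attribution).
Descriptors are computed on the canonically renumbered molecule so that any
SMILES spelling of the same structure yields bit-identical vectors
(eigenvalue-based descriptors are atom-order sensitive).

### Applicability domain

Reliability gating uses the Euclidean distance from a query to its nearest
training compound.  Raw descriptors mix units and scales, so distances are
computed in z-scored space (training means and SDs; constant features get
unit spread and thus carry no distance).  The threshold — fixed at training
time and serialized — is

```
threshold = mean + 3 · SD   of within-training 1-NN (excluding self) distances
```

with k and the multiplier configurable.  No standard threshold exists for
this construction; mean + 3·SD is the common outlier convention and is the
package's default.  Distances are computed with a KD-tree that evaluates
squared differences directly, so distance-to-self is exactly zero (the usual
dot-product shortcut produces small spurious self-distances).  Out-of-domain
compounds are never classified — they stay unresolved with the distance
recorded.

### Shapley explanations

No SHAP library is assumed; `pmtscreen.treeshap` computes **exact
interventional Shapley values** for sklearn tree ensembles.  For one
explained compound x and one background sample b, a tree reduces per leaf to
a unanimity-type game ("all x-required path features in the coalition, no
b-required feature in it"), whose Shapley values and pairwise interaction
indices have closed forms; summing over leaves, trees and a background set
gives attributions satisfying additivity *exactly*:
`base + Σφ = model output` to float precision (inputs are cast through
float32 first, mirroring sklearn's internal cast, so the decomposed output
is the model's actual output).  Interaction matrices share the attribution
background; they are symmetric and their rows sum to the per-feature
attributions.  The implementation is validated against brute-force subset
enumeration in the test suite.  The default background is 25 training
samples (seeded); interaction computation is quadratic in path features and
is opt-in.

Global importance is the mean absolute attribution per feature.  Dependence
exports pair each feature value with its attribution and suggest a coloring
feature (the feature most correlated with the residual attribution after
removing the linear trend — a cheap proxy for the strongest interaction
partner, not a Shapley interaction ranking).

## The synthetic data generator

`pmtscreen.simulate` is first-class, tested code: it defines the study
conditions under which the pipeline's guarantees are demonstrated.

**What it emulates.**  A 542-compound roster with origin mix 287 synthetic /
130 natural / 125 undefined (largest-remainder apportionment of fractions
0.530/0.240/0.230); structural families matching the chemical classes
reported from permafrost soils; experimental-property coverage for 25% of
the roster; a known reference list carrying 7 PMT + 4 vPvM + 4 PMT&vPvM
positives (plus 20 evaluated negatives); EF/NER soil concentrations with the
non-extractable pool three orders of magnitude above the extractable one
(log-normal, σ = 1.2, EF location 40 ng/g dw); eight sites across 31.5–38.5°N
with a mild (8%/degree) southward concentration increase.

Structures come from an enumerable **motif grammar** (~680 valid, unique
canonical SMILES): PFAS chains F(CF₂)ₙ-X with polar heads, trialkyl/aryl
phosphates, chlorinated (hydroxy/carboxy) aromatics, small polar halogenated
series (halo acids, alcohols, amides, nitriles, sulfonates), brominated
phenols/anisoles/pyrroles, terpenoid scaffold series, plain aliphatics.  A
grammar guarantees parseable chemistry and controllable fingerprint
signatures.  Every motif appears as a *contiguous series* (chain lengths,
substitution counts) rather than a one-off structure — a deliberate
property: one-off motifs have near-constant fragment descriptors whose
z-scores explode when the variant is absent from a training sample, creating
artificial applicability-domain outliers.

**Ground truth.**  Positive iff `logP_estimate < 2.0` and at least one
halogen — a monotone, descriptor-level rule, so rule screen, classifier and
explanation ranking can all be checked against the same written-down truth.
With the default family mix this plants ≈ 34% positives (realized rate is
recorded per roster in the truth table; all closed-loop checks compare
against the realized rate, not the nominal one).  Positive compounds are
assigned a designated subclass (PMT / vPvM / both) in proportion 7:4:4.
Property evidence is drawn inside the half-life and log K_oc bands implied
by each compound's true class, so at zero label noise the rule screen
recovers the truth exactly on covered compounds; label noise swaps a
compound's evidence-generating class at the configured rate.

**Training sets** lay a deterministic stratified backbone over the grammar
(every ⌈V/n⌉-th variant in grammar order) before random fill.  Consequence:
compounds resampled from the training distribution always have a same-series
neighbor in the training set, so the all-in-domain property holds by
construction rather than by threshold tuning.

**What it does not emulate.**  Real rosters have continuous structural
diversity (the grammar is discrete), no exactly-known truth rule,
correlated and systematically biased experimental evidence, detection-limit
censoring, and origin labels assigned by expert judgement rather than by
motif family.  Passing the closed-loop tests therefore demonstrates that the
pipeline's plumbing, ordering, thresholds and model recover a known signal
under controlled conditions — not that any particular real-world roster
would be screened with this accuracy.  The noncyclic share of positives
(~90% here) is a property of the chain-heavy synthetic grammar, not a
real-world estimate.

## Numerical and reporting conventions

* Problem sizes: roster n = 542, training n = 400, 5-fold CV, SHAP
  background 25 — the full default conditions run in seconds to a minute.
* Dedup key is the canonical SMILES; CAS is a secondary match key only.
  Merged duplicates keep the first id; origin merges with precedence
  synthetic > natural > undefined (the conservative anthropogenic reading).
* Prevalence tables: ties in occurrence counts order by MACCS key number
  ascending; display percentages round to integers (the noncyclic share to
  one decimal) while exact values are retained in machine output.
* Concentration summaries cover positives only; the latitude trend is a
  Spearman rank correlation of site latitude against site total, reported
  descriptively with no significance claim (at 8 sites it has no power).
* Reports are byte-identical across reruns on identical inputs and seed:
  JSON is written with sorted keys and all orderings are deterministic.
* Every stochastic step takes an explicit seed (default 42); derived
  generator streams use fixed small offsets from the master seed.

## Known limitations

* The rule screen trusts the evidence table as given: no quality weighting,
  no inter-study reconciliation beyond the median/min aggregations.
* The toxicity criterion is flag-based; absence of a flag is never evidence
  of safety.
* The AD threshold convention (mean + 3·SD of 1-NN distances) is sensitive
  to training-set redundancy: duplicated training compounds shrink the
  threshold.
* Exact Shapley interaction values scale quadratically with path length and
  background size; the defaults keep them affordable on hundreds, not
  hundreds of thousands, of compounds.
* MACCS keys whose public definitions are placeholders ('?') are computed by
  RDKit's conventions; prevalence oracles in the tests skip them.
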