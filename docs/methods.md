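# Methods

## The cascade

The classifier is a serial composition of one statistical and two
rule-based stages. A molecule first receives a binary call from a
soft-margin C-SVC with RBF kernel trained on 25 scaled descriptors.
Positives are final (**mutagenic**). Negatives pass through two
structural-alert checkpoints: firing any *enhancing* alert relabels the
compound **mutagenic**; otherwise firing any *suspicious* alert labels it
**suspicious**; survivors are **non-mutagenic**. Checkpoint 2 is evaluated
only when checkpoint 1 did not fire, so a compound firing both kinds is
mutagenic via checkpoint 1. Molecules whose structure cannot be parsed or
whose descriptors cannot be computed are **unpredicted** — reported as
such, never defaulted to a class.

Because the checkpoints act only on predicted negatives, they can convert
false negatives into true positives (and true negatives into false
positives) but can never create a new false negative. This gives the
monotone-safety guarantee the design is built around:
FN(min_fn) ≤ FN(max_accuracy) ≤ FN(bare SVM), with the false-positive
ordering reversed. With an empty alert partition the cascade reduces
exactly to the SVM.

## Descriptors

* **E-state.** For heavy atom *i*, the intrinsic state is
  I = ((2/N)²·δv + 1)/δ with N the principal quantum number, δv = valence
  electrons − attached hydrogens, δ = heavy-atom σ-degree. The E-state is
  S_i = I_i + Σ_j (I_i − I_j)/r_ij², r_ij = topological distance + 1,
  summed within the connected fragment (distances are undefined across
  fragments). Perturbations are antisymmetric, so ΣS = ΣI exactly — a
  property test. **Gmin** is min_i S_i. A lone heavy atom has δ = 0,
  outside the definition; we substitute δ = 1 rather than fail the
  compound.
* **idwbar.** With g_k unordered atom pairs at distance k and Wiener number
  W = Σ k·g_k: idwbar = (W·log₂W − Σ g_k·k·log₂k)/W. Several
  distance-information indices exist; we fix this magnitude-based mean
  form (single atoms give 0; multi-fragment inputs use the largest
  fragment, which `standardize()` makes moot).
* **ALOGP.** Additive atom-contribution logP over all atoms including
  hydrogens. We use the Wildman–Crippen refinement of the Ghose–Crippen
  atom typing: it is the atom-additive scheme with published parameters
  and an independent implementation available for cross-checking, and the
  two schemes play the same role in the feature set. The table ships as
  YAML; patterns are tried in order and the first match (on the first
  mapped atom) assigns the type. An atom matched by no type fails the
  descriptor explicitly rather than contributing silently as zero.
* **nrings.** Cyclomatic number bonds − atoms + components: the smallest
  number of bond deletions leaving an acyclic graph.
* **Atom-type counts.** 21 disjoint Kier–Hall-style bonding-environment
  types over C/N/O/S/halogens (e.g. `sCH3`, `aaCH`, `ddsN`), configured in
  YAML. The loader probes a small diverse panel and rejects overlapping
  predicates; atoms matching no type are simply uncounted. The nitro group
  is counted identically in both its charge-separated and pentavalent
  drawn forms. The published 25-descriptor study list is only fully
  specified in its supplementary material, so the exact membership is a
  runtime configuration; the shipped default covers the common
  environments and keeps the 4 + 21 layout.
* **Scaling.** Each training column is divided by its maximum absolute
  value (all-zero columns get factor 1). Factors are fitted on the
  training set only, serialized with the model, and re-applied verbatim at
  prediction time.

## Statistical layer

scikit-learn's libsvm C-SVC, RBF kernel, no class weights — the cascade,
not skewed misclassification costs, is the false-negative tool. Defaults
(C, γ) = (8, 16), the published grid-search optimum for this descriptor
set; `tune_hyperparameters` re-derives a choice by 10-fold cross-validated
accuracy over exponential grids (C ∈ 2^[−5..15], γ ∈ 2^[−15..3]), ties
broken toward smaller C then smaller γ. Cross-validated predictions use
seeded stratified folds; folds degenerating to one class are redrawn a
bounded number of times. Ten folds are used both for tuning and for the
rule-selection predictions.

## Rule selection

Alerts are audited on the cross-validated predicted negatives of the
training set (resubstitution predictions would flatter the SVM and starve
the audit). For each alert: `caught_fn` = true mutagens it matches there,
`generated_fp` = true non-mutagens. The partition is a pure function of
these counts and two knobs:

* `min_support` = 5: an alert firing on fewer than 5 predicted negatives
  is statistically unreliable; it may enter the enhancing set only if the
  source literature reports a nominal 0% false-positive rate for it
  (`literature_fp_rate_zero` in the rulebase).
* `suspicious_floor` = 0.25: a non-enhancing alert is suspicious when it
  still catches ≥ 1 FN and caught_fn ≥ 0.25 × generated_fp.

The published criteria are qualitative ("more FNs caught than FPs
generated", "remarkable removal power but higher misclassification"); the
numeric thresholds above are this package's operationalisation and are
surfaced as CLI flags and recorded in the model bundle. Rules are audited
independently — no joint set-cover optimisation.

## Synthetic data

`synth.generate` emulates the *shape* of a labelled Ames set: ~20 benign
scaffolds (alkanes, benzenes, ethers, esters) joined to either an
alert-bearing fragment (nitroaromatic, aromatic amine, epoxide, alkyl
halide, nitrosamine, hydrazine, aldehyde, azide, mustard) or a benign one.
Defaults: 56% mutagens (the class balance of the classical 4204-compound
benchmark), alert/label correlation 0.9, decoy rate 0.1, fully
reproducible from a seed. Mutagenicity here is assigned by construction,
not by chemistry: passing tests demonstrate the *mechanics* of the cascade
(rule audit arithmetic, monotone safety, FN recovery), not predictive
validity on real chemicals. Real sets have far broader scaffold diversity,
label noise near the assay's ~85% reproducibility, and alert prevalences
the generator does not model.

Evaluation sizes: the synthetic end-to-end check uses n = 1000 with a
stratified 80/20 split; unit tests use 100–400 molecules. Stratification
uses (label × fired-alert profile) as a reproducible proxy for the
functional-group stratification described for the original benchmark,
whose concrete scheme is unpublished.

## Rulebase fidelity

The 30 alerts follow the Benigni/Bossa mutagenicity rulebase (Toxtree
lineage) but the original SMARTS and exception lists are not printed in
the primary source; the shipped transcription is best-effort and
versioned, with per-alert provenance notes. The shipped default partition
(5 enhancing, 1 suspicious) is the outcome of this package's own
rule-selection run on its synthetic fixtures — a format demonstration, not
the published 12/4 assignment, which can be dropped in as a `partition:`
block when available.

## Numerical choices and degenerate inputs

* Distances via sparse BFS shortest paths; E-state perturbations vectorised.
* Multi-fragment inputs: `standardize()` keeps the largest covalent
  fragment; charge states are kept as drawn (no neutralisation pass, so
  charge-separated nitro groups are preserved).
* Unparseable records are carried through every stage flagged, and
  surface as `unpredicted` with their input row intact.
* Statistics with an empty denominator (no positives, reference FN = 0)
  are reported as NaN, never as 0.
* All randomness (splits, CV folds, fixture generation) flows from
  explicit integer seeds.

## Limitations

* Descriptor parity with the original 25-descriptor matrix is approximate:
  the atom-type list and two dropped descriptors live in supplementary
  material, and the original values came from a different toolkit (CDK).
* No applicability-domain estimate and no probability calibration; the
  SVM emits hard labels only.
* The alert SMARTS are a reconstruction; compounds relying on subtle
  exception chemistry (e.g. specific mitigating substituents of aromatic
  amines) may be screened differently than by Toxtree.
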