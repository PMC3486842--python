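# Methods

## Scope and model structure

The package predicts, for a nutrient–organism pair, (i) whether the nutrient
can act as a sole carbon source (G/NG), (ii) the biomass it yields when it
is the only carbon source, and (iii) the biomass produced on a medium with
many carbon sources. The model is phenomenological: it uses no kinetic or
reaction-level detail, only the nutrient's structural class, carbon count,
pathway memberships and composition, plus three organism-level enzyme flags
and the transported-nutrient set. Flux balance analysis on stoichiometric
networks plays the role of the experiment: it generates the labels and
yields the model is trained on and validated against.

Assumptions inherited from that framing: aerobic growth with a fixed
minimal medium that supports no growth by itself; maximal conversion of
carbon into biomass (no growth-rate kinetics, no regulation beyond the
one-sugar rule for media); carbon is the only limiting element considered.

## Classification cascade

Rules fire in a fixed order; the first applicable rule decides.

1. **Uptake gate.** Nutrients outside the organism's transported set are
   NG. Fatty acids bypass the gate: they can enter by membrane diffusion,
   so their fate is decided by enzymes, not transporters.
2. **Class rules.** Cell-boundary compounds and cofactors have cellular
   functions that select against catabolism; inorganic compounds carry no
   usable organic carbon; pyrimidines are consistently not catabolized.
   All four classes are NG. Sugars and sugar derivatives are G.
3. **Purines.** G iff the organism encodes 5-hydroxyisourate hydrolase
   (EC 3.5.2.17), the committed step of urate degradation to glyoxylate.
4. **Fatty acids.** G iff both terminal β-oxidation enzymes are present:
   L-3-hydroxyacyl-CoA dehydrogenase (EC 1.1.1.35) and 3-ketoacyl-CoA
   thiolase (EC 2.3.1.16).
5. **Complex nutrients** of the remaining classes are decomposed into
   simple parts (a recursive expansion over the composition DAG;
   multiplicities multiply through); the parent is G iff at least one part
   classifies G. Parts are classified with the uptake gate skipped, since
   hydrolysis happens intracellularly. Aggregating by "any part G" is a
   design choice, consistent with the yield model counting any
   catabolizable component's carbons.
6. **Logistic rule.** Everything else (amino acids, the derivative classes,
   organic compounds) is scored by the pathway model; G iff P > 0.5, with
   ties resolved to NG because false positives are the dominant error mode
   of pathway-based prediction.

Note one deliberate asymmetry: classes decided at steps 2–3 are decided
*before* decomposition. A cell-boundary lipid containing catabolizable
fatty-acid chains stays NG — no hydrolase exists to release the chains —
and the fixture network generator encodes the same fact by giving
hydrolysis reactions only to nutrients of decomposition-eligible classes.

## Logistic pathway model and selection

The linear predictor is β₀ + Σβₚx_ip + Σβ_pq·x_ip·x_iq over 0/1 pathway
membership indicators. Fitting is maximum likelihood with every coefficient
box-constrained to |β| ≤ 20. The cap exists because pathway indicators
separate easily at small sample sizes (a pathway whose member nutrients are
all G has an infinite MLE); a fit with any coefficient at the cap is
flagged `separated`. The optimizer is L-BFGS-B on the exact negative
log-likelihood and gradient; on non-separated data the result agrees with
an unconstrained IRLS fit to ~1e-4 (checked against statsmodels in the test
suite).

Forward selection starts from the intercept-only model. Each step fits
every candidate term on the full dataset and ranks candidates by balanced
accuracy (mean of TP and TN rates; configurable to raw accuracy):

* **Pathway candidates** are ranked on the nutrients *not yet covered* by a
  previously selected G-type pathway. Pathways overlap heavily, so without
  this exclusion a new candidate earns credit for nutrients an earlier
  pathway already explains. Pathways with no uncovered members are dropped
  from the candidate set. A selected pathway is tagged G-type when more
  than half of its member rows are G.
* **Pair candidates** (membership interactions) are ranked on all rows:
  their purpose is to flip false positives *inside* selected G pathways,
  which are by construction covered.

The top candidate is accepted only if it improves **both** AIC and BIC of
the full fit (k = 1 + P + z parameters, n dataset rows). Requiring both is
deliberate: with capped fits on separable data, redundant terms can shave
the AIC by slightly enlarging margins while the BIC worsens, and a term
supported by only one criterion is weak evidence. When no pathway is
accepted, selection moves to pairs; when no pair is accepted, it stops.
Ties break lexicographically on term name, which also makes the procedure
deterministic for duplicate membership columns.

TP/TN rates use the 0.5 threshold with ties counted NG. The AUC is built by
the ranked-sweep construction — sort nutrients by predicted probability,
walk down the list accumulating the fractions of G and NG seen, trapezoid
area under the resulting curve — with tied probabilities advanced as one
block, which makes it identical to the Mann–Whitney statistic with average
ranks (asserted against scikit-learn on tied fixtures).

## Yield model

For a G nutrient, B_i = y_s · C_i^eff.

* **y_s** (sugar-reference yield) is the unweighted mean of B/C over the
  organism's G sugars — sugars sit at the per-carbon efficiency envelope
  because their hydroxyl groups reduce NAD⁺ during catabolism. All uptaken
  G sugars enter the average. An organism with no G sugars has no
  reference; callers may pass a fallback (the training-set class value),
  otherwise the error says so.
* **Effective carbons**: C for simple non-purines; C − 3 (floored at 0) for
  purines, which leak three carbons as CO₂ and urea when the ring is
  reduced to glyoxylate; for complex nutrients, the sum of effective
  carbons over *catabolizable* simple components with multiplicity
  (nucleoside purines are therefore handled through decomposition: sugar
  part plus base part). A thymidine-like nutrient (C = 10) with a G
  phospho-ribose (C = 5) and an NG thymine contributes 5.
* The model refuses anaerobic organisms: anaerobic energetics change the
  ATP cost of polymerizing biomass and break the aerobic yield envelope the
  sugar reference assumes.

Yield tables record B/(y_s·C) and B/(y_s·C_eff) per nutrient; on fixtures
with partially catabolizable complex nutrients the within-class variance of
the latter is never larger — that reduction is the point of the correction.

## Complex media

B_m = Σ over present G nutrients of y_c·C_eff. Class yields y_c are a
two-level average — the mean per-carbon yield over class members within
each training species, then the mean across species — computed on effective
carbons (which matters for purines and tryptophan-like complex amino acids
and is a no-op otherwise). Media are restricted to sugars, fatty acids,
amino acids, purines and pyrimidines, nucleobases only, with at most one
sugar (glucose), reflecting diauxic repression of secondary sugars.

Ensembles: each eligible nutrient enters a medium independently with
probability p; defaults are 1000 media at each p ∈ {0.1, 0.5, 0.9}.
Validation regresses prediction on FBA measurement through the origin,
K = Σ pred·meas / Σ meas² (unweighted over media), plus the Spearman rank
correlation with average-rank ties. K < 1 means the additive model
under-predicts — the expected signature of synergy between catabolic
pathways sharing the metabolic network.

Numerical choice: before ranking, both series are snapped onto a grid of
1e-8 times their scale. Measurements are LP objectives, so media with
identical true biomass return values equal only to solver tolerance, and
sub-tolerance noise would otherwise scramble rank ties.

## FBA engine

The stoichiometric matrix has one row per reaction and one column per
metabolite; steady state is v·S = 0 with per-reaction bounds, and the LP
maximizes the biomass reaction (scipy's HiGHS solver; feasibility 1e-9,
objective reported to 1e-8; on networks of ≤6 reactions the optimum matches
exhaustive vertex enumeration to 1e-8). Exchange reactions produce their
extracellular metabolite from nothing, so positive flux is uptake and the
medium caps the upper bound; the default carbon-source bound is 10 flux
units (mmol·gDW⁻¹·h⁻¹ by convention). Reversibility is encoded by negative
lower bounds, not by reaction splitting.

A nutrient is G when adding it to the minimal medium lifts biomass flux
above ε = 1e-6 (configurable); a minimal medium that grows by itself is an
error, not a warning. ATP maintenance — the non-growth ATP drain fitted to
empirical growth rates in reconstructions — is removed before labeling by
zeroing the bounds of the reaction matched by an id pattern (ambiguous
matches error; absent maintenance warns). Molar yield is biomass flux per
unit of uptake flux actually used, which is invariant to the bound on a
linear network. A biomass-ATP-coefficient override is not modeled; the
maintenance knob is the id pattern only.

Models interchange as a TSV reaction dialect (id, equation "A + 2 B -> C",
bounds, optional role column marking biomass and exchanges) with an exact
round-trip; SBML reading is optional via cobra.

## Synthetic fixtures

The generator stands in for reconstructions and pathway databases at desk
scale. A catalog of ~44 nutrients spans all twelve classes and includes
fixed complex nutrients with known effective carbons (thymidine-like
nucleotide, tryptophan-like amino acid whose indole moiety is not
catabolizable, lipid-A-like boundary lipid with two fatty-acid chains, one
nested complex) plus seeded random organic compounds carrying pathway
memberships. Five organisms vary the three gating enzymes; one is
anaerobic. Carbon counts stay ≤ 16 so hand arithmetic and brute-force
oracles stay easy.

Planted FBA networks are linear: every catabolizable simple nutrient gets
exchange → transport → a catabolic reaction producing (effective carbons ×
y₀) units of a biomass precursor, complex nutrients of
decomposition-eligible classes get a hydrolysis reaction into their simple
parts, and non-catabolizable parts get secretion drains. By construction
B = y₀·C_eff exactly (default y₀ = 0.1 biomass per carbon per unit flux),
so the yield model's limit behavior is testable to LP tolerance. An
optional synergy reaction converts co-products of two specific chains into
extra precursor, making multi-nutrient media strictly super-additive —
the directional effect the additive media model is expected to
under-predict.

Labeled training tables draw memberships i.i.d. Bernoulli(0.5) over
planted and decoy pathways and labels Bernoulli from the planted logistic
model. The default planted design (β₀ = −1, β_A = +2, β_B = −1,
β_AB = +1.5) keeps all four membership-cell logits within ±2, so every
coefficient is identifiable at moderate n (worst-case Fisher standard
error ≈ 0.23 at n = 2000); coefficient-recovery checks use the
per-coefficient median absolute error over 20 seeded replicates. A
separate deterministic-label dataset plants a two-pathway + one-pair
structure (pwC occurring only inside pwA, labels G iff (A∨B)∧¬(A∧C)) whose
optimal model forward selection must recover; because pwC ⊆ pwA, the
main-effect reparametrization {A, B, C} is an equivalent near-exact AIC
tie, so the brute-force cross-check asserts attainment of the minimal AIC
rather than uniqueness of the argmin.

All fixture randomness flows from one mandatory seed through a single
`numpy` Generator per spec; identical seeds reproduce catalogs, datasets,
ensembles and whole pipeline runs byte for byte.

## What the fixtures do and do not show

Passing tests demonstrate internal consistency: the cascade, yield and
media models exactly recover structure that the fixture networks plant by
construction (100% label agreement, K = 1, ρ = 1 in the zero-synergy
limit). Real reconstructions differ in ways the fixtures deliberately
omit: pathway annotations are noisy and overlapping rather than planted;
per-carbon yields vary within and across classes; catabolic routes share
intermediates, producing the under-prediction (K < 1) seen against real
FBA rather than the clean super-additivity of the planted synergy
reaction; and transporter annotations are incomplete. Fixture-level
exactness therefore validates the machinery, not the biological accuracy
of the rules on any particular species.

## Problem sizes and defaults

| knob | default | meaning |
| --- | --- | --- |
| uptake bound | 10 flux units | carbon-source uptake cap (per-nutrient) |
| ε | 1e-6 | growth-significance threshold on biomass flux |
| coefficient cap | 20 | logistic coefficient magnitude bound under separation |
| threshold | 0.5 | G/NG probability cutoff (ties → NG) |
| y₀ | 0.1 | fixture per-carbon yield |
| ensembles | 1000 media × p ∈ {0.1, 0.5, 0.9} | media validation |
| pipeline ensembles | 200 media per p | `catapot run` default |

The pipeline default of 200 media per p keeps a full run under a few
seconds while leaving the ensemble statistics well resolved; the
acceptance script uses the full 3 × 1000.

## Known limitations

Nitrogen/sulfur/energy-source potential is out of scope, as are growth-rate
kinetics, uptake kinetics, regulation beyond the one-sugar media rule,
minimal-medium prediction, flux variability, and thermodynamic/loopless
constraints. The hydroxyl-group mechanism behind the sugar yield envelope
is not modeled — only the y_s reference it motivates. Multi-copy complex
components are treated identically whether or not each copy's bond is
cleavable.
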