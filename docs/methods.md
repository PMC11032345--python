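# Methods

`acprop` models a protein-level question in kinase drug discovery: why do
some kinases accumulate *activity cliffs* (ACs) — pairs of nearly identical
inhibitors with ≥ 100-fold potency differences — while other kinases with
hundreds of inhibitors show none?  The package treats AC propensity as a
property of the whole protein sequence and builds the complete analysis
chain needed to test that idea, from raw activity tables to validated
classifiers.  This note records the model, the conventions, and the design
choices made where the design was genuinely open.

## Activity curation

Raw tables carry one row per measurement: molecule id, SMILES, kinase id,
Ki (nM), qualifier.  Curation applies, in order:

1. **Censoring.** Only exact Ki values survive; `>`, `<` and `~` qualified
   measurements are excluded.
2. **Replicate aggregation.** Duplicate identical rows are collapsed.
   Replicates of a molecule–kinase pair are combined by geometric mean
   *provided* max/min ≤ 10; otherwise the pair is discarded entirely.
   "Same order of magnitude" is operationalized as the ratio bound with an
   inclusive boundary; whether the bound should instead compare rounded log
   bins is underdetermined, and the ratio form is the natural reading.
3. **Canonicalization.** SMILES are canonicalized (RDKit) at curation time so
   downstream core comparison is string equality.
4. **Type-II filtering.** Kinase inhibitors that require the DFG-out inactive
   conformation (type II) are recognized by signature substructures; any
   molecule matching any SMARTS in the signature list is excluded, leaving a
   type-I population.  The package ships a three-pattern demo list (diaryl
   urea, 3-CF3-benzamide, diaryl thiourea); the full published signature
   set is not distributed and can be supplied as a plain text file.

Potency is expressed as pKi = 9 − log10(Ki/nM).  Curation is idempotent and
produces unique (molecule, kinase) keys.

## MMP mining and activity cliffs

A matched molecular pair (MMP) is two molecules separated by one chemical
transformation: they share a **core of ≥ 10 heavy atoms** and differ by one
terminal **fragment of ≤ 5 heavy atoms** (attachment points not counted).
Detection is by single-cut fragmentation: every acyclic single bond between
heavy atoms is cut, both pieces are canonicalized with a generic `[*]`
attachment marker, and cuts violating either size bound are discarded.
Cores are indexed; molecules sharing a core with different fragments form an
MMP.  Conventions:

* **Hydrogen transforms.** A "hydrogen fragment" is the bare attachment
  marker: for every heavy atom carrying hydrogen, a virtual cut yields the
  whole molecule (with marker) as core.  This makes H→F-style MMPs
  expressible.
* **One pair, one transform.** If a pair is reachable through several shared
  cores, the largest core (smallest transform) wins; ties break
  lexicographically on the fragment pair.  Enumeration order never matters.
* **Cliff call.** `is_cliff ⇔ ΔpKi ≥ 2.0` (at least 100-fold).  The boundary
  is inclusive; boundary cases are measure-zero in practice.

Per kinase, the propensity statistic is **ACs/MMPs% = 100·n_ACs/n_MMPs**,
classified under three schemes (boundaries inclusive):

| scheme  | classes |
|---------|---------|
| default | 0 → No ACs; (0, 1] → Low ACs; > 1 → High ACs |
| A       | 0 → No ACs; > 0 → With ACs |
| B       | as default with the Low/High boundary at 2.59 |

The 2.59 constant is the mean + 1 SD of the ACs/MMPs% values in the bundled
80-kinase survey table (`acprop/data/kinase_ac_survey.csv`); when the
pipeline runs on its own data it recomputes the threshold from the realized
percentages the same way.  Transforms observed in ≥ 2 kinases are
cross-tabulated (AC status per kinase = "any pair is a cliff", since
aggregation over repeated observations is otherwise unspecified) and
labelled `exclusive_AC`, `varying` or `never_AC`.

## Sequence descriptors (9920 features)

Twelve groups are concatenated in fixed order; the total of exactly 9920
named features pins the parameterization (8 autocorrelation scales, 30 lags,
λ = 30):

AAC 20 · dipeptide 400 · tripeptide 8000 · Moreau-Broto 240 · Moran 240 ·
Geary 240 · CTD 147 · conjoint triad 343 · SOCN 60 · QSO 100 · PAAC 50 ·
APAAC 80.

Key formulas (p = property value standardized to zero mean / unit SD over
the 20 amino acids; N = sequence length; d = lag):

* composition: counts over sliding windows divided by N, N−1, N−2;
* Moreau-Broto: AC(d) = Σᵢ p(i)p(i+d)/(N−d);
* Moran: I(d) = [Σᵢ (p(i)−p̄)(p(i+d)−p̄)/(N−d)] / [Σᵢ(p(i)−p̄)²/N];
* Geary: C(d) = [Σᵢ (p(i)−p(i+d))²/(2(N−d))] / [Σᵢ(p(i)−p̄)²/(N−1)];
* CTD: 7 physicochemical attributes × 3-group partitions; composition,
  boundary-crossing transitions, and distribution (position of the first,
  25/50/75/100% occurrence as % of N);
* conjoint triad: 7-class triad frequencies / (N−2);
* SOCN/QSO: τ_d = Σᵢ d(Rᵢ, Rᵢ₊d)² under two residue-distance schemes — a
  physicochemical distance derived from the standardized
  hydrophobicity/hydrophilicity/side-chain-mass triple, and the Grantham
  chemical distance computed from its published composition/polarity/volume
  parameters; QSO weighting 0.1;
* PAAC/APAAC: Chou's pseudo-composition with weight 0.05, λ = 30.

Numerical conventions: Moran and Geary return 0 at every lag when the
property variance over the sequence is zero (homopolymers; the check is
robust to floating-point roundoff).  An empty CTD group contributes five
zero distribution values.  Non-canonical letters (B, J, O, U, X, Z) are
rejected by default; an optional drop mode removes them.  Sequences must be
longer than the maximum lag (30) for the full vector.

Naming: tripeptides are named by their residues (`GTT`), the Moran block by
scale and lag (`CHAM820101.lag6`, `DAYM780201.lag5`) — matching how these
descriptors are usually cited — while Moreau-Broto and Geary carry a kind
prefix to keep all 9920 names unique.  CTD uses `prop{k}.G{g}[.residue{r}]`
with the attribute order hydrophobicity, van der Waals volume, polarity,
polarizability, charge, secondary structure, solvent accessibility (so
`prop5.G2.residue0` is the first-occurrence position of charge-neutral
residues).  The attribute order is fixed and documented here but is a
package convention; other tools may order the seven attributes differently,
so cross-tool comparison should go through the attribute names, not indices.
The eight autocorrelation scales (AAindex: CIDH920105, BHAR880101,
CHAM820101, CHAM820102, CHOC760101, BIGC670101, CHAM810101, DAYM780201) and
all partition/property tables ship as JSON data files.

## Classification and evaluation

Descriptors are the explanatory variables; the propensity class is the
response.  Constant-value columns are dropped at matrix assembly.  The
train/test split is 80/20 by kinase, stratified by class (stratification is
the package's choice — with 64 training kinases over 3 imbalanced classes an
unstratified split can starve a class).

Learners (fixed hyperparameters):

* **Random forest** — 100 trees, entropy criterion.  The reference
  configuration used a gain-ratio splitting criterion that scikit-learn does
  not implement; plain information gain is the closest available setting.
* **Gradient boosting (XGBoost)** — 100 rounds, η = 0.3, γ = 0, depth 6,
  min child weight 1, no subsampling, λ = 1, α = 0.
* **Gaussian Naive Bayes** — per-feature variances floored at (10⁻⁴)²,
  mirroring a 10⁻⁴ probability floor.

Evaluation uses **leave-20%-out cross-validation** (stratified fivefold;
every row predicted exactly once; at n = 64 the fold sizes are
13/13/13/13/12) and a held-out test set.  Metrics are accuracy
(trace of the confusion matrix over N — the binary "TP+TN over N" form
generalized to three classes) and **Cohen's kappa**
κ = (Po − Pe)/(1 − Pe), banded qualitatively (0.41–0.60 moderate,
0.61–0.80 substantial, 0.81–1.00 almost perfect; negative = worse than
random).  Prediction ties resolve to the earlier class in the fixed order
No < Low < High.

## Feature selection and validation

* **Global feature importance (GFI).** A surrogate random forest is trained
  to reproduce (overfit) the fitted model's predictions; feature score =
  Σ 1/(1+level) over all splits on that feature in all surrogate trees.  The
  1/(1+level) weight is this package's concrete reading of "split count and
  level"; whether the reference tallies were depth-weighted or plain sums is
  not stated.  Features scoring > 0 are retained; the GA candidate set is
  capped at the top 180 by score, matching the scale at which the original
  analysis retained impactful descriptors.
* **GA wrapper selection.** Binary chromosomes over the candidates; fitness
  is the CV kappa of the wrapped learner on the selected subset.  Operators
  (unspecified in the reference workflow, standard wrapper-GA choices here,
  all exposed in config): tournament selection (size 3), uniform crossover
  (rate 0.9), per-bit mutation 1/L, elitism 1, early stop after 50 stagnant
  generations.  Full-scale budget: population 100, ≤ 500 generations; the
  pipeline's fast default is population 20, ≤ 20 generations with stagnation
  10.  All-zero masks get −∞ fitness.  Fitness evaluations are cached by
  mask, so the budget is an upper bound on refits.
* **Y-scrambling.** Class labels are permuted uniformly per trial
  (preserving marginals — "random bioactivity data") and the CV is re-run on
  the selected subset.  Full scale is 1000 trials; the fast default is 200.
  A real signal must beat the null: the unscrambled kappa should exceed
  every trial's kappa, and the null mean should sit near 0 (accuracy near
  the majority-class rate).

## Synthetic study generator

No curated per-kinase activity tables are publicly deposited, so the
generator manufactures complete studies with the statistical structure the
analysis assumes, with ground truth recorded for every planted effect.

* **Proteins.** Uniform-random sequences of length 300–1600 (the span of the
  80 surveyed kinases).  Class-marking tripeptides are *inserted* (never
  substituted, keeping the background composition uniform) at a configured
  per-100-residue rate: by default VME marks "No ACs" (rate 0.5), GTT (0.5)
  and EMY (0.3) mark "High ACs", following the direction of the descriptor
  trends in the surveyed kinases.  Insertion counts are Binomial(L,
  rate/100).  The default rates are a package choice: they put the planted
  tripeptide composition roughly an order of magnitude above the uniform
  background rate (≈ (L−2)/8000), which is what the survey's
  presence/absence contrast looks like at composition scale, while leaving
  presence of a motif alone insufficient for classification (background
  occurrences produce false positives the learner must out-weigh).
* **Ligands.** Molecules are a scaffold core (≥ 10 heavy atoms) joined to a
  small substituent (≤ 5 heavy atoms) from bundled libraries, so
  same-scaffold molecules form MMPs by construction.  The 76-core library is
  verified **MMP-closed** over the substituent set: no two scaffolds can
  yield molecules sharing a valid single-cut core.  This matters: scaffolds
  that are small decorations of one another would otherwise create
  cross-scaffold MMPs with uncontrolled potency deltas and corrupt the
  planted truth.
* **Potencies and cliffs.** Each regular scaffold group of k molecules
  shares a base log10 Ki (uniform on [0, 3], i.e. 1 nM–1 µM) plus noise
  clipped to ±0.35 log units, so non-cliff pairs differ by ≤ 0.7.  Each
  planted cliff is a dedicated 2-molecule group whose members differ by
  3.0 ± noise, hence ≥ 2.3.  The gap around the 2.0 threshold makes the
  planted labels unflippable by noise, and the realized ACs/MMPs% equals the
  planted value exactly.  The number of cliff groups is deterministic,
  n_cliff = max(1, round(r·M/(1−r))) for class rate r and M regular pairs
  (defaults r = 0 / 0.005 / 0.03 put kinases at 0% / ≈0.66% / ≈2.9%, inside
  the No/Low/High bands).  Deterministic counts, rather than per-pair coin
  flips, are what make the class bands realizable at desk scale.
* **Type-II decoys.** A configured fraction of molecules (default 10%)
  carry a grafted diaryl-urea fragment matching the first demo signature;
  they exercise the SMARTS filter and vanish before MMP mining.
* **Defaults.** 80 kinases with class mixture 0.45/0.20/0.35 (the class
  proportions of the survey table), 20 scaffolds × 6 substituents per
  kinase.  Everything is deterministic given the config seed (per-kinase
  child seeds are spawned from it), and fixture files are byte-stable.

What the generator does **not** emulate: real kinase phylogeny or homology
structure, realistic medicinal chemistry (substituent choice is uniform,
potencies carry no SAR beyond the planted cliffs), assay heterogeneity, or
correlated descriptor structure between sequence regions.  Passing tests
therefore demonstrate that the machinery is correct and can recover planted
protein-level signal — not that real kinase sequences predict real AC
propensity at any particular accuracy.

## Pipeline, seeds and problem sizes

`run_pipeline` executes curation → MMP/AC mining → propensity →
descriptors → matrix assembly → GFI → GA → CV/test evaluation →
Y-scrambling → report, writing every intermediate as CSV so each report
number is re-derivable.  One global seed fans out to per-stage seeds through
a NumPy `SeedSequence`; identical configs give byte-identical reports.
Report serialization rounds percentages to 1 decimal and metrics to 2;
full precision is kept internally.

The default study scale (80 kinases, ≈ 140 molecules each, fast GA, 200
scrambling trials) runs in a few minutes on one CPU; the full-scale GA
budget and 1000-trial scrambling are available behind `--full`.  At the
default scale, the recovery experiment's GA-RF model typically reaches CV
kappa ≈ 0.85 and held-out kappa between about 0.6 and 0.9 depending on the
seed, while the scrambled null centers within ±0.05 of zero with maxima
around 0.3 — reproduced by `scripts/acceptance.py`.

## Known limitations

* Single-cut MMPs only; multi-cut transforms and maximum-common-substructure
  similarity are out of scope, as are 3D/crystallographic and binding-site
  descriptors.
* The descriptor values depend on the bundled property scales; other
  implementations using different AAindex normalizations or attribute
  orderings will differ in value while agreeing in structure.
* The APAAC denominator 1 + wΣτ is not sign-protected; for adversarial
  (strongly anticorrelated) sequences it could approach zero.  Random and
  biological sequences keep it near 1.
* Whether a commercial MMP protocol counts a pair once per pair or once per
  cut, and whether it cuts only acyclic single bonds, is not documented;
  this package counts once per pair and cuts acyclic single bonds, which is
  standard MMP practice.
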