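# Methods

This note documents the models, numerical choices, and design decisions
behind petmine, and states what the synthetic-data validations do and do
not establish.

## Sequence data model

Sequences are held over the 20 canonical one-letter codes; the ambiguity
codes B/Z/X/U/O are accepted on input but excluded from every composition
denominator (a sequence with no unambiguous residue is a degenerate-input
error). The rationale is interpretability: compositions remain fractions
of well-defined residues, at the cost of slightly shortening the effective
sequence. Signal peptides are carried as a structured `SP=1..N` token in
the FASTA description (1-based inclusive end of the signal peptide); no
prediction is performed — boundaries are consumed as annotations.
Gap characters `-` and `.` are both accepted on read; `-` is written.

## Featurization

The default vector has 50 named components in a fixed order:

* **aac (20):** canonical residue fractions among unambiguous residues;
  sums to 1 to within 1e-12.
* **ggap (10):** g-gap dipeptide compositions `a(x)_g b` — the count of
  windows with residue `a` at position i and `b` at i+g+1, divided by the
  window count L−g−1. 1200 candidates exist (400 ordered pairs × g ∈
  {0,1,2}); ten are retained. With no trained selection available, a
  documented fallback list of charged/aliphatic pairings is used; any
  trained model carries its own selection. Sequences shorter than one
  window score 0 rather than erroring, so fixed-width vectors stay
  computable. At a fixed g the 400 compositions of an ambiguity-free
  sequence sum to exactly 1.
* **physicochemical (20):** class compositions (acidic, basic, non-polar,
  acyclic, aliphatic, aromatic, charged, EFMR, tiny, small, IVYWREL),
  smoothed ratios, mean maximum solvent-accessible area, (E+K)/(Q+H),
  charged-vs-polar ratio, molecular weight, and mean heat capacity.

Residue-class memberships that are fixed by convention (EFMR = {E,F,M,R};
tiny = {A,G,P,S}; small = {T,D}; IVYWREL; positive = {R,K}; negative =
{D,E}) are validated at load time. Classes with several textbook variants
are shipped as editable data (`petmine/data/residue_classes.json`):
acidic = DE, basic = KRH, polar = STNQYCHDEKR with non-polar its
complement, cyclic = FWYHP with acyclic its complement, aliphatic (feature
table) = AGVLI. The five-class grouping used by the positional chi-squared
test is different by design — aliphatic AGVLIMCP, aromatic FWYH, positive
RK, negative DE, polar NQST — and partitions the 20 residues exactly
(checked at load).

Numerical choices:

* **Ratio smoothing.** All ratio features are (count_num + 1)/(count_den
  + 1), keeping them finite on short or compositionally extreme sequences
  without discarding records. "Charged vs polar composition" is
  implemented as this smoothed ratio of counts.
* **Constants.** Max ASA uses the theoretical-maximum scale of Tien et
  al. (2013); heat capacities are the Hutchens (1970) partial molar
  values (cal mol⁻¹ K⁻¹); masses are standard average residue masses with
  water at 18.02 Da (so Gly → 57.05 + 18.02 = 75.07 Da); the pKa set is
  the EMBOSS nine-group set. Other published scales differ by roughly a
  constant factor; classifier behavior is invariant to per-feature
  rescaling once features are standardized, so the choice of scale does
  not affect classification.
* **Isoelectric point.** The Henderson–Hasselbalch net charge is strictly
  decreasing in pH, so pI is found by bisection on [0, 14] to 1e-4. The
  test suite checks it against a dense 0.001-pH-grid sign-change search on
  random peptides (agreement within 0.01 pH units).

## Thermophilicity classification

OGT bands (psychrophilic <15 °C, mesophilic 25–37 °C, thermophilic
45–70 °C, hyperthermophilic >80 °C) are applied literally: temperatures
between bands yield *no* label rather than a nearest-band assignment,
because the bands are disjoint by construction of the organism panel they
describe. Four binary schemes (PM, MT, TH, MTH) pair the classes; MTH
(mesophilic vs thermophilic+hyperthermophilic) is the scheme the triage
pipeline uses.

* **Redundancy clustering** reimplements the CD-HIT idea as greedy
  representative clustering with exact identity: records are visited by
  decreasing length, each joining the first cluster whose representative
  shares identity ≥ threshold (matches over the shorter length under a
  maximizing global alignment), else founding a cluster. Word-filter
  heuristics are unnecessary at the scales this package targets. The ≥ is
  inclusive, and the ordering rule makes the result deterministic.
* **Splits** assign whole clusters to train/tune/validation greedily by
  largest remaining deficit after a seeded shuffle, so no near-duplicate
  pair straddles a partition.
* **Feature selection** fits a 100-tree random forest on the 1200 g-gap
  candidates only and keeps the top 10 by mean impurity decrease, ties
  broken lexicographically.
* **Training** standardizes features with train-set statistics for the
  distance/margin methods (SVM, logistic regression, kNN) and trains tree
  and naive Bayes methods on raw features; zero-variance features are
  dropped with a warning. Hyperparameters come from small documented
  grids (e.g. SVM: RBF, C ∈ {0.1, 1, 10}, γ ∈ {scale, 0.01, 0.001})
  searched against a separate tuning split; ties resolve to the earlier
  grid point. Cross-validation evaluates each method at its first
  (default) grid point, stratified by class and respecting clusters when
  cluster ids are attached.
* **Serialization.** A trained model is stored as JSON holding the
  feature names, selected dipeptides, standardization statistics and the
  fitted parameters themselves (tree arrays, support vectors and dual
  coefficients, regression coefficients, neighbor tables). Prediction
  always runs from these stored parameters, so a saved and reloaded model
  reproduces its in-memory predictions exactly.

## Profile HMM

Match columns are alignment columns with gap fraction ≤ 0.5. The state
graph is the full match/insert/delete transition set (including I→D and
D→I), which lets the state path observed for every alignment row be
counted directly without remapping disallowed transitions; this is the
one deliberate departure from a strict Plan7 topology, whose omission of
those two transitions buys nothing at this scale. Local alignment is
provided by flank states N and C that emit background residues with
self-loop probability η = M/(M+1), uniform entry B→M_k (probability 1/M),
and a fixed local-exit probability τ = 0.05 from each match state k < M
(core transitions renormalized to 1−τ).

Emissions are (weighted counts + pseudocount×background) normalized, with
pseudocount weight 1 per state; transitions take a Laplace count of 1 per
allowed target. Sequence weighting is uniform by default with
Henikoff position-based weighting available. The background is uniform by
default (configurable).

The reported score is log₂ P(seq|model) − log₂ P(seq|null) with the null
an i.i.d. background model of geometric length (the same η), computed in
log space. Consequences: flank and ambiguous-residue emissions cancel
exactly from the log-odds, and the Forward score is always ≥ the Viterbi
score. These bit scores approximate but do not reproduce HMMER's;
search thresholds are therefore configuration rather than constants, and
E-values are not computed (no extreme-value calibration).

Correctness is established against an independent oracle that enumerates
every state path explicitly: on all toy models with M ≤ 4 and all
sequences of length ≤ 5 over a two-letter alphabet, Forward and Viterbi
agree with the enumeration to ~1e-15 relative (asserted at 1e-9). The
uniform local entry means the single-path limit only exists for M = 1 on
one-residue sequences (prefix-shifted entries otherwise carry real
probability); that case is additionally checked against a hand-computed
2-bit score.

## Discrimination analyses

The score method builds, per CV fold, an HMM from the sub-alignment of
training actives (rows cut from one fixed master alignment, columns that
became all-gap dropped — no realignment per fold) and scores held-out
actives and inactives; the difference method additionally builds an
inactive-homolog HMM and uses the score difference. Folds are stratified
by class. Held-out scores are pooled; AUC is the Mann–Whitney statistic
with half-credit for ties, and ρ is the Pearson correlation of mid-ranks
between scores and continuous activity values.

## Positional chi-squared screen

Columns gapped in strictly more than 90% of rows are removed first.
Each remaining column yields a categories×2 table (observed residues, or
the five residue classes) against active/inactive. Gaps form their own
category by default — the presence of an insertion is itself positional
information — with a drop-gaps mode available. The statistic is Pearson's
chi-squared without continuity correction; rows with zero total are
dropped before computing dof = (rows−1)(cols−1); a single observed
category yields statistic 0 and p = 1. Raw p-values are the screen;
a Bonferroni-adjusted value is reported alongside and never silently
applied. An optional guard warns when any expected count falls below a
user-set floor.

## Triage pipeline

`hmm_search → map_ogt → apply_filters → dedup_candidates → report`.
Thermotolerance is OGT ≥ 50 °C for mapped ids (so 49.9 °C fails and
50.0 °C passes) and predicted class ∈ {thermophilic, hyperthermophilic}
for unmapped ids, with provenance recorded. Score windows are per-source
open intervals with both endpoints strict (a score of exactly 100.0 fails
a min-100 window, mirroring the ">100 / <55" convention they encode).
Deduplication groups identical mature sequences (residues after the
annotated signal peptide) and keeps the highest-scoring member, ties by
lexicographic id. Every input id appears exactly once in the report;
selected rows are exactly the pass-all rows that won their dedup group;
stage counts are logged as JSON lines.

## Synthetic data: what it emulates and what it does not

* **Proteomes:** i.i.d. residues from SwissProt-like background
  frequencies; the positive class re-allocates δ probability mass onto
  the designated set (IVYWREL ∪ {D,E,K,R}, established thermostability
  correlates) proportionally, with renormalization. OGT is uniform per
  class: 55–70 °C for the positive class — kept inside the thermophilic
  band so banding never silently drops or unbalances records — and
  25–37 °C for the negative class. Default δ = 0.1; δ = 0.2 is the
  separable regime used when a strong signal is required.
* **Families:** a star phylogeny around one sampled ancestor; per-site
  substitutions, geometric indels (mean length 1.5, inserted residues
  from background). The catalytic motif (G-x-S-x-G core plus distal His
  and Asp at fixed length fractions) is immune to substitution in
  actives, randomized to non-motif residues in inactives, and protected
  from indels in both, so truth coordinates stay valid. Inactives can
  optionally carry an extra substitution rate (`inactive_extra_rate`,
  default 0), modeling relaxed purifying selection on non-functional
  homologs; the "separable family" regime used in validation is mutation
  rate 0.05 with extra rate 0.15. The true alignment is tracked through
  every indel event and ungaps exactly to the emitted sequences.
* **RNG discipline:** every generator draws from
  `numpy.random.default_rng([seed, stream_id])` with a fixed stream id
  per operation, so outputs are byte-identical across runs and platforms
  and adding one generator call never perturbs another.

These data are simpler than real proteomes in known ways: residues are
i.i.d. (no secondary-structure or domain signal), phylogeny is a star (no
tree-correlated substitutions), and thermophilicity is purely
compositional. Passing the validations therefore establishes that the
implementations are correct and calibrated under their stated models —
not that the classifiers or HMM scores reach any particular accuracy on
real organisms, which depends on corpus composition and alignment quality
outside this package's scope.

## Validation problem sizes

Chosen once as the package's study conditions:

* Planted-dipeptide recovery: 400 sequences per class, lengths 80–200,
  five planted descriptors × 3 occurrences, 10 seeds; ≥4/5 recovered in
  the top 10 per seed.
* DP-vs-enumeration: all models M ∈ {1..4} (two random draws each), all
  two-letter sequences of length ≤ 5; relative tolerance 1e-9.
* Chi-squared type-I calibration: 600-column null alignments over four
  equiprobable residues at 80 rows (expected cell counts ≈ 10, so the
  asymptotic chi-squared reference is valid — with 20 residue categories
  at this depth most expected counts would fall below 1 and the
  calibration check itself would be meaningless), 20 label permutations,
  α = 0.01 against the binomial 99% interval.
* Classifier calibration: 400 sequences per class; every method within
  0.5 ± 0.07 at δ = 0 and ≥ 0.9 at δ = 0.2 under fivefold CV.
* Discrimination: 20 actives + 20 inactives, lengths 80–120, separable
  regime as above; pooled AUC ≥ 0.95. The permutation null reassigns the
  20/20 split at random and reruns the whole CV; because a single
  permutation's AUC has standard deviation ≈ 0.09 at n = 40, the check is
  on the mean over 10 permutations (≈ 0.5 ± 0.1).
* Triage: 20 family members (biased composition, δ = 0.35, so the four
  classifier-routed members sit far from any sensible decision boundary)
  + 80 decoys; windows dbA = (10, ∞), dbB = (−∞, 10) bits, search
  threshold 10 bits; exactly 12 dedup-group representatives selectable.
  Truth for the two duplicate pairs is expressed at group level because
  the surviving representative is whichever copy scores higher.

## Known limitations

* Bit scores are not HMMER-calibrated and no E-values are produced;
  thresholds must be chosen per deployment.
* The clustering identity uses a match-maximizing alignment (no gap or
  mismatch penalties), which upper-bounds alignment-based identity; at
  the 40% threshold this is conservative (merges more, splits less).
* Multi-domain proteins, glocal/multihit alignment modes, and DNA models
  are out of scope.
* The chi-squared screen tests columns independently; covariation between
  positions is deliberately not modeled.
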