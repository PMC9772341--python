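# petmine

A toolkit for mining thermotolerant PET hydrolases — serine hydrolases
(cutinase/lipase/esterase-like enzymes) that depolymerize poly(ethylene
terephthalate) — from protein sequence collections. It is written for
computational biologists who want to run, inspect, or stress-test every
computational stage of such a mining campaign on their own data or on fully
synthetic data with known ground truth.

The toolkit covers four connected analyses:

1. **Profile-HMM homology search.** A profile hidden Markov model with
   match/insert/delete states is estimated from a multiple sequence
   alignment of known family members. A sequence *x* is scored in log-odds
   bits,

   ```
   S(x) = log2 [ P(x | HMM, local mode) / P(x | null) ],
   ```

   where the null model emits i.i.d. background residues with a geometric
   length matched to the model. Both the Forward (sum over paths) and
   Viterbi (best path) scores are available, and `hmm_search` ranks a
   database by Forward score.

2. **Thermophilicity prediction.** Sequences are represented by 50
   features: the 20 amino-acid compositions; 10 g-gap dipeptide
   compositions `a(x)_g b` (selected from 1200 candidates over g ∈ {0,1,2}
   by random-forest Gini importance); and 20 residue-type/physicochemical
   features (class compositions and ratios, IVYWREL and EFMR compositions,
   mean maximum solvent-accessible area, molecular weight, heat capacity,
   (E+K)/(Q+H), isoelectric-point-related ratios). Binary classifiers
   (SVM, logistic regression, random forest, Gaussian naive Bayes, kNN)
   are trained on organisms banded by optimal growth temperature (OGT):
   psychrophilic (<15 °C), mesophilic (25–37 °C), thermophilic (45–70 °C),
   hyperthermophilic (>80 °C). Redundancy is controlled by CD-HIT-style
   greedy clustering at 40% identity, and data splits assign whole
   clusters to one partition.

3. **Activity discrimination and positional statistics.** Given an
   alignment of enzymatically active family members and inactive homologs,
   the *score method* uses the active-family HMM bit score as the
   predictor of activity, and the *difference method* uses
   bits(active HMM) − bits(inactive HMM); both are evaluated by fivefold
   cross-validation with the Mann–Whitney AUC and Spearman's ρ against
   continuous activity data. A per-column chi-squared test of independence
   (residue or five-way residue-class categories × active/inactive)
   screens alignment positions, after removing columns gapped in more than
   90% of sequences.

4. **Candidate triage.** The end-to-end pipeline: HMM search over a
   database → OGT annotation (measured where a table maps the id,
   predicted thermophilicity otherwise) → thermotolerance filter
   (OGT ≥ 50 °C, or predicted thermophilic) and per-source bit-score
   windows → redundancy removal on mature sequences (signal peptide
   excluded) → a per-sequence report with every filter outcome.

A synthetic-data module generates OGT-labeled proteomes with a tunable
compositional effect, homolog families with an intact-vs-ablated catalytic
motif (G-x-S-x-G plus distal His/Asp) and known true alignments, planted
dipeptide signals, and partial OGT tables — so every stage can be validated
against construction-time truth.

## Worked example

Build a profile HMM from a synthetic homolog family, score the family and
some decoys, and check discrimination:

```python
import numpy as np
from petmine import build_phmm, forward_score, hmm_search, roc_auc
from petmine.io import SequenceRecord, CANONICAL_AA
from petmine.synthetic import SyntheticConfig, gen_homolog_family

cfg = SyntheticConfig(seed=2, length=(60, 90), n_active=20, n_inactive=0,
                      mutation_rate=0.05)
family, alignment, truth = gen_homolog_family(cfg)
model = build_phmm(alignment)
print(f"match states: {model.M}")

rng = np.random.default_rng(2)
decoys = [SequenceRecord(id=f"rand{i}",
                         residues="".join(rng.choice(list(CANONICAL_AA), 75)))
          for i in range(20)]
fam_scores = [forward_score(model, r) for r in family]
decoy_scores = [forward_score(model, r) for r in decoys]
print(f"family bits:  {min(fam_scores):.1f} .. {max(fam_scores):.1f}")
print(f"decoy bits:   {min(decoy_scores):.1f} .. {max(decoy_scores):.1f}")
print(f"family-vs-decoy AUC: {roc_auc(fam_scores, decoy_scores):.2f}")
```

Output:

```
match states: 75
family bits:  253.8 .. 286.5
decoy bits:   -3.1 .. 0.3
family-vs-decoy AUC: 1.00
```

Family members score 254–287 bits because their residues match the
position-specific match emissions far better than the i.i.d. background;
unrelated decoys hover near 0 bits (no better than the null), so the score
separates the family perfectly (AUC 1.0).

The same operations are exposed on the command line:

```bash
petmine simulate family --seed 2 --n 20 --out sim/
petmine hmmbuild --aln sim/family_true.afa --out model.json
petmine hmmscore --model model.json --in sim/family.fasta --out hits.tsv
petmine msatest --aln sim/family_true.afa --labels sim/labels.tsv \
    --grouping class --out positions.tsv
```

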