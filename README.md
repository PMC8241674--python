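# toxfunnel

A toolkit for machine-learning cardiotoxicity screening of small-molecule
libraries. It is aimed at computational chemists and drug-discovery teams
who want to triage a compound library for cardiac safety before committing
to synthesis or wet-lab work, and at method developers who need a
transparent, fully testable re-implementation of the common
descriptor → classifier → filtering-funnel workflow.

## What it does

The pipeline has five stages, each usable on its own:

1. **Descriptors** (`toxfunnel.descriptors`) — parse compound libraries
   (`.smi`, SDF, CSV) and compute a seven-descriptor panel per molecule:
   Crippen atom-contribution logP, a fragment-based drug-likeness score
   *S* = Σᵢ sᵢ / √m over the *m* matched scored fragments, SMARTS-defined
   counts of amines, alkyl-amines, aromatic nitrogens and basic nitrogens,
   and ligand efficiency LE = −ΔG / N_heavy when a binding affinity is
   supplied (missing otherwise, never imputed).
2. **Feature selection** (`toxfunnel.feature_selection`) — the
   correlation-gated rule: keep descriptors with point-biserial |r| > 0.1
   against the endpoint label, then for every surviving pair with pairwise
   |r| > 0.9 drop the member with the weaker target correlation.
3. **Classifier benchmark** (`toxfunnel.model_bench`) — AdaBoost, kNN,
   Gaussian naive Bayes, random forest and RBF-SVM models for five
   cardiotoxicity endpoints (arrhythmia, cardiac failure, heart block,
   hypertension, myocardial infarction), evaluated with exact
   leave-one-out sampling (n folds, scaler fit per training fold) and
   reported as ROC/AUC plus the sensitivity / specificity / overall
   predictive accuracy / precision panel.
4. **Safety funnel** (`toxfunnel.cascade`) — three nested filtering
   tiers: (1) all endpoint models predict non-toxic, (2) no mutagenicity /
   tumorigenicity / reproductive-toxicity structural alert, (3) no
   hepatotoxicity / immunotoxicity alert. Alert predicates are pluggable:
   bundled demonstrative SMARTS lists, your own YAML lists, or an exported
   per-compound verdict table.
5. **Validation analyses** (`toxfunnel.docking_post`,
   `toxfunnel.validation_analysis`) — hERG docking post-processing
   (replicate aggregation, Ki = exp(ΔG/RT) conversion at 298.15 K,
   ranking against doxorubicin/dexrazoxane controls), fold-change
   overlap/reversal analysis across treatments, and in-vivo event-rate
   classification against a 10% experimental-noise threshold.

A synthetic-data generator (`toxfunnel.synthetic`) produces labeled
descriptor tables with known logistic ground truth and injectable
collinearity, so every stage is testable without any external download.

## Worked example

```python
from toxfunnel.descriptors import parse_compound_library, compute_descriptor_panel

records, rejected = parse_compound_library(
    "CN1CCC[C@H]1c1cccnc1\tnicotine\nCC(=O)Oc1ccccc1C(=O)O\taspirin\n", "smi")
print(compute_descriptor_panel(records).round(3).to_string())
```

```
              logp  drug_likeness  amines  ligand_efficiency  alkyl_amines  aromatic_nitrogens  basic_nitrogens
compound_id
nicotine     1.848          1.061     1.0                NaN           1.0                 1.0              2.0
aspirin      1.310          0.900     0.0                NaN           0.0                 0.0              0.0
```

Nicotine's pyrrolidine N counts as one (alkyl) amine and, together with
the pyridine nitrogen, gives two basic nitrogens; ligand efficiency is
missing because no binding affinity was supplied. Docking post-processing
converts binding energies to predicted inhibition constants and ranks
against the control drugs:

```python
from toxfunnel.docking_post import ki_from_energy, rank_vs_controls
from toxfunnel.reference_data import herg_docking_table, POSITIVE_CONTROL, NEGATIVE_CONTROL

print(f"Ki(artemisinin B, -4.467 kcal/mol) = {ki_from_energy(-4.467)*1e6:.1f} uM")
comp = rank_vs_controls(herg_docking_table(), POSITIVE_CONTROL, NEGATIVE_CONTROL)
for e in comp.estimates[:3]:
    print(f"{e.compound_id:35s} {e.lbe_mean:7.3f} kcal/mol  {comp.calls[e.compound_id]}")
```

```
Ki(artemisinin B, -4.467 kcal/mol) = 531.7 uM
artemisinin_b                        -4.467 kcal/mol  weaker_than_positive
dexrazoxane                          -4.570 kcal/mol  weaker_than_positive
dihydroartemisinin_furanoacetate     -4.893 kcal/mol  weaker_than_positive
```

Artemisinin B is the weakest hERG binder in the bundled reference table —
weaker even than the cardioprotective control dexrazoxane — which is the
desired profile for cardiac safety.

The same functionality is exposed on the command line:

```bash
toxfunnel descriptors --in lib.smi --out desc.csv
toxfunnel select --desc desc.csv --labels labels.csv --endpoint arrhythmia --out sel.json
toxfunnel train --desc desc.csv --labels labels.csv --algo random_forest --seed 42 --out suite/
toxfunnel screen --in lib.smi --suite suite/ --out funnel.json --survivors safe.smi
toxfunnel dock-post --scores scores.tsv --positive doxorubicin --negative dexrazoxane --out ranked.csv
toxfunnel eventrate --events 1 --n 30
```

## Limitations

The bundled drug-likeness fragment table and structural-alert lists are
small demonstrative sets; absolute drug-likeness values and funnel
survivor counts are not comparable to those of proprietary descriptor or
alert software. See `docs/methods.md` for the full model description,
parameter defaults and numerical conventions.
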