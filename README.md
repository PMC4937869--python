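# erconsensus

Consensus modeling of estrogen-receptor (ER) activity predictions for
chemical-screening prioritization.

Regulators need to rank tens of thousands of man-made chemicals for
potential endocrine disruption, but in-vivo testing is far too slow and
expensive to apply to all of them. A practical alternative is to ask many
independently built in-silico models (QSAR and docking) to predict each
chemical's ER **binding**, **agonist** and **antagonist** activity, and to
combine their calls into a single accuracy-weighted consensus. This package
implements that data-engineering and statistics layer for computational
toxicologists and cheminformaticians:

1. **Structure curation** (`erconsensus.curation`) — raw SDF/SMILES
   inventories are parsed, inorganics and metals removed, salts stripped to
   the largest organic fragment, structures > 1000 g/mol dropped, mesomers
   and tautomers canonicalized, charges neutralized, stereochemistry
   removed, and duplicates merged on the standard InChI, yielding a unique
   QSAR-ready chemical set.
2. **Reference building** (`erconsensus.reference`) — heterogeneous
   literature activity records (binding, transactivation and proliferation
   assays, mixed molar units, contradictory sources) are harmonized to AC50
   in µM (inactives carry a 1 M sentinel) and distilled into a categorical
   reference (majority call; chemicals whose sources disagree by more than
   20% are excluded; agonist/antagonist calls propagate to binding) and a
   five-level potency reference
   (strong < 0.09 µM ≤ moderate < 0.18 µM ≤ weak < 20 µM ≤ very weak
   ≤ 800 µM < inactive) via class scores {0, 0.25, 0.5, 0.75, 1} averaged
   over sources.
3. **Model scoring** (`erconsensus.scoring`) — every model is evaluated on
   six chemical subsets (HTS training chemicals outside the ambiguous AUC
   band 0.01–0.1; all literature chemicals; ≥ 2 sources; no very-weak
   actives; inside the model's applicability domain; all filters combined)
   using sensitivity, specificity and balanced accuracy
   BA = (Se + Sp)/2, summarized as

   * Score₁ = (N_pred/N_total) · (1/5) · Σᵢ BAᵢ · (n_pred,i / nᵢ) over the
     five literature subsets (favors wide-coverage models), and
   * Score₂ = (BA_HTS + BA_all-filters)/2 (favors accurate models).

4. **Consensus** (`erconsensus.consensus`) — per chemical, the Score₂
   values of the models calling *active* and *inactive* are summed and
   normalized by the number of predicting models; the larger average wins.
   Continuous models are combined as C = Σⱼ wⱼ·s(Pⱼ) with weights
   wⱼ = scoreⱼ/Σscore over the predicted potency classes Pⱼ. Four
   correction rules reconcile the categorical/quantitative layers and the
   three endpoints (an active agonist or antagonist is always an active
   binder), and a concordance-threshold sweep identifies "potential
   actives" at configurable stringency.
5. **Synthetic worlds** (`erconsensus.simulate`) — seeded generators for
   ground truth (~10% active prevalence), model ensembles with chosen
   sensitivity/specificity/coverage, multi-source error-prone literature,
   and HTS-style AUC training scores, so the entire pipeline runs and is
   tested without any external data.

## Worked example

```python
from erconsensus.config import RunConfig
from erconsensus.pipeline import run_pipeline

run_pipeline(RunConfig(seed=42, n_chemicals=150, n_models=8,
                       out_dir="run_output"))
```

The run directory contains every stage output as delimited text. The
binding rows of the consensus summary (`consensus_statistics.tsv`) for this
seed read:

```
activity_type  data_slice          n_reference  tp  fn  fp  tn  sensitivity  specificity  balanced_accuracy
binding        toxcast             136          15  0   33  88  1.0          0.73         0.86
binding        literature_all      142          14  3   36  89  0.82         0.71         0.77
binding        literature_min7src  14           1   0   2   11  1.0          0.85         0.92
```

Reading the first row: against the HTS-derived labels (136 unambiguous
chemicals), the corrected binding consensus recovered every true active
(sensitivity 1.0) while calling 33 of 121 inactives active (specificity
0.73), i.e. balanced accuracy 0.86. The corrected consensus deliberately
trades specificity for sensitivity — the correction rules exist to
minimize false negatives in a prioritization setting — and the
high-evidence literature slice (≥ 7 sources) scores markedly better than
the full literature slice, because single-source references are themselves
noisy. `report.json` records the seed, a hash of every
policy threshold, per-rule correction counts and consensus call counts;
rerunning the same config reproduces all outputs byte for byte.

The same stages are scriptable from the shell:

```bash
erconsensus simulate --seed 5 --n-chemicals 500 --out world/
erconsensus build-eval --entries world/literature_entries.tsv --out refs/
erconsensus score-models --preds world/predictions --refs refs/ \
    --training world/training_auc.tsv --out scores.tsv
erconsensus consensus --preds world/predictions --scores scores.tsv --out cons/
erconsensus run --config config.yaml
```

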