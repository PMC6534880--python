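# smilesrl

De novo molecule generation with a recurrent SMILES policy trained by
policy-gradient reinforcement learning against a QSAR activity reward, with
a frozen *exploration network* that stochastically overrides token selection
to preserve chemical diversity.

The package covers the full workflow:

1. **`smilesrl.vocab`** — lossless SMILES tokenizer, vocabulary with
   `GO`/`EOS` control tokens, encode/decode, RDKit-based validity check.
2. **`smilesrl.qsar`** — activity-dataset curation (canonical-SMILES
   merging, pChEMBL averaging, 6.5 activity cut-off, "Not Active" rule),
   ECFP6 fingerprints (radius 3, 4096 bits), and four predictors
   (RF / SVM / NB / DNN) with stratified five-fold cross-validation.
3. **`smilesrl.generator`** — embedding + stacked-GRU policy network
   (NumPy, hand-derived backpropagation), maximum-likelihood pre-training
   and fine-tuning with teacher forcing, autoregressive multinomial
   sampling capped at 100 steps.
4. **`smilesrl.reinforce`** — the REINFORCE loop: ε-mixed sampling between
   the trainable exploitation network and a frozen exploration network,
   per-epoch deduplication by canonical SMILES, reward `Q − β` from the
   predictor (invalid molecules get reward 0), advantage-weighted
   policy-gradient updates.
5. **`smilesrl.evaluate`** — valid / desired / unique percentages, Tanimoto
   internal diversity (all ordered pairs incl. self-pairs), fused/furan/
   benzene substructure statistics, 19D physicochemical descriptors,
   PCA / t-SNE projections, Murcko-scaffold k-means occupancy comparison,
   and candidate ranking by predicted activity and novelty.
6. **`smilesrl.fixtures`** — synthetic stand-ins for the real corpora: a
   fragment-grammar SMILES corpus (valid by construction) and an activity
   table with labels driven by a planted furan motif plus label noise.
7. **`smilesrl.pipeline` / `smilesrl.cli`** — end-to-end orchestration with
   stage checkpointing, seeded reproducibility and TSV logs.

The generator and the DNN predictor are implemented directly on NumPy
(no deep-learning framework is required at run time); the analytic
gradients are verified against central finite differences in the test
suite.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the scaled-down acceptance criteria
(tokenizer round trip, diversity oracle, QSAR AUC, generator learnability,
policy-gradient finite-difference check, exploration-rate calibration, RL
efficacy and the exploration-diversity trend). The full suite takes
roughly 15 minutes on one CPU; heavy artifacts (the shared pre-trained
generator and RF predictor) are session-scoped fixtures.

## CLI

Every stage is a subcommand of `smilesrl`:

```bash
smilesrl make-fixtures --n-corpus 2000 --n-activity 600 --seed 0 --out run/
smilesrl train-qsar --activity run/activity.csv --algorithm RF --out run/predictor.joblib --cv-report run/cv.tsv
smilesrl pretrain --corpus run/corpus.smi --epochs 50 --batch-size 128 --lr 2e-3 \
    --embed-dim 32 --hidden-dim 64 --n-layers 1 --out run/pretrained.npz
smilesrl finetune --model run/pretrained.npz --corpus run/actives.smi --epochs 10 --out run/finetuned.npz
smilesrl train-rl --pretrained run/pretrained.npz --explore run/finetuned.npz \
    --predictor run/predictor.joblib --epsilon 0.1 --beta 0.0 --epochs 200 --seed 0 --out run/rl.npz
smilesrl sample --model run/rl.npz -n 10000 --seed 1 --out run/samples.smi
smilesrl evaluate --smiles run/samples.smi --predictor run/predictor.joblib --out run/report.tsv
smilesrl cluster-compare --reference run/actives.smi --query run/samples.smi -k 20 --mode murcko --out run/occupancy.tsv
```

or run everything end to end from a YAML config (stages are checkpointed
and resumable):

```bash
smilesrl run-all --config config.yaml --seed 1 --out run/
```

Paper-scale defaults (embedding 128, hidden 512, 3 GRU layers, batch 500,
lr 1e-3, 1000 epochs pre-training, 200 RL epochs) are the CLI defaults;
the desk-scale settings shown above train in minutes on one CPU.

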