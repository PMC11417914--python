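# deamipred

Sequence-only prediction of antibody deamidation liabilities. Given
antibody chain sequences (FASTA) and, for training, site-specific
%-deamidation time courses from stressed-sample peptide mapping, the
package:

1. **labels** every asparagine/glutamine site as a deamidation *hot spot*
   or *inactive* using an early-increment rule (> 1.0% growth over
   t0→1wk or 1wk→2wk of the stress study);
2. **featurizes** each site two ways — a *global* per-residue contextual
   embedding of the whole chain from a pluggable protein-language-model
   backend (a deterministic mock backend ships for offline use; a real
   ESM-2 backend activates when `torch`/`fair-esm` are installed), and a
   *local* fixed-width token window around the site;
3. **trains** three model variants — global-only DNN, local-only
   (learned token embedding + bidirectional LSTM), and the *chimeric*
   concatenation of both — for hot-spot classification, plus a
   3-output regression head predicting the 2/4/8-week extents;
4. **evaluates** with an imbalance-aware metric suite (accuracy,
   precision, recall, specificity, F1, MCC, rank-based AUC), stratified
   k-fold cross-validation, and a window-size sweep;
5. **compares** against the canonical NG/NS/NN motif baseline and probes
   the local model for its learned X+1 / X−1 motif rankings;
6. **screens** FASTA-only clone panels, reporting per-site probabilities
   and projected extents plus per-chain aggregates with a low-liability
   flag.

Because measured deamidation datasets are typically proprietary, a
fully seeded synthetic generator (`deamipred.synthetic_data`) emulates
the relevant statistical structure: ~12% active sites, successor-motif
dominated first-order kinetics (NG ≫ NS ≈ NN), predecessor multipliers
(S/E/W), a planted ±5-residue context effect, measurement noise, 0.1%
LOQ censoring, and occasional coverage loss. All neural components are
implemented in numpy with hand-verified backprop, so nothing beyond the
scientific Python stack is required.

## CLI

```bash
# make a synthetic dataset (FASTA + time-course CSV + ground truth)
deamipred simulate --out-dir data/sim --seed 7 --n-molecules 45

# label sites
deamipred build-dataset --fasta data/sim/chains.fasta \
    --timecourse data/sim/timecourses.csv \
    --out data/labeled.csv --summary data/summary.csv

# cross-validate a variant / sweep the window size
deamipred cv --fasta data/sim/chains.fasta --dataset data/labeled.csv \
    --variant chimeric -k 5 --out cv_metrics.csv
deamipred sweep-window --fasta data/sim/chains.fasta --dataset data/labeled.csv \
    --sizes 3,11,31 --out sweep.csv

# train checkpoints and screen a FASTA-only clone panel
deamipred train --fasta data/sim/chains.fasta --dataset data/labeled.csv \
    --variant chimeric --task classification --out ckpt/clf
deamipred train --fasta data/sim/chains.fasta --dataset data/labeled.csv \
    --variant chimeric --task regression --out ckpt/reg
deamipred screen --fasta clones.fasta --classifier ckpt/clf \
    --regressor ckpt/reg --out screen.csv --aggregate-out screen_agg.csv
```

Run configuration (window size, embedder name, thresholds, training
hyperparameters) lives in a YAML/JSON `RunConfig`; pass `--config` to
any training command. Embedder names `mock-d<dim>-s<seed>` select the
deterministic mock backend; any other name is treated as an ESM model
name (requires the optional `torch` + `fair-esm`).

## Layout

- `src/deamipred/io_formats.py` — FASTA / time-course CSV / prediction /
  config readers and writers, core domain types
- `src/deamipred/labeling.py` — increment-rule labeling, candidate-site
  enumeration, dataset summaries
- `src/deamipred/global_embedding.py` — embedding backends (mock + ESM),
  site-vector extraction, on-disk cache
- `src/deamipred/local_sequence.py` — token vocabulary and window
  extraction
- `src/deamipred/nn.py` — numpy NN core: BiLSTM local encoder, dense
  head, losses, Adam (gradients verified against finite differences)
- `src/deamipred/chimeric_model.py` — model variants, training with
  early stopping, prediction, checkpoints
- `src/deamipred/evaluation.py` — metrics, ROC/AUC, stratified CV,
  window sweep
- `src/deamipred/baseline_motif.py` — NG/NS/NN baseline and motif
  probing
- `src/deamipred/synthetic_data.py` — seeded synthetic dataset generator
- `src/deamipred/benchmark.py` — default desk-scale benchmark setup
- `src/deamipred/cli.py` — `deamipred` command group
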