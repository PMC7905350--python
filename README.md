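# eegfatigue

Binary brain-state classification (fatigue vs. alert) from multichannel
EEG-like recordings with a sparse Gaussian radial-basis-function network.

The pipeline:

1. **Preprocess** — polyphase downsampling (500 → 200 Hz by default),
   zero-phase fourth-order Butterworth band-pass (1–45 Hz), segmentation into
   non-overlapping 10-s epochs.
2. **Features** — PCA fitted independently on every epoch (channels as
   observations), the top-10 score matrix flattened to one row per epoch
   (32 × 10 → 320 features), min-max normalized to [−1, 1].
3. **Classifier** — every training input is a candidate Gaussian center;
   regularized orthogonal least squares with a D-optimality term greedily
   selects centers until no candidate has a positive combined
   error-reduction ratio; weights are recovered by back-substitution.
4. **Hyperparameters** — particle swarm optimization searches the
   regularization weight λ ∈ [1e−7, 1], kernel width ρ ∈ [1, 220] and
   D-optimality weight β ∈ [1e−7, 1] (λ, β on a log scale), scoring each
   candidate triple by validation-set MSE of a freshly trained network.
5. **Evaluation** — confusion counts at the strict 0.5 decision threshold,
   sensitivity/specificity/accuracy, ROC by threshold sweep with trapezoidal
   AUC, stratified k-fold cross-validation.

A synthetic two-state EEG generator (1/f background sources, amplitude-
modulated 8–13 Hz oscillations with posterior emphasis, configurable
between-state effect size) makes the whole chain testable end to end; the
class band-power ratio converges to `(1 + effect_size)^2`.

## Command line

```sh
# synthesize a 6-subject study (two 20-min states each)
eegfatigue simulate --subjects 6 --duration 1200 --effect 0.5 --seed 1 --out data/

# recordings -> per-epoch PCA feature tables
eegfatigue preprocess --in data/ --out feats/ --target-rate 200 --band 1 45 \
    --order 4 --window 10 --pcs 10

# two-level training (swarm over lambda, rho, beta)
eegfatigue train --features feats/features_S01.csv --val feats/features_S02.csv \
    --swarm 15 --iters 30 --seed 1 --out model.json

# fixed-hyperparameter baseline pathway
eegfatigue train --features train.csv --val val.csv \
    --fixed rho=110,beta=1e-4,lambda=1e-3 --out baseline.json

eegfatigue predict  --model model.json --features feats.csv --out labels.csv
eegfatigue evaluate --model model.json --features val.csv   --out report.json
eegfatigue crossval --features feats/features_S01.csv --folds 6 --seed 1 --out cv.json
```

Recordings are channels-as-rows TSV matrices with a JSON sidecar
(`rate`, `channel_names`, `label`, `subject_id`), or classic 16-bit EDF
files; models are JSON.

## Layout

| module | role |
| --- | --- |
| `eegfatigue.types` | `Recording`, `EpochSet`, `FeatureSet` containers |
| `eegfatigue.signal_pipeline` | resample, band-pass, segment, per-epoch PCA, feature building |
| `eegfatigue.rols` | candidate construction, orthogonal forward selection, weight recovery |
| `eegfatigue.predict` | network evaluation and the 0.5 decision rule |
| `eegfatigue.pso` | global-best particle swarm with log-scaled dimensions |
| `eegfatigue.trainer` | two-level training loop, fixed-hyperparameter baseline |
| `eegfatigue.evaluation` | confusion metrics, ROC/AUC, stratified k-fold CV |
| `eegfatigue.synthetic` | two-state EEG-like study generator |
| `eegfatigue.storage` | TSV/EDF recordings, feature tables, model JSON, manifests |
| `eegfatigue.cli` | `eegfatigue` command group |
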