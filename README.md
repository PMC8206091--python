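# retinerve

Structure-function estimation for glaucoma: predict the 52 age-corrected
total-deviation (TD) values of a 24-2 Humphrey visual field, and their Mean
Deviation (MD) summary, from a 768-sample peripapillary retinal nerve fiber
layer (RNFL) thickness profile (TSNIT order, 3.45 mm SDOCT circle scan).

The package is aimed at researchers in ophthalmic imaging and visual
psychophysics who want an anatomically constrained, fully reproducible
implementation of recursive 1D-convolutional structure-function mapping —
including its baselines, the class-imbalance-weighted multi-task loss, the
training and sweep protocol, an evaluation suite, and a synthetic paired-data
generator with known ground truth (the clinical registries such models are
trained on are private).

## The model

Retinal ganglion axons run in arcuate bundles that converge on the optic
disc without crossing the horizontal raphe, so the superior hemiretina
(profile samples 0..383) determines the inferior chart hemifield and vice
versa. Each of two independent hemiretina sub-networks is built from 1D
convolutions and max pooling only:

1. a conv/pool block with a strided convolutional skip compresses the
   384-sample half-profile into a 96-long, 12-channel state `r⁽⁰⁾`;
2. the **Recursive Progression Layer** — a single length-preserving
   convolution with linear activation — is applied repeatedly,
   `r⁽ᵗ⁾ = RPL(r⁽ᵗ⁻¹⁾)`, each pass modelling one step of outward movement
   along the fiber bundles;
3. a second conv/pool/skip block and a single-channel conv head read each
   state out into 5 values; pass *t* emits its first {5,4,4,4,4,4,1}ₜ values
   as the chart points of that pass, ordered from the blind spot outward, so
   7 passes produce all 26 points of a hemifield.

The multi-task variant adds `ẑ = ρᵀŷ`, a fixed-mask MD estimate. Training
minimizes

    L = (1−β) Σᵢ λᵢ Σⱼ ρⱼ (yᵢⱼ − ŷᵢⱼ)² + β Σᵢ λᵢ (zᵢ − ẑᵢ)²

with record weights `λᵢ = (1−α)/N + α/(4 N_I(i))` over the four MD intervals
(> −6, (−6,−16], (−16,−26], ≤ −26 dB) and location weights
`ρⱼ ∝ exp(−d²ⱼ/2γ²)` in the center distance. Baselines: per-hemifield linear
regression (no intercepts, 19,968 weights), a 384-32-32-26 fully connected
model (28,468), and a non-recursive convolutional ablation (27,840); the
recursive model has 18,864.

Everything runs on a compact in-repo numpy autodiff core (blocked im2col
convolutions over BLAS; no deep-learning framework required).

## Worked example

```python
from retinerve import StructureFunctionModel, GeneratorConfig, LossConfig
from retinerve.synthetic import generate_dataset
from retinerve.records import split_by_patient

# 2,000 synthetic paired records; patient-level train/val/test split
dataset, truth = generate_dataset(GeneratorConfig(seed=5))
dataset = split_by_patient(dataset, seed=5)

model = StructureFunctionModel(dataset, arch="retinn",
                               loss=LossConfig(alpha=0.0, beta=0.0, gamma=5.0))
result = model.fit(max_epochs=20, n_runs=1, seeds=[0], batch_size=128)
print(result.summary())
```

prints (abridged):

```
Structure-function regression results
=====================================================
architecture:     retinn    trainable params: 18,864
loss: alpha=0.0 beta=0.0 gamma=5.0
runs: 1 (best run 0, epoch 19, val loss 44.71538)
-----------------------------------------------------
pointwise MAE (test split, dB):
         overall: 4.840 (0.137)   n=400
   early_or_none: 3.512 (0.024)   n=266
        moderate: 4.642 (0.137)   n=54
        advanced: 9.390 (0.348)   n=80
MD MAE: 3.745 (0.165)
sectoral mean deviation (MAE, R^2):
         central: 4.523, 0.273
        ...
  inferior_nasal: 2.950, 0.738
```

The per-stage errors reproduce the qualitative clinical picture: estimates
are most accurate for early/no disease and degrade sharply in the advanced
group, where the SDOCT floor effect erases the structural signal. Raising
α shifts accuracy toward the rare advanced interval at the expense of the
majority classes (`retinerve.training.grid_search` sweeps the full
(α, β, γ) grid; `retinerve.evaluation.tradeoff_report` tabulates the
trade-off).

A CLI wraps the same pipeline:

```bash
retinerve simulate --config gen.yaml --out data.csv --seed 17
retinerve train --data data.csv --model retinn --out runs/
retinerve evaluate --data data.csv --model runs/best.ckpt.npz --report report.json
retinerve gridsearch --data data.csv --grid grid.yaml --out grid.csv
```

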