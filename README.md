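# ivspec

Chemometric calibration of **iodine value** (IV, g I₂ / 100 g oil — the
standard measure of lipid unsaturation) from portable vibrational spectra
(NIR and Raman), for analysts replacing wet-chemistry titration with
on-site spectroscopy. The package provides the full workflow:

- **PLS1 regression** — the bilinear calibration model X = T Pᵀ + E,
  y = T qᵀ + f, fitted by NIPALS deflation, with the latent-variable count
  chosen by 5-fold cross-validation (RMSECV on pooled out-of-fold
  residuals) and the standard validation metrics RMSEC/RMSEP and
  Q² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)².
- **Four resampling-based wavelength selectors**:
  **MCUVE** (Monte Carlo uninformative variable elimination — coefficient
  stability c_j = β̄_j / s(β_j) ranked against appended artificial noise
  channels), **CARS** (competitive adaptive reweighted sampling — forced
  shrinkage along r_i = a·e^(−ki) plus coefficient-weighted competitive
  resampling), **BOSS** (bootstrapping soft shrinkage — weighted bootstrap
  subsets whose best 10% vote channel weights w_i = Σ_k b_{i,k}), and
  **VCPA** (variable combination population analysis — binary matrix
  sampling, best-model frequency ranking, shrinkage to ω = 14 candidates,
  then an exhaustive 2¹⁴ − 1 subset search).
- **Kennard–Stone partitioning** (deterministic max–min distance
  calibration/test split), mean centering, and a fixed CSV dialect with
  bit-exact round-trips.
- A **repeated-evaluation benchmark** (50 seeded repeats; mean ± SD of
  nVAR, nLV, Q²cv, Q²test, RMSEC, RMSEP per method).
- A **synthetic oil-blend generator** — four-component mixtures with
  Gaussian-band pure spectra on three instrument profiles (125 / 3108 /
  3122 channels), plus a planted-sparse-signal fixture with a truth mask so
  selector recall and precision are measurable.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import numpy as np
from ivspec import (SimulationConfig, generate_dataset, kennard_stone_split,
                    evaluate_model)
from ivspec.cars import CarsConfig, select_cars

cfg = SimulationConfig(n_samples=59, instrument_profile="micronir", seed=42)
ds, truth, fractions = generate_dataset(cfg)
split = kennard_stone_split(ds, 36)          # 36 calibration / 23 test

full, full_nlv = evaluate_model(ds, split, np.arange(ds.n_channels), seed=42)
sel, trace = select_cars(ds, split, CarsConfig(seed=42))
cars, nlv = evaluate_model(ds, split, sel.selected_indices, seed=42)
```

This prints (via the f-strings in the example script):

```
full spectrum: nVAR=125 nLV=3 RMSEC=0.5449 RMSEP=0.5010 Q2test=0.9910
CARS:          nVAR=25 nLV=7 RMSEC=0.1909 RMSEP=0.7235 Q2test=0.9812
```

Reading: on this synthetic 59-sample MicroNIR-like blend set, the
full-spectrum model needs all 125 channels and 3 latent variables for a
test error of 0.50 IV units; CARS compresses the model to 25 channels
(clustered on the C–H combination-band region near 1390–1440 nm) with a
lower calibration error (0.19) and a slightly higher test error (0.72) —
the classic selection trade-off the benchmark protocol quantifies over
repeated runs.

The same workflow is scriptable from the shell:

```sh
ivspec --seed 42 simulate --profile micronir --out blends.csv
ivspec --seed 42 select --data blends.csv --method cars --out cars_channels.csv
ivspec --seed 42 benchmark --data blends.csv --repeats 50 --out report.csv
```

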