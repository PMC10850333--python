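# nirimpurity

A calibration pipeline for predicting impurity mass fraction in seed cotton
from near-infrared reflectance spectra (125 channels, 950–1650 nm):

- **Preprocessing** — per-spectrum min–max normalization, standard normal
  variate (SNV), and Savitzky–Golay smoothing.
- **Sample partitioning** — deterministic SPXY (joint X–Y distance
  Kennard–Stone) train/test splitting.
- **Wavelength selection** — successive projections algorithm (SPA, scored by
  cross-validated MLR RMSE) and random frog (seeded stochastic subset search
  with per-variable selection probabilities).
- **Chemometric models** — NIPALS PLS1 regression, RBF ε-SVR, and RBF LSSVM
  (direct KKT linear-system solve), each with seeded 5-fold CV hyperparameter
  search.
- **1D convolutional network** — three conv stages (16/64/48 channels),
  average pooling, and a single-node linear head (~15k parameters),
  implemented on NumPy with hand-written backprop and Adam, trained with a
  log-of-MSE loss; SELU/ReLU/Sigmoid activation ablation.
- **Synthetic data** — a seeded generator producing reflectance spectra with
  Gaussian absorption bands whose depths scale linearly with the impurity
  target, plus multiplicative scatter, baseline drift, and white noise, so
  the whole pipeline is testable end-to-end.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, exact preprocessing identities, seeded recovery rates, and
report-structure checks); the remaining modules are unit/property tests.

## CLI

Every stage is a subcommand of the `nirimpurity` entry point, exchanging
plain-text artifacts (CSV spectra tables, JSON splits/selections/models):

```sh
nirimpurity simulate  --seed 7 --out spectra.csv --truth truth.json
nirimpurity split     --data spectra.csv --n-train 180 --out split.json
nirimpurity select    --data spectra.csv --split split.json \
                      --method spa --preprocess normalization --out sel.json
nirimpurity fit       --data spectra.csv --split split.json --selection sel.json \
                      --preprocess normalization --model lssvm --out model.json
nirimpurity evaluate  --data spectra.csv --split split.json \
                      --model-file model.json --preprocess normalization
nirimpurity train-net --data spectra.csv --split split.json \
                      --activation selu --preprocess normalization \
                      --history-out loss.csv
nirimpurity grid      --data spectra.csv --out grid.csv      # 18-row report
nirimpurity ablate    --data spectra.csv --out ablation.csv  # 9-row report
```

The `grid` report has one row per preprocessing × selector × model
combination with columns `pre_processing`, `VN` (number of selected
wavelengths), `R_C`, `RMSE_C`, `R_P`, `RMSE_P`; `ablate` covers the
3 preprocessing × 3 activation network grid on full-spectrum input.

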