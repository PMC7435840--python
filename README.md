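# alqc — quality control of artemether–lumefantrine tablets

`alqc` is a Python library for the two-arm quality control of
artemether–lumefantrine (AL) fixed-dose antimalarial tablets, written for
analysts and chemometricians working on falsified-medicine screening:

1. **NIR screening arm** — handheld-instrument diffuse-reflectance spectra
   (900–1700 nm) are preprocessed with a Savitzky–Golay second derivative
   (second-degree polynomial) and multiplicative scatter correction (MSC),
   restricted to the informative 1085–1601 nm window, explored by PCA, and
   classified per brand with **DD-SIMCA** one-class models. A tablet is
   accepted by its brand's model iff

   `c = N_h·h/h₀ + N_v·v/v₀ ≤ χ²₁₋α(N_h + N_v)`

   where *h* is the score distance (leverage in the PC subspace,
   `h = Σₐ t²ₐ/λₐ`), *v* the orthogonal distance (squared residual norm),
   and the scales *h₀, v₀* and degrees of freedom *N_h, N_v* are estimated
   from the training class by the method of moments. Falsified tablets with
   no active ingredient fail spectacularly in *v*.

2. **HPLC quantification arm** — peak-area tables from a green
   ethanol/acetic-acid RP-HPLC assay are validated by the **total-error
   accuracy profile**: per-day single-level calibration, back-calculation,
   one-way random-effects variance components (repeatability σ_r,
   intermediate precision σ_IP), and **β-expectation tolerance intervals**

   `bias% ± t_{ν,(1+β)/2} · √(1 + 1/(p·n·B²)) · 100·σ_IP/μ_T`

   judged against ±10% acceptance limits; plus tablet content assay through
   the 1:2 / 1:100 dilution scheme, API-presence verdicts, chromatographic
   figures of merit (k, As, Rs), and analytical greenness scores (Eco-scale
   penalty points, NEMI quadrants).

A first-class **synthetic-data module** emulates the full seven-product
study (27 batches × 10 tablets = 270 spectra, including a falsified
illicit-channel product) and the laboratory's validation/assay observations
with known ground truth, so the whole pipeline is testable end to end
without an instrument.

## Worked example

```python
from alqc import screening, synthetic

study = synthetic.simulate_study(seed=1)      # 270 spectra, 7 products
results = screening.screen_study(study)       # 3 brands with >= 5 batches
print(screening.performance_table(results))
```

prints

```
      brand  A   alpha  sensitivity  specificity  n_target_test  n_target_accepted
AL Macleods  1 0.00010        100.0        100.0             20                 20
   Combiart  1 0.00010        100.0        100.0             30                 30
    Komefan  1 0.00001        100.0        100.0             20                 20
```

Each row is one brand's DD-SIMCA model, trained on its first three batches,
with the number of PCs `A` and significance level `alpha` chosen by the
two-stage sequential optimiser. Sensitivity 100 means every held-out
same-brand tablet was accepted; specificity 100 means every tablet of every
other product — including the 30 falsified illicit-channel tablets — was
rejected.

The `examples/` directory holds one short narrative script per capability
(study simulation, preprocessing + PCA, DD-SIMCA screening, accuracy
profile, assay + greenness); each prints the numbers it computes and a line
on what they mean. A thin CLI mirrors the same steps
(`alqc simulate|preprocess|pca|screen|validate|assay|greenness`, with
`--config`, `--seed`, `--out`, `--no-plots`).

## Layout

- `src/alqc/synthetic.py` — study/validation/assay generators with ground truth
- `src/alqc/preprocess.py` — SG derivative, MSC, window truncation, fitted state
- `src/alqc/pca.py` — deterministic PCA, Hotelling confidence ellipse
- `src/alqc/ddsimca.py` — one-class models, distances, optimisation, serialization
- `src/alqc/screening.py` — batch-wise splits and per-brand screening workflow
- `src/alqc/validation.py` — calibration, accuracy profile, assay, peak metrics
- `src/alqc/greenness.py` — Eco-scale and NEMI rule engines
- `docs/methods.md` — model assumptions, parameter choices, limitations
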