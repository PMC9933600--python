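# nanoqspr

Quantitative structure–property modeling of polymeric-nanoparticle
**zeta potential** (ζ, mV) from three blocks of descriptors:

* **core** — continuous physicochemical properties of the polymer core
  (e.g. AMW-P, the average molecular weight of the polymer);
* **coating** — small-integer counts describing the surface
  functionalization (e.g. nCsp2-C, the number of sp²-hybridized carbons);
* **corona** — binary protein-corona fingerprint bits, one per serum
  protein, 1 if the protein is found adsorbed on the particle.

Zeta potential is the standard proxy for colloidal stability
(|ζ| ≳ 30 mV ≈ stable suspension), and in biological media it depends
not only on the bare particle but also on the adsorbed protein layer.
The package is aimed at computational nanotoxicologists who want to fit,
validate and interrogate such models on small descriptor tables.

## What it implements

* **PLS1 via NIPALS** — the endpoint is regressed on a small number of
  latent vectors (LVs), orthogonal score directions `t_a = X_a w_a`
  maximizing covariance with ζ, with `w_a ∝ X_aᵀy` and deflation
  `X_{a+1} = X_a − t_a p_aᵀ`.  Coefficients are reported both per
  descriptor SD ("standardized", mV/SD) and in raw units, with per-LV
  explained variance of the descriptor block and of ζ.
* **Autoscaling** with training-set parameters only; descriptors that are
  constant over the training rows are dropped, which is what makes honest
  leave-one-out folds well defined when a fingerprint bit occurs in a
  single training particle.
* **Validation battery** — R², RMSEC, leave-one-out Q²cv / RMSECV (scaler
  refit per fold), external Q²ext (Q²F1, training-mean reference) and
  RMSEP.
* **Applicability domain** — hat-matrix leverages
  `h_i = x_iᵀ(XᵀX)⁻¹x_i`, warning threshold `h* = 3p/n`, standardized
  residuals, Williams-plot data and flags (descriptor-space or
  latent-score-space leverage).
* **GA descriptor selection** — seeded genetic algorithm (tournament
  selection, uniform crossover, per-bit mutation, elitism) minimizing
  RMSECV over descriptor subsets and LV counts, with an exhaustive-search
  oracle for small pools.
* **Nested domain comparison** — core vs core+coating vs
  core+coating+corona models, quantifying what each block adds.
* **Synthetic data generator** — descriptor pools with the same block
  structure and a planted sparse linear ζ-relationship, for testing
  selection and validation code with known ground truth.

A 20-particle, 5-descriptor modeling table (7 polymer cores, 7 coating
chemistries, 3 corona fingerprint bits, ζ from −70 to +50 mV, 14
training / 6 validation samples) ships with the package as
`load_fixture_table1()`.

## Worked example

```python
import nanoqspr as nq

table = nq.load_fixture_table1()
model, report = nq.validate_model(table, n_lv=2)
print(f"R2     = {report.R2:.3f}   RMSEC  = {report.RMSEC:.2f} mV")
print(f"Q2_ext = {report.Q2_ext:.3f}   RMSEP  = {report.RMSEP:.2f} mV")
print(f"Q2_cv  = {report.Q2_cv:.3f}   RMSECV = {report.RMSECV:.2f} mV")
print(nq.standardized_coefficients(model))
ad = nq.williams_data(model, table, leverage_space="scores")
print(f"h* = {ad.h_star:.2f}, outliers = {ad.n_outliers}")
```

prints

```
R2     = 0.957   RMSEC  = 6.84 mV
Q2_ext = 0.893   RMSEP  = 7.36 mV
Q2_cv  = 0.429   RMSECV = 24.81 mV
{'AMW-P': 16.22244405986862, 'nCsp2-C': -9.56017645000939, 'CC1rs': 21.735482432589976, 'AA-I': 17.496661828413945, 'kininogen-1': -5.384085638316653}
h* = 1.07, outliers = 0
```

Reading: the 2-LV model explains 95.7% of the training ζ variance and
predicts the six held-out particles to 7.4 mV; heavier cores and
adsorbed complement C1r / Apo A-I push ζ positive, sp²-rich coatings
push it negative (in mV per descriptor SD).  RMSECV is much larger than
RMSEP because two corona bits occur in exactly one training particle
each — when that particle is held out, the fold cannot learn the bit's
effect; the LOO table in `report.loo` shows those two folds carrying
most of the cross-validation error.  No sample exceeds 3 SD residuals
and all score-space leverages stay below h* = 3·5/14 ≈ 1.07.

The same pipeline is scriptable from the shell:

```bash
nanoqspr validate              # fixture by default
nanoqspr reproduce --out out/  # fit + validation + AD + domain comparison
nanoqspr simulate --n-samples 60 --seed 7 --out sim/
nanoqspr ga --input sim/synthetic.csv --schema sim/synthetic_schema.yaml
```

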