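# fracopd

Fractional-dynamics characterization and staging of chronic obstructive
pulmonary disease (COPD) from multichannel physiological recordings.

COPD is conventionally staged by spirometry (GOLD stages 0–4 from FEV1
%predicted once FEV1/FVC < 0.70), which is effort-dependent and
insensitive to early disease. An alternative is to read disease state
out of the *dynamics* of passively recorded overnight signals (thorax
and abdomen breathing effort, SpO₂, pulse, plethysmograph, nasal
pressure, ...). This package implements that pipeline for researchers
working with multichannel polygraphy:

1. **Multifractal analysis (MF-DFA).** Per channel, the scaling
   function S(q, s) = {(1/N_s) Σ_v F(v, s)^q}^{1/q} over window scales
   s and moment orders q, its focus point S(q, L) at the full signal
   length, the generalized Hurst exponent H(q) (slope of log S vs
   log s), group confidence bands, and Wasserstein distances between
   H(q) curves.
2. **Fractional-order coupled model.** Across channels, the discrete
   system Δ^α x[k+1] = A x[k] + B u[k] under the Grünwald–Letnikov
   operator Δ^{α_i} x_i[k] = Σ_j ψ(α_i, j) x_i[k−j], with per-channel
   order estimation, least-squares coupling identification, and an
   alternating estimator for sparse unknown inputs u (p < n). The
   flattened coupling matrix A (12² = 144 or 6² = 36 values) is the
   feature vector.
3. **Staging classifier.** A feedforward net 144 → 300 → 100 → 5
   (ReLU, dropout 0.2, rmsprop, categorical cross-entropy; 74,105
   trainable parameters), evaluated by shuffled 5-fold
   cross-validation, leave-one-institution-out hold-out, and a
   reduced-montage (36-feature) transfer configuration, with a
   multinomial-logistic linear probe as separability baseline.

Because the clinical datasets this methodology targets are not publicly
deposited, the package includes a first-class synthetic module:
exact fractional Gaussian noise (circulant embedding), binomial
cascades with closed-form h(q), fractional coupled-system simulation,
and staged multi-institution cohorts with a controlled stage signal in
the coupling matrix. Every estimator is validated against these
analytic oracles; see `docs/methods.md` for what the synthetic cohorts
do and do not establish about real recordings.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from fracopd import (CohortSpec, gen_staged_cohort, NetSpec, kfold_eval,
                     linear_probe, gen_binomial_cascade, cascade_hurst,
                     MfdfaConfig, scaling_function, hurst_curve)
from fracopd.pipeline import dataset_from_records

# MF-DFA against an analytic multifractal oracle
x, meta = gen_binomial_cascade(14, 0.75)
cfg = MfdfaConfig()
curve = hurst_curve(scaling_function(x, cfg), cfg)
print("q      :", " ".join(f"{q:6.0f}" for q in curve.q_grid))
print("H(q)   :", " ".join(f"{h:6.3f}" for h in curve.H))
print("analytic:", " ".join(f"{h:6.3f}" for h in cascade_hurst(0.75, curve.q_grid)))

# synthetic staged cohort -> coupling features -> 5-fold staging
cohort = gen_staged_cohort(CohortSpec(n_patients=20, records_per_patient=3,
                                      n_samples=3000, seed=7))
ds = dataset_from_records(cohort)
print("records:", ds.features.shape[0], "features:", ds.features.shape[1])
rep = kfold_eval(ds, k=5, spec=NetSpec(input_dim=144, epochs=100, seed=0), seed=0)
print(f"5-fold accuracy: {rep.accuracy_mean:.3f} +/- {rep.accuracy_sd:.3f}")
print(f"linear probe:    {linear_probe(ds, k=5, seed=0):.3f}")
```

Output:

```
q      :     -5     -3     -1      1      3      5
H(q)   :  1.786  1.681  1.420  0.982  0.722  0.624
analytic:  1.801  1.684  1.415  1.000  0.731  0.614
records: 60 features: 144
5-fold accuracy: 0.983 +/- 0.037
linear probe:    0.850
```

The estimated H(q) is decreasing in q and tracks the cascade's
closed-form exponent within a few hundredths — the signature of a
correctly recovered multifractal. On the 60-record cohort the staging
net separates the five stages almost perfectly (the stage signal was
planted in the coupling matrix at 1.4× the feature-noise floor), and
the linear probe confirms the features are linearly informative; a
cohort generated with `coupling_shift=0` drops both to the 20% chance
level.

A command-line interface mirrors the library
(`fracopd simulate | mfdfa | extract | evaluate | pipeline`); records
travel as one CSV per record (samples × channels) plus a manifest CSV,
and EDF files can be read directly.

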