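# fermsense

Inverse-system soft sensing for fed-batch *Pichia pastoris* fermentation.

During the methanol-induction phase of an industrial *P. pastoris*
inulinase process, the states that matter most — cell concentration `X`,
substrate (methanol) concentration `S` and enzyme concentration `E` —
can only be measured by slow offline assays, while dissolved oxygen
`C_L`, pH (as hydrogen-ion concentration `[H+]`), broth volume `V`, the
four feed rates and the environment (temperature, agitation, airflow)
stream in continuously. `fermsense` reconstructs the unmeasured states
from the measured ones in real time. It is aimed at bioprocess engineers
and researchers who want a fully simulatable, testable reference
implementation of the approach.

## The method

**Grey-box process model.** Six balance equations with pluggable
specific-rate laws (states x₁..x₆ = X, S, E, C_L, [H⁺], V; feeds
u₁..u₄ = methanol, ammonia, phosphate, antifoam, in L/h):

```
ẋ1 = μ x1 − (x1/x6) Σ a1i ui
ẋ2 = −ν x1 + S_C u1 / x6 − (x2/x6) Σ a2i ui
ẋ3 = ρ x1 − K_P x3 + (K_M u3 + K_A u4)/x6 − (x3/x6) Σ a3i ui
ẋ4 = −η x1 + K_La (C_L* − x4) − (x4/x6) Σ a4i ui
ẋ5 = γ x1 − (x5/x6) Σ a5i ui + (S_f u1 − S_m u3 − S_n u2 − S_a u4)/x6
ẋ6 = Σ ui
```

The default rate bundle couples everything through the specific growth
rate μ (Monod uptake × substrate inhibition × oxygen limitation ×
logistic crowding × product inhibition), with ν = μ/Y_XS + m_S,
ρ = αμ + β (Luedeking–Piret), η = μ/Y_XO + m_O, γ = c_H μ.

**Invertibility diagnostic.** The unmeasured states are recoverable from
the measured outputs only where the map (x₁,x₂,x₃) → (ẍ₄, ẋ₄, ẋ₅) has a
full-rank 3×3 Jacobian. `jacobian_J` estimates that Jacobian by central
finite differences along the simulated flow and decides the numerical
rank by singular-value thresholding on a row-equilibrated copy.

**Inverse extended model.** A 13-dimensional feature vector
(x₄, x₅, x₆, ẋ₄, ẍ₄, ẋ₅, u₁..u₄, Tw, Sa, Fa) — derivatives from
five-point stencils, all channels normalized on training data only — is
mapped to each target state by its own fully connected network (ReLU
hidden layers, linear output) trained from scratch with Adam
(m_t, v_t moment estimates with bias correction) against the MSE loss.
Cascading the fitted inverse model with the process gives a composite
pseudo-linear system whose deviation from the identity map is the
headline diagnostic.

Everything is testable offline: the `synthetic` module generates
campaigns with the assumed structure — 240 h of induction, near-constant
sized feed programs, offline assays every 4 h (60 pairs per batch), and
Gaussian sensor noise at instrument accuracies (DO ±0.5 %, pH ±0.02,
flow ±2 %).

## Worked example

```python
import numpy as np
from fermsense import (CampaignConfig, generate_campaign, SoftSensorRegressor,
                       evaluate, cascade_identity_check, jacobian_J, default_rate_laws)

cfg = CampaignConfig(seed=7)            # 240-h induction, 4-h assays, sensor noise on
batch = generate_campaign(cfg)[0]
ds = batch.dataset.assign_chronological_split(0.7)
X_train, y_train, _ = ds.rows("train")

sensor = SoftSensorRegressor(max_epochs=4000, random_state=0)
sensor.fit(ds.X.iloc[:len(y_train)], y_train)

report = evaluate(sensor, ds, interp_minutes=30)
print("offline pairs:", len(ds))
print("train MSE (normalized):", {k: f"{v:.2e}" for k, v in report.mse_train.items()})
print("median relative error :", {k: f"{v:.4f}" for k, v in report.medians.items()})

med = cascade_identity_check(sensor, batch.traj, ds.t)
print("cascade identity check:", {k: f"{v:.4f}" for k, v in med.items()})

i = len(batch.traj) // 2
rep = jacobian_J(batch.traj.states[i], batch.traj.feeds[i],
                 default_rate_laws(cfg.kinetics), cfg.model)
print("mid-induction Jacobian rank:", rep.rank, "-> invertible:", rep.invertible)
```

Output:

```
offline pairs: 60
train MSE (normalized): {'x1': '4.07e-12', 'x2': '1.72e-10', 'x3': '9.42e-08'}
median relative error : {'x1': '0.0000', 'x2': '0.0000', 'x3': '0.0004'}
cascade identity check: {'x1': '0.0079', 'x2': '0.0094', 'x3': '0.0473'}
mid-induction Jacobian rank: 3 -> invertible: True
```

The campaign yields the expected 60 assay pairs; the three networks fit
their (normalized) training targets essentially exactly; and the cascade
of the inverse model with the simulated process reconstructs cell,
substrate and enzyme concentration with median relative errors of about
0.8 %, 0.9 % and 4.7 % under instrument-level sensor noise. The
mid-induction Jacobian has rank 3, i.e. the reconstruction is locally
well-posed there.

A CLI mirrors the library (`fermsense simulate | generate |
build-dataset | train | predict | evaluate | online-correct |
invertibility-check`); every command takes `--seed`, `--out` and
`--log-level` and logs its resolved configuration.

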