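# agglearn

Iterative, structure-based machine learning for discovering small-molecule
inhibitors of alpha-synuclein (aS) aggregation — the protein whose
autocatalytic fibril proliferation underlies Parkinson's disease and other
synucleinopathies — plus the chemical-kinetics analysis that turns
plate-reader ThT assays into the potency signal the learner trains on.

## Who this is for

Groups running seeded aggregation assays who want to (i) quantify compound
potency rigorously (half-times, amplification and elongation rates, oligomer
flux, KIC50), (ii) prioritize which compounds to test next with an
uncertainty-aware model instead of similarity searching alone, and
(iii) audit what the model learned. Everything runs offline: a synthetic
structure–activity world is built in, so the full loop is testable without a
wet lab.

## The models at the core

**Aggregation kinetics.** Lightly seeded aS aggregation is fitted with the
generalized logistic for the fibril mass fraction

    M(t)/m_tot = 1 − [1 + (a/c) e^{κt}]^{−c},   c = √(2/(n₂(n₂+1))), n₂ = 4

where κ = √(2k₊k₂ m_tot^{n₂+1}) is the secondary-nucleation amplification
rate; the compound effect is reported as k₂,rel = (κ/κ_ctrl)². Heavily
seeded reactions give the elongation rate from the early slope
dM/dt|₀ = 2k₊P(0)m(0). The flux of monomers into oligomers is

    φ(t) = (1/r₊)[(m₀/m(t))·M″ + (1/m₀)((m₀/m(t))·M′)²],  r₊ = 2k₊m(0)

evaluated from analytic derivatives of the fitted logistic. Dose series are
summarized by the KIC50 — the concentration raising t½ by 50% over the
vehicle control — from a Hill fit of the approximate rate 1/t½. Potency for
learning is the normalized half-time t½/t½(DMSO); > 2 is "potent".

**Potency model.** Molecules are standardized, Morgan-fingerprinted
(radius 2, 2048 bits) and embedded (external latent vectors, or a built-in
fingerprint-PCA fallback). A random forest predicts the normalized
half-time; a Gaussian process fitted to the forest's out-of-bag residuals
supplies the posterior uncertainty. Candidates are ranked by
`prediction − β·uncertainty` and selected by consensus over independently
seeded refits; tested batches are fed back and the loop repeats. Shapley
attributions (exact, tree-path recursion) and hierarchical clustering
expose which latent dimensions drive the predictions.

**Binding.** A minimal 1:1 SPR model: K_D = k_d/k_a, with global
(k_a, k_d, R_max) fits across analyte concentration series.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from agglearn.kinetics import (LogisticFit, simulate_trace, fit_amplification,
                               k2_relative, relative_half_time)
from agglearn.binding import kd_from_rates

t = np.linspace(0, 125, 250)                    # hours, as in a 125 h run
ctrl = simulate_trace(LogisticFit(kappa=0.5, a=1e-3), t, noise_sd=0.02, seed=1)
cmpd = simulate_trace(LogisticFit(kappa=0.3, a=1e-3), t, noise_sd=0.02, seed=2)

s = relative_half_time(cmpd, ctrl)
print(f"t_half compound = {s.t_half:.2f} h  (normalized {s.t_half_norm:.2f}, potent={s.potent})")
print(f"k2 relative = {k2_relative(fit_amplification(cmpd), fit_amplification(ctrl)):.3f}")
print(f"KD = {kd_from_rates(1.936e5, 1.315e-2)*1e9:.0f} nM")
```

prints

```
t_half compound = 26.07 h  (normalized 1.64, potent=False)
k2 relative = 0.358
KD = 68 nM
```

read: the compound slows aggregation (half-time 26 h vs 15.9 h for the
control) but the 1.64× normalized half-time is below the 2× potency bar; the
fitted squared-κ ratio says secondary nucleation is cut to ~36% of the
control; and a compound with k_a = 1.936×10⁵ M⁻¹s⁻¹, k_d = 1.315×10⁻² s⁻¹
binds fibrils with K_D = 68 nM.

An end-to-end synthetic campaign (library generation, hidden
structure–activity landscape, three iterations of consensus selection vs a
random baseline) runs from the command line:

```bash
agglearn pipeline run --seed 0 --out-dir out/
```

Other subcommands: `agglearn chemspace search|cluster|fingerprint|mpo`,
`agglearn kinetics fit|kic50|flux|simulate`, `agglearn binding
fit|simulate`, `agglearn synthdata library|landscape|traces`, `agglearn
learner benchmark`.

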