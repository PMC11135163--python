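# desvisc

Viscosity modelling of choline-chloride deep eutectic solvents (DESs) and
their cosolvent mixtures from sigma-profile molecular descriptors.

## The problem

DESs — eutectic mixtures of a hydrogen-bond acceptor salt such as choline
chloride ([Ch]Cl) with donors like glycerol, ethylene glycol or urea — are
attractive green solvents, but most are too viscous at room temperature to
pump or mix, and adding even a little water or alcohol changes the
viscosity by orders of magnitude. Screening candidate formulations
experimentally is slow; a model that predicts viscosity from molecular
structure, composition and temperature lets the screening happen on a
laptop.

`desvisc` implements the quantitative structure–property pipeline for this
task, for solvent researchers and modellers:

1. **Descriptors.** Each compound's COSMO-type sigma-profile
   `p(sigma)*A` (surface area per screening charge density, 31 points over
   ±0.03 e/Å²) is integrated by the trapezoidal rule over eight contiguous
   regions, giving areas `S1..S8` spanning strong hydrogen-bond donor →
   nonpolar → strong acceptor character. Mixture descriptors follow the
   mole-fraction mixing rule `S_i(mix) = Σ_j x_j S_i^j`.
2. **Model.** A feed-forward network maps the nine inputs
   `(S1..S8, T)` — min–max scaled to [−1, 1] — through tanh hidden layers
   (reference architecture 9‑19‑16‑1) to `log10(η / mPa·s)`:

   `H_{p,n} = tanh( Σ_m W_{n,p,m} u_{(p−1),m} + b_{n,p} )`,
   with an affine output neuron.

   Training minimizes the Bayesian-regularized objective
   `F = β E_D + α E_W` (sum-squared error + sum-squared weights) with a
   Levenberg–Marquardt inner loop; `α, β` are re-estimated each step from
   the evidence framework via the effective number of parameters
   `γ = N_w − 2α tr(H⁻¹)`.
3. **Validation.** Ordered-response splitting (sort by `log η`, every 9th
   record → untouched external set ≈ 11%, the rest randomly divided so
   training holds 80% of the total); `R²`, RMSE and AARD on `log η`;
   leave-one-system-out `Q²`; Williams-plot applicability domain
   (leverage `h_i = v_i (VᵀV)⁻¹ v_iᵀ` against `h* = 3(d*+1)/p`,
   standardized residuals against ±3); and PaD sensitivity — exact network
   gradients, squared and normalized into per-input contributions.
4. **Synthetic data.** A generator producing sigma-profiles
   (Gaussian-peak templates) and viscosity records from a recorded
   Vogel–Fulcher–Tammann-like law
   `log10 η = A(S) + B(S)/(T − T0(S))` with multiplicative noise, so the
   whole pipeline is testable end to end and the generating law serves as
   ground truth.

## Worked example

`examples/02_train_and_evaluate.py` generates a 378-record synthetic study
(18 systems, 283–363 K, dilution series with three cosolvents), splits it
80/9/11 and trains a 9‑8‑1 network:

```
records: 378; trained parameters: 89
final alpha=4.46 beta=5.32e+03 gamma=58.4 effective parameters
   train: n= 302  R2=0.99954  RMSE=0.01754  AARD=2.14%
    test: n=  34  R2=0.99878  RMSE=0.01901  AARD=1.90%
external: n=  42  R2=0.99909  RMSE=0.02447  AARD=2.58%
```

RMSE is in decades of `log10 η`; AARD is the mean relative deviation of
the predicted `log η`; `gamma` says that the evidence framework is using
~58 of the 89 weights — the rest are pruned by the adaptive penalty. The
other examples cover descriptor construction, the Williams plot
(coverage 99.21% on this study), PaD contributions and an extrapolation
check with leverage guards.

The same workflow is scriptable from a shell:

```bash
desvisc simulate --out work --seed 3
desvisc train --dataset work/dataset.csv --profiles work/profiles \
              --model work/model.json --arch 9,19,16,1 --seed 3
desvisc predict --model work/model.json --profiles work/profiles \
                --queries work/dataset.csv --dataset work/dataset.csv \
                --out work/predictions.csv
```

`predict` reports both `log10 η` and `η` in mPa·s and attaches a
leverage-based applicability-domain flag to every query.

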