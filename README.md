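# bindspec

Quantitative analysis of the binding of an anionic porphyrin photosensitizer
(TSPP, 5,10,15,20-tetrakis(4-sulfonatophenyl)porphyrin) to human serum
albumin (HSA) from single-wavelength spectroscopic data, plus the companion
kinetic and thermal-stability analyses.  It is written for photochemists and
drug-delivery researchers who quantify ligand–plasma-protein interactions
with UV–VIS titrations, laser flash photolysis, circular dichroism and
differential scanning fluorimetry (DSF), and want the full numerical chain —
from raw series to binding constants — scripted, testable and reproducible.

## What it computes

**Single-class binding isotherm.**  For a ligand L binding `n` identical,
independent sites on a protein P with dissociation constant
`K_d = [L][P]/[LP]`, mass balance turns the equilibrium into a quadratic in
the bound-species absorbance `xA_LP`:

```
xA_LP = ½ l ε_b [ C_T + nC_H + K_d − √((C_T + nC_H + K_d)² − 4 nC_H C_T) ]
```

where `C_T`, `C_H` are total ligand and protein concentrations, `l` the path
length and `ε_b` the bound-state extinction coefficient.  Only the minus
root is physical (the plus root exceeds the total-ligand absorbance).  The
bound fraction `x = (A_obs − A_L)/(A_LP − A_L)` is reconstructed from three
parallel reference titrations (ligand only / low protein / protein excess)
and `(n, K_d, ε_b)` are fitted by bounded trust-region least squares.

**Two-class Scatchard analysis.**  For two site classes `(n₁, K_d1)`,
`(n₂, K_d2)` the Scatchard plot

```
[LP]/(C_H·[L])  versus  ν = [LP]/C_H
```

is curved; its limiting slopes are `−1/K_d1` (ν→0) and `−1/K_d2` (ν→∞), the
vertical intercept is `n₁/K_d1 + n₂/K_d2` and the x-intercept `n₁ + n₂`.
Two straight lines fitted to the low- and high-occupancy subsets give the
classic rough estimates (and an `exact_intercepts` variant solves the
intercept system instead of using the `K_d1 ≪ K_d2` approximations).

**Triplet-decay kinetics.**  Transient absorbance decays
`ΔA(t) = ΔA₀ + Σ Aᵢ exp(−t/tᵢ)` are fitted with one or two exponentials and
summarised by the amplitude-weighted average lifetime
`t_av = Σ Aᵢtᵢ² / Σ Aᵢtᵢ`.

**Transition detection.**  Segmented linear regression (exhaustive search
over contiguous partitions, 2 or 3 segments, breakpoints from line
intersections) locates mechanism changes in ellipticity-vs-concentration or
-vs-temperature series; melting temperatures are the first-derivative maxima
of DSF melt channels (Savitzky–Golay derivative with peak refinement).

**Synthetic data.**  Every input has a generator with known ground truth
(`bindspec.simulate`), defaulting to the study conditions: titration grid
0.54–6.04 µM ligand with 2/75 µM protein, fixed-ligand 5 µM vs 1–12 µM
protein, 400 µs / 2 ms decay lifetimes, and two-transition melt curves at
56.2 / 72.2 °C.

## Worked example

```python
from bindspec import SingleSiteBinding
from bindspec.simulate import gen_titration, NoiseSpec

series = gen_titration(noise=NoiseSpec(sigma=0.005, seed=1))
print(SingleSiteBinding(series).fit().summary())
```

```
Single-class binding fit
========================
points                  12
n_sites           2.852  +/- 0.089
k_d (uM)          0.528  +/- 0.2
eps_b (1/uM/cm)  0.2096  +/- 0.0093
k_b (1/uM)        1.894
R^2              0.9996
```

The generator simulated a 12-point three-solution titration from the ground
truth `n = 2.7`, `K_d = 0.3 µM`, `ε_b = 0.20 µM⁻¹cm⁻¹` with 0.005 absorbance
noise; the refit recovers about 2.9 sites per albumin and the bound-state
extinction within 5%, while `K_d` — weakly constrained by this design, as
its large standard error shows — scatters more.  The same pattern holds for
the other stages:

```python
from bindspec import MeltAnalysis
from bindspec.simulate import gen_melt
print(MeltAnalysis(gen_melt(noise=NoiseSpec(sigma=0.0, seed=0))).find_tm().summary())
```

```
Melting temperatures (f350 derivative peaks)
============================================
smoothing: degree 2, window 21 points
Tm = 56.20 C   dF/dT = 523
Tm = 72.20 C   dF/dT = 523
```

## Command line

Each generator has a CLI twin writing a CSV plus a ground-truth sidecar, and
each analysis stage reads those CSVs and writes a JSON report:

```bash
bindspec simulate-titration -o titration.csv --seed 11
bindspec fit-titration titration.csv --out results/
bindspec simulate-melt -o melt.csv --sigma 0
bindspec find-tm melt.csv --out results/
```

`bindspec run config.yaml` executes a YAML-configured stage; unknown keys
are rejected before any computation.

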