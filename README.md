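# fcscreen

Fluorescence-fluctuation analysis for screening small molecules against
amyloid-β aggregation.

Fluorescence correlation spectroscopy (FCS) watches the intensity
fluctuations produced by single fluorescent molecules diffusing through a
femtoliter-scale confocal volume.  The decay time of the intensity
autocorrelation reports molecular size (diffusion time τ_D), its
amplitude reports concentration (1/N), and the count rate per particle
(CPP) reports how many fluorophores travel together — i.e. oligomer
size.  Combined with thioflavin T (an amyloid-binding dye) or FRET
between donor/acceptor-labeled peptides, these readouts follow amyloid
aggregation in solution over hours and quantify whether a compound
inhibits or accelerates it.

`fcscreen` implements that computational chain end to end:

* **Correlation model** — the normalized confocal 3D-diffusion
  autocorrelation with triplet blinking,

  G(τ) = 1 + (1/N) · [1 + F/(1−F) · e^(−τ/τ_T)] ·
  Σᵢ fᵢ (1 + τ/τ_D,i)⁻¹ (1 + τ/(s²τ_D,i))⁻¹ᐟ²,

  with one or two diffusing components (Σfᵢ = 1), the weighted diffusion
  time τ_w = Σᵢ fᵢ τ_D,i, and observation-volume calibration from a
  reference dye (w₀ = √(4·D_ref·τ_D,ref), z₀ = s·w₀,
  V_eff = π³ᐟ² w₀² z₀; e.g. rhodamine 6G, D = 414 µm²/s).
* **Correlator** — a multi-tau estimator (16 lags per stage, bin
  doubling) with symmetric normalization and segment-based standard
  errors, plus a brute-force direct estimator kept as the reference.
* **Fitting** — Levenberg–Marquardt estimation of
  (N, F_T, τ_T, fᵢ, τ_D,i) with fixed structure parameter, model-variant
  selection (1/2 components, ± triplet), and median/quartile summaries of
  repeated measurements (e.g. 30 × 10 s per time point).
* **Brightness & dose–response** — CPP = CR/N in the acceptor channel of
  FRET-FCS, 4-parameter-logistic IC50 fits of CPP versus compound
  concentration, and a deterministic no-effect / inhibition /
  acceleration classifier for time-lapse trajectories.
* **Viability** — CV = 100·(total − dead)/total with Welch-t comparison
  across conditions.
* **Simulator** — Brownian dynamics of point emitters in a periodic box
  with a 3D-Gaussian detection profile and Poisson counting, plus fast
  generators for noisy correlation curves, sigmoidal aggregation time
  courses and 4PL dose–response tables.  Every stage of the pipeline is
  therefore testable against known ground truth without instrument data.

## Worked example

Simulate a recording of a single diffusing species (D = 15 µm²/s in a
w₀ = 0.25 µm volume, so τ_D = w₀²/4D ≈ 1.04 ms), correlate and fit it:

```python
import fcscreen as f

species = f.SpeciesSpec("monomer", diffusion_coefficient=15.0,
                        mean_copies=3.0, brightness=(3e4,))
config = f.SimulationConfig(species=(species,), bin_time=5e-5,
                            duration=20.0, lateral_radius=0.25,
                            axial_radius=1.25)
trace = f.simulate_trace(config, seed=1)
curve = f.autocorrelate(trace)
fit = f.fit_curve(curve, n_components=1, triplet=False,
                  structure_parameter=5.0)
print(f"count rate {f.count_rate(trace):.0f} counts/s")
print(f"tau_D = {fit.params.components[0].diffusion_time*1e6:.0f} us, "
      f"N = {fit.params.n_particles:.2f}")
```

Output:

```
count rate 31870 counts/s
tau_D = 1034 us, N = 3.01
```

The fitted diffusion time is within 1% of the 1042 µs implied by the
simulated diffusion coefficient, and the fitted particle number matches
the configured mean occupancy of the effective volume (3.0).

The same flow is available from the shell:

```sh
fcscreen simulate-trace --species monomer:15:3:30000 \
    --bin-time 5e-5 --duration 20 --seed 1 --out run/
fcscreen correlate --trace run/trace.tsv --out run/
fcscreen fit --curve run/curve.tsv --components 1 --no-triplet \
    -s 5.0 --out run/
fcscreen calibrate --tau-d 25e-6 -s 5       # rhodamine 6G volume calibration
```

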