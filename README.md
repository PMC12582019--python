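# g4fold

Quantitative analysis of G-quadruplex (G4) folding measurements:
single-molecule FRET trajectories, circular-dichroism (CD) spectroscopy,
binding titrations and NMR chemical-shift perturbations, with seeded
synthetic-data generators so every estimator can be validated by
parameter recovery.

The package targets the typical study of a metastable G4 — a G-rich DNA
sequence whose folding is driven by K⁺ and can be stabilized and
accelerated by a protein ligand — and the quantities such a study
reports: FRET population fractions, folding/unfolding rates, G4 topology
calls, melting midpoints, dissociation constants.

## Models and statistics

**Two-state smFRET kinetics.** A surface-immobilized molecule carries a
donor/acceptor pair; the apparent FRET efficiency per frame is
E = I_A / (I_A + I_D) after background subtraction. The conformation is
modeled as a two-state continuous-time Markov process — a low-FRET
(unfolded/compacted) state and a high-FRET (folded G4) state — with rates
k_lh (folding) and k_hl (unfolding), sampled at the camera frame interval
Δt, so the per-frame switching probability is 1 − exp(−kΔt). Per-molecule
FRET values (mean of the first 15 valid frames) are histogrammed and
decomposed into one or two Gaussian populations; the percent area
a·σ of each component gives the population fractions. Frames are assigned
to states by thresholding at the midpoint of the fitted means, maximal
runs become dwells, and rates are estimated from the dwell statistics.
Three estimators are provided; the headline one is the censoring-aware
occupancy estimator k = (transitions out of the state) / (time spent in
the state), which stays unbiased when mean dwells approach the trace
length. The folding equilibrium is summarized as
ΔG = −RT ln(K_eq) with K_eq from fractions or from rates.

**CD spectroscopy.** Spectra are Savitzky–Golay smoothed and classified
by the canonical G4 band rules (parallel: +264/−240 nm; antiparallel:
+295/+240/−260 nm; hybrid or mixture: +264 and +290 nm). In-situ folding
kinetics follow f(t) = a(1 − e^(−bt)) or the two-phase form
a(1 − e^(−bt)) + c(1 − e^(−dt)), selected by an F-test with an
identifiability guard (b/d ≥ 3). Thermal melting is fitted with the
Boltzmann sigmoid θ(T) = θ_f + (θ_u − θ_f)/(1 + exp((T_m − T)/w)).

**Binding.** Titrations are fitted with the single-site isotherm with
ligand depletion: the bound fraction of labeled DNA is the root of the
binding quadratic f = ((P + D + K_D) − √((P + D + K_D)² − 4PD))/(2D).
Unsaturated series are flagged. Amide chemical-shift perturbations are
combined as CSP = √((0.102·Δδ_N)² + (Δδ_H)²) and ranked with a
mean + 1 SD outlier rule.

## Worked example

```python
from g4fold import TwoStateModel, run_smfret_workflow

model = TwoStateModel(k_lh=0.011, k_hl=0.050, e_low=0.49, e_high=0.85,
                      frame_interval=0.3, n_frames=300, seed=1)
report = run_smfret_workflow(model=model, n_molecules=200)

report["populations"]["means"]              # [0.490, 0.849]
report["populations"]["fractions_percent"]  # [80.9, 19.1]
report["rates"]["low->high"]["occupancy"]   # rate 0.0119 +/- 0.0009 1/s
report["rates"]["high->low"]["occupancy"]   # rate 0.0446 +/- 0.0034 1/s
report["energetics"]["dG_rates_kJ_mol"]     # +3.23 kJ/mol (K_eq = 0.27)
```

The simulated ensemble was generated with folding rate 0.011 s⁻¹ and
unfolding rate 0.050 s⁻¹; the full pipeline (bleach detection, FRET
conversion, two-Gaussian decomposition at centers ≈0.49/0.85, state
assignment, dwell extraction) recovers 0.0119 and 0.0446 s⁻¹. The
positive ΔG says the folded high-FRET state is the minority at these
rates (stationary occupancy k_lh/(k_lh+k_hl) ≈ 18%, matching the fitted
19.1% high-FRET fraction).

The same analyses are available from the shell:

```
g4fold simulate traces --out traces.tsv --n-molecules 200 --seed 1
g4fold workflow smfret --traces-path traces.tsv --out report.json
g4fold simulate melt --out melt.tsv --tm 52.8 --noise-sd 0.2
g4fold cd melt melt.tsv
```

## Layout

- `src/g4fold/simulate.py` — seeded generators with ground truth retained
- `src/g4fold/traces.py` — background, FRET, photobleach, histograms
- `src/g4fold/populations.py` — Gaussian decomposition and model selection
- `src/g4fold/kinetics.py` — state assignment, dwells, rates, energetics
- `src/g4fold/cd.py` — smoothing, topology, exponential and melting fits
- `src/g4fold/binding.py` — depletion isotherm and CSP analysis
- `src/g4fold/io.py`, `workflows.py`, `cli.py` — formats, pipelines, CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
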