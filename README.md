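# lupusim

Mechanistic simulation of innate immune-cell amplification at the onset of
lupus nephritis.

Lupus nephritis in lupus-prone NZB/W F1 mice begins with a burst of type-I
interferon (IFN-I), the activation of kidney-resident helper ILC, and the
recruitment of NK cells, monocytes and macrophages that together damage the
tissue. In genetically predisposed animals the damage feeds back — through
immune-complex deposits and further IFN-I release — onto the same cells
that caused it, and the circuit can lock into a chronic, self-amplifying
state. `lupusim` implements this course of events as a coupled ODE system
of nine cell-state variables, four tissue cytokines and an algebraic IFN-I
level, together with

* a generic modelling toolkit (cubic Hill gating `h[x,K] = x³/(K³+x³)`,
  capped drive sums, Erlang delay chains `R[k,n]` via the linear chain
  trick, declarative network assembly) in `lupusim.framework`;
* the specific lupus model (genotypes NZB/W vs wild type, poly(I:C)
  stimulation weeks 19–23, tILC/vNK depletion, feedback knockouts
  F1–F5) in `lupusim.model` / `lupusim.params` / `lupusim.schedule`;
* a hybrid stochastic extension in which spontaneous acute inflammatory
  events — a telegraph process with Erlang-distributed episode durations,
  sampled exactly by the Gillespie algorithm — drive immune-complex
  deposition (`lupusim.telegraph`, `lupusim.hybrid`);
* the in-silico experiment suite: ESRD-referenced outcome normalisation,
  ±20% sensitivity scans, depletion strength and timing grids, log-normal
  virtual cohorts, hybrid cohorts and the switching-frequency
  (stochastic-resonance) scan (`lupusim.analysis`);
* a command-line interface (`lupusim simulate|hybrid|knockout|deplete|
  cohort|sensitivity|calibrate|rerun`) with scenario presets, tidy CSV
  output and JSON run manifests sufficient for bit-compatible re-runs.

Disease outcomes are normalised to an end-stage renal disease (ESRD)
reference: 95% of the maximal damage of the default stimulated NZB/W run;
pre-ESRD — the model's proteinuria proxy — is 70% of that value, read out
at week 25 of age. See `docs/methods.md` for the model equations,
parameter provenance, the calibration constraint set and numerical choices.

## Worked example

```python
from lupusim import (default_parameters, InterventionSchedule, simulate,
                     esrd_reference, time_to_esrd, ifn_peak_times)

params = default_parameters()            # calibrated NZB/W defaults
ref = esrd_reference(params)             # ESRD/pre-ESRD normalisation

# stimulated lupus-prone run, stopped at end-stage renal disease
traj = simulate(params, InterventionSchedule(), horizon=40.0,
                stop_at_damage=ref.esrd_damage)
print("IFN-I maxima (weeks):", [round(t, 1) for t in ifn_peak_times(traj)])
print("time to ESRD (weeks):", round(ref.esrd_week, 1))

# wild-type contrast: transient damage, full recovery
wt = simulate(params, InterventionSchedule(genotype="wt"), horizon=40.0)
print("WT damage at week 35 / peak:",
      round(wt.at(35.0, "x8") / wt.damage.max(), 3))

# untreated lupus-prone mice: late spontaneous onset
untreated = simulate(params, InterventionSchedule(polyic_window=None),
                     horizon=60.0)
print("untreated time to ESRD (weeks):",
      round(time_to_esrd(untreated, ref), 1))
```

prints

```
IFN-I maxima (weeks): [23.0, 26.1]
time to ESRD (weeks): 31.4
WT damage at week 35 / peak: 0.073
untreated time to ESRD (weeks): 38.7
```

The stimulated run shows the two-peak interferon response — the first peak
at the end of the poly(I:C) window, the second when damage- and
immune-complex-driven IFN-I release saturates — and progresses to ESRD,
while the wild-type run recovers and the untreated lupus-prone run ignites
spontaneously almost two months later. The same objects drive the
cohort experiments, e.g.

```python
from lupusim import cohort_pre_esrd_fraction
frac, se = cohort_pre_esrd_fraction(params, InterventionSchedule(),
                                    n=1000, sd_fraction=0.1, seed=1, ref=ref)
```

which perturbs every rate parameter log-normally (~10% CV) per virtual
animal and reports the fraction with pre-ESRD damage at week 25.

Command-line equivalents:

```sh
lupusim simulate nzbw_polyic --stop-at-esrd -o out/
lupusim cohort aagm1 --n 1000 --seed 1 -o out/
lupusim hybrid nzbw_hybrid --seed 7 -o out/
```

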