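# dcishist

Microsimulation of the natural history of preclinical ductal carcinoma in
situ (DCIS) with mammography screening superimposed counterfactually.

The model tracks one breast lesion per woman through a multi-state graph:
normal tissue → preclinical undetectable DCIS → (optionally) preclinical
screen-detectable DCIS → one of three exits — preclinical invasive breast
cancer (P1), clinical DCIS (P2), or regression to no breast cancer (P3) —
with preclinical invasive disease surfacing clinically after a further
dwell.  Six canonical submodels cross three undetectable→screen-detectable
progression fractions (30%, 50%, 80%) with regression allowed or
prohibited.  Dwell times are path-conditional exponentials, so each exit
path carries its own mean sojourn time (MST).

Every woman is simulated twice — a screened and an unscreened universe —
sharing all natural-history randomness via per-woman substreams keyed by
(master seed, woman id).  Screen detection uses period-specific
mammography sensitivity for DCIS (0.45 / 0.55 / 0.70 / 0.85 for 1975–1984,
1985–1999, 2000–2009, 2010 onwards) and is an absorbing excision.  The
paired universes support counterfactual overdiagnosis accounting: a
screen-detected case is overdiagnosed iff it would never have surfaced
clinically in the unscreened universe before other-cause death.

## Modules

| module | contents |
|---|---|
| `natural_history` | submodel configs, parameter set, onset hazard, lesion trajectory sampling |
| `screening` | sensitivity schedules, dissemination patterns, screen-schedule generation, detection overlay |
| `cohort_sim` | life tables, paired-universe population engine (birth cohorts 1890–1996) |
| `outcomes` | incidence tables (age-standardized over 30–79), empirical MSTs, progression proportions, overdiagnosis |
| `gof_calibration` | chi-square goodness of fit on yearly age-adjusted rates; Nelder–Mead calibration with common random numbers |
| `synthetic_data` | ground-truth life tables, dissemination ramps, standard weights, SEER-like observed incidence |

## CLI

```bash
# generate a synthetic world with known truth (writes 4 CSVs + manifest + config)
dcishist synth --scenario 2b --seed 3 --out out/synth

# simulate a paired population from a config; writes events + outcome CSVs
dcishist simulate --config out/synth/config.yaml --n 20000 --seed 1 --out out/run

# fit free parameters to an observed-incidence CSV
dcishist calibrate --config out/synth/config.yaml \
    --observed out/synth/observed_incidence.csv \
    --free "p1=0.2:0.95" --n-sim 8000 --seed 1 --out out/fit
```

## Library example

```python
from dcishist.synthetic_data import scenario
from dcishist.cohort_sim import simulate_population
from dcishist.outcomes import compute_incidence, compute_overdiagnosis, estimate_mst

scn = scenario("2b", seed=1)
log = simulate_population(scn.population_spec(n_women=50_000))
incidence = compute_incidence(log, "screened")
report = compute_overdiagnosis(log)
mst = estimate_mst(log)  # unscreened universe, per exit path
```
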