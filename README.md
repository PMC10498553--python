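# perspecta

Multi-perspective cost-effectiveness analysis toolkit: an individual-level
state-transition Monte Carlo engine with dual-perspective (patient / health
sector) cost and DALY accounting, probabilistic sensitivity analysis (PSA),
efficiency-frontier/ICER/CEAC analytics, annuity-based affordability
assessment, and a five-pattern perspective-congruence decision framework.
The package ships the Mozambique HIV treatment case — six ARV delivery
strategies parameterized from published values — as its worked example.

## Layout

| module | contents |
| --- | --- |
| `perspecta.params` | distribution specs (point / PERT→beta), `ParameterSet`, strategy and run configuration, YAML I/O, the packaged `data/mozambique.yaml`, synthetic fixtures |
| `perspecta.disease` | 17-state model (4 CD4 bands × 4 care statuses + death), rate/risk/odds-ratio→monthly-probability conversions, per-strategy `TransitionModel` |
| `perspecta.engine` | seeded, vectorized monthly-cycle microsimulation with half-cycle-corrected discounting, YLD+YLL DALY accounting, per-person results |
| `perspecta.economics` | patient (travel + time) and health-sector (ARV + facility + viral load + case management) per-cycle cost models |
| `perspecta.cea` | efficiency frontier with strict and extended dominance, ICER ladders, NMB-equivalent optimum, annuity annualization, affordability, CEACs |
| `perspecta.framework` | five-pattern congruence classifier (perfectly/weakly congruent, incongruent, consistent, inconsistent) and report rendering |
| `perspecta.pipeline` | end-to-end orchestration: base case → frontiers → affordability → verdict → PSA → CEACs, with a run manifest |
| `perspecta.casedata` | published per-strategy results of the Mozambique case used by the deterministic analytics |

## CLI

```bash
# full pipeline on the packaged Mozambique case at desk scale
perspecta run --scale 0.05 --seed 42 --outdir results/

# one strategy's cohort, per-person CSV
perspecta simulate --strategy clinical_6m --n 10000 --seed 1 --out persons.csv

# analytics on prepared CSVs
perspecta cea --results points.csv --out icer.csv
perspecta ceac --psa-results psa.csv --out ceac.csv
perspecta afford --results costs.csv --threshold 4.14
perspecta classify --hs-results hs.csv --patient-results patient.csv \
    --wtp 140.1 --threshold 4.14
```

`perspecta run` writes `icer_{patient,health_sector}.csv`,
`ceac_{patient,health_sector}.csv`, `affordability.csv`, `psa_results.csv`,
`verdict.txt`, and `manifest.json`. All randomness flows from the single
`--seed`; identical inputs give byte-identical outputs.

## Notes on the case model

- PERT parameters use the classic λ=4 beta parameterization sampled on
  their (min, mode, max) support; base-case values are the modes.
- Rates convert to monthly probabilities by constant-hazard exponentials,
  n-month risks by geometric de-compounding, and the multi-month LTFU odds
  ratios apply to the 1-month strategy's 2-year risk on the odds scale.
- All strategies force 1-month clinical refills during the first 3 months
  on ART and while CD4 < 200; the mixed strategy assigns persons 50/50 to
  its clinical 6-month and community 3-month arms at baseline.
- The patient per-visit cost is reconstructed from published travel/time
  inputs (band-midpoint transit times, time valued at net national income
  over 2000 h/year); it reproduces the published cost *orderings* and
  approximate magnitudes, which is the model's calibration target.
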