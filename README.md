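# phagedyn

Hybrid deterministic–stochastic simulator of lytic phage / bacteria
population dynamics with CRISPR-type adaptive immunity, plus the matching
assay estimators.

The community is organised in *orders*: bacteria `B_0..B_n` by the number of
spacers carried, phage `P_0..P_m` by the number of escape (protospacer/PAM)
mutations; a phage of order `j` replicates only on hosts of order `i <= j`
and is destroyed by adsorption to any higher-order host. The model couples:

- Monod resource-limited batch growth with explicit resource depletion;
- mass-action adsorption and a fated infected state with an exact
  latent-period delay (circular flux buffer, `lam` an integer multiple of `dt`);
- burst release of `beta - 1` particles per lysed cell;
- Monte Carlo creation of single spacer-acquiring survivors (probability `m`
  per replicative infection) and single escape-mutant particles (probability
  `mu` per released particle), in the per-step unit-event scheme or a
  Poisson-count variant for large fluxes;
- an optional lysis-released compound (`LY`) that kills dividing cells and
  drives entry into a phage-shielded persister pool;
- a serial-transfer protocol (periodic dilution into fresh medium, with
  optional binomial resampling of small populations).

Estimators: log-linear growth-rate regression with 95% CI, one-step growth
analysis (latent period and burst size from windowed PFU means),
escape-mutant plating frequency, and a polynomial density→OD calibration
with a floor for the low-density artifact region.

## Layout

| module | contents |
|---|---|
| `phagedyn.core` | parameters, community state, delay buffer, deterministic fluxes |
| `phagedyn.engine` | Euler + Monte Carlo integrator, transfers, time series |
| `phagedyn.extended` | lysis-compound extension (killing, persistence) |
| `phagedyn.estimators` | growth-rate / one-step / plating-frequency / OD routines |
| `phagedyn.scenarios` | named presets and synthetic-assay fixture generators |
| `phagedyn.io` | YAML/JSON scenario configs, TSV/CSV trajectory serialization |
| `phagedyn.cli` | `phagedyn` command-line interface |

## CLI

```sh
phagedyn presets                                  # list named scenarios
phagedyn simulate --preset fig2 --seed 1 --out ts.tsv
phagedyn simulate my_scenario.yaml --out ts.tsv   # YAML or JSON config
phagedyn transfers --preset fig11-serial --seed 0 --n-transfers 9 --out days.tsv
phagedyn export-preset fig10bcd --out scen.yaml

phagedyn fixtures growth-curve --v 1.37 --noise-sd 0.1 --seed 4 --out curve.tsv
phagedyn fixtures one-step --out onestep.tsv
phagedyn fixtures lysate --mu 1e-6 --seed 1

phagedyn estimate growth  --input curve.tsv --window 0 2
phagedyn estimate onestep --input onestep.tsv
phagedyn estimate cemfreq --plaques-bim 50 --dilution-bim 10 \
                          --plaques-wt 100 --dilution-wt 1e6
```

Trajectories are written as TSV (`time_h, r_ug_ml, B0.., P0.., Mij.., LY,
BP0, BP1`) with the event log in a sibling `*.events.tsv`; estimator output
is JSON. Exit codes: 0 success, 2 validation error, 1 runtime failure.
Runs are pure functions of (config, seed), and `--log-level INFO` logs the
fully resolved parameter set so any output is reconstructable from its log
line.

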