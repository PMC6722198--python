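# btu — 2D brain tissue unit drug distribution simulator

`btu` simulates the concentration–time profile of a drug inside a single
50 × 50 µm unit of brain extracellular fluid (ECF) bounded on all four
sides by capillaries. Free drug obeys an advection–diffusion PDE coupled at
every grid node to two binding ODEs (specific, saturable target sites and
non-specific, high-capacity sites). The capillary walls carry Robin
(flux-matching) boundary conditions: the inward diffusive flux density
equals `P·(Cpl(t) − C_wall)`, where the blood-plasma forcing `Cpl(t)` is a
closed-form IV bolus or oral (two-exponential) profile. The system is
discretized with second-order central finite differences (method of lines,
ghost-node elimination for the Robin walls) and integrated with an adaptive
implicit BDF scheme using the stencil's sparse Jacobian pattern.

Everything is deterministic — there is no randomness anywhere, and the CLI
deliberately refuses a `--seed` flag.

## Layout

| module | contents |
| --- | --- |
| `btu.model_core` | parameter dataclasses, physiological-range validation, canonical presets |
| `btu.plasma_pk` | analytic plasma forcing (IV / oral), peak and AUC identities |
| `btu.binding_kinetics` | reaction terms, algebraic equilibria, occupancy |
| `btu.pde_solver` | grid, semi-discrete RHS, `simulate`, dimensionless groups |
| `btu.oracles_checks` | independent 0D well-mixed oracle, mass-balance / symmetry auditors |
| `btu.experiments` | scenario suite (binding on/off, kinetic and permeability sweeps, spatial maps) with named checks |
| `btu.io_cli` | TOML config, CSV/JSON serialization, the `btu` CLI |
| `btu.figures` | per-figure CSV + PNG outputs |

## CLI

```bash
# default run (Table-of-defaults parameters, 51×51 grid, t_end = 2e5 s)
btu simulate --outdir out/

# overrides: config file, grid, horizon, snapshot times
btu simulate --config my.toml --grid 101 101 --t-end 1e5 --snapshots 250,1000,5000

# one-parameter multiplicative sweep
btu sweep --param P --multipliers 0.1,1,10 --outdir sweep_out/

# reproduce the scenario figures (CSV + PNG per figure id)
btu figures --which 2,3,7,8 --outdir figs/

# verification suites; exits 3 on failure
btu check --suite mass        # conservation audit vs boundary influx
btu check --suite symmetry    # v = 0 mirror symmetry
btu check --suite oracle      # analytic well-mixed limit
btu check --suite convergence # Richardson order on nx ∈ {11,21,41}
```

Exit codes: 0 success, 1 validation/config error, 2 solver failure,
3 failed check suite.

Config files are TOML with keys named after the model symbols
(`D_eff, v, P, B1max, k1on, k1off, B2max, k2on, k2off, F, Dose, ka, ke, V,
xr, yr, nx, ny`) plus optional `[solver]` and `[output]` tables. Unknown
keys are errors; missing keys use the defaults. Units: m, s, µmol/L,
µmol (Dose), L (V).

A run writes `timeseries.csv` (`t,C_pl,C_ECF_center,B1_center,B2_center`),
`snapshots.csv` (`t,i,j,x_m,y_m,C,B1,B2`) and `meta.json` (full parameter
set with per-key provenance, dimensionless groups, solver diagnostics).

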