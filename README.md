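# retinoflux

Analysis toolkit for radiolabeled retinol (ROH) transport assays across
brain-microvascular-endothelial-cell (BMEC) monolayers:

- **speciation** — mass-action equilibrium distribution of ROH among its
  serum carriers: free ROH, apo/holo retinol-binding protein (RBP) and the
  ternary ROH-RBP-transthyretin (TTR) complex, including non-binding mutant
  carriers (complexation abolished via an infinite dissociation constant).
- **radiometry** — scintillation counts (DPM) to molar amounts and
  concentrations, cell-volume geometry, TEER area correction.
- **kinetics** — monophasic partitioning and biphasic uptake models (a
  secondary storage phase triggers once the cellular concentration crosses a
  threshold), global nonlinear least-squares fitting with seeded
  multistarts, extra-sum-of-squares F test / AIC model comparison, and the
  free-versus-carrier-delivered contribution analysis.
- **permeability** — sampling-corrected cumulative basolateral amounts,
  apparent permeability (Pe_app, cm/s), mass-balance closure, and apical /
  cellular normalizations.
- **synthetic** — seeded simulators for accumulation time courses and
  dual-tracer Transwell assays (three-compartment RK4 integration with
  exact sampling events; Gaussian-CV or Poisson counting noise).
- **workflow** — configuration, CSV/JSON I/O and an end-to-end pipeline
  producing a JSON report with manifest.

Unit policy throughout: concentrations in uM, time in minutes, volumes in
litres, Pe in cm/s.

## CLI

```sh
retinoflux speciate --config cfg.json            # one equilibrium solve (JSON out)
retinoflux speciate --config cfg.json --table    # delivery-mode CSV table
retinoflux simulate accumulation --seed 0 --out data/
retinoflux simulate transwell    --seed 0 --out data/
retinoflux fit-accumulation --data data/accumulation.csv --model biphasic --compare --out fit.json
retinoflux permeability --data data/transwell.csv --out pe.json
retinoflux run --seed 0 --out results/           # full pipeline + report.json
```

`cfg.json` for `speciate`:

```json
{"total_roh_uM": 2, "total_rbp_uM": 2, "total_ttr_uM": 4,
 "kd_roh_rbp_uM": 0.1, "kd_holo_ttr_uM": 0.25, "variant": "wt"}
```

## Library example

```python
import numpy as np
from retinoflux import (EquilibriumSystem, KineticParams, Timecourse,
                        fit_accumulation, predict_biphasic, solve_ternary)

state = solve_ternary(EquilibriumSystem(2, 2, 4, 0.1, 0.25))
print(state.free_roh)  # ~0.135 uM free ROH

p = KineticParams(kp=90, k1=0.02, kp_star=70, k1_star=0.01, ccell_star=36)
t = np.arange(5.0, 125.0, 5.0)
tc = [Timecourse(cf=cf, times=t, ccell=predict_biphasic(p, cf, t))
      for cf in (0.1, 0.4, 2.0)]
fit = fit_accumulation(tc, "biphasic", seed=0)
```
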