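# spinetraffic

Stochastic compartmental modelling of AMPA-receptor (AMPAR) trafficking on a
spiny dendritic segment, for computational neuroscientists studying how
synapses share a finite pool of receptors.

Synaptic strength at glutamatergic synapses tracks the number of AMPARs held
at each postsynaptic density (PSD).  Receptors diffuse laterally in the
membrane, are trapped by PSD scaffold proteins, and cycle through
intracellular pools by endo/exocytosis.  Because all of this involves finite,
saturable resources, potentiating or depressing one synapse changes its
neighbours: `spinetraffic` simulates a 2 µm dendrite with five spines and
quantifies this *heterosynaptic plasticity* — the compensatory receptor
loss at non-stimulated synapses after LTP, the gain after LTD, and the way
these changes modulate later inductions.

## Model in brief

Per PSD, scaffolds trap receptors by mass action,

    scaffold + AMPAR  ⇌  scaffold·AMPAR ,   k_f1 = 1 µm²·molecule⁻¹·s⁻¹,
                                            k_b1 = 100 s⁻¹ (basal)

with the LTP scaffold state dissociating at `k_b1/10` and the LTD state at
`10·k_b1`.  LTP/LTD at a spine are induced by releasing 100 copies of a
generic enzyme into its cytosol, which converts that PSD's 300 scaffolds
within a second.  A perisynaptic endocytic zone with 10 copies of a single
endocytic/exocytic enzyme exchanges receptors with a ~100-copy cytosolic
pool per spine.  Free receptors (1000 at rest) hop between well-mixed
membrane compartments at finite-volume diffusion rates.  Everything is
simulated with an exact, numba-compiled Gillespie SSA (tau-leaping and a
mean-field ODE oracle are also provided); receptor and scaffold totals are
conserved exactly.  The only fitted parameters are the four trafficking
rates, frozen in a shipped calibration artifact
(`spinetraffic/data/calibrated_params.json`).

## Worked example

```python
from spinetraffic import make_protocol, run_protocol
from spinetraffic.analysis import summarize_percent_changes

trajs = run_protocol(make_protocol("ltp_at_1", n_replicates=5))
print(summarize_percent_changes(trajs, (10.0, 180.0)).to_string(index=False))
```

```
 psd  t_start  t_end       mean       std  n
   1     10.0  180.0 118.086274 13.692639  5
   2     10.0  180.0  -3.834582  3.406511  5
   3     10.0  180.0 -10.962658  4.312792  5
   4     10.0  180.0  -3.496049  8.938751  5
   5     10.0  180.0  -7.939035  8.640420  5
```

LTP at spine 1 (enzyme released at t = 10 s) roughly doubles PSD1's synaptic
receptor count (+118% here), while every non-stimulated PSD loses receptors
(−3 to −11% across 5 replicates) — heterosynaptic depression emerging purely
from competition for the shared receptor pool.  The `examples/` directory walks through the
other capabilities: resting-state calibration checks and parameter sweeps
(`constitutive_trafficking.py`), multi-spine LTP/LTD with significance tests
(`heterosynaptic_ltp.py`), sequential inductions (`sequential_plasticity.py`),
the two-state scaffold variant (`two_state_model.py`), and the calibration
report (`calibration_report.py`).

A thin CLI wraps the same machinery:

```bash
spinetraffic list-protocols
spinetraffic run ltp_at_12 --out runs/
spinetraffic sweep scaffolds
spinetraffic reproduce fig4
```

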