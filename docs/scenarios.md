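# Scenario YAML schema

`cardiomp run <scenario.yaml>` (and `cardiomp.protocols.run_scenario`)
accepts a YAML mapping with the fields below; all are optional and default
to the healthy three-cycle protocol.

```yaml
name: demo_hf_pump          # run label; names the output CSV
mode: 0d                    # '0d' | 'staged' (tissue-driven <Ta>)
cycles: 3                   # >= 1 cardiac cycles to simulate
heart_rate: null            # bpm; null = 60 healthy / 80 failing heart
heart_failure: true         # apply the dilated-cardiomyopathy transform
pump_rpm: 2100.0            # constant pump set speed (RPM), or use:
pump_schedule:              # piecewise-linear (time_ms, RPM) breakpoints
  - [0.0, 2100.0]
  - [2625.0, 2100.0]
  - [2925.0, 3150.0]
mitral_stenosis_factor: 1.0 # multiplies the mitral resistance (>= 1)
dt: 0.05                    # integrator step, ms
output_dir: runs/demo       # CSV + metrics.json + record.json land here
seed: 0                     # reserved for randomized fixtures; the
                            # simulation path itself is deterministic
overrides:
  pump:                     # PumpParams field overrides
    omega_set_rpm: 2400.0
```

Output CSV columns: `t_ms, P_lv, P_rv, P_ao, P_pa, V_lv, V_rv, Q_mi,
Q_ao, Q_tri, Q_pa, Ta_lv, Ta_rv` plus, when a pump is attached, `omega,
omega_set, I_pump, Q_pump, dP_pump`. Pressures mmHg, volumes ml, valve
flows ml/s, pump flow L/min, speeds rad/s, tension kPa. The `record.json`
manifest carries a SHA-256 per CSV; re-running the same scenario
byte-reproduces them.
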