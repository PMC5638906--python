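# stprnn

A mean-field model of a developing cortical network — one excitatory (E) and
one inhibitory (I) population, recurrently coupled through synapses with
short-term plasticity (STP) — together with the dynamical-systems analyses
needed to study how immature, mostly silent networks produce large
synchronized bursts ("cluster activity") and how that activity sparsifies
around eye-opening.

The package is for computational neuroscientists who want to simulate and
dissect this developmental transition quantitatively: evoked and spontaneous
bursts, hidden unstable states in the fast (firing-rate) dynamics,
inhibition-stabilized-network (ISN) operating regimes, receptor-blockade
experiments, and parameter-substitution experiments that attribute the
sparsification to specific maturational changes.

## The model

The state is ten-dimensional: two rates plus depression/facilitation
variables (x, u) for each connection ij ∈ {EE, EI, IE, II} (first index
postsynaptic). Rates follow a Wilson–Cowan-type threshold-linear system

```
tau_E dE_r/dt = -E_r + [J_E u_EE x_EE E_r - J_I u_EI x_EI I_r + e_E - theta_E]_+
tau_I dI_r/dt = -I_r + [J_E u_IE x_IE E_r - J_I u_II x_II I_r + e_I - theta_I]_+
```

and each connection carries Tsodyks–Markram dynamics driven by its
presynaptic rate A_j:

```
dx_ij/dt = (1 - x_ij)/tau_r_j - u_ij x_ij A_j
du_ij/dt = (U_j - u_ij)/tau_f_j + U_j (1 - u_ij) A_j
```

J, U, tau_r and tau_f are properties of the presynaptic population, so the
instantaneous efficacy of a connection is J_j·u_ij·x_ij. Freezing these
products turns the network into a 2-D static-efficacy system whose fixed
points expose the transient unstable state that gates burst generation.

Parameters at four postnatal stages (P3, P10, P14, P20 — bracketing
eye-opening in rodent visual cortex) ship with the package
(`stprnn.load_stage`); they encode the measured maturation of membrane and
synaptic kinetics, release probabilities, absolute efficacies and activity
thresholds.

## Worked example

```python
import stprnn as sp

# evoked cluster at P10: standard impulse protocol (30 Hz external pulse,
# 1 ms, to the E population, network initially at rest)
params = sp.load_stage("P10")
traj = sp.run_impulse_protocol(params)
event = sp.detect_cluster(traj)
print(sp.ps_net_amp(traj))        # 83.72  (cluster size, dimensionless)
print(event.duration * 1e3)       # 263.3  (cluster duration, ms)
print(event.type)                 # mono_stable: ends back at rest

# after eye-opening the same protocol lands on a spontaneous attractor
for fp in sp.find_fixed_points(sp.load_stage("P14")):
    print(f"({fp.E_r:.3f}, {fp.I_r:.3f})", "stable" if fp.stable else "unstable")
# (0.000, 0.000) stable
# (0.260, 0.000) unstable
# (1.897, 0.897) stable      <- the new attractor; an ISN operating point

# operating-regime area ratio grows across development
for s in sp.STAGE_LABELS:
    print(s, round(sp.aod_ratio(sp.load_stage(s), resolution=101), 3))
# P3 0.0   P10 0.286   P14 1.81   P20 5.124
```

The cluster size is `PS_net_amp = omega * (A_sum_peak - A_sum_baseline)`
with `A_sum = E_r + I_r` and `omega = 1`; its decline across P10 → P14 → P20
(83.7 → 29.7 → 15.1 here) is the model's expression of developmental
sparsification, while `AOD_ISN/AOD_Unstable` measures how the unstable
low-rate region of the operating-regime map is replaced by
inhibition-stabilized states.

The same analyses are scriptable from a shell:

```
$ stprnn simulate --stage P3 --impulse 30 --out run_p3
P3: mono_stable cluster, PS_net_amp=60.64, duration=322.5 ms
$ stprnn simulate --stage P3 --blockade gaba --out run_p3_block
P3:gaba_block: mono_stable cluster, PS_net_amp=65.12, duration=317.4 ms
```

Other subcommands: `fixed-points`, `domain-map`, `perturbation-map`,
`recovery-curve`, `substitution-experiment`, `report-stages`.

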