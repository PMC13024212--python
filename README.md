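# cysredox

A reduced kinetic model of **cysteine allocation under hypoxia** in cancer
cells, with its complete inference workflow: flux-based calibration,
bootstrap practical-identifiability analysis, variance-based Sobol
sensitivity, and steady-state continuation over the hypoxia range with
linear stability analysis.

It is aimed at systems-biology modellers working with exometabolomic data:
extracellular metabolite concentrations measured at two time points, turned
into apparent uptake/secretion fluxes, and used to constrain an intracellular
mechanistic model whose state variables are otherwise unobserved.

## The model

Five intracellular concentrations (mM) evolve over time: cysteine *C*,
reduced glutathione *G*, reactive oxygen species *R*, hydrogen sulfide *S*
and ATP *A*. Hypoxia is a fixed external level *H* ∈ [0, 1].

```
dC/dt = kin·Cext − VG·C/(KG+C) − VS·C/(KS+C) − kC·C
dG/dt = (1+αH)·VG·C/(KG+C) − kRG·G·R
dR/dt = (1+βH)·kROS − kRG·G·R
dS/dt = VS·C/(KS+C) − kS·S
dA/dt = kAO·G·(1−H) + kAS·S − kAd·A
```

Cysteine is imported (kin·Cext) and partitioned between two saturable
branches — glutathione synthesis (VG, KG) and H₂S production (VS, KS) — plus
a basal drain. GSH removes ROS by mass action; hypoxia amplifies both ROS
generation (β) and GSH-synthesis demand (α), and suppresses oxygen-dependent
ATP production, which H₂S partially replaces. Because the *G* and *R*
equations share the bilinear sink kRG·G·R, the Jacobian is structurally rank
deficient: every steady state carries an exactly zero eigenvalue (a neutral
direction in the (G, R) plane) and is at best *normally* attractive.

Calibration minimises the sum of squared **relative** errors between
time-averaged model fluxes, v̄ = (1/24)∫₀²⁴ v(t) dt, and apparent
experimental fluxes v = (M(0) − M(24))/24, over mapped metabolites and
conditions, with multi-start bounded trust-region least squares. Parameter
uncertainty comes from a multiplicative-noise bootstrap with percentile
confidence intervals; output sensitivity from Saltelli-design Sobol indices
(Saltelli-2010 S1, Jansen ST) of four 24 h outputs (A(24), ∫A, ∫R, ∫A/∫R).

## Worked example

```python
import numpy as np
import cysredox as cx

params = cx.default_parameters()          # repository defaults, H = 1
y0 = cx.State(C=0.05, G=1.0, R=0.01, S=0.05, A=1.0)

traj = cx.integrate(y0, params, 24.0)     # 24 h under severe hypoxia
m = cx.output_metrics(traj)
print(round(m.A24, 3), round(m.ATPint, 2), round(m.ROSint, 3))
# 0.202 7.65 0.134

scan = cx.hypoxia_scan(params, np.linspace(0, 1, 11))
print(np.round(scan.ATP[[0, 5, 10]], 3))  # steady-state ATP at H=0,0.5,1
# [2.6   1.402 0.201]
print(f"{cx.stability_report(scan).max_real_part:.2e}")
# 1.78e-15
```

ATP at 24 h is 0.202 mM with a cumulative exposure of 7.65 mM·h and a
cumulative ROS burden of 0.134 mM·h. The continuation shows steady-state ATP
eroding from 2.60 mM (normoxia) to 0.20 mM (severe hypoxia) while the
largest Jacobian eigenvalue real part stays at rounding level — a graded,
bifurcation-free decline.

A command-line interface mirrors the library
(`cysredox simulate|calibrate|bootstrap|sobol|scan|synth --help`).

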