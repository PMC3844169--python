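# fontansim

Closed-loop lumped-parameter (0D) hemodynamics of a pediatric
single-ventricle circulation in the two late stages of the Fontan pathway:
the **bidirectional Glenn anastomosis** (BCPA — superior vena cava sewn to
the pulmonary arteries, inferior vena cava still draining to the heart) and
the **total cavopulmonary connection** (TCPC — both venae cavae routed to
the lungs).  The package quantifies the *acute, pre-adaptation* hemodynamic
changes of the completion surgery — how much transpulmonary flow rises and
how much systemic venous pressure climbs the moment the IVC is re-routed —
and how those changes depend on pulmonary vascular resistance, lower-body
arteriolar resistance, ventricular systolic/diastolic elastance, and mitral
regurgitation severity.  It is aimed at researchers in computational
cardiovascular physiology and at quantitatively minded clinicians studying
perioperative Fontan risk.

## Model

The circulation is a closed circuit of compliant compartments and
resistive–inertial flow segments.  Mass and momentum conservation at each
element give

    dP/dt = (Q_in − Q_out) / C ,
    dQ/dt = (P_up − R·Q − P_down) / L .

The single-ventricle heart has three chambers (RA, LA, LV — the atria
communicate through an atrial septal defect) governed by a time-varying
elastance law with pressure-proportional wall viscoelasticity,

    P_cc(t) = E(t)·V_cc + S_cc·dV_cc/dt ,   E(t) = E_s·e(t) + E_d ,
    S_cc = k_S·P_cc  ⇒  P_cc = E(t)·V_cc / (1 − k_S·dV_cc/dt) ,

with a two-cosine normalized activation e(t).  Cardiac valves follow a
two-mode Bernoulli-resistance law

    ΔP = R_v·Q + B_v·Q·|Q| + L_v·dQ/dt ,

closing on gradient reversal once the jet has decayed; a regurgitant
mitral valve instead admits retrograde systolic flow through an orifice of
effective area A_reg with

    B_reg = ρ/2·(1/A_reg − 1/A_la)² ,   L_reg = 2ρ√π·(1/√A_reg − 1/√A_la) ,

where A_la is the spherical-equivalent left-atrial cross-section.  The
system is integrated with fixed-step RK4 (dt = 1e-4 s) to the periodic
steady state; total stressed blood volume is calibrated so the Glenn-model
mean arterial pressure equals its 72.1 mmHg reference and is then frozen,
so that the TCPC run differs from the Glenn run by exactly one edge of the
circuit — the IVC outlet.  See `docs/methods.md` for the full account.

## Worked example

```python
from fontansim import default_parameters, run_pair

params = default_parameters()          # 17 kg child, calibrated V_tot
glenn, fontan = run_pair(params)

print(f"Glenn : mQ_pul {glenn.mQ_pul:5.1f} mL/s  CO {glenn.CO:5.1f} mL/s  "
      f"mP_ivc {glenn.mP_ivc:4.1f} mmHg  EF {glenn.EF:4.1f} %")
print(f"Fontan: mQ_pul {fontan.mQ_pul:5.1f} mL/s  CO {fontan.CO:5.1f} mL/s  "
      f"mP_ivc {fontan.mP_ivc:4.1f} mmHg  EF {fontan.EF:4.1f} %")
```

prints

```
Glenn : mQ_pul  15.6 mL/s  CO  29.9 mL/s  mP_ivc  5.4 mmHg  EF 62.9 %
Fontan: mQ_pul  18.5 mL/s  CO  18.5 mL/s  mP_ivc  7.7 mmHg  EF 61.5 %
```

Reading: before completion only upper-body venous return (≈16 mL/s of the
≈30 mL/s output) crosses the lungs; after completion the circuit is in
series, so pulmonary flow and cardiac output coincide — transpulmonary
(oxygenated) flow rises ≈18% while cardiac output falls ≈38% and IVC
("central venous") pressure climbs ≈42%, because no adaptation mechanisms
(the model has none, by design) defend the operating point.

The same experiments are scriptable from a shell:

```bash
fontansim run   --topology bcpa --out results/
fontansim sweep --target rpul --grid 0.5:2.5:0.1 --out rpul_sweep.csv
fontansim mvreg --areas 0.01:0.21:0.02 --out mvreg_sweep.csv
fontansim calibrate --target 72.1
```

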