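# il6loop

A qualitative systems-biology model of the **E2F1–STAT3/IL-6/IL6R
autocrine–paracrine loop** between melanoma cells and CD4⁺ T cells,
together with the regulatory screen that nominates IL-6 as the hub of an
E2F1-driven immunomodulatory network — all exercisable on seeded
synthetic data, with no external downloads.

## Who this is for

Researchers studying tumour–immune cytokine crosstalk who want a small,
fully reproducible ODE model of IL-6 signalling between two cell
compartments sharing a culture medium, plus the standard promoter- and
gene-level screening steps (PWM scanning, DEG filtering, network hub
ranking) wired into one tested package.

## The model

Each cell compartment *c* (melanoma or CD4⁺ T cell) carries IL6 mRNA
*m*, free/phosphorylated STAT3 (*S*, *pS*) and free/occupied membrane
IL-6 receptor (*R*, *C*); compartments share one well-mixed extracellular
IL-6 pool *I*:

```
dm/dt  = k0 + k1 · H(E2F1; K_E, h_E) · H(pS; K_S, h_S) − d_m·m
dC/dt  = k_on·I·R − (k_off + k_int)·C            R = R_tot − C
dpS/dt = k_p·C·(S_tot − pS) − k_dp·pS
dI/dt  = Σ_c k_sec·m_c − d_I·I − Σ_c (k_on·I·R_c − k_off·C_c) + infusion
```

with `H(x; K, h) = xʰ/(Kʰ + xʰ)`. IL6 transcription is an **AND-gate**:
E2F1 (a constant input, in arbitrary units) and active STAT3 activate
the promoter multiplicatively, encoding their synergy. Secreted IL-6
binds the receptor, the occupied receptor phosphorylates STAT3, and the
loop closes — autocrine within a compartment, paracrine between
compartments. The two cell types share one kinetic scheme and differ in
expression levels (melanoma: high E2F1, low receptor, constitutive basal
IL6 transcription; CD4⁺: low E2F1, high receptor — membrane IL6R is
largely leukocyte-restricted). Units are arbitrary (a.u.) and hours.

On top of the model the package implements the published simulation
protocols (switch-off initial state; E2F1 scans over 0.1–100 a.u. and
E2F1×STAT3 scans over 0.1–10 a.u., IL-6 read at 100 h), a 10-condition
virtual coculture panel with knockdown/inhibitor/antibody/recombinant-IL-6
perturbations, ultrasensitivity metrics (apparent Hill coefficient via
the EC90/EC10 convention), hysteresis screening, and log-space
least-squares parameter fitting. The regulatory screen covers strict
DEG cut-offs (p < 0.05, |FC| > 1.5), three-way candidate intersection,
degree-based hub ranking (score > 0.4), JASPAR-style PWM scanning at an
85% relative profile score threshold, and composite E2F1/STAT3 element
detection on promoters.

## A worked example

```python
import il6loop as il

panel = il.run_panel(il.standard_panel())
print(panel.table[["condition", "IL6_readout"]].head(7).to_string(index=False))
```

prints (IL-6 in the medium after 72 h of culture, a.u.):

```
              condition  IL6_readout
     melanoma_mono_ctrl    14.901940
       melanoma_mono_kd     9.761609
               cd4_mono     0.000005
         coculture_ctrl    17.019961
           coculture_kd    11.885912
coculture_ctrl_anti_il6     1.482790
  coculture_kd_anti_il6     1.015533
```

Melanoma monocultures secrete IL-6 on their own; CD4⁺ monocultures
essentially none. Coculture exceeds the **sum** of both monocultures
(1.14×) — the paracrine feedback loop amplifies secretion. E2F1
knockdown reduces coculture IL-6 by ~30%, but only knockdown *combined*
with the neutralising antibody drives the panel to its minimum. And

```python
scan = il.scan_E2F1(il.monoculture("cd4"), 0.1, 100, 41)
print(il.ultrasensitivity(scan).n_H)     # 2.05  -> ultrasensitive
```

quantifies the switch-like CD4⁺ dose-response created by the autocrine
feedback. The `examples/` directory holds one short narrative script
per capability (trajectories, scans, the sufficiency contour, motif
detection, the gene screen, parameter recovery); each prints the numbers
it computes and a line on what they mean. A thin CLI mirrors the same
operations (`il6loop scan|scan2d|panel|fit|screen|motif|synth`).

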