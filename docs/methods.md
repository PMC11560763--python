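# Methods

## Model structure

The model is a deliberately minimal, qualitative ODE description of
IL-6 signalling between one or two cell compartments sharing a
well-mixed extracellular medium (volume factors set to 1). Per
compartment the species are IL6 mRNA, free and phosphorylated STAT3,
and free and ligand-occupied membrane IL-6 receptor; the medium holds
extracellular IL-6. The reaction scheme is:

* **Transcription** — basal rate `k0` plus an induced term
  `k1·H(E2F1; K_E, h_E)·H(pS; K_S, h_S)`. The multiplicative (AND-gate)
  composition of the two Hill activations encodes the synergy of E2F1
  and active STAT3 on the IL6 promoter: either input at zero removes
  the induced term entirely, and the response to one factor saturates
  at a ceiling set by the other.
* **Translation + secretion** — lumped into a single first-order flux
  `k_sec·m` into the medium. Intracellular IL-6 protein is not a
  separate state; the quantity read out is extracellular IL-6, the
  species an ELISA on the supernatant measures.
* **Receptor binding** — reversible (`k_on`, `k_off`) with first-order
  internalisation `k_int` that destroys the ligand and recycles the
  receptor, under receptor conservation `R + C = R_tot`.
* **STAT3 activation** — mass-action phosphorylation by the occupied
  receptor under total-STAT3 conservation `S + pS = S_tot`, with
  first-order dephosphorylation.

E2F1 is an *input*, constant per simulation, not a dynamical species:
the protocols scan it as an expression level in arbitrary units. Both
conservation laws are enforced structurally — the integrator carries
only `m`, `pS`, `C` and `I`, and the free pools are reconstructed — so
conservation holds exactly, not merely to integrator tolerance.

Classical signalling only: trans-signalling through soluble IL6R, gp130
stoichiometry, SOCS feedback and JAK intermediates are out of scope.

### Assumptions worth stating

* One shared kinetic scheme for both cell types. The cell types differ
  in expression state: E2F1 level, total STAT3, total receptor, and
  basal IL6 transcription `k0`. Treating `k0` as cell state (rather
  than a shared constant) reflects that melanoma lines express IL-6
  constitutively while resting T cells secrete almost none, and it is
  also structurally necessary: the CD4⁺ compartment's ~10× receptor
  level gives its autocrine loop a far higher gain, and no single
  shared `k0` lets melanoma ignite in coculture while the CD4⁺
  monoculture stays silent and the CD4⁺ switch threshold remains inside
  the scanned E2F1 range.
* `h_S = 2` (pSTAT3 acts as a dimer) is the ultrasensitivity source,
  amplified by the IL-6 → pSTAT3 → IL-6 positive feedback; `h_E = 1`
  keeps the direct E2F1 dose-response graded.
* The antibody perturbation is a first-order sink on the medium rather
  than explicit antibody–ligand binding: one fewer species, same
  qualitative effect. Wet-lab doses (ng/ml, µM) have no a.u.
  conversion in a qualitative model, so all perturbations are
  dimensionless knobs with configurable defaults.

## Parameters

All defaults live in `src/il6loop/data/defaults.yaml`; nothing numeric
is hard-coded in logic. Units: concentrations a.u., time hours.

| parameter | default | meaning |
|---|---|---|
| `k0` | 3·10⁻⁴ (melanoma), 1.5·10⁻⁶ (cd4) | basal IL6 transcription, a.u./h |
| `k1` | 5.0 | maximal induced transcription, a.u./h |
| `K_E`, `h_E` | 1.5, 1 | E2F1 half-activation (a.u.), exponent |
| `K_S`, `h_S` | 0.2, 2 | pSTAT3 half-activation (a.u.), exponent |
| `d_m` | 0.5 /h | mRNA decay (~1.4 h half-life) |
| `k_sec` | 1.0 /h | secretion per mRNA |
| `d_I` | 0.5 /h | extracellular IL-6 clearance |
| `k_on`, `k_off` | 1.0 /(a.u.·h), 0.5 /h | receptor binding |
| `k_int` | 0.02 /h | complex internalisation (ligand destroyed) |
| `k_p`, `k_dp` | 1.0 /(a.u.·h), 0.5 /h | STAT3 (de)phosphorylation |
| melanoma expression | E2F1 10, S_tot 1, R_tot 0.5 | graded high-gain regime |
| cd4 expression | E2F1 0.2, S_tot 1.5, R_tot 5 | switch-like regime |
| perturbation defaults | KD ×0.2, Stattic ×0.1, sink 5 /h, infusion 1 a.u./h | residual factors / rates |

The kinetic values were chosen once, by a small calibration exercise
against the qualitative regimes the model must occupy, and then frozen:
the melanoma instance ignites its autocrine loop from the switch-off
state and responds to E2F1 with high gain across 0.1–100 a.u.; the CD4⁺
instance stays silent in monoculture but is switch-like (apparent Hill
coefficient ≈ 2) once driven; coculture amplifies beyond the sum of the
monocultures; and the E2F1×STAT3 sufficiency contour is a genuine
trade-off curve. The loop-ignition structure behind these choices is a
saddle-node: with dimeric pSTAT3 action the off-state is locally
attracting until basal drive (∝ `k0`·loop gain) removes the low branch,
so placing each instance on the right side of its threshold fixes the
admissible `k0` windows analytically; the remaining constants were
tuned inside those windows by simulation. The default melanoma
instance is bistable for E2F1 roughly in 0.05–0.2 a.u. (the hysteresis
screen detects this window), monostable-high at its default E2F1 = 10.

## Protocols

* **Switch-off initialisation** — all simulations start from zero
  transcript, zero extracellular IL-6, zero receptor occupancy, fully
  dephosphorylated STAT3.
* **Scans** — E2F1 over 0.1–100 a.u. (default 41 log-spaced points) and
  E2F1×STAT3 over 0.1–10 a.u. (default 25×25), each point an
  independent simulation read at 100 h. Readout time is a protocol
  constant, not an integrator property.
* **Panel** — 10 mono/coculture × perturbation conditions cultured 72 h
  (the coculture protocol's duration), IL-6 read at t_end.
* **Ultrasensitivity** — EC10/EC50/EC90 by monotone interpolation of
  the normalised response in log-dose space;
  `n_H = log 81 / log(EC90/EC10)` (Goldbeter–Koshland convention,
  robust for non-Hill shapes); graded < 1.2 ≤ ultrasensitive < 4 ≤
  switch-like.
* **Sufficiency contour** — per STAT3 grid row, the least E2F1 whose
  readout reaches a level (default 50% of the scan's dynamic range),
  linearly interpolated between bracketing grid points.

## Numerics

LSODA (stiffness-switching) with rtol 1e-8 / atol 1e-10; output values
in (−atol, 0) are clamped to zero, anything lower raises. Steady states
are operational — integrate in doubling windows until ‖rhs‖∞ < tol —
and are cross-checked in the tests against independent algebraic root
solves; no eigenvalue analysis. The RHS is compiled per system into a
scalar closure (the E2F1 Hill term is constant per simulation), which
is what makes 41-point scans and multistart fitting interactive-speed.
The hysteresis screen sweeps a knob up and down, seeding each steady
state with the previous one, and reports levels where the two sweeps
disagree by > 5% relative.

## Fitting

Loss: Σ (log(model + ε) − log(obs + ε))², ε = 1e-6 — readouts span
decades and multiplicative noise is the natural error model. Bounded
L-BFGS-B in log10-parameter space from (default) 8 log-uniform seeded
starts, followed by one tight polish from the winner; simulation
failures at a candidate return a large penalty. The shipped benchmark
frees one cell-scoped kinetic (`melanoma.k1`), one shared constant
(`kinetics.K_S`) and one perturbation knob (`perturbations.e2f1_kd`),
bounded a decade either side of truth. On the default noisy panel
(10 conditions, 3 replicates, CV 0.1) recovery error is noise-limited,
typically 3–20% across seeds; noiseless single-parameter recovery is
< 0.01%. The loss profiled around truth is locally convex in each free
parameter (checked by finite differences in the tests), documenting
that the default free set is identifiable from the default panel.

## Synthetic data

* **Cytokine observations** — deterministic panel readouts with
  mean-preserving multiplicative lognormal replicate noise of stated
  CV (default 0.1, n = 3): ELISA values are positive and their errors
  scale with level. True means are recorded in the table metadata.
* **Regulatory fixtures** — a gene universe with independent TF-target
  and immune-annotation membership draws; planted down-regulated genes
  get fold changes in −(1.6–5.0) and p-values < 0.01, nulls get
  |FC| < 1.2 and uniform p-values, so nulls can never pass the 1.5-fold
  cut and the recorded truth is exact by construction (computed by
  direct set logic, not by the screening code under test).
* **Promoter fixtures** — i.i.d. background at a stated GC fraction
  (default 0.41, human-promoter-like) with non-overlapping consensus
  (or deliberately mutated) plants, including composite E2F1–STAT3
  plants at a stated centre gap (default 13 bp, the IL6-promoter-like
  geometry; integer offsets quantise the realised gap to ±0.5 bp).
* One global seed fans out to fixed per-generator substreams, so
  adding a generator never shifts existing outputs.

What the generators do *not* emulate: real array normalisation
artefacts, correlated replicate structure, p-value/fold-change
dependence, promoter sequence composition beyond GC content, or motif
co-occurrence statistics. Passing tests therefore demonstrate the
correctness of the procedures and the qualitative behaviour of the
model — not calibration against any real transcriptome or ELISA
dataset.

## Screen conventions

Strict inequalities for both DEG cut-offs (p < 0.05, |FC| > 1.5);
boundary records are excluded. Duplicate symbols collapse to the most
significant record before filtering. PFM → log-odds conversion uses
pseudocount 0.8 split by a uniform 0.25 background (a common
JASPAR-tool convention; both configurable); the relative profile score
rescales a window's summed log-odds linearly between the matrix's
minimum and maximum attainable scores. Coordinates are 0-based
half-open internally; promoter reports use negative offsets from the
TSS. Composite elements pair cross-factor hits by motif-centre
distance, default cap 50 bp — "close proximity" on a promoter with a
~13 bp observed gap passes at any reasonable default. The shipped
E2F1/STAT3 matrices are synthetic toy matrices (strong consensus with
mild degeneracy), shipped in JASPAR flat format and read through
Biopython; they are fixtures, not database matrices. Network hubs are
ranked by plain degree after thresholding edge scores at 0.4, ties
broken lexicographically; sub-clustering of the published figure is
deliberately simplified to degree ranking, since the clustering method
and k are not fixed by the procedure being reproduced.

## Known limitations

* The model is qualitative; a.u. concentrations are not calibrated to
  pg/ml, and perturbation strengths are not dose-converted.
* Ignition of the loop near its saddle-node threshold makes readouts
  there sensitive to parameters; the shipped defaults sit away from
  thresholds by design, but user configurations near them will show
  steep parameter dependence.
* The 100 h scan readout is a transient for slowly-igniting
  configurations, not a steady state; this matches the protocol but
  means scan values can differ from the asymptotic response.
* CD8⁺ compartments, Th1/Th2 polarisation states, PD-1/IFN-γ readouts
  and patient-data correlations are interpretation layers, not model
  states, and are out of scope.
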