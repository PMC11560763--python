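# Shipped model configuration.  All concentrations in arbitrary units (a.u.),
# time in hours.  One kinetic scheme shared by both cell types; the cell
# types differ only in expression levels.
kinetics:
  k0: 3.0e-4    # basal IL6 transcription, a.u./h (per-cell override below)
  k1: 5.0       # maximal induced IL6 transcription, a.u./h
  K_E: 1.5      # E2F1 half-activation, a.u.
  h_E: 1.0      # E2F1 Hill exponent
  K_S: 0.2      # pSTAT3 half-activation, a.u.
  h_S: 2.0      # pSTAT3 Hill exponent (STAT3 acts as a dimer)
  d_m: 0.5      # IL6 mRNA decay, 1/h
  k_sec: 1.0    # IL-6 synthesis + secretion per mRNA, 1/h
  d_I: 0.5      # extracellular IL-6 clearance, 1/h
  k_on: 1.0     # IL-6/receptor association, 1/(a.u. h)
  k_off: 0.5    # complex dissociation, 1/h
  k_int: 0.02   # complex internalisation (ligand destroyed), 1/h
  k_p: 1.0      # STAT3 phosphorylation per occupied receptor, 1/(a.u. h)
  k_dp: 0.5     # STAT3 dephosphorylation, 1/h

# Expression levels prior to activation (a.u.).  Melanoma: high E2F1,
# low-moderate receptor, constitutive basal IL6 transcription (graded
# high-gain regime).  CD4+ T cell: low E2F1, high receptor (membrane
# IL6R largely restricted to leukocytes), near-zero basal IL6
# transcription (switch-like regime).
melanoma:
  E2F1: 10.0
  S_tot: 1.0
  R_tot: 0.5
  k0: 3.0e-4
cd4:
  E2F1: 0.2
  S_tot: 1.5
  R_tot: 5.0
  k0: 1.5e-6

# Default perturbation strengths (dimensionless factors / rates); the
# wet-lab doses they emulate have no a.u. conversion, so these are
# qualitative knobs.
perturbations:
  e2f1_kd: 0.2             # residual E2F1 fraction under shRNA knockdown
  stat3_inhibition: 0.1    # residual phosphorylation rate under Stattic
  il6_neutralization: 5.0  # first-order antibody sink on the medium, 1/h
  exogenous_il6: 1.0       # recombinant IL-6 infusion, a.u./h

protocol:
  scan_readout_h: 100.0    # IL-6 readout time for expression scans
  panel_t_end_h: 72.0      # culture duration for condition panels

screen:
  p_cut: 0.05              # DEG p-value cut (strict <)
  fc_cut: 1.5              # DEG |fold-change| cut (strict >)
  score_cut: 0.4           # interaction-score cut for network edges
  motif_threshold: 0.85    # relative PWM profile score threshold
  max_gap_bp: 50           # max centre gap of a composite element, bp
  pseudocount: 0.8         # PFM -> log-odds pseudocount
  background_gc: 0.5       # uniform background for log-odds
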