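# tmdscan force-field parameter set, version 1
#
# Seven-atomic-type classification with per-type van der Waals radius r0 (A),
# Lennard-Jones well depth eps (kJ/mol), transfer energy Etr (kJ/mol/A^2,
# positive = hydrophobic, favorable to leave water) and hydrophobicity flag.
# Transfer energies follow atomic-solvation-parameter magnitudes of the
# Eisenberg-McLachlan family; partial charges are a minimal amide-dipole +
# formal-side-chain-charge scheme.  Both are documented stand-ins for the
# laboratory-internal FCPAC charge set and transfer-energy table they model;
# replace this file to use other values.
version: 1
energy_units: kJ/mol
rsol: 1.4                 # water molecule radius, Angstrom
alip: 0.018               # lipid perturbation constant, kJ/mol/A^2
coulomb_constant: 1389.35 # kJ/mol * A / e^2
dielectric:
  eps_low: 1.0
  eps_high: 80.0
  d_low_nm: 0.2
  d_high_nm: 1.0
  mode: interatomic       # interatomic | depth  (distance argument of eps)

atom_types:
  1: {name: C_aliphatic, element: C, r0: 1.90, eps: 0.30, etr: 0.067, hydrophobic: true}
  2: {name: C_aromatic,  element: C, r0: 1.85, eps: 0.30, etr: 0.067, hydrophobic: true}
  3: {name: C_polar,     element: C, r0: 1.80, eps: 0.25, etr: 0.008, hydrophobic: true}
  4: {name: N_polar,     element: N, r0: 1.65, eps: 0.70, etr: -0.025, hydrophobic: false}
  5: {name: O_polar,     element: O, r0: 1.55, eps: 0.85, etr: -0.025, hydrophobic: false}
  6: {name: S_thioether, element: S, r0: 1.85, eps: 1.00, etr: 0.085, hydrophobic: true}
  7: {name: H_polar,     element: H, r0: 1.00, eps: 0.10, etr: -0.004, hydrophobic: false}

# default backbone partial charges (fractions of unit charge)
backbone_charges: {N: -0.28, H: 0.28, CA: 0.0, C: 0.38, O: -0.38}

# side-chain partial charges by residue; atoms absent here are neutral
sidechain_charges:
  SER: {OG: -0.30, CB: 0.30}
  THR: {OG1: -0.30, CB: 0.30}
  CYS: {SG: -0.10, CB: 0.10}
  TYR: {OH: -0.30, CZ: 0.30}
  ASN: {OD1: -0.38, CG: 0.28, ND2: 0.10}
  GLN: {OE1: -0.38, CD: 0.28, NE2: 0.10}
  HIS: {ND1: -0.20, NE2: -0.20, CE1: 0.40}
  TRP: {NE1: -0.10, CD1: 0.10}
  MET: {SD: -0.10, CG: 0.05, CE: 0.05}
  ASP: {OD1: -0.55, OD2: -0.55, CG: 0.10}
  GLU: {OE1: -0.55, OE2: -0.55, CD: 0.10}
  LYS: {NZ: 1.00}
  ARG: {CZ: 0.20, NE: 0.10, NH1: 0.35, NH2: 0.35}

# per-residue charge overrides for backbone atoms
backbone_charge_overrides:
  PRO: {N: 0.0}

# transfer-energy overrides for charged-group atoms (kJ/mol/A^2)
etr_overrides:
  ASP: {OD1: -0.10, OD2: -0.10}
  GLU: {OE1: -0.10, OE2: -0.10}
  LYS: {NZ: -0.21}
  ARG: {NE: -0.12, NH1: -0.12, NH2: -0.12}
  HIS: {ND1: -0.05, NE2: -0.05}

# implicit-membrane interface geometry (nm); the logistic steepness and
# midpoint are fitted so C(1.35) = 1e-3 and C(1.8) = 1 - 1e-3.  The OPM-style
# decay constant alpha = 1/0.9 A^-1 is retained for provenance only; the
# plateau fit takes precedence.
membrane:
  z_core_nm: 1.35
  z_water_nm: 1.8
  plateau_tol: 1.0e-3
  opm_alpha_per_A: 1.111
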