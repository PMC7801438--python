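"""Physical constants and unit conversions used across the package.

All internal energies are J/mol; kJ/mol appears only at reporting level.
Trajectory coordinates are Angstrom, times picoseconds; diffusion
coefficients are converted to SI once, at the estimate boundary.
"""

#: Gas constant, J K^-1 mol^-1.
R_GAS = 8.314

#: Exact conversion: 1 A^2/ps = 1e-20 m^2 / 1e-12 s = 1e-8 m^2/s.
A2_PER_PS_TO_M2_PER_S = 1e-8

#: Kyte-Doolittle hydropathy scale (three-letter residue codes).
#: Positive = hydrophobic. Raw values span [-4.5, +4.5].
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Normalization divisor mapping Kyte-Doolittle onto [-1, 1].
KD_NORM = 4.5
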