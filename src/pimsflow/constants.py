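"""Physical constants and modification mass deltas (monoisotopic, Da)."""

#: Proton mass used for every m/z <-> neutral-mass conversion.
M_PROTON = 1.007276466

#: Nominal spacing between adjacent isotopologue centroids of a protein.
ISOTOPE_SPACING = 1.00235

#: Averagine monomer: average elemental composition per amino-acid residue.
AVERAGINE_MONOMER = {
    "C": 4.9384,
    "H": 7.7583,
    "N": 1.3577,
    "O": 1.4773,
    "S": 0.0417,
}

#: Average mass of one averagine monomer (Da).
AVERAGINE_MONOMER_MASS = 111.1254

#: Monoisotopic deltas for intact-mass-tag modifications (Da).
MOD_DELTAS = {
    "met_loss": -131.040485,
    "water_loss": -18.010565,
    "acetyl": 42.010565,
    "phospho": 79.966331,
}
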