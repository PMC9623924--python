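"""Physical constants used throughout the package.

Residue masses are monoisotopic masses of amino-acid *residues* (the free
amino acid minus one water), in daltons.  A peptide's neutral monoisotopic
mass is the sum of its residue masses plus one water.  Values are the
standard ones used by search engines; a unit test checks them against an
independent mass calculator.
"""

from __future__ import annotations

# Monoisotopic residue masses (Da), 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass of water (Da), added once per peptide.
WATER_MASS: float = 18.010565

#: Mass of a proton (Da); converts precursor m/z to neutral mass.
PROTON_MASS: float = 1.00727646

#: Carbamidomethylation of cysteine (fixed modification in the reference
#: search conditions).
CARBAMIDOMETHYL: float = 57.02146

#: Oxidation of methionine (variable modification in the reference search
#: conditions).
OXIDATION: float = 15.99491

STANDARD_AA = frozenset(RESIDUE_MASS)

#: Ambiguity/rare letters occasionally present in protein databases.  They
#: have no defined monoisotopic mass, so peptides containing them are
#: excluded from mass indexing.
NONSTANDARD_AA = frozenset("BJOUXZ")

# Average amino-acid frequencies of a large curated protein database
# (UniProtKB/Swiss-Prot release statistics), used as the default residue
# distribution for simulated proteomes and de Bruijn edge weights.
SWISSPROT_AA_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_total = sum(SWISSPROT_AA_FREQS.values())
SWISSPROT_AA_FREQS = {aa: f / _total for aa, f in SWISSPROT_AA_FREQS.items()}
del _total
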