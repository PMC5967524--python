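{
  "comment": "ProtOr-style per-element van der Waals radii (Angstrom) and per-residue maximum solvent accessibilities (Angstrom^2, theoretical Gly-X-Gly maxima). Main-chain reference is a single fully-extended-backbone value; side-chain reference is total minus main-chain (floored).",
  "radii": {
    "C": 1.88,
    "N": 1.64,
    "O": 1.46,
    "S": 1.77,
    "P": 1.8,
    "H": 1.1,
    "default": 1.8
  },
  "max_sasa_total": {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
    "default": 200.0
  },
  "max_sasa_mainchain": 38.0,
  "min_sidechain_reference": 10.0
}
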