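{
  "comment": "Hydrogen-bond donor/acceptor atom names. 'common' applies to every residue of that kind; per-residue entries add to it. Edit to extend coverage.",
  "rna": {
    "common_donors": ["O2'", "O2*"],
    "common_acceptors": ["OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O2'", "O3'", "O4'", "O5'", "O2*", "O3*", "O4*", "O5*"],
    "donors": {
      "G": ["N1", "N2"],
      "A": ["N6"],
      "C": ["N4"],
      "U": ["N3"]
    },
    "acceptors": {
      "G": ["N3", "N7", "O6"],
      "A": ["N1", "N3", "N7"],
      "C": ["O2", "N3"],
      "U": ["O2", "O4"]
    }
  },
  "protein": {
    "common_donors": ["N"],
    "common_acceptors": ["O", "OXT"],
    "donors": {
      "ARG": ["NE", "NH1", "NH2"],
      "LYS": ["NZ"],
      "HIS": ["ND1", "NE2"],
      "ASN": ["ND2"],
      "GLN": ["NE2"],
      "SER": ["OG"],
      "THR": ["OG1"],
      "TYR": ["OH"],
      "TRP": ["NE1"],
      "CYS": ["SG"]
    },
    "acceptors": {
      "ASP": ["OD1", "OD2"],
      "GLU": ["OE1", "OE2"],
      "HIS": ["ND1", "NE2"],
      "ASN": ["OD1"],
      "GLN": ["OE1"],
      "SER": ["OG"],
      "THR": ["OG1"],
      "TYR": ["OH"],
      "MET": ["SD"]
    }
  },
  "ligand": {
    "donor_elements": ["N", "O", "S"],
    "acceptor_elements": ["N", "O", "S", "F"]
  }
}
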