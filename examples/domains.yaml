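# Domain definitions (mature-FVa residue numbering).
# C1, C2 and A2 carry the standard boundaries; the A1 and A3 boundaries
# are NOT standardized and must be chosen by the user for their model.
# The values below are the ones used by the synthetic toy protein.
domains:
  A1: {ranges: [[29, 303]], atoms: [CA]}
  A2: {ranges: [[320, 655]], atoms: [CA]}
  A3: {ranges: [[1546, 1877]], atoms: [CA]}
  C1: {ranges: [[1879, 2033]], atoms: [CA]}
  C2: {ranges: [[2038, 2193]], atoms: [CA]}
linker_residue: 2037
# kick dihedral residue order: C2 outer, C2 near-interface,
# C1 near-interface, C1 outer
kick_order: [2186, 2127, 2026, 1967]
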