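# Spike residue membership template (INCOMPLETE - fill in for your
# model).  Only the residues named in the accompanying text are listed;
# complete each loop's membership from your structure before running
# `exthmmm analyze-insertion`.
"C1 spike 1": []              # truncated loop; complete from structure
"C1 spike 2": []              # e.g. around K1954/K1958
"C1 spike 3": [1957, 1907]    # L1957; R1907 adjacent basic residue
"C2 spike 1": [2060, 2063, 2064]   # K2060, W2063, W2064
"C2 spike 2": [2080]               # R2080
"C2 spike 3": [2114, 2116]         # K2114, L2116
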