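# ILLUSTRATIVE basin gates for the scissors-kick (phi, theta) plane.
# Published landscapes name the basins but do not quantify their
# boundaries; these rectangles are examples of the gating format only.
# Supply your own gates for any quantitative per-basin analysis.
# Assignment tie-break: first matching gate in list order wins.
- {label: Xtal, phi: [115, 135], theta: [-30, 10]}
- {label: m1, phi: [110, 130], theta: [10, 50]}
- {label: m2, phi: [85, 110], theta: [-40, 10]}
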