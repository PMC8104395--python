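# Reduced 3x3-hypercolumn lattice for tests and oracle comparisons.
# All circuit parameters match the packaged defaults; only the lattice shrinks.

[lattice]
n_hc_per_side = 3
groups_per_hc_side = 7
hc_size = 0.25
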