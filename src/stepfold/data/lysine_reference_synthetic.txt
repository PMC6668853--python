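# Synthetic stand-in for the lysine reference parameters used when
# post-processing a non-canonical rotamer library: per-chi angular standard
# deviations (degrees) typical of an unbranched, positively charged side
# chain, plus a reference energy (kcal/mol). These values are constructed,
# not extracted from any published rotamer library.
chi1 9.1
chi2 10.3
chi3 11.2
chi4 12.6
reference_energy 0.92
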