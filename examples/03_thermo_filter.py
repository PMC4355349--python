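"""GC content, melting temperature and the probe filter.

Scores a few 50-mers with the nearest-neighbor Tm model (50 mM monovalent
salt, 0.25 uM oligo) and shows which pass the standard capture filter
(GC 35-65%, Tm 55-65 degC).  The AT-rich and GC-rich probes fail on both
counts; note how strongly Tm tracks GC at fixed length.
"""

from probecap import ProbeDesignParams, gc_percent, melting_temp, passes_filters

probes = {
    "AT-rich": "ATATTTAAATTATATAAATTTATATTTAAATATTTAAATATATTTAAATA",
    "moderate": "CCCATAAAGATAAGAGTGACACCTCAGTAATCTACCATATGCAGATTAGA",
    "GC-rich": "GCGGCCGCGGGCCCGCGGCGCCCGGGCGCGGCCGCGCCCGGGCCGCGGGC",
}
params = ProbeDesignParams()

print(f"{'probe':10s} {'GC%':>6s} {'Tm_NN':>7s} {'Tm_GCrule':>9s}  passes")
for name, seq in probes.items():
    gc = gc_percent(seq)
    tm_nn = melting_temp(seq)
    tm_gc = melting_temp(seq, method="gc_rule")
    print(f"{name:10s} {gc:6.1f} {tm_nn:7.2f} {tm_gc:9.2f}  {passes_filters(seq, params)}")
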