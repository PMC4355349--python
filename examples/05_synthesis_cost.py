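"""Synthesis-cycle cost of designed probes.

The array synthesizer delivers bases cyclically (A, C, G, T, A, ...); each
coupled base waits for its next delivery round, so cost depends on base
order, not just length.  A 50-mer needs between 50 and 200 cycles; typical
random-ish probes land near 125-135.  Coupling runs 3'->5'.
"""

from probecap import probe_cycles, synthesis_cycles

print("walk examples (consumed in coupling order):")
for seq in ("A", "ACGT", "AAAA", "TGCA"):
    print(f"  {seq:6s} -> {synthesis_cycles(seq):3d} cycles")

probe = "TGCCCGTCAACTCAATCCTCCTTCGGTAGCAATCGTCGTGACGGGTTTAG"
print(f"\n50-mer probe, coupling 3'->5': {probe_cycles(probe)} cycles")
print(f"same probe, coupling 5'->3':  {probe_cycles(probe, three_prime_first=False)} cycles")
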