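# probecap

Capture-probe design for targeted metagenomics.

Shotgun sequencing of a soil or gut metagenome spends most of its reads on
DNA you are not studying. Hybridization capture fixes that: a set of
synthetic 50-mer oligonucleotide probes ("baits") is hybridized to the
fragment pool and pulls down only the fragments matching your target genes
before sequencing. The hard part is designing probes for *thousands* of
genes and gene families at once — diverse enough to cover every family,
specific enough not to drag one family's fragments onto another family's
probes, and manufacturable at reasonable cost.

`probecap` turns a multi-FASTA of target nucleotide sequences into such a
probe set:

1. **Length filter** — sequences longer than a cutoff (default 20 kb) are
   treated as genomic contigs/scaffolds and removed; the targets should be
   single genes.
2. **Clustering** — greedy incremental clustering at an identity threshold
   *t* (default 0.9). Sequences are processed longest-first; each joins the
   first cluster whose representative it matches at identity
   ≥ *t*, where identity = (identical aligned bases under a banded
   alignment) / (length of the shorter sequence). Each cluster then behaves
   as one design group, which also makes the probe set insensitive to
   sequence abundance.
3. **Primary design** — per cluster, every probe-length window of every
   member is a candidate. A spaced seed (four 10-base words separated by
   ≤ 2 don't-care bases) defines matching: a candidate hits a target when
   all care positions agree at some offset/anchor. Candidates must pass the
   GC/Tm filter and be *group-specific* (zero seed hits in any other
   cluster); survivors are ranked by within-cluster coverage and positional
   spread, and at most `max_probes_per_cluster` (default 3) are emitted.
4. **Rescue** — clusters left probe-less get a second pass: multi-member
   clusters are multiple-aligned (center-star), collapsed to a consensus at
   90 % column support (ambiguous columns → N), and the consensus is tiled
   end-to-end with probe-length windows (plus a 3'-anchored terminal tile);
   singletons are tiled directly. Windows with N are discarded and the rest
   pass through the same GC/Tm filter, optionally with relaxed rescue-stage
   parameters.
5. **Outputs** — six files per run (per-stage summaries, primary and full
   probe TSVs, the cluster file, a non-redundant probe set) plus a run
   manifest, and a per-probe **synthesis-cycle** count (cyclic A→C→G→T base
   delivery, coupling 3'→5') as a manufacturing-cost proxy.

Probes are filtered on GC content (default 35–65 %) and melting temperature
(default 55–65 °C) computed with unified nearest-neighbor thermodynamics:

    Tm = ΔH / (ΔS + 0.368 (N−1) ln[Na⁺] + R ln(C_T/4)) − 273.15

with ΔH, ΔS summed over dinucleotide stacks plus terminal initiation terms
(50 mM monovalent salt, 0.25 µM oligo by default; a classic GC-rule formula
is available as a fast alternative).

## Worked example

`examples/` contains one short script per capability. The main one designs
probes for a synthetic dataset of 8 gene families:

```bash
$ python examples/01_design_probes.py
input sequences:             48
clusters:                    8
clusters with probes (run1): 8
clusters with probes (run2): 8
probes emitted:              22
non-redundant probes:        22

first three probes:
  cl00000_primary_1  cluster 0  offset 30  GC 38.0%  Tm 64.21C  115 cycles
  cl00000_primary_2  cluster 0  offset 444  GC 36.0%  Tm 64.88C  131 cycles
  cl00000_primary_3  cluster 0  offset 51  GC 40.0%  Tm 64.93C  119 cycles
```

All 8 planted families are recovered as clusters and every cluster receives
group-specific probes in the primary stage (run1 = run2 here; the rescue
stage has nothing left to do). Each probe reports its source offset, GC,
nearest-neighbor Tm and synthesis-cycle cost.
`examples/04_rescue_tiling.py` shows the opposite regime: GC-skewed
families fail the primary filter and are recovered by the rescue stage with
relaxed redesign parameters (4 → 9 clusters covered).

The same pipeline is available from the shell:

```bash
probecap synth -o targets.fa --families 8 --members 6 --length 600 --seed 1
probecap design targets.fa -o run1 --preset capture50
probecap cluster targets.fa -o clusters.clstr    # stop after clustering
probecap cost run1/probe_file2                   # synthesis cycles
```

## Layout

```
src/probecap/      library (seqio, cluster, thermo, probe_primary,
                   probe_rescue, costing, reporting, synth, pipeline, cli)
examples/          one narrative script per capability
tests/             pytest suite with independent oracles
docs/methods.md    models, parameters, numerical choices, limitations
```
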