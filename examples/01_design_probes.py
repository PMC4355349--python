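"""Full probe-design run on a synthetic gene-family dataset.

Generates 8 families of 6 members (600 nt, 3% within-family divergence),
runs the whole pipeline at the standard capture parameters (50-mer probes,
GC 35-65%, Tm 55-65 degC, up to 3 probes per cluster, clustering identity
0.9) and prints the per-stage summary.  "run1" counts clusters covered by
group-specific primary probes; "run2" adds clusters covered after the
consensus/tiling rescue stage.
"""

from probecap import run_pipeline, validate_config
from probecap.synth import FamilySpec, generate_dataset

records, truth = generate_dataset(FamilySpec(8, 6, 600, 0.03, seed=1))
config = validate_config({"preset": "capture50"})
results = run_pipeline(config, records=records)

s1, s2 = results.summary_run1, results.summary_run2
print(f"input sequences:             {len(records)}")
print(f"clusters:                    {s1.clusters_total}")
print(f"clusters with probes (run1): {s1.clusters_with_probes}")
print(f"clusters with probes (run2): {s2.clusters_with_probes}")
print(f"probes emitted:              {s2.probes_emitted}")
print(f"non-redundant probes:        {len(results.nonredundant_probes)}")
print()
print("first three probes:")
for p in results.probes_run2[:3]:
    print(f"  {p.probe_id}  cluster {p.cluster_id}  offset {p.offset}  "
          f"GC {p.gc:.1f}%  Tm {p.tm:.2f}C  {p.cycles} cycles")
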