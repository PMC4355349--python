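"""Greedy identity clustering on its own.

Builds three small families plus one unrelated singleton, clusters at 90%
identity and prints each cluster with member identities to the
representative.  Identity is the fraction of identical aligned bases
(banded alignment, free gaps) over the shorter sequence.
"""

import numpy as np

from probecap import ClusteringParams, SequenceRecord, greedy_cluster, mutate
from probecap.synth import _ancestor
from probecap._seq import decode

rng = np.random.default_rng(7)
records = []
for fam in range(3):
    ancestor = decode(_ancestor(400, 0.5, rng))
    for m in range(4):
        records.append(
            SequenceRecord(f"fam{fam}_m{m}", mutate(ancestor, 0.03, 0.002, rng))
        )
records.append(SequenceRecord("loner", decode(_ancestor(400, 0.5, rng))))

clusters = greedy_cluster(records, ClusteringParams(identity_threshold=0.9))
print(f"{len(records)} sequences -> {len(clusters)} clusters\n")
for cl in clusters:
    print(f"cluster {cl.cluster_id} (representative {cl.representative_id}):")
    for m in cl.members:
        print(f"  {m.record_id:12s} identity {m.identity:.3f} strand {m.strand}")
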