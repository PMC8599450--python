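"""Clonality and cosine similarity on small hand-built repertoires.

A repertoire dominated by one clone has high clonality (1 - normalised
Shannon entropy); cosine similarity between union-indexed abundance
vectors quantifies how much two repertoires overlap, independent of
sequencing depth.
"""

import pandas as pd

from tcrdyn import (
    Repertoire,
    SampleMeta,
    abundance_pair,
    clonality,
    cosine_similarity,
    spatial_similarity,
)


def rep(counts, **meta):
    table = pd.DataFrame(
        {
            "clone_key": list(counts),
            "cdr3_aa": [f"CASS{k}GELF" for k in counts],
            "v_call": "TRBV5",
            "j_call": "TRBJ2",
            "umi_count": list(counts.values()),
        }
    )
    return Repertoire(meta=SampleMeta(**meta), table=table)


even = rep({"A": 25, "B": 25, "C": 25, "D": 25}, patient_id="P1", timepoint="pre")
skewed = rep({"A": 90, "B": 4, "C": 3, "D": 3}, patient_id="P1", timepoint="post")

print(f"even repertoire clonality:   {clonality(even).value:.4f}  (0 = perfectly even)")
print(f"skewed repertoire clonality: {clonality(skewed).value:.4f}  (-> 1 = one clone dominates)")

sim = cosine_similarity(abundance_pair(even, skewed))
print(f"cosine(even, skewed) = {sim.value:.4f} over {sim.n_union} union clones, "
      f"{sim.n_shared} shared")

# two tumour regions sampled from similar clone mixtures score near 1
r1 = rep({"A": 50, "B": 30, "C": 20}, patient_id="P1", timepoint="pre", region_id="R1")
r2 = rep({"A": 45, "B": 35, "C": 20}, patient_id="P1", timepoint="pre", region_id="R2")
print("\nspatial similarity matrix (regions of one timepoint):")
print(spatial_similarity([r1, r2]).round(4))
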