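"""Cross-link confidence filtering and distance validation on a model.

Applies the confidence rules (score > 40, identified in ≥2 of 3
replicates), maps surviving links onto a multi-chain coordinate model
over all chain-copy pairings, flags overlength restraints, and checks
disulfide Sγ–Sγ geometry.
"""

import tempfile

import pandas as pd

from c4bpkit import synthetic as syn
from c4bpkit.xlink import ModelCoordinates, disulfide_check, filter_links, validate_links

fx = syn.gen_xl_fixture(seed=5, out_dir=tempfile.mkdtemp())
links = pd.read_csv(fx["links"], sep="\t")
kept = filter_links(links, min_score=40, min_replicates=2)
print(f"{links.shape[0]} PSM-level rows -> {len(kept)} confident unique links")

model = ModelCoordinates.from_file(fx["model"])
for v in validate_links(kept, model, fx["chain_map"]):
    if v.unmappable:
        print(f"  {v.protein_a} {v.site_a} -- {v.protein_b} {v.site_b}: unmappable")
        continue
    note = " OVERLENGTH" if v.overlength else ""
    print(
        f"  {v.protein_a} {v.site_a} -- {v.protein_b} {v.site_b} ({v.linker}, "
        f"{v.link_class}): {v.min_distance_a:.1f} Å via {v.best_pairing}{note}"
    )

for r in disulfide_check(model, fx["cys_pairs"], threshold_a=2.05):
    verdict = "plausible" if r["plausible"] else "too long"
    print(f"  disulfide {r['pair']}: {r['distance_a']:.2f} Å ({verdict})")
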