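"""Climatic profiles: per-genus shares, the >75% assignment rule, and the
clade-level profile with regular subsampling of oversampled genera.
"""

import numpy as np

from climoccur import (GridDefinition, OccurrenceRecord, Regionalization,
                       clade_profile, compare_to_qualitative, genus_profile)


def rec(genus, lon, lat, rid):
    return OccurrenceRecord(record_id=rid, genus=genus,
                            longitude_text=f"{lon:.4f}",
                            latitude_text=f"{lat:.4f}", longitude=lon,
                            latitude=lat, source="demo")


# a toy regionalization: lon < 10 tropical, 10-15 subtropical, >= 15 temperate
grid = GridDefinition(0.0, 0.0, 1.0, 20, 1)
codes = np.array([[0] * 10 + [1] * 5 + [2] * 5])
layer = Regionalization("toy", grid, codes,
                        {0: "tropical", 1: "subtropical", 2: "temperate"})

rng = np.random.default_rng(0)
genus_a = [rec("GenusA", float(rng.uniform(0, 12.5)), 0.5, f"a{i}")
           for i in range(200)]   # mostly tropical, some subtropical
genus_b = [rec("GenusB", float(rng.uniform(10, 20)), 0.5, f"b{i}")
           for i in range(2000)]  # oversampled; subtropical + temperate

profiles = [genus_profile(genus_a, layer), genus_profile(genus_b, layer)]
for p in profiles:
    shares = {c: round(s, 1) for c, s in sorted(p.shares.items())}
    print(f"{p.taxon}: shares {shares} -> assignment: {p.assignment}"
          f"  (n_used={p.n_used}, unequivocal needs a share > 75%)")

clade = clade_profile(genus_a + genus_b, layer, oversample_cap=1500,
                      target=1000, seed=0)
print(f"\nCLADE profile (GenusB reduced from 2000 to 1000 regular picks):")
print("  shares:", {c: round(s, 1) for c, s in sorted(clade.shares.items())},
      f" n_used={clade.n_used}")

table = compare_to_qualitative(
    profiles, {"GenusA": "tropical", "GenusB": "temperate"},
    merge_rules={"subtropical": "tropical"})
print("\nagreement with qualitative tropical/temperate labels:")
print(table.to_string(index=False))
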