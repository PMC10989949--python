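"""Classify a pan-genome's clusters as core / accessory / unique.

Reconstructs the composition of a 12-genome pan-genome with 11,716
orthologous clusters of which 419 occur in every genome and 6,976 in
exactly one, then summarizes it.
"""

from paneval import GeneId, PanProfile, summarize

genomes = [f"g{i:02d}" for i in range(12)]
clusters, cid = [], 0
for _ in range(419):                       # core: present in all 12 genomes
    clusters.append({GeneId(g, f"c{cid}") for g in genomes})
    cid += 1
for i in range(6976):                      # unique: a single genome each
    clusters.append({GeneId(genomes[i % 12], f"c{cid}")})
    cid += 1
for i in range(11716 - 419 - 6976):        # accessory: 2..11 genomes
    clusters.append({GeneId(g, f"c{cid}") for g in genomes[: 2 + i % 10]})
    cid += 1

s = summarize(PanProfile("demo", clusters), set(genomes), core_fraction=1.0)
print(f"total clusters : {s.total_clusters}")
print(f"core           : {s.core_count} ({s.core_pct:.2f}%)")
print(f"accessory      : {s.accessory_count} ({s.accessory_pct:.2f}%)")
print(f"unique         : {s.unique_count} ({s.unique_pct:.2f}%)")

# core_pct 3.57 means only ~1 cluster in 28 is shared by all genomes --
# a very open pan-genome, typical of a genus-level genome set.
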