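# paneval

Evaluate, compare and summarize prokaryotic **pan-genome profiles**.

The first and most consequential step of a pan-genome analysis is clustering
genes into orthologous groups, and the many tools that do it (Roary,
OrthoFinder, panX, PPanGGoLiN, ...) routinely disagree on the same genome
set. `paneval` is for microbial comparative genomicists who have run two or
more such tools and need a principled answer to *which clustering should I
trust for downstream analysis?* It operates purely on cluster profiles — no
sequences required.

## The score

Let the *pair universe* be every unordered gene pair (gᵢ, gⱼ) co-clustered
by at least one of the N profiles. Each pair awards at most one point per
profile *s*:

* **COG branch** — if both genes carry a COG annotation:
  * same COG and (gᵢ, gⱼ) co-clustered in *s* → score_s + 1
  * different COG and (gᵢ, gⱼ) separated in *s* → score_s + 1
* **Consensus branch** — otherwise, with c = number of profiles placing the
  pair together and a cutoff x (default N/2):
  * c > x and co-clustered in *s* → score_s + 1
  * c < x and separated in *s* → score_s + 1 (no award at c = x)

So 0 ≤ score_s ≤ |universe|, and the highest-scoring profile is reported as
the most reliable (ties broken lexicographically and listed). Profiles are
first *harmonized*: a gene clustered by one tool but missing from another is
added to the latter as a singleton.

The package also extracts **links** (co-clustered pairs, optionally
restricted to each profile's core clusters) and intersects them into a
shared-link matrix between tools, and classifies clusters into **core**
(present in ≥ `core_fraction` of genomes, default all), **accessory**, and
**unique** (exactly one genome), with percentages truncated to two decimals.

## Worked example

`examples/01_score_profiles.py` scores three tools that disagree about four
genes, with COG labels for three of them (g4 unannotated) and x = 1.5:

```
rank 1: P1  score=4/4
rank 2: P3  score=3/4
rank 3: P2  score=2/4
best profile: P1
```

Four pairs are co-clustered by at least one tool. P1 agrees with the COG
arbiter on (g1,g2), (g1,g3) and (g2,g3) and with the cross-tool consensus on
(g3,g4), so it scores the maximum 4; P2, which lumps the different-COG gene
g3 in with g1 and g2, scores 2. `examples/02_summarize_pangenome.py` builds
a 12-genome pan-genome of 11,716 clusters and prints its composition —
419 core clusters (3.57%) and 6,976 unique clusters (59.54%) — the profile of
a very open, genus-level genome set.

## Command line

```bash
paneval simulate -G 6 -K 40 --seed 7 -o sim/            # synthetic fixture set
paneval score --profile tsv:sim/truth.clusters.tsv \
              --profile tsv:sim/tool1.clusters.tsv \
              --profile tsv:sim/tool2.clusters.tsv \
              --cog sim/cog.tsv -o out/                 # best profile on stdout
paneval compare --profile roary:gene_presence_absence.csv \
                --profile orthofinder:Orthogroups.tsv   # shared core-link matrix
paneval summarize --profile roary:gene_presence_absence.csv
```

Profile inputs are format-tagged (`roary:`, `orthofinder:`, `tsv:`); see
`paneval <cmd> --help` for flags, YAML config support and exit codes.

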