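"""Score three disagreeing cluster profiles and pick the most reliable one.

Builds the minimal hand-checkable instance: four genes, three tools that
disagree on where g3 and g4 belong, and COG labels for three of the genes.
"""

from paneval import (
    CogAnnotation,
    GeneId,
    PanProfile,
    ScoringConfig,
    best_profile,
    score_profiles,
)

g1, g2, g3, g4 = (GeneId("S", f"g{i}") for i in range(1, 5))

profiles = [
    PanProfile("P1", [{g1, g2}, {g3}, {g4}]),       # keeps g3 and g4 apart
    PanProfile("P2", [{g1, g2, g3}, {g4}]),         # lumps g3 in with g1,g2
    PanProfile("P3", [{g1, g2}, {g3, g4}]),         # pairs g3 with g4
]
cog = CogAnnotation({g1: "C1", g2: "C1", g3: "C2"})  # g4 unannotated

report = score_profiles(profiles, cog, ScoringConfig(x=1.5))
for entry in sorted(report.entries, key=lambda e: e.rank):
    print(f"rank {entry.rank}: {entry.name}  score={entry.score}/{entry.pairs_total}")
name, ties = best_profile(report)
print(f"best profile: {name}" + (f" (tied with {ties})" if ties else ""))

# Each of the 4 co-clustered pairs awards one point to every profile that
# agrees with the arbiter (COG labels where both genes have one, cross-tool
# consensus otherwise).  P1 agrees on all 4 pairs and wins.
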