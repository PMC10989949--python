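"""Shared fixtures: the hand-scored worked example, a case-study-shaped
profile builder, and seeded random scoring instances."""

import hypothesis
import numpy as np
import pytest

from paneval import (
    CogAnnotation,
    GeneId,
    PanProfile,
    PerturbationSpec,
    annotate_cog_synthetic,
    perturb_profile,
    simulate_pangenome,
)

hypothesis.settings.register_profile(
    "paneval", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("paneval")


@pytest.fixture
def worked_example():
    """Four genes, three profiles, x=1.5: hand-enumerated scores 4/2/3.

    P1 splits g3 and g4 off; P2 lumps g3 with the g1-g2 pair; P3 pairs g3
    with g4.  COG says g1 and g2 belong together and g3 is different; g4 is
    unannotated, so the (g3, g4) pair falls to the consensus branch.
    """
    g1, g2, g3, g4 = (GeneId("S", f"g{i}") for i in range(1, 5))
    profiles = [
        PanProfile("P1", [{g1, g2}, {g3}, {g4}]),
        PanProfile("P2", [{g1, g2, g3}, {g4}]),
        PanProfile("P3", [{g1, g2}, {g3, g4}]),
    ]
    cog = CogAnnotation({g1: "C1", g2: "C1", g3: "C2"})
    return profiles, cog


def build_case_study_profile(
    total=11716, n_core=419, n_unique=6976, n_genomes=12, name="case"
):
    """A profile shaped like a 12-genome pan-genome report: the given number
    of full-occurrence clusters, occurrence-1 clusters, and accessory
    clusters at occurrences cycling over 2..n_genomes-1."""
    genomes = [f"g{i:02d}" for i in range(n_genomes)]
    clusters = []
    cid = 0
    for _ in range(n_core):
        clusters.append({GeneId(g, f"c{cid}") for g in genomes})
        cid += 1
    for i in range(n_unique):
        clusters.append({GeneId(genomes[i % n_genomes], f"c{cid}")})
        cid += 1
    n_accessory = total - n_core - n_unique
    for i in range(n_accessory):
        occ = 2 + (i % (n_genomes - 2))  # occurrences 2..n_genomes-1
        clusters.append({GeneId(g, f"c{cid}") for g in genomes[:occ]})
        cid += 1
    return PanProfile(name, clusters), set(genomes)


def random_instance(seed, max_genomes=6, max_families=25, n_profiles=None):
    """A seeded random scoring instance: synthetic truth, partial/erroneous
    COG labels, and several independently perturbed tool-like profiles."""
    rng = np.random.default_rng(seed)
    G = int(rng.integers(2, max_genomes + 1))
    K = int(rng.integers(3, max_families + 1))
    truth = simulate_pangenome(
        G, K,
        core_frac=float(rng.uniform(0, 0.5)),
        paralog_rate=float(rng.uniform(0, 0.1)),
        seed=int(rng.integers(2**31)),
    )
    cog = annotate_cog_synthetic(
        truth,
        coverage=float(rng.uniform(0, 1)),
        error_rate=float(rng.uniform(0, 0.2)),
        seed=int(rng.integers(2**31)),
    )
    if n_profiles is None:
        n_profiles = int(rng.integers(2, 7))
    profiles = [
        perturb_profile(
            truth,
            PerturbationSpec(
                split_rate=float(rng.uniform(0, 0.5)),
                merge_rate=float(rng.uniform(0, 0.5)),
                drop_rate=float(rng.uniform(0, 0.2)),
                seed=int(rng.integers(2**31)),
            ),
            name=f"tool{i + 1}",
        )
        for i in range(n_profiles)
    ]
    return truth, cog, profiles
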