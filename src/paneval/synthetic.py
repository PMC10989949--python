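"""Synthetic pan-genomes, annotations and tool-like noisy profiles.

The generator emulates the study design the evaluation is built for: a
ground-truth pan-genome of G genomes and K gene families, where a chosen
fraction of families is core (present in every genome), the rest draw their
occurrence uniformly from 1..G-1 (so core, accessory and unique clusters
all arise), and paralogs appear with a small per-(family, genome)
probability.  COG labels are family-consistent with tunable coverage and
error, and noisy "tool" profiles are produced from the truth by three
perturbations that mimic real clustering failure modes:

* **split** — a cluster is broken into two random halves (over-splitting,
  the signature of tools that fragment core families);
* **merge** — a cluster is fused with a uniformly chosen other cluster
  (over-lumping);
* **drop**  — individual genes are omitted (harmonization later reinstates
  them as singletons).

All randomness flows from integer seeds through ``numpy.random.default_rng``;
sets are always iterated in sorted order before drawing, so every operation
is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set

import numpy as np

from .errors import ConfigError
from .model import GeneId, PanProfile
from .profile_io import CogAnnotation

__all__ = [
    "SyntheticTruth",
    "PerturbationSpec",
    "simulate_pangenome",
    "annotate_cog_synthetic",
    "perturb_profile",
]

DEFAULT_CORE_FRAC = 0.2
DEFAULT_PARALOG_RATE = 0.05
DEFAULT_COVERAGE = 0.8
DEFAULT_ERROR_RATE = 0.02


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated ground-truth pan-genome.

    ``truth_profile`` clusters coincide exactly with gene families;
    ``family_of_gene`` is total over the gene universe.
    """

    genomes: List[str]
    truth_profile: PanProfile
    family_of_gene: Mapping[GeneId, str]
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def families(self) -> List[str]:
        return sorted(set(self.family_of_gene.values()))


@dataclass(frozen=True)
class PerturbationSpec:
    """Noise model for one tool-like profile."""

    split_rate: float = 0.0
    merge_rate: float = 0.0
    drop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split_rate", "merge_rate", "drop_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


def simulate_pangenome(
    G: int,
    K: int,
    core_frac: float = DEFAULT_CORE_FRAC,
    paralog_rate: float = DEFAULT_PARALOG_RATE,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate a ground-truth pan-genome.

    Parameters
    ----------
    G
        Number of genomes (>= 2).
    K
        Number of gene families (>= 1).
    core_frac
        Fraction of families present in all G genomes (rounded to a count);
        the remaining families draw occurrence uniformly from 1..G-1.
    paralog_rate
        Probability that a (family, genome) slot carries one extra paralog
        in addition to its single gene.
    """
    if G < 2:
        raise ConfigError(f"need at least 2 genomes, got G={G}")
    if K < 1:
        raise ConfigError(f"need at least 1 family, got K={K}")
    if not (0.0 <= core_frac <= 1.0):
        raise ConfigError(f"core_frac must be in [0, 1], got {core_frac}")
    if not (0.0 <= paralog_rate <= 1.0):
        raise ConfigError(f"paralog_rate must be in [0, 1], got {paralog_rate}")

    rng = np.random.default_rng(seed)
    genomes = [f"G{i + 1:03d}" for i in range(G)]
    n_core = int(math.floor(core_frac * K + 0.5))

    clusters: List[Set[GeneId]] = []
    family_of_gene: Dict[GeneId, str] = {}
    for k in range(K):
        family = f"F{k + 1:05d}"
        if k < n_core:
            present = list(range(G))
        else:
            occ = int(rng.integers(1, G))  # uniform on 1..G-1
            present = sorted(rng.choice(G, size=occ, replace=False).tolist())
        cluster: Set[GeneId] = set()
        for gi in present:
            copies = 1 + (1 if rng.random() < paralog_rate else 0)
            for c in range(copies):
                local = family if c == 0 else f"{family}.p{c + 1}"
                gene = GeneId(genomes[gi], local)
                cluster.add(gene)
                family_of_gene[gene] = family
        clusters.append(cluster)

    return SyntheticTruth(
        genomes=genomes,
        truth_profile=PanProfile("truth", clusters),
        family_of_gene=family_of_gene,
        params={
            "G": G,
            "K": K,
            "core_frac": core_frac,
            "paralog_rate": paralog_rate,
            "seed": seed,
        },
    )


def annotate_cog_synthetic(
    truth: SyntheticTruth,
    coverage: float = DEFAULT_COVERAGE,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> CogAnnotation:
    """Family-consistent COG labels with tunable coverage and error.

    Each gene is annotated with probability *coverage*; an annotated gene
    receives its family's COG identifier except that, with probability
    *error_rate*, it receives a uniformly chosen different family's
    identifier instead.
    """
    if not (0.0 <= coverage <= 1.0):
        raise ConfigError(f"coverage must be in [0, 1], got {coverage}")
    if not (0.0 <= error_rate <= 1.0):
        raise ConfigError(f"error_rate must be in [0, 1], got {error_rate}")
    rng = np.random.default_rng(seed)
    families = truth.families
    cog_of_family = {fam: f"COG{i + 1:04d}" for i, fam in enumerate(families)}
    assignments: Dict[GeneId, str] = {}
    for gene in sorted(truth.family_of_gene, key=str):
        if rng.random() >= coverage:
            continue
        family = truth.family_of_gene[gene]
        if len(families) >= 2 and rng.random() < error_rate:
            others = [f for f in families if f != family]
            family = others[int(rng.integers(len(others)))]
        assignments[gene] = cog_of_family[family]
    return CogAnnotation(assignments=assignments)


def perturb_profile(
    truth: SyntheticTruth,
    spec: PerturbationSpec,
    name: str,
) -> PanProfile:
    """Derive a tool-like noisy profile from the truth.

    Passes run in a fixed order — split, then merge, then drop — each
    deciding independently per cluster (or per gene for drop).  Splits cut a
    shuffled member list at a uniform point, so every non-trivial
    bipartition is reachable; merges fuse a cluster into a uniformly chosen
    surviving partner.  The output is always a valid disjoint profile.
    """
    rng = np.random.default_rng(spec.seed)

    # split pass
    split_out: List[Set[GeneId]] = []
    for cluster in truth.truth_profile.clusters:
        members = sorted(cluster, key=str)
        if len(members) >= 2 and rng.random() < spec.split_rate:
            order = rng.permutation(len(members))
            cut = int(rng.integers(1, len(members)))
            left = {members[i] for i in order[:cut]}
            right = {members[i] for i in order[cut:]}
            split_out.extend([left, right])
        else:
            split_out.append(set(members))

    # merge pass: a cluster chosen for merging is fused into a surviving partner
    merged: List[Set[GeneId]] = [set(c) for c in split_out]
    alive = list(range(len(merged)))
    for idx in range(len(merged)):
        if merged[idx] is None or len(alive) < 2:
            continue
        if rng.random() < spec.merge_rate:
            partners = [i for i in alive if i != idx]
            partner = partners[int(rng.integers(len(partners)))]
            merged[partner] |= merged[idx]
            merged[idx] = None
            alive.remove(idx)

    # drop pass
    final: List[Set[GeneId]] = []
    for cluster in merged:
        if cluster is None:
            continue
        kept = {g for g in sorted(cluster, key=str) if rng.random() >= spec.drop_rate}
        if kept:
            final.append(kept)

    return PanProfile(name, final)
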