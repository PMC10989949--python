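"""Core domain types and pan-genome cluster classification.

A *profile* is one tool's partition of a gene universe into orthologous
clusters.  Clusters are classified by **occurrence** -- the number of
distinct genomes contributing at least one gene to the cluster -- into

* ``unique``     : occurrence == 1 (the cluster belongs to a single genome);
* ``core``       : occurrence >= ceil(core_fraction * n_genomes);
* ``accessory``  : everything in between.

``unique`` takes precedence over ``core`` in the degenerate one-genome case.
Occurrence counts genomes, not genes, so paralog-containing clusters are
handled deterministically.

Percentages in :class:`ProfileSummary` are truncated (not rounded) to two
decimals, matching how pan-genome reports conventionally print them; the
truncation is done in integer arithmetic so it is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .errors import (
    ConfigError,
    DuplicateGeneError,
    FormatError,
    UnknownGenomeError,
    UsageError,
)

__all__ = [
    "GeneId",
    "PanProfile",
    "ClusterClass",
    "ProfileSummary",
    "classify_clusters",
    "summarize",
    "harmonize_profiles",
]

_FORBIDDEN = ("|", "\t")


@dataclass(frozen=True)
class GeneId:
    """A gene, qualified by the genome it lives in.

    Rendered canonically as ``"genome|local_id"``; that rendered form is the
    unique key of a gene within a universe and defines the canonical ordering
    used for gene pairs.
    """

    genome: str
    local_id: str

    def __post_init__(self) -> None:
        for name, value in (("genome", self.genome), ("local_id", self.local_id)):
            if not value:
                raise FormatError(f"GeneId {name} must be non-empty")
            if any(ch in value for ch in _FORBIDDEN):
                raise FormatError(
                    f"GeneId {name} {value!r} may not contain '|' or tab characters"
                )

    def __str__(self) -> str:
        return f"{self.genome}|{self.local_id}"

    def __lt__(self, other: "GeneId") -> bool:
        return str(self) < str(other)

    @classmethod
    def parse(cls, token: str) -> "GeneId":
        """Parse an embedded ``genome|local_id`` token."""
        parts = token.split("|")
        if len(parts) != 2:
            raise FormatError(f"cannot parse {token!r} as 'genome|local_id'")
        return cls(parts[0], parts[1])


class PanProfile:
    """One tool's clustering of a gene universe into orthologous clusters.

    Clusters are disjoint non-empty sets of :class:`GeneId`; ``gene_index``
    maps each gene to the ordinal of its cluster and is the exact inverse of
    cluster membership.
    """

    __slots__ = ("name", "clusters", "gene_index")

    def __init__(self, name: str, clusters: Iterable[Iterable[GeneId]]):
        self.name = name
        self.clusters: List[frozenset] = [frozenset(c) for c in clusters]
        self.gene_index: Dict[GeneId, int] = {}
        for ordinal, cluster in enumerate(self.clusters):
            if not cluster:
                raise FormatError(
                    f"profile {name!r}: cluster at position {ordinal} is empty"
                )
            for gene in cluster:
                if gene in self.gene_index:
                    raise DuplicateGeneError(
                        f"profile {name!r}: gene {gene} appears in more than one cluster"
                    )
                self.gene_index[gene] = ordinal

    @property
    def genes(self):
        return self.gene_index.keys()

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    def genomes(self) -> Set[str]:
        return {g.genome for g in self.gene_index}

    def cluster_of(self, gene: GeneId):
        """Ordinal of the cluster containing *gene*, or None if absent."""
        return self.gene_index.get(gene)

    def same_clustering(self, other: "PanProfile") -> bool:
        """True if both profiles induce the identical partition (names ignored)."""
        return set(self.clusters) == set(other.clusters)

    def __repr__(self) -> str:
        return (
            f"PanProfile({self.name!r}, {self.n_clusters} clusters, "
            f"{self.n_genes} genes)"
        )


@dataclass(frozen=True)
class ClusterClass:
    """Classification of one cluster: label plus genome occurrence."""

    label: str  # "core" | "accessory" | "unique"
    occurrence: int


@dataclass(frozen=True)
class ProfileSummary:
    """Core/accessory/unique composition of one profile.

    Percentages are on the 0-100 scale, truncated to two decimals;
    ``per_genome_unique`` maps every genome to the number of unique clusters
    whose sole genome it is (zero included).
    """

    name: str
    total_clusters: int
    core_count: int
    accessory_count: int
    unique_count: int
    core_pct: float
    accessory_pct: float
    unique_pct: float
    per_genome_unique: Mapping[str, int] = field(default_factory=dict)


def _core_threshold(core_fraction: float, n_genomes: int) -> int:
    if not (0.0 < core_fraction <= 1.0):
        raise ConfigError(f"core_fraction must be in (0, 1], got {core_fraction}")
    # round before ceil to absorb float noise such as 0.07 * 100 = 7.000000000000001
    return math.ceil(round(core_fraction * n_genomes, 9))


def classify_clusters(
    profile: PanProfile,
    genomes: Set[str],
    core_fraction: float = 1.0,
) -> List[ClusterClass]:
    """Classify every cluster of *profile* as core, accessory or unique.

    Parameters
    ----------
    genomes
        The full genome set of the study; every gene's genome must be in it.
    core_fraction
        Fraction of genomes a cluster must reach to count as core
        (default 1.0: strict core, present in all genomes).
    """
    genomes = set(genomes)
    if not genomes:
        raise UsageError("genome set must be non-empty")
    threshold = _core_threshold(core_fraction, len(genomes))
    classes: List[ClusterClass] = []
    for cluster in profile.clusters:
        seen = {g.genome for g in cluster}
        unknown = seen - genomes
        if unknown:
            bad = next(g for g in sorted(cluster) if g.genome in unknown)
            raise UnknownGenomeError(
                f"gene {bad} references genome {bad.genome!r}, "
                "which is not in the given genome set"
            )
        occ = len(seen)
        if occ == 1:
            label = "unique"
        elif occ >= threshold:
            label = "core"
        else:
            label = "accessory"
        classes.append(ClusterClass(label=label, occurrence=occ))
    return classes


def _trunc_pct(count: int, total: int) -> float:
    """Percentage of count/total truncated to 2 decimals, in exact integer math."""
    return (count * 10000) // total / 100


def summarize(
    profile: PanProfile,
    genomes: Set[str],
    core_fraction: float = 1.0,
) -> ProfileSummary:
    """Aggregate :func:`classify_clusters` into counts and percentages."""
    if profile.n_clusters == 0:
        raise UsageError(f"profile {profile.name!r} has no clusters to summarize")
    classes = classify_clusters(profile, genomes, core_fraction)
    counts = {"core": 0, "accessory": 0, "unique": 0}
    per_genome_unique: Dict[str, int] = {g: 0 for g in sorted(genomes)}
    for cluster, cls in zip(profile.clusters, classes):
        counts[cls.label] += 1
        if cls.label == "unique":
            sole = next(iter(cluster)).genome
            per_genome_unique[sole] += 1
    total = profile.n_clusters
    return ProfileSummary(
        name=profile.name,
        total_clusters=total,
        core_count=counts["core"],
        accessory_count=counts["accessory"],
        unique_count=counts["unique"],
        core_pct=_trunc_pct(counts["core"], total),
        accessory_pct=_trunc_pct(counts["accessory"], total),
        unique_pct=_trunc_pct(counts["unique"], total),
        per_genome_unique=per_genome_unique,
    )


def harmonize_profiles(
    profiles: Sequence[PanProfile],
    strict: bool = False,
) -> Tuple[List[PanProfile], Dict[str, int]]:
    """Bring all profiles onto one shared gene universe.

    A gene clustered by at least one tool but absent from profile *s* (e.g.
    unassigned or dropped) is added to *s* as a singleton cluster: it is
    co-clustered with nothing, which is the neutral statement about it.  With
    ``strict=True`` a universe mismatch raises instead.

    Returns the harmonized profiles (originals are reused when already
    complete) and a map profile name -> number of singletons added, so
    callers can flag the repair in reports.
    """
    universe: Set[GeneId] = set()
    for p in profiles:
        universe.update(p.gene_index)
    out: List[PanProfile] = []
    added: Dict[str, int] = {}
    for p in profiles:
        missing = universe - p.gene_index.keys()
        added[p.name] = len(missing)
        if not missing:
            out.append(p)
            continue
        if strict:
            raise UsageError(
                f"profile {p.name!r} is missing {len(missing)} gene(s) present "
                "in other profiles (strict mode refuses singleton completion)"
            )
        extra = [{g} for g in sorted(missing)]
        out.append(PanProfile(p.name, list(p.clusters) + extra))
    return out, added
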