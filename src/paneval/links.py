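"""Co-clustered gene-pair links and the shared-link matrix.

A *link* is an unordered pair of genes placed in the same cluster by a
profile; a cluster of size k contributes k(k-1)/2 links.  Links can be
taken over all clusters (the scoring pair universe) or restricted to each
profile's core clusters (the tool-comparison convention).  The shared-link
matrix counts links common to each pair of profiles and is the direct
numeric analogue of a chord diagram of core-gene agreement between tools.

Pair enumeration is per cluster, never over the full cross product, so cost
scales with the sum of squared cluster sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Set

import pandas as pd

from .errors import ConfigError, UsageError
from .model import GeneId, PanProfile, classify_clusters

__all__ = [
    "GenePair",
    "LinkSet",
    "cocluster_pairs",
    "pair_universe",
    "shared_link_matrix",
    "SCOPE_ALL",
    "SCOPE_CORE",
]

SCOPE_ALL = "all_clusters"
SCOPE_CORE = "core_clusters"
_SCOPES = {SCOPE_ALL, SCOPE_CORE, "all", "core"}


def _canon_scope(scope: str) -> str:
    if scope not in _SCOPES:
        raise ConfigError(f"unknown scope {scope!r}; use 'all_clusters' or 'core_clusters'")
    return SCOPE_CORE if scope in (SCOPE_CORE, "core") else SCOPE_ALL


@dataclass(frozen=True)
class GenePair:
    """Canonical unordered pair of genes: ``a < b`` on the rendered form."""

    a: GeneId
    b: GeneId

    def __post_init__(self) -> None:
        if not str(self.a) < str(self.b):
            raise ConfigError(
                f"GenePair({self.a}, {self.b}) is not in canonical order; "
                "use GenePair.of()"
            )

    @classmethod
    def of(cls, g: GeneId, h: GeneId) -> "GenePair":
        if g == h:
            raise ConfigError(f"a gene cannot pair with itself: {g}")
        return cls(g, h) if str(g) < str(h) else cls(h, g)

    def __lt__(self, other: "GenePair") -> bool:
        return (str(self.a), str(self.b)) < (str(other.a), str(other.b))

    def __iter__(self):
        return iter((self.a, self.b))


@dataclass(frozen=True)
class LinkSet:
    """All links of one profile under a stated scope."""

    profile_name: str
    pairs: FrozenSet[GenePair]
    scope: str

    def __len__(self) -> int:
        return len(self.pairs)


def cocluster_pairs(
    profile: PanProfile,
    scope: str = SCOPE_ALL,
    genomes: Optional[Set[str]] = None,
    core_fraction: float = 1.0,
    max_cluster_size: Optional[int] = None,
) -> LinkSet:
    """Enumerate all within-cluster gene pairs of *profile*.

    With ``scope="core_clusters"`` only clusters classified as core (against
    *genomes*, default the profile's own genomes, at *core_fraction*)
    contribute pairs.  ``max_cluster_size`` guards against pathological
    clusters whose quadratic pair count would be unaffordable.
    """
    scope = _canon_scope(scope)
    selected = profile.clusters
    if scope == SCOPE_CORE:
        if genomes is None:
            genomes = profile.genomes()
        classes = classify_clusters(profile, genomes, core_fraction)
        selected = [c for c, k in zip(profile.clusters, classes) if k.label == "core"]
    pairs: Set[GenePair] = set()
    for cluster in selected:
        if max_cluster_size is not None and len(cluster) > max_cluster_size:
            raise UsageError(
                f"profile {profile.name!r}: cluster of size {len(cluster)} exceeds "
                f"max_cluster_size={max_cluster_size}; raise the guard if this "
                "cluster is genuine"
            )
        members = sorted(cluster, key=str)
        # members are sorted by rendered form, so pairs come out canonical
        pairs.update(GenePair(a, b) for a, b in itertools.combinations(members, 2))
    return LinkSet(profile_name=profile.name, pairs=frozenset(pairs), scope=scope)


def pair_universe(
    profiles: Sequence[PanProfile],
    scope: str = SCOPE_ALL,
    genomes: Optional[Set[str]] = None,
    core_fraction: float = 1.0,
) -> Set[GenePair]:
    """Union of co-clustered pairs over all profiles (the scoring universe)."""
    if len(profiles) < 2:
        raise UsageError("pair_universe needs at least two profiles")
    universe: Set[GenePair] = set()
    for p in profiles:
        universe.update(
            cocluster_pairs(p, scope=scope, genomes=genomes,
                            core_fraction=core_fraction).pairs
        )
    return universe


def shared_link_matrix(
    profiles: Sequence[PanProfile],
    scope: str = SCOPE_CORE,
    genomes: Optional[Set[str]] = None,
    core_fraction: float = 1.0,
) -> pd.DataFrame:
    """Symmetric matrix of shared link counts between profiles.

    Entry (s, t) is the number of links extracted from both profiles under
    the given scope; the diagonal is each profile's own link count.  Default
    scope is core clusters, each classified against its own profile.
    """
    if len(profiles) < 2:
        raise UsageError("shared_link_matrix needs at least two profiles")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise UsageError(f"profile names must be unique, got {names}")
    sets = [
        cocluster_pairs(p, scope=scope, genomes=genomes,
                        core_fraction=core_fraction).pairs
        for p in profiles
    ]
    n = len(profiles)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i in range(n):
        mat.iat[i, i] = len(sets[i])
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            mat.iat[i, j] = shared
            mat.iat[j, i] = shared
    return mat
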