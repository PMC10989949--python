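"""Profile scoring by gene-pair concordance.

Every pair of genes co-clustered by at least one profile (the *pair
universe*) casts one vote per profile:

* **COG branch** — when both genes carry a COG annotation, the annotation is
  the arbiter: a profile earns a point for co-clustering a same-COG pair, or
  for separating a different-COG pair.
* **Consensus branch** — when annotation cannot arbitrate, the other
  profiles do: with ``c`` profiles placing the pair together and a cutoff
  ``x``, a profile earns a point for co-clustering when ``c > x`` and (under
  the default majority rule) for separating when ``c < x``.  At ``c == x``
  no point is awarded either way.

A profile's score is the number of pairs on which it agrees with the
arbiter, so ``0 <= score <= |universe|`` and the profile with the highest
score is reported as the most reliable clustering.

``score_profiles_bruteforce`` is a deliberately naive reference
implementation (explicit membership scans over cluster lists, no index)
retained so the optimized scorer can be cross-checked against an
independent code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .errors import ConfigError, UsageError
from .links import SCOPE_ALL, GenePair, pair_universe
from .model import PanProfile, harmonize_profiles
from .profile_io import CogAnnotation

__all__ = [
    "ScoringConfig",
    "PairEvidence",
    "ProfileScore",
    "ScoreReport",
    "build_pair_evidence",
    "score_profiles",
    "score_profiles_bruteforce",
    "best_profile",
]

RULE_MAJORITY = "majority"
RULE_LITERAL = "literal"


@dataclass
class ScoringConfig:
    """Knobs of the scoring algorithm.

    x
        Consensus cutoff: the number of profiles that must report a pair
        together before co-clustering it is rewarded.  Default ``None``
        means N/2 (possibly fractional, which removes the ``c == x`` dead
        zone for even N).
    scope
        Which clusters feed the pair universe: ``all_clusters`` (default)
        or ``core_clusters``.
    consensus_rule
        ``majority`` (default): separation is rewarded when fewer than x
        profiles place the pair together.  ``literal``: separation is
        rewarded when fewer than x profiles place the pair apart — an
        alternative reading of the consensus condition, kept for audit.
    core_fraction
        Core threshold used only when ``scope="core_clusters"``.
    """

    x: Optional[float] = None
    scope: str = SCOPE_ALL
    consensus_rule: str = RULE_MAJORITY
    core_fraction: float = 1.0

    def resolved_x(self, n_profiles: int) -> float:
        x = n_profiles / 2 if self.x is None else self.x
        if not (0 <= x <= n_profiles):
            raise ConfigError(
                f"cutoff x={x} must lie in [0, {n_profiles}] for {n_profiles} profiles"
            )
        if self.consensus_rule not in (RULE_MAJORITY, RULE_LITERAL):
            raise ConfigError(
                f"consensus_rule must be 'majority' or 'literal', "
                f"got {self.consensus_rule!r}"
            )
        return x


@dataclass(frozen=True)
class PairEvidence:
    """What the profiles and the annotation say about one universe pair."""

    pair: GenePair
    per_profile_together: Tuple[bool, ...]
    both_annotated: bool
    same_cog: Optional[bool]  # defined only when both_annotated

    @property
    def together_count(self) -> int:
        return sum(self.per_profile_together)


@dataclass(frozen=True)
class ProfileScore:
    """One profile's row of the score report."""

    name: str
    score: int
    pairs_total: int
    pairs_cog_branch: int
    pairs_consensus_branch: int
    score_fraction: float
    rank: int
    is_best: bool
    ties: Tuple[str, ...]
    singletons_added: int = 0


@dataclass
class ScoreReport:
    """Scores, ranking and best-profile designation for a set of profiles."""

    entries: List[ProfileScore]
    pairs_total: int
    pairs_cog_branch: int
    pairs_consensus_branch: int
    x: float
    scope: str
    consensus_rule: str
    harmonization_added: Dict[str, int] = field(default_factory=dict)

    def by_name(self, name: str) -> ProfileScore:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def scores(self) -> Dict[str, int]:
        return {e.name: e.score for e in self.entries}

    @property
    def best(self) -> ProfileScore:
        return next(e for e in self.entries if e.is_best)


def build_pair_evidence(
    profiles: Sequence[PanProfile],
    universe: Set[GenePair],
    cog: Optional[CogAnnotation] = None,
) -> List[PairEvidence]:
    """Collect per-pair co-clustering flags and annotation status.

    Profiles must share one gene universe (harmonize first); evidence is
    returned in canonical pair order.
    """
    cog = cog or CogAnnotation()
    indexes = [p.gene_index for p in profiles]
    evidence: List[PairEvidence] = []
    for pair in sorted(universe):
        together = tuple(
            idx.get(pair.a) is not None and idx.get(pair.a) == idx.get(pair.b)
            for idx in indexes
        )
        ca, cb = cog.get(pair.a), cog.get(pair.b)
        both = ca is not None and cb is not None
        evidence.append(
            PairEvidence(
                pair=pair,
                per_profile_together=together,
                both_annotated=both,
                same_cog=(ca == cb) if both else None,
            )
        )
    return evidence


def score_profiles(
    profiles: Sequence[PanProfile],
    cog: Optional[CogAnnotation] = None,
    config: Optional[ScoringConfig] = None,
    strict: bool = False,
) -> ScoreReport:
    """Score every profile by pair concordance and rank them.

    Profiles are harmonized onto one gene universe first (singleton
    completion; ``strict=True`` errors on mismatch instead, and the number
    of singletons added per profile is recorded in the report).
    """
    if len(profiles) < 2:
        raise UsageError("scoring needs at least two profiles")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise UsageError(f"profile names must be unique, got {names}")
    config = config or ScoringConfig()
    n = len(profiles)
    x = config.resolved_x(n)

    harmonized, added = harmonize_profiles(profiles, strict=strict)
    universe = pair_universe(
        harmonized, scope=config.scope, core_fraction=config.core_fraction
    )
    evidence = build_pair_evidence(harmonized, universe, cog)

    scores = [0] * n
    n_cog = 0
    for ev in evidence:
        if ev.both_annotated:
            n_cog += 1
            for s, together in enumerate(ev.per_profile_together):
                if ev.same_cog == together:  # agree with the annotation arbiter
                    scores[s] += 1
        else:
            c = ev.together_count
            reward_together = c > x
            if config.consensus_rule == RULE_MAJORITY:
                reward_apart = c < x
            else:  # literal reading: "apart in fewer than x profiles"
                reward_apart = (n - c) < x
            for s, together in enumerate(ev.per_profile_together):
                if together:
                    if reward_together:
                        scores[s] += 1
                elif reward_apart:
                    scores[s] += 1

    total = len(universe)
    n_consensus = total - n_cog
    best_score = max(scores)
    winners = sorted(name for name, sc in zip(names, scores) if sc == best_score)
    ties = tuple(winners) if len(winners) > 1 else ()
    entries = []
    for name, sc in zip(names, scores):
        rank = 1 + sum(other > sc for other in scores)
        entries.append(
            ProfileScore(
                name=name,
                score=sc,
                pairs_total=total,
                pairs_cog_branch=n_cog,
                pairs_consensus_branch=n_consensus,
                score_fraction=(sc / total) if total else 0.0,
                rank=rank,
                is_best=(name == winners[0]),
                ties=ties,
                singletons_added=added.get(name, 0),
            )
        )
    return ScoreReport(
        entries=entries,
        pairs_total=total,
        pairs_cog_branch=n_cog,
        pairs_consensus_branch=n_consensus,
        x=x,
        scope=config.scope,
        consensus_rule=config.consensus_rule,
        harmonization_added=added,
    )


def best_profile(report: ScoreReport) -> Tuple[str, List[str]]:
    """Name of the top-scoring profile plus the full tie list (empty if unique).

    Ties are broken lexicographically, but all co-ranked names are returned
    so callers can surface them prominently.
    """
    if not report.entries:
        raise UsageError("empty score report")
    best = report.best
    return best.name, list(best.ties)


# ---------------------------------------------------------------------------
# independent reference implementation
# ---------------------------------------------------------------------------

def _same_cluster_scan(profile: PanProfile, a, b) -> bool:
    # membership scan over the raw cluster list; genes missing from the
    # profile are implicitly singletons and co-cluster with nothing
    for cluster in profile.clusters:
        if a in cluster:
            return b in cluster
    return False


def score_profiles_bruteforce(
    profiles: Sequence[PanProfile],
    cog: Optional[CogAnnotation] = None,
    config: Optional[ScoringConfig] = None,
) -> Dict[str, int]:
    """Naive reference scorer: per-pair, per-profile membership scans.

    Uses no gene index and no harmonization step (absent genes are treated
    as singletons directly), so it shares no code path with
    :func:`score_profiles`.  Quadratic in cluster count per lookup — only
    for small cross-check instances.
    """
    if len(profiles) < 2:
        raise UsageError("scoring needs at least two profiles")
    config = config or ScoringConfig()
    if config.scope != SCOPE_ALL:
        raise ConfigError("brute-force scorer supports scope='all_clusters' only")
    cog = cog or CogAnnotation()
    n = len(profiles)
    x = config.resolved_x(n)

    pairs = set()
    for p in profiles:
        for cluster in p.clusters:
            members = sorted(cluster, key=str)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add((members[i], members[j]))

    scores = {p.name: 0 for p in profiles}
    for a, b in pairs:
        ca, cb = cog.get(a), cog.get(b)
        if ca is not None and cb is not None:
            for p in profiles:
                together = _same_cluster_scan(p, a, b)
                if (ca == cb and together) or (ca != cb and not together):
                    scores[p.name] += 1
        else:
            c = sum(_same_cluster_scan(p, a, b) for p in profiles)
            if config.consensus_rule == RULE_MAJORITY:
                apart_ok = c < x
            else:
                apart_ok = (n - c) < x
            for p in profiles:
                together = _same_cluster_scan(p, a, b)
                if together and c > x:
                    scores[p.name] += 1
                elif not together and apart_ok:
                    scores[p.name] += 1
    return scores
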