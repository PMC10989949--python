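"""Readers and writers for cluster-profile and annotation file formats.

Supported inputs
----------------
* Roary ``gene_presence_absence.csv`` — quoted CSV, 14 fixed metadata
  columns then one column per genome; cells may hold several paralog
  tokens separated by tab or semicolon.
* OrthoFinder ``Orthogroups.tsv`` (plus optional
  ``Orthogroups_UnassignedGenes.tsv``) — TSV, one column per species,
  cells are ", "-separated gene lists.
* Generic cluster TSV — ``cluster_id<TAB>gene_token``, one row per gene;
  tokens are either embedded ``genome|local`` forms or bare tokens
  resolved through a genome map.
* COG table — ``gene_token<TAB>cog_id``; blank COG means unannotated.
* Genome map — ``gene_token<TAB>genome_id``.

Every reader rejects files that would violate profile disjointness
(duplicate genes) rather than silently repairing them, and reading the same
file twice yields an identical profile.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import pandas as pd

from .errors import (
    AnnotationConflictError,
    DuplicateGeneError,
    FormatError,
    UnknownGenomeError,
    UsageError,
)
from .model import GeneId, PanProfile, ProfileSummary

__all__ = [
    "CogAnnotation",
    "GenomeMap",
    "ROARY_META_COLUMNS",
    "read_roary_csv",
    "read_orthofinder_tsv",
    "read_generic_clusters",
    "read_cog_table",
    "read_genome_map",
    "write_presence_absence",
    "write_generic_clusters",
    "write_cog_table",
    "write_genome_map",
    "write_matrix_tsv",
    "write_summary_tsv",
    "write_per_genome_unique_tsv",
    "write_pairs_tsv",
]

# The fixed metadata columns Roary writes before the genome columns.
ROARY_META_COLUMNS = (
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
)


@dataclass(frozen=True)
class CogAnnotation:
    """Partial map gene -> COG identifier; absence means unannotated."""

    assignments: Mapping[GeneId, str] = field(default_factory=dict)

    def get(self, gene: GeneId) -> Optional[str]:
        return self.assignments.get(gene)

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class GenomeMap:
    """Map from bare gene token to the genome it belongs to."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def resolve(self, token: str) -> GeneId:
        if "|" in token:
            return GeneId.parse(token)
        genome = self.mapping.get(token)
        if genome is None:
            raise UnknownGenomeError(f"gene token {token!r} is not in the genome map")
        return GeneId(genome, token)


def _resolve_token(token: str, genome_map: Union[GenomeMap, str, None]) -> GeneId:
    if isinstance(genome_map, GenomeMap):
        return genome_map.resolve(token)
    if "|" in token:
        return GeneId.parse(token)
    raise UnknownGenomeError(
        f"gene token {token!r} has no 'genome|local' form and no genome map was given"
    )


def read_roary_csv(
    path: Union[str, Path],
    paralog_separators: Iterable[str] = ("\t", ";"),
    name: Optional[str] = None,
) -> PanProfile:
    """Read a Roary ``gene_presence_absence.csv`` into a profile.

    One cluster per data row; cluster members are the non-empty tokens of
    the genome columns (column 15 onward), split on *paralog_separators*,
    each qualified by its column's genome name.
    """
    path = Path(path)
    seps = list(paralog_separators)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) < len(ROARY_META_COLUMNS) + 1:
            raise FormatError(
                f"{path}: expected at least 15 columns "
                f"(14 Roary metadata columns plus genomes), found {len(header)}"
            )
        for i, expected in enumerate(ROARY_META_COLUMNS[:4]):
            if header[i].strip() != expected:
                raise FormatError(
                    f"{path}: header column {i + 1} is {header[i]!r}, "
                    f"expected {expected!r} (not a Roary gene_presence_absence.csv?)"
                )
        genomes = [h.strip() for h in header[len(ROARY_META_COLUMNS):]]
        clusters: List[Set[GeneId]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            members: Set[GeneId] = set()
            cells = row[len(ROARY_META_COLUMNS):]
            for genome, cell in zip(genomes, cells):
                for token in _split_tokens(cell, seps):
                    members.add(GeneId(genome, token))
            if not members:
                raise FormatError(
                    f"{path}:{lineno}: row {row[0]!r} has no genes in any genome column"
                )
            clusters.append(members)
    return _build_profile(name or path.stem, clusters, str(path))


def _split_tokens(cell: str, separators: Sequence[str]) -> List[str]:
    parts = [cell]
    for sep in separators:
        parts = [piece for part in parts for piece in part.split(sep)]
    return [p.strip() for p in parts if p.strip()]


def read_orthofinder_tsv(
    path: Union[str, Path],
    unassigned_path: Union[str, Path, None] = None,
    name: Optional[str] = None,
) -> PanProfile:
    """Read an OrthoFinder ``Orthogroups.tsv`` into a profile.

    Each orthogroup row becomes one cluster; genes in the optional
    unassigned-genes table (same layout) become singleton clusters.
    """
    path = Path(path)
    clusters: List[Set[GeneId]] = []
    for cluster in _iter_orthogroup_rows(path, require_genes=True):
        clusters.append(cluster)
    if unassigned_path is not None:
        for cluster in _iter_orthogroup_rows(Path(unassigned_path), require_genes=False):
            for gene in sorted(cluster):
                clusters.append({gene})
    return _build_profile(name or path.stem, clusters, str(path))


def _iter_orthogroup_rows(path: Path, require_genes: bool):
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0].strip().lower() not in ("orthogroup", "orthogroups"):
            raise FormatError(
                f"{path}: first header column is {header[0]!r}, expected 'Orthogroup'"
            )
        species = [h.strip() for h in header[1:]]
        if not species:
            raise FormatError(f"{path}: no species columns after 'Orthogroup'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            members: Set[GeneId] = set()
            for sp, cell in zip(species, row[1:]):
                for token in cell.split(","):
                    token = token.strip()
                    if token:
                        members.add(GeneId(sp, token))
            if not members:
                if require_genes:
                    raise FormatError(
                        f"{path}:{lineno}: orthogroup {row[0]!r} has no genes"
                    )
                continue
            yield members


def read_generic_clusters(
    path: Union[str, Path],
    genome_map: Union[GenomeMap, str, None] = "embedded",
    name: Optional[str] = None,
) -> PanProfile:
    """Read a two-column ``cluster_id<TAB>gene_token`` TSV into a profile.

    With ``genome_map="embedded"`` tokens must carry the ``genome|local``
    form; otherwise they are resolved through the given :class:`GenomeMap`.
    Clusters keep file order.
    """
    path = Path(path)
    gmap = None if genome_map == "embedded" else genome_map
    grouped: Dict[str, Set[GeneId]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected 'cluster_id<TAB>gene_token', got {line!r}"
                )
            cid, token = parts[0].strip(), parts[1].strip()
            gene = _resolve_token(token, gmap)
            grouped.setdefault(cid, set()).add(gene)
    return _build_profile(name or path.stem, list(grouped.values()), str(path))


def _build_profile(name: str, clusters: List[Set[GeneId]], source: str) -> PanProfile:
    try:
        return PanProfile(name, clusters)
    except DuplicateGeneError as exc:
        raise DuplicateGeneError(f"{source}: {exc}") from None


def read_cog_table(
    path: Union[str, Path],
    genome_map: Union[GenomeMap, str, None] = "embedded",
) -> CogAnnotation:
    """Read a ``gene_token<TAB>cog_id`` TSV.

    Blank COG fields mean unannotated and are skipped; identical duplicate
    rows are deduplicated; conflicting duplicates are an error.
    """
    path = Path(path)
    gmap = None if genome_map == "embedded" else genome_map
    assignments: Dict[GeneId, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2) or not parts[0].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected 'gene_token<TAB>cog_id', got {line!r}"
                )
            token = parts[0].strip()
            cog = parts[1].strip() if len(parts) == 2 else ""
            if not cog:
                continue
            gene = _resolve_token(token, gmap)
            previous = assignments.get(gene)
            if previous is not None and previous != cog:
                raise AnnotationConflictError(
                    f"{path}:{lineno}: gene {gene} assigned both "
                    f"{previous!r} and {cog!r}"
                )
            assignments[gene] = cog
    return CogAnnotation(assignments=assignments)


def read_genome_map(path: Union[str, Path]) -> GenomeMap:
    """Read a ``gene_token<TAB>genome_id`` TSV."""
    path = Path(path)
    mapping: Dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(
                    f"{path}:{lineno}: expected 'gene_token<TAB>genome_id', got {line!r}"
                )
            token, genome = parts[0].strip(), parts[1].strip()
            previous = mapping.get(token)
            if previous is not None and previous != genome:
                raise FormatError(
                    f"{path}:{lineno}: token {token!r} mapped to both "
                    f"{previous!r} and {genome!r}"
                )
            mapping[token] = genome
    return GenomeMap(mapping=mapping)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_presence_absence(
    profile: PanProfile,
    genomes: Set[str],
    path: Union[str, Path],
) -> None:
    """Write a cluster x genome gene-count matrix as TSV.

    Rows are clusters in input order with stable ids C000001..., columns are
    the sorted genomes, cells are the number of genes of that genome in that
    cluster (paralogs count individually).
    """
    if not genomes:
        raise UsageError("genome set must be non-empty")
    cols = sorted(genomes)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("cluster\t" + "\t".join(cols) + "\n")
        for ordinal, cluster in enumerate(profile.clusters, start=1):
            counts = {g: 0 for g in cols}
            for gene in cluster:
                if gene.genome not in counts:
                    raise UnknownGenomeError(
                        f"gene {gene} references genome {gene.genome!r}, "
                        "which is not in the given genome set"
                    )
                counts[gene.genome] += 1
            fh.write(
                f"C{ordinal:06d}\t" + "\t".join(str(counts[g]) for g in cols) + "\n"
            )


def write_generic_clusters(profile: PanProfile, path: Union[str, Path]) -> None:
    """Write a profile as a generic cluster TSV with embedded gene tokens."""
    path = Path(path)
    with path.open("w") as fh:
        for ordinal, cluster in enumerate(profile.clusters, start=1):
            cid = f"C{ordinal:06d}"
            for gene in sorted(cluster):
                fh.write(f"{cid}\t{gene}\n")


def write_cog_table(cog: CogAnnotation, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene in sorted(cog.assignments, key=str):
            fh.write(f"{gene}\t{cog.assignments[gene]}\n")


def write_genome_map(genes: Iterable[GeneId], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for gene in sorted(set(genes)):
            fh.write(f"{gene}\t{gene.genome}\n")


def write_matrix_tsv(matrix: pd.DataFrame, path: Union[str, Path], scope: str = "") -> None:
    """Write a labelled shared-link matrix as TSV (scope noted in the corner cell)."""
    out = matrix.copy()
    out.index.name = f"profile[{scope}]" if scope else "profile"
    out.to_csv(path, sep="\t")


def write_summary_tsv(summaries: Sequence[ProfileSummary], path: Union[str, Path]) -> None:
    rows = [
        {
            "profile": s.name,
            "total_clusters": s.total_clusters,
            "core": s.core_count,
            "accessory": s.accessory_count,
            "unique": s.unique_count,
            "core_pct": f"{s.core_pct:.2f}",
            "accessory_pct": f"{s.accessory_pct:.2f}",
            "unique_pct": f"{s.unique_pct:.2f}",
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_per_genome_unique_tsv(
    summaries: Sequence[ProfileSummary], path: Union[str, Path]
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("profile\tgenome\tunique_clusters\n")
        for s in summaries:
            for genome in sorted(s.per_genome_unique):
                fh.write(f"{s.name}\t{genome}\t{s.per_genome_unique[genome]}\n")


def write_pairs_tsv(pairs, path: Union[str, Path]) -> None:
    """Debug export of a pair set as a two-column TSV."""
    path = Path(path)
    with path.open("w") as fh:
        for pair in sorted(pairs):
            fh.write(f"{pair.a}\t{pair.b}\n")
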