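"""Sub-genome-aware marker classification for an allotetraploid genome.

Groundnut carries two homoeologous sub-genomes (A: Arahy.01-10,
B: Arahy.11-20) with high sequence similarity, so a marker's context
sequence may align to one sub-genome, to its homoeologous locus on the
other, or to repetitive loci. Alignments of each marker against each
sub-genome, filtered at a 95% threshold, are classified per sub-genome
and combined into assay categories:

* Category 1 — unique to a single sub-genome (diploid-pattern marker,
  dosage 0..2);
* Category 2 — one locus on each sub-genome (tetraploid-pattern,
  dosage 0..4);
* Category 3 — two loci on the same sub-genome or more than two loci
  overall (excluded from the standard assay design path).

Alignments are inputs (tabular hits); this module does not run an
aligner. The 95% threshold is applied to both the identity and the
query-coverage fraction of a hit; both cut-offs are configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .marker_catalog import MarkerDef
from .published import subgenome_of_chromosome


@dataclass
class AlignmentHit:
    """One mapping of a marker context sequence to a sub-genome locus.

    ``target_position`` is the 1-based position of the variant site when
    the alignment resolves it, else 0 (region known, site not).
    """

    marker_id: str
    target_chromosome: str
    target_position: int = 0
    identity_fraction: float = 1.0
    query_coverage_fraction: float = 1.0
    mismatches: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must be in [0, 1]")
        if not 0.0 <= self.query_coverage_fraction <= 1.0:
            raise ValueError("query_coverage_fraction must be in [0, 1]")

    @property
    def subgenome(self) -> str:
        return subgenome_of_chromosome(self.target_chromosome)


class MappingClass(enum.Enum):
    """Per-(marker, sub-genome) mapping outcome."""

    UNIQUE_POSITION = "unique_position"
    UNIQUE_REGION_NO_POSITION = "unique_region_no_position"
    MULTI_SAME_SUBGENOME = "multi_same_subgenome"
    UNMAPPED = "unmapped"


@dataclass
class CategoryAssignment:
    marker_id: str
    category: str
    loci: list[tuple[str, int]] = field(default_factory=list)
    subgenome: str = "none"
    position_unresolved: bool = False


def classify_subgenome(
    hits: Sequence[AlignmentHit],
    threshold: float = 0.95,
    coverage_threshold: Optional[float] = None,
) -> MappingClass:
    """Classify one marker's hits against one sub-genome.

    Hits below the identity threshold (or the coverage threshold, which
    defaults to the same value) are discarded. Zero surviving hits is
    unmapped; one hit is unique (with or without a resolved variant
    position); two or more is multi-locus.
    """
    cov = threshold if coverage_threshold is None else coverage_threshold
    surviving = [
        h for h in hits
        if h.identity_fraction >= threshold and h.query_coverage_fraction >= cov
    ]
    if not surviving:
        return MappingClass.UNMAPPED
    if len(surviving) > 1:
        return MappingClass.MULTI_SAME_SUBGENOME
    if surviving[0].target_position > 0:
        return MappingClass.UNIQUE_POSITION
    return MappingClass.UNIQUE_REGION_NO_POSITION


def surviving_loci(
    hits: Sequence[AlignmentHit],
    threshold: float = 0.95,
    coverage_threshold: Optional[float] = None,
) -> list[tuple[str, int]]:
    """Loci of hits passing the thresholds, sorted for determinism."""
    cov = threshold if coverage_threshold is None else coverage_threshold
    loci = [
        (h.target_chromosome, h.target_position)
        for h in hits
        if h.identity_fraction >= threshold and h.query_coverage_fraction >= cov
    ]
    return sorted(loci)


_UNIQUE = {MappingClass.UNIQUE_POSITION, MappingClass.UNIQUE_REGION_NO_POSITION}


def assign_category(
    class_a: MappingClass,
    class_b: MappingClass,
    loci_a: Sequence[tuple[str, int]] = (),
    loci_b: Sequence[tuple[str, int]] = (),
    marker_id: str = "",
) -> CategoryAssignment:
    """Combine per-sub-genome mapping classes into an assay category.

    Unique on exactly one sub-genome -> cat1; unique on both -> cat2;
    multi-locus on either sub-genome (or more than two loci overall)
    -> cat3; unmapped on both -> unmapped. A unique hit without a
    resolved variant position still counts as unique but flags the
    assignment ``position_unresolved``.
    """
    multi = MappingClass.MULTI_SAME_SUBGENOME
    unresolved = MappingClass.UNIQUE_REGION_NO_POSITION in (class_a, class_b)
    all_loci = list(loci_a) + list(loci_b)

    if class_a is multi or class_b is multi or len(all_loci) > 2:
        return CategoryAssignment(
            marker_id, "cat3", all_loci, "none", unresolved
        )
    a_unique = class_a in _UNIQUE
    b_unique = class_b in _UNIQUE
    if a_unique and b_unique:
        return CategoryAssignment(
            marker_id, "cat2", all_loci, "both", unresolved
        )
    if a_unique or b_unique:
        return CategoryAssignment(
            marker_id, "cat1", all_loci, "A" if a_unique else "B", unresolved
        )
    return CategoryAssignment(marker_id, "unmapped", [], "none", False)


@dataclass
class CategorySummary:
    """Counts from categorizing a catalog (a partition of the catalog)."""

    n_markers: int
    by_category: dict[str, int]
    by_subgenome: dict[str, int]
    by_chromosome: dict[str, int]
    cat3_excluded_ids: list[str]
    unknown_hit_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.by_chromosome.items()), columns=["chromosome", "n_markers"]
        )


def categorize_catalog(
    markers: Sequence[MarkerDef],
    hits: Iterable[AlignmentHit],
    threshold: float = 0.95,
    coverage_threshold: Optional[float] = None,
) -> tuple[list[CategoryAssignment], CategorySummary]:
    """Categorize every marker of a catalog from an alignment-hit table.

    Each marker receives exactly one category; markers in the catalog
    with no hits are unmapped. Hits referencing unknown marker ids are
    reported in the summary and otherwise ignored. Category-3 markers
    are flagged for exclusion from assay design. The input markers are
    annotated in place (category, subgenome).
    """
    known = {m.marker_id for m in markers}
    per_marker: dict[str, dict[str, list[AlignmentHit]]] = {
        mid: {"A": [], "B": []} for mid in known
    }
    unknown: list[str] = []
    for h in hits:
        if h.marker_id not in known:
            unknown.append(h.marker_id)
            continue
        per_marker[h.marker_id][h.subgenome].append(h)

    assignments: list[CategoryAssignment] = []
    by_category: dict[str, int] = {}
    by_subgenome: dict[str, int] = {}
    by_chromosome: dict[str, int] = {}
    cat3: list[str] = []
    for m in markers:
        hits_a = per_marker[m.marker_id]["A"]
        hits_b = per_marker[m.marker_id]["B"]
        a = assign_category(
            classify_subgenome(hits_a, threshold, coverage_threshold),
            classify_subgenome(hits_b, threshold, coverage_threshold),
            surviving_loci(hits_a, threshold, coverage_threshold),
            surviving_loci(hits_b, threshold, coverage_threshold),
            marker_id=m.marker_id,
        )
        assignments.append(a)
        m.category = a.category
        m.subgenome = a.subgenome
        by_category[a.category] = by_category.get(a.category, 0) + 1
        by_subgenome[a.subgenome] = by_subgenome.get(a.subgenome, 0) + 1
        # one tally per marker (primary = first sorted locus) so the
        # per-chromosome table sums to the catalog size
        chrom = a.loci[0][0] if a.loci else "unmapped"
        by_chromosome[chrom] = by_chromosome.get(chrom, 0) + 1
        if a.category == "cat3":
            cat3.append(m.marker_id)

    summary = CategorySummary(
        n_markers=len(markers),
        by_category=by_category,
        by_subgenome=by_subgenome,
        by_chromosome=by_chromosome,
        cat3_excluded_ids=cat3,
        unknown_hit_ids=sorted(set(unknown)),
    )
    return assignments, summary


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Read a named-column TSV of alignment hits.

    Expected columns: ``qseqid`` (marker id), ``sseqid`` (target
    chromosome), ``pident`` (percent identity), ``qcovs`` (percent query
    coverage); optional ``mismatch`` and ``variant_pos`` (resolved
    1-based variant position, 0/absent if unresolved).
    """
    df = pd.read_csv(path, sep="\t")
    hits = []
    for _, row in df.iterrows():
        hits.append(
            AlignmentHit(
                marker_id=str(row["qseqid"]),
                target_chromosome=str(row["sseqid"]),
                target_position=int(row.get("variant_pos", 0) or 0),
                identity_fraction=float(row["pident"]) / 100.0,
                query_coverage_fraction=float(row["qcovs"]) / 100.0,
                mismatches=int(row.get("mismatch", 0) or 0),
            )
        )
    return hits


def from_blast_outfmt6(
    path: str | Path, query_lengths: Optional[Mapping[str, int]] = None
) -> list[AlignmentHit]:
    """Convert 12-column BLAST-style tabular output to alignment hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Query coverage is computed as aligned
    query span over ``query_lengths[qseqid]`` when lengths are supplied,
    else taken as complete. The variant position is left unresolved
    (0): plain hit tables do not locate the variant within the hit.
    """
    names = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=names)
    hits = []
    for _, row in df.iterrows():
        qid = str(row["qseqid"])
        span = abs(int(row["qend"]) - int(row["qstart"])) + 1
        if query_lengths and qid in query_lengths:
            coverage = min(span / query_lengths[qid], 1.0)
        else:
            coverage = 1.0
        hits.append(
            AlignmentHit(
                marker_id=qid,
                target_chromosome=str(row["sseqid"]),
                target_position=0,
                identity_fraction=float(row["pident"]) / 100.0,
                query_coverage_fraction=coverage,
                mismatches=int(row["mismatch"]),
            )
        )
    return hits
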