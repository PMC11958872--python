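"""Core marker and genotype-matrix data types with text-table IO.

The toolkit works with three kinds of tables:

* marker tables — one row per SNP/indel candidate or panel member
  (CSV/TSV with a header);
* genotype matrices — a hapmap-dialect text file, samples in columns,
  markers in rows, calls stored as alt-allele dosage strings;
* sample-name conversion tables mapping raw accession names to
  standardized identifiers.

Coordinates are 1-based and inclusive throughout (hapmap convention).
Tetraploid-pattern markers carry dosages 0..4 which have no diploid IUPAC
encoding, so the hapmap writer emits numeric dosages and records each
marker's dosage scale in a ``<path>.ploidy.tsv`` sidecar.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1  #: sentinel for a missing dosage call

_HAPMAP_META_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

VALID_CATEGORIES = {"cat1", "cat2", "cat3", "unmapped", "unset"}
VALID_SUBGENOMES = {"A", "B", "both", "none"}
VALID_VARIANT_CLASSES = {"SNP", "insertion", "deletion"}


def infer_variant_class(ref_allele: str, alt_allele: str) -> str:
    """Classify a variant from its allele tokens.

    Single-base ref and alt -> SNP; a longer alt -> insertion; otherwise
    deletion (covers ``-`` deletion tokens and truncated alts).
    """
    if len(ref_allele) == 1 and len(alt_allele) == 1 and alt_allele != "-":
        return "SNP"
    if len(alt_allele) > len(ref_allele):
        return "insertion"
    return "deletion"


@dataclass
class MarkerStats:
    """Per-marker summary statistics over a genotyped panel."""

    pic: Optional[float] = None
    maf: Optional[float] = None
    het_proportion: Optional[float] = None
    missing_proportion: Optional[float] = None
    n_called: int = 0


@dataclass
class MarkerDef:
    """One candidate or panel marker.

    ``category`` follows the tetraploid mapping classification: cat1
    amplifies a single sub-genome, cat2 one locus on each sub-genome,
    cat3 repetitive/multi-locus context.
    """

    marker_id: str
    chromosome: str
    position: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    flank: str = ""
    variant_class: str = "SNP"
    category: str = "unset"
    subgenome: str = "none"
    trait_tag: Optional[str] = None
    stats: Optional[MarkerStats] = None

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if self.position < 1:
            raise ValueError(
                f"marker {self.marker_id}: position must be >= 1 (1-based)"
            )
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subgenome not in VALID_SUBGENOMES:
            raise ValueError(f"unknown subgenome {self.subgenome!r}")
        if self.variant_class not in VALID_VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.category == "cat2" and self.subgenome != "both":
            raise ValueError(
                f"marker {self.marker_id}: category cat2 requires subgenome 'both'"
            )


class MarkerTableError(ValueError):
    """Raised for malformed marker tables (e.g. missing mandatory columns)."""


# accepted header aliases for the mandatory columns
_COLUMN_ALIASES = {
    "marker_id": {"marker_id", "rs#", "rs", "id", "snp_id", "marker"},
    "chromosome": {"chromosome", "chrom", "chr"},
    "position": {"position", "pos", "bp"},
}


def _resolve_column(columns: Sequence[str], canonical: str) -> Optional[str]:
    lowered = {c.lower(): c for c in columns}
    for alias in _COLUMN_ALIASES[canonical]:
        if alias in lowered:
            return lowered[alias]
    return None


def read_marker_table(path: str | Path, sep: Optional[str] = None) -> list[MarkerDef]:
    """Read a delimited marker table into a list of :class:`MarkerDef`.

    The header must name at least marker id, chromosome, position and
    alleles (either ``ref_allele``/``alt_allele`` columns or a combined
    ``alleles`` column like ``A/G``). Rows whose position does not parse
    as a positive integer are rejected; their 0-based row indices are
    reported in a warning.

    Duplicate marker ids are *not* an error here — conflict resolution is
    the job of :func:`remove_ambiguous`.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    id_col = _resolve_column(df.columns, "marker_id")
    chrom_col = _resolve_column(df.columns, "chromosome")
    pos_col = _resolve_column(df.columns, "position")
    missing = [name for name, col in
               [("marker_id", id_col), ("chromosome", chrom_col), ("position", pos_col)]
               if col is None]
    if missing:
        raise MarkerTableError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )

    cols = {c.lower(): c for c in df.columns}
    markers: list[MarkerDef] = []
    rejected: list[int] = []
    for i, row in df.iterrows():
        try:
            position = int(str(row[pos_col]))
            if position < 1:
                raise ValueError
        except (ValueError, TypeError):
            rejected.append(int(i))
            continue
        if "ref_allele" in cols and "alt_allele" in cols:
            ref, alt = row[cols["ref_allele"]], row[cols["alt_allele"]]
        elif "alleles" in cols:
            tokens = re.split(r"[/,]", str(row[cols["alleles"]]))
            ref = tokens[0] if tokens else "A"
            alt = tokens[1] if len(tokens) > 1 else "G"
        else:
            ref, alt = "A", "G"
        stats = None
        stat_fields = {}
        for name in ("pic", "maf", "het_proportion", "missing_proportion"):
            if name in cols and str(row[cols[name]]) not in ("", "NA"):
                try:
                    stat_fields[name] = float(row[cols[name]])
                except ValueError:
                    pass
        if stat_fields:
            stats = MarkerStats(**stat_fields)
        markers.append(
            MarkerDef(
                marker_id=str(row[id_col]),
                chromosome=str(row[chrom_col]),
                position=position,
                ref_allele=str(ref),
                alt_allele=str(alt),
                flank=str(row[cols["flank"]]) if "flank" in cols else "",
                variant_class=infer_variant_class(str(ref), str(alt)),
                category=str(row[cols["category"]]) if "category" in cols
                and str(row[cols["category"]]) in VALID_CATEGORIES else "unset",
                trait_tag=(str(row[cols["trait_tag"]]) or None)
                if "trait_tag" in cols else None,
                stats=stats,
            )
        )
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} row(s) with unparseable "
            f"positions at indices {rejected}",
            stacklevel=2,
        )
    return markers


def write_marker_table(markers: Iterable[MarkerDef], path: str | Path) -> None:
    """Write markers back out as CSV (inverse of :func:`read_marker_table`)."""
    rows = []
    for m in markers:
        row = {
            "marker_id": m.marker_id, "chromosome": m.chromosome,
            "position": m.position, "ref_allele": m.ref_allele,
            "alt_allele": m.alt_allele, "flank": m.flank,
            "category": m.category, "trait_tag": m.trait_tag or "",
        }
        if m.stats is not None:
            for name in ("pic", "maf", "het_proportion", "missing_proportion"):
                value = getattr(m.stats, name)
                row[name] = "" if value is None else value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def remove_ambiguous(
    markers: Sequence[MarkerDef],
) -> tuple[list[MarkerDef], set[str]]:
    """Drop markers with ambiguous identity.

    A marker record is ambiguous when two or more ids occupy the same
    (chromosome, position), or when one id is listed at two or more
    positions. Whole conflict groups are removed — no member is kept —
    which makes the operation conservative, deterministic and idempotent.

    Returns the surviving markers (input order preserved) and the set of
    removed marker ids.
    """
    by_locus: dict[tuple[str, int], set[str]] = {}
    by_id: dict[str, set[tuple[str, int]]] = {}
    for m in markers:
        by_locus.setdefault((m.chromosome, m.position), set()).add(m.marker_id)
        by_id.setdefault(m.marker_id, set()).add((m.chromosome, m.position))

    bad_ids: set[str] = set()
    for ids in by_locus.values():
        if len(ids) > 1:
            bad_ids |= ids
    for marker_id, loci in by_id.items():
        if len(loci) > 1:
            bad_ids.add(marker_id)

    clean = [m for m in markers if m.marker_id not in bad_ids]
    return clean, bad_ids


@dataclass
class GenotypeMatrix:
    """Samples x markers alt-allele dosage calls.

    ``calls`` holds integer dosages bounded by the per-marker
    ``ploidy_scale`` (2 for diploid-pattern markers, 4 for
    tetraploid-pattern), with :data:`MISSING` for no-calls.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    ploidy_scale: np.ndarray
    set_labels: Optional[list[str]] = None
    chromosomes: Optional[list[str]] = None
    positions: Optional[np.ndarray] = None
    alleles: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.ploidy_scale = np.asarray(self.ploidy_scale, dtype=np.int16)
        n_samples, n_markers = self.calls.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match calls rows")
        if len(self.marker_ids) != n_markers:
            raise ValueError("marker_ids length does not match calls columns")
        if self.ploidy_scale.shape != (n_markers,):
            raise ValueError("ploidy_scale must be per-marker")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        valid = (self.calls == MISSING) | (
            (self.calls >= 0) & (self.calls <= self.ploidy_scale[None, :])
        )
        if not valid.all():
            raise ValueError("calls out of [0, ploidy_scale] range")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(
        self,
        sample_idx: Optional[np.ndarray] = None,
        marker_idx: Optional[np.ndarray] = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given index arrays."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in s],
            marker_ids=[self.marker_ids[j] for j in m],
            calls=self.calls[np.ix_(s, m)],
            ploidy_scale=self.ploidy_scale[m],
            set_labels=None if self.set_labels is None
            else [self.set_labels[i] for i in s],
            chromosomes=None if self.chromosomes is None
            else [self.chromosomes[j] for j in m],
            positions=None if self.positions is None else self.positions[m],
            alleles=None if self.alleles is None
            else [self.alleles[j] for j in m],
        )

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_ids.index(sample_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.ploidy_scale, other.ploidy_scale)
        )


@dataclass
class HapmapReadResult:
    matrix: GenotypeMatrix
    n_unknown_symbols: int


def write_hapmap(matrix: GenotypeMatrix, path: str | Path) -> list[str]:
    """Write a genotype matrix as a hapmap-dialect text file.

    Calls are written as numeric dosage strings ("0".."4", "NA" for
    missing); a ``<path>.ploidy.tsv`` sidecar records per-marker dosage
    scales whenever any marker is tetraploid-pattern. Markers whose
    allele field lists three or more alleles (multi-SNP positions) are
    excluded from the output; their ids are returned.
    """
    path = Path(path)
    excluded: list[str] = []
    keep: list[int] = []
    for j, mid in enumerate(matrix.marker_ids):
        allele_str = matrix.alleles[j] if matrix.alleles is not None else "A/G"
        if len([a for a in re.split(r"[/,]", allele_str) if a]) > 2:
            excluded.append(mid)
        else:
            keep.append(j)

    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive; calls: alt-allele dosage\n")
        fh.write("\t".join(_HAPMAP_META_COLS + list(matrix.sample_ids)) + "\n")
        for j in keep:
            alleles = matrix.alleles[j] if matrix.alleles is not None else "A/G"
            chrom = matrix.chromosomes[j] if matrix.chromosomes is not None else "NA"
            pos = int(matrix.positions[j]) if matrix.positions is not None else j + 1
            meta = [matrix.marker_ids[j], alleles, chrom, str(pos), "+",
                    "NA", "NA", "NA", "NA", "NA", "NA"]
            calls = [
                "NA" if c == MISSING else str(int(c)) for c in matrix.calls[:, j]
            ]
            fh.write("\t".join(meta + calls) + "\n")

    if np.any(matrix.ploidy_scale[keep] != 2):
        sidecar = path.with_name(path.name + ".ploidy.tsv")
        with open(sidecar, "w") as fh:
            fh.write("marker_id\tploidy_scale\n")
            for j in keep:
                fh.write(f"{matrix.marker_ids[j]}\t{int(matrix.ploidy_scale[j])}\n")
    return excluded


def read_hapmap(path: str | Path) -> HapmapReadResult:
    """Read a hapmap-dialect file written by :func:`write_hapmap`.

    Unknown call symbols become missing and are counted rather than
    raising. Ploidy scales are taken from the sidecar when present,
    defaulting to diploid.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    header = lines[0].split("\t")
    sample_ids = header[len(_HAPMAP_META_COLS):]

    marker_ids, chroms, positions, alleles = [], [], [], []
    rows = []
    n_unknown = 0
    for ln in lines[1:]:
        fields = ln.split("\t")
        marker_ids.append(fields[0])
        alleles.append(fields[1])
        chroms.append(fields[2])
        positions.append(int(fields[3]))
        row = []
        for token in fields[len(_HAPMAP_META_COLS):]:
            if token == "NA":
                row.append(MISSING)
            else:
                try:
                    row.append(int(token))
                except ValueError:
                    n_unknown += 1
                    row.append(MISSING)
        rows.append(row)

    ploidy = np.full(len(marker_ids), 2, dtype=np.int16)
    sidecar = path.with_name(path.name + ".ploidy.tsv")
    if sidecar.exists():
        table = pd.read_csv(sidecar, sep="\t").set_index("marker_id")
        for j, mid in enumerate(marker_ids):
            if mid in table.index:
                ploidy[j] = int(table.loc[mid, "ploidy_scale"])

    calls = np.array(rows, dtype=np.int16).T if rows else np.zeros(
        (len(sample_ids), 0), dtype=np.int16
    )
    matrix = GenotypeMatrix(
        sample_ids=list(sample_ids),
        marker_ids=marker_ids,
        calls=calls,
        ploidy_scale=ploidy,
        chromosomes=chroms,
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
    )
    return HapmapReadResult(matrix=matrix, n_unknown_symbols=n_unknown)


@dataclass
class SampleNameMap:
    """Invertible original -> standardized sample-name conversion table.

    Stored positionally so duplicated original names (which receive
    distinct standardized names) are preserved.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def standardized(self) -> list[str]:
        return [s for _, s in self.pairs]

    def originals(self) -> list[str]:
        return [o for o, _ in self.pairs]

    def invert(self) -> dict[str, str]:
        return {s: o for o, s in self.pairs}

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"original_name": self.originals(),
             "standardized_name": self.standardized()}
        ).to_csv(path, index=False)


def standardize_sample_names(names: Sequence[str]) -> SampleNameMap:
    """Standardize raw accession names for downstream tools.

    Characters outside ``[A-Za-z0-9_.-]`` are replaced with underscores;
    name collisions (including those the replacement creates) are
    resolved by appending ``_2``, ``_3``, ... in input order, so the
    resulting map is injective over its input positions.
    """
    pairs: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for name in names:
        clean = re.sub(r"[^A-Za-z0-9_.\-]", "_", name) or "sample"
        if clean in seen:
            seen[clean] += 1
            candidate = f"{clean}_{seen[clean]}"
            while candidate in seen:
                seen[clean] += 1
                candidate = f"{clean}_{seen[clean]}"
            seen[candidate] = 1
            pairs.append((name, candidate))
        else:
            seen[clean] = 1
            pairs.append((name, clean))
    return SampleNameMap(pairs=pairs)


def apply_name_map(matrix: GenotypeMatrix, name_map: SampleNameMap) -> GenotypeMatrix:
    """Return a copy of *matrix* with standardized sample names.

    Applied positionally when the map covers exactly the matrix's
    samples in order, otherwise by first-match lookup.
    """
    if name_map.originals() == matrix.sample_ids:
        new_ids = name_map.standardized()
    else:
        lookup = {o: s for o, s in reversed(name_map.pairs)}
        new_ids = [lookup.get(s, s) for s in matrix.sample_ids]
    return replace(matrix, sample_ids=new_ids)
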