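"""Foreground/background selection support for marker-assisted backcrossing.

Given genotypes of a donor parent, a recurrent parent and derived
backcross lines, this module screens the panel for parent-polymorphic
markers (both parents called, homozygous, and for different alleles —
the informative markers), checks foreground trait markers, and
computes recurrent-parent genome recovery (RPG%):

    RPG% = 100 * (n_recurrent_hom + 0.5 * n_het) / n_informative_called

per chromosome and overall, the standard MABC accounting in which a
heterozygous call contributes half a recovered genome equivalent.
Missing line calls drop out of both numerator and denominator; a
chromosome with no informative called marker is reported as missing
rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .marker_catalog import MISSING, GenotypeMatrix


@dataclass
class PolymorphismScreen:
    """Outcome of the parent polymorphism screen."""

    polymorphic_ids: list[str]
    excluded: dict[str, str]  # marker_id -> reason

    @property
    def n_polymorphic(self) -> int:
        return len(self.polymorphic_ids)


def polymorphic_markers(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    marker_ids: Sequence[str],
    ploidy_scale: np.ndarray,
) -> PolymorphismScreen:
    """Markers informative for ancestry between two parents.

    A marker qualifies iff both parents are called, both are homozygous
    (dosage 0 or full ploidy), and their alleles differ. Heterozygous or
    missing parents make ancestry ambiguous and are excluded with the
    reason recorded (``het_parent`` / ``missing_parent`` /
    ``monomorphic``).
    """
    a = np.asarray(parent_a)
    b = np.asarray(parent_b)
    if not (len(a) == len(b) == len(marker_ids)):
        raise ValueError("parents and marker_ids must cover the same markers")
    ploidy = np.asarray(ploidy_scale)
    poly: list[str] = []
    excluded: dict[str, str] = {}
    for j, mid in enumerate(marker_ids):
        if a[j] == MISSING or b[j] == MISSING:
            excluded[mid] = "missing_parent"
        elif a[j] not in (0, ploidy[j]) or b[j] not in (0, ploidy[j]):
            excluded[mid] = "het_parent"
        elif a[j] == b[j]:
            excluded[mid] = "monomorphic"
        else:
            poly.append(mid)
    return PolymorphismScreen(polymorphic_ids=poly, excluded=excluded)


@dataclass
class RecoveryReport:
    """Recurrent-parent genome recovery of one backcross line."""

    line_id: str
    overall_rpg_percent: Optional[float]
    per_chromosome_rpg: dict[str, Optional[float]]
    n_informative: int
    n_informative_called: int
    foreground_status: dict[str, str] = field(default_factory=dict)

    def to_long_frame(self) -> pd.DataFrame:
        """Per-chromosome long table (circos-style export)."""
        return pd.DataFrame(
            {
                "line_id": self.line_id,
                "chromosome": list(self.per_chromosome_rpg),
                "rpg_percent": list(self.per_chromosome_rpg.values()),
            }
        )


def background_recovery(
    line: np.ndarray,
    recurrent: np.ndarray,
    donor: np.ndarray,
    marker_ids: Sequence[str],
    chromosomes: Sequence[str],
    ploidy_scale: np.ndarray,
    informative_ids: Sequence[str],
    line_id: str = "line",
    trait_marker_ids: Sequence[str] = (),
) -> RecoveryReport:
    """Score one line's background genome recovery over informative markers.

    Each informative called marker is classified against the parents:
    equal to the recurrent homozygote -> recurrent (weight 1),
    equal to the donor homozygote -> donor (weight 0), intermediate ->
    het (weight 0.5). Foreground trait markers are reported by the same
    classification (donor / recurrent / het / missing).
    """
    if not len(informative_ids):
        raise ValueError("informative_ids must be non-empty")
    index = {mid: j for j, mid in enumerate(marker_ids)}
    per_chrom_counts: dict[str, list[float]] = {}
    for mid in informative_ids:
        j = index[mid]
        call = line[j]
        if call == MISSING:
            continue
        if call == recurrent[j]:
            weight = 1.0
        elif call == donor[j]:
            weight = 0.0
        else:
            weight = 0.5
        per_chrom_counts.setdefault(chromosomes[j], []).append(weight)

    per_chrom: dict[str, Optional[float]] = {}
    total_weight = 0.0
    total_n = 0
    for chrom in dict.fromkeys(chromosomes[index[mid]] for mid in informative_ids):
        weights = per_chrom_counts.get(chrom)
        if not weights:
            per_chrom[chrom] = None
            continue
        per_chrom[chrom] = 100.0 * sum(weights) / len(weights)
        total_weight += sum(weights)
        total_n += len(weights)
    overall = 100.0 * total_weight / total_n if total_n else None

    foreground: dict[str, str] = {}
    for mid in trait_marker_ids:
        j = index.get(mid)
        if j is None or line[j] == MISSING:
            foreground[mid] = "missing"
        elif line[j] == recurrent[j]:
            foreground[mid] = "recurrent"
        elif line[j] == donor[j]:
            foreground[mid] = "donor"
        else:
            foreground[mid] = "het"
    return RecoveryReport(
        line_id=line_id,
        overall_rpg_percent=overall,
        per_chromosome_rpg=per_chrom,
        n_informative=len(informative_ids),
        n_informative_called=total_n,
        foreground_status=foreground,
    )


def recovery_from_matrix(
    matrix: GenotypeMatrix,
    recurrent_id: str,
    donor_id: str,
    line_ids: Optional[Sequence[str]] = None,
    trait_marker_ids: Sequence[str] = (),
) -> tuple[list[RecoveryReport], PolymorphismScreen]:
    """Convenience wrapper: screen parents, then score every line."""
    recurrent = matrix.sample_row(recurrent_id)
    donor = matrix.sample_row(donor_id)
    screen = polymorphic_markers(
        donor, recurrent, matrix.marker_ids, matrix.ploidy_scale
    )
    if line_ids is None:
        line_ids = [
            s for s in matrix.sample_ids if s not in (recurrent_id, donor_id)
        ]
    chroms = matrix.chromosomes or ["chr1"] * matrix.n_markers
    reports = [
        background_recovery(
            matrix.sample_row(line_id), recurrent, donor,
            matrix.marker_ids, chroms, matrix.ploidy_scale,
            screen.polymorphic_ids, line_id=line_id,
            trait_marker_ids=trait_marker_ids,
        )
        for line_id in line_ids
    ]
    return reports, screen


@dataclass
class PanelComparison:
    """High-density vs mid-density recovery comparison."""

    per_line: pd.DataFrame
    marker_density_ratio: float


def compare_panels(
    recovery_hd: Sequence[RecoveryReport],
    recovery_md: Sequence[RecoveryReport],
) -> PanelComparison:
    """Per-line RPG deltas between two panels genotyping the same lines.

    ``delta`` columns are high-density minus mid-density; the marker
    density ratio is informative markers HD / MD.
    """
    hd = {r.line_id: r for r in recovery_hd}
    md = {r.line_id: r for r in recovery_md}
    if set(hd) != set(md):
        raise ValueError(
            f"line sets differ: {sorted(set(hd) ^ set(md))}"
        )
    rows = []
    for line_id in hd:
        a, b = hd[line_id], md[line_id]
        row = {
            "line_id": line_id,
            "rpg_hd": a.overall_rpg_percent,
            "rpg_md": b.overall_rpg_percent,
            "delta_overall": None
            if a.overall_rpg_percent is None or b.overall_rpg_percent is None
            else a.overall_rpg_percent - b.overall_rpg_percent,
        }
        for chrom in a.per_chromosome_rpg:
            va = a.per_chromosome_rpg.get(chrom)
            vb = b.per_chromosome_rpg.get(chrom)
            row[f"delta_{chrom}"] = None if va is None or vb is None else va - vb
        rows.append(row)
    n_hd = recovery_hd[0].n_informative if recovery_hd else 0
    n_md = recovery_md[0].n_informative if recovery_md else 0
    ratio = n_hd / n_md if n_md else float("nan")
    return PanelComparison(
        per_line=pd.DataFrame(rows).sort_values("line_id").reset_index(drop=True),
        marker_density_ratio=ratio,
    )
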