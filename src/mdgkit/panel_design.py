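"""Informative-SNP panel selection.

Implements the statistics and filters used to distill a mid-density
panel out of a high-density candidate pool: polymorphism information
content (PIC, Botstein form), minor allele frequency, heterozygosity
and missingness per marker; candidate quality filters; a flanking-SNP
spacing rule; and PIC-ranked selection with optional per-chromosome
balancing and unconditional inclusion of trait-associated markers.

For a biallelic marker the Botstein PIC

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2

is maximized at p = 0.5 with value 0.375, strictly below the 0.5 bound
that applies to gene diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .marker_catalog import MISSING, MarkerDef, MarkerStats


@dataclass
class SelectionConfig:
    """Thresholds and sizes for candidate filtering and panel selection.

    Defaults are the published assay's criteria: PIC >= 0.374, missing
    proportion < 0.2, heterozygous proportion <= 0.05 (markers with more
    than 5% heterozygous calls are removed), no neighbouring SNP within
    200 bp, 5,000 prioritized markers with 3,027 kept in reserve.
    """

    pic_min: float = 0.374
    missing_max: float = 0.2
    het_max: float = 0.05
    flank_window_bp: int = 200
    target_size: int = 5000
    reserve_size: int = 3027
    per_chromosome_balancing: bool = False

    def __post_init__(self) -> None:
        for name in ("pic_min", "missing_max", "het_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")


def compute_pic(allele_freqs: Sequence[float]) -> float:
    """Polymorphism information content of a locus from allele frequencies.

    Frequencies must be non-negative and sum to 1 (tolerance 1e-9).
    For two alleles the value is bounded by 0.375.
    """
    p = np.asarray(allele_freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("allele frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1, got {p.sum()!r}")
    sq = p ** 2
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * sq[i] * sq[j]
    return float(1.0 - sq.sum() - cross)


def compute_marker_stats(column: np.ndarray, ploidy_scale: int) -> MarkerStats:
    """Summary statistics for one marker from its dosage-call column.

    MAF counts alt alleles weighted by dosage over called samples and
    folds to <= 0.5; heterozygosity is the fraction of called samples
    with an intermediate dosage; PIC is computed from the two allele
    frequencies. An all-missing column yields ``n_called=0`` with
    undefined (None) statistics.
    """
    calls = np.asarray(column)
    if calls.size == 0:
        raise ValueError("marker column must be non-empty")
    called = calls[calls != MISSING]
    n_called = int(called.size)
    missing_proportion = 1.0 - n_called / calls.size
    if n_called == 0:
        return MarkerStats(missing_proportion=missing_proportion, n_called=0)
    alt_freq = float(called.sum()) / (n_called * ploidy_scale)
    maf = min(alt_freq, 1.0 - alt_freq)
    het = float(((called > 0) & (called < ploidy_scale)).mean())
    pic = compute_pic((1.0 - alt_freq, alt_freq))
    return MarkerStats(
        pic=pic, maf=maf, het_proportion=het,
        missing_proportion=missing_proportion, n_called=n_called,
    )


def annotate_stats(markers: Sequence[MarkerDef], matrix) -> list[MarkerDef]:
    """Attach matrix-derived stats to every marker present in *matrix*."""
    index = {mid: j for j, mid in enumerate(matrix.marker_ids)}
    out = []
    for m in markers:
        j = index.get(m.marker_id)
        if j is not None:
            m.stats = compute_marker_stats(
                matrix.calls[:, j], int(matrix.ploidy_scale[j])
            )
        out.append(m)
    return out


@dataclass
class FilterLedger:
    """Per-rule rejection counts with first-failing-rule attribution."""

    n_input: int = 0
    n_passed: int = 0
    rejected_missing: int = 0
    rejected_het: int = 0
    rejected_pic: int = 0
    rejected_ids: dict[str, str] = field(default_factory=dict)


def filter_candidates(
    markers: Sequence[MarkerDef], config: SelectionConfig
) -> tuple[list[str], FilterLedger]:
    """Apply the candidate quality filters.

    A marker passes iff missing_proportion < ``missing_max`` AND
    het_proportion <= ``het_max`` AND pic >= ``pic_min``. Rejections are
    attributed to the first failing rule in the fixed order (missing,
    het, pic); markers without statistics fail the missing rule.
    """
    ledger = FilterLedger(n_input=len(markers))
    passing: list[str] = []
    for m in markers:
        s = m.stats
        if s is None or s.missing_proportion is None or s.missing_proportion >= config.missing_max:
            ledger.rejected_missing += 1
            ledger.rejected_ids[m.marker_id] = "missing"
        elif s.het_proportion is None or s.het_proportion > config.het_max:
            ledger.rejected_het += 1
            ledger.rejected_ids[m.marker_id] = "het"
        elif s.pic is None or s.pic < config.pic_min:
            ledger.rejected_pic += 1
            ledger.rejected_ids[m.marker_id] = "pic"
        else:
            passing.append(m.marker_id)
    ledger.n_passed = len(passing)
    return passing, ledger


def flank_spacing_filter(
    markers: Sequence[MarkerDef], window_bp: int = 200
) -> tuple[list[str], list[str]]:
    """Split markers into isolated and crowded sets.

    A marker is crowded when another marker lies on the same chromosome
    within +/- ``window_bp`` (inclusive) of its position; the relation is
    symmetric, so both members of a close pair are crowded.
    """
    isolated: list[str] = []
    crowded: list[str] = []
    by_chrom: dict[str, list[MarkerDef]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom_markers in by_chrom.values():
        chrom_markers.sort(key=lambda m: (m.position, m.marker_id))
        positions = [m.position for m in chrom_markers]
        for i, m in enumerate(chrom_markers):
            near = (
                (i > 0 and m.position - positions[i - 1] <= window_bp)
                or (i + 1 < len(positions) and positions[i + 1] - m.position <= window_bp)
            )
            (crowded if near else isolated).append(m.marker_id)
    return isolated, crowded


@dataclass
class PanelSelection:
    """Outcome of panel selection."""

    selected_ids: list[str]
    reserve_ids: list[str]
    trait_ids: list[str]
    per_chromosome: dict[str, int]

    def to_frame(self, markers: Sequence[MarkerDef]):
        import pandas as pd

        status = {}
        for mid in self.selected_ids:
            status[mid] = "trait" if mid in set(self.trait_ids) else "selected"
        for mid in self.reserve_ids:
            status[mid] = "reserve"
        rows = [
            {
                "marker_id": m.marker_id,
                "chromosome": m.chromosome,
                "position": m.position,
                "pic": None if m.stats is None else m.stats.pic,
                "status": status[m.marker_id],
            }
            for m in markers
            if m.marker_id in status
        ]
        return pd.DataFrame(rows)


def _rank_key(m: MarkerDef):
    pic = m.stats.pic if m.stats is not None and m.stats.pic is not None else -1.0
    return (-pic, m.chromosome, m.position, m.marker_id)


def _largest_remainder(avail: dict[str, int], slots: int) -> dict[str, int]:
    """Apportion *slots* across chromosomes proportionally to availability
    (largest-remainder method), capped by availability."""
    total = sum(avail.values())
    if total == 0 or slots <= 0:
        return {c: 0 for c in avail}
    quota = {c: slots * n / total for c, n in avail.items()}
    alloc = {c: min(int(q), avail[c]) for c, q in quota.items()}
    remaining = slots - sum(alloc.values())
    order = sorted(avail, key=lambda c: (-(quota[c] - int(quota[c])), c))
    while remaining > 0:
        progressed = False
        for c in order:
            if remaining == 0:
                break
            if alloc[c] < avail[c]:
                alloc[c] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            break
    return alloc


def select_panel(
    markers: Sequence[MarkerDef],
    config: SelectionConfig,
    trait_markers: Iterable[MarkerDef] = (),
) -> PanelSelection:
    """Select the panel by descending PIC with trait markers always in.

    Candidates are assumed to have passed :func:`filter_candidates`.
    Trait markers bypass the statistical filters and occupy slots first.
    With ``per_chromosome_balancing`` the remaining slots are apportioned
    across chromosomes proportionally to candidate availability
    (largest-remainder) and filled by PIC rank within each chromosome;
    otherwise filled by global PIC rank. The next-best unselected
    candidates, ranked globally, form the reserve. Ties break on
    (chromosome, position, marker id), making selection invariant to
    input row order.
    """
    trait_list = sorted(trait_markers, key=_rank_key)
    trait_ids = [m.marker_id for m in trait_list]
    trait_set = set(trait_ids)
    candidates = sorted(
        (m for m in markers if m.marker_id not in trait_set), key=_rank_key
    )

    slots = max(config.target_size - len(trait_ids), 0)
    if len(candidates) <= slots:
        chosen = list(candidates)
    elif config.per_chromosome_balancing:
        by_chrom: dict[str, list[MarkerDef]] = {}
        for m in candidates:
            by_chrom.setdefault(m.chromosome, []).append(m)
        alloc = _largest_remainder(
            {c: len(ms) for c, ms in by_chrom.items()}, slots
        )
        chosen = []
        for chrom in sorted(by_chrom):
            chosen.extend(by_chrom[chrom][: alloc[chrom]])
        chosen.sort(key=_rank_key)
    else:
        chosen = candidates[:slots]

    chosen_ids = {m.marker_id for m in chosen}
    leftovers = [m for m in candidates if m.marker_id not in chosen_ids]
    reserve = leftovers[: config.reserve_size]

    selected = trait_list + chosen
    per_chromosome: dict[str, int] = {}
    for m in selected:
        per_chromosome[m.chromosome] = per_chromosome.get(m.chromosome, 0) + 1
    return PanelSelection(
        selected_ids=[m.marker_id for m in selected],
        reserve_ids=[m.marker_id for m in reserve],
        trait_ids=trait_ids,
        per_chromosome=per_chromosome,
    )
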