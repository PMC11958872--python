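"""Synthetic data generation for panel design, calling and breeding tests.

Three generators:

* :func:`simulate_population` — multi-set genotype panels under a
  Balding-Nichols two-level model: per-set allele frequencies are drawn
  around ancestral frequencies with variance governed by a set-level
  differentiation parameter (F_ST), and genotypes carry excess
  homozygosity controlled by an inbreeding coefficient. This emulates
  breeding panels that mix a diverse reference set (high F_ST, low
  inbreeding) with near-fixed advanced breeding lines (high
  inbreeding).
* :func:`simulate_reads` — amplicon read counts: negative-binomial
  depth around a target mean (default 100x) and binomial allele reads
  at the cluster mean of each sample's true state, with sequencing
  error folded in.
* :func:`simulate_backcross` — marker-assisted backcross pedigrees:
  gametes form with Poisson-count crossovers placed uniformly per
  chromosome; after n backcrosses to the recurrent parent the expected
  donor-genome fraction is 0.5^(n+1), and each selfing generation
  halves heterozygosity in expectation.

All generators are fully reproducible from their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dosage_caller import ClusterModel
from .marker_catalog import MISSING, GenotypeMatrix, MarkerDef
from .published import ASSAY_CHROMOSOME_COUNTS


@dataclass
class SetSpec:
    """One sample set of a structured panel."""

    label: str
    n_samples: int
    divergence_fst: float = 0.05
    inbreeding_f: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_fst <= 1.0:
            raise ValueError("divergence_fst must be in [0, 1]")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must be in [0, 1]")


@dataclass
class PopulationSpec:
    """Configuration for :func:`simulate_population`."""

    n_markers: int
    set_specs: list[SetSpec]
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    ploidy_scale: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")


@dataclass
class ReadSimSpec:
    """Configuration for :func:`simulate_reads`."""

    mean_depth: float = 100.0
    depth_dispersion: Optional[float] = 10.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


def default_marker_map(n_markers: int, prefix: str = "M") -> list[MarkerDef]:
    """A deterministic marker map over the 20-chromosome layout.

    Markers are apportioned across chromosomes proportionally to the
    released 5K assay's per-chromosome counts and placed on an evenly
    spaced 1-based grid (far enough apart to satisfy the 200 bp spacing
    rule by construction).
    """
    counts = ASSAY_CHROMOSOME_COUNTS
    total = sum(counts.values())
    quota = {c: n_markers * n / total for c, n in counts.items()}
    alloc = {c: int(q) for c, q in quota.items()}
    order = sorted(counts, key=lambda c: (-(quota[c] - int(quota[c])), c))
    i = 0
    while sum(alloc.values()) < n_markers:
        alloc[order[i % len(order)]] += 1
        i += 1
    markers: list[MarkerDef] = []
    k = 1
    for chrom in sorted(counts):
        for j in range(alloc[chrom]):
            markers.append(
                MarkerDef(
                    marker_id=f"{prefix}{k:05d}",
                    chromosome=chrom,
                    position=1 + j * 10_000,
                )
            )
            k += 1
    return markers


def simulate_population(
    spec: PopulationSpec, panel: Optional[Sequence[MarkerDef]] = None
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Draw a structured multi-set genotype panel.

    Ancestral alt-allele frequencies are drawn with the minor-allele
    frequency uniform on ``maf_range`` (the alt allele is the minor one
    with probability 1/2). Each set's frequencies follow
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p when its
    ``divergence_fst`` F is positive. Genotype dosages are binomial in
    ``ploidy_scale``, except that with probability ``inbreeding_f`` an
    individual is fully homozygous at the locus (one Bernoulli draw
    scaled to full dosage), producing the classic inbreeding excess of
    homozygotes; at F=1 no heterozygotes occur.

    Returns the genotype matrix (with per-sample set labels) and the
    realized per-set allele frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    markers = list(panel) if panel is not None else default_marker_map(spec.n_markers)
    if len(markers) != spec.n_markers:
        spec = PopulationSpec(
            n_markers=len(markers), set_specs=spec.set_specs,
            maf_range=spec.maf_range, missing_rate=spec.missing_rate,
            ploidy_scale=spec.ploidy_scale, seed=spec.seed,
        )
    m = spec.n_markers
    maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    flip = rng.random(m) < 0.5
    ancestral = np.where(flip, 1.0 - maf, maf)

    sample_ids: list[str] = []
    set_labels: list[str] = []
    rows: list[np.ndarray] = []
    set_freqs: dict[str, np.ndarray] = {}
    for set_spec in spec.set_specs:
        fst = set_spec.divergence_fst
        if fst > 0:
            a = ancestral * (1 - fst) / fst
            b = (1 - ancestral) * (1 - fst) / fst
            p = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
        else:
            p = ancestral.copy()
        set_freqs[set_spec.label] = p
        for i in range(set_spec.n_samples):
            outbred = rng.binomial(spec.ploidy_scale, p)
            homozygous = rng.binomial(1, p) * spec.ploidy_scale
            is_inbred = rng.random(m) < set_spec.inbreeding_f
            dosage = np.where(is_inbred, homozygous, outbred).astype(np.int16)
            rows.append(dosage)
            sample_ids.append(f"{set_spec.label}_{i + 1:04d}")
            set_labels.append(set_spec.label)

    calls = np.vstack(rows) if rows else np.zeros((0, m), dtype=np.int16)
    if spec.missing_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=[mk.marker_id for mk in markers],
        calls=calls,
        ploidy_scale=np.full(m, spec.ploidy_scale, dtype=np.int16),
        set_labels=set_labels,
        chromosomes=[mk.chromosome for mk in markers],
        positions=np.array([mk.position for mk in markers], dtype=np.int64),
        alleles=[f"{mk.ref_allele}/{mk.alt_allele}" for mk in markers],
    )
    return matrix, set_freqs


def _draw_depths(rng: np.random.Generator, n: int, spec: ReadSimSpec) -> np.ndarray:
    """Negative-binomial (gamma-Poisson) depths; Poisson when dispersion
    is None/inf."""
    k = spec.depth_dispersion
    if k is None or not np.isfinite(k):
        return rng.poisson(spec.mean_depth, size=n)
    p = k / (k + spec.mean_depth)
    return rng.negative_binomial(k, p, size=n)


def simulate_reads(
    matrix: GenotypeMatrix,
    models: Mapping[str, ClusterModel],
    spec: ReadSimSpec,
) -> pd.DataFrame:
    """Simulate amplicon read counts for every called cell of *matrix*.

    Each cell's true state is the model state matching its dosage; alt
    reads are binomial at the state's error-adjusted cluster mean.
    Returns a record table (sample_id, marker_id, ref_reads, alt_reads).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for j, mid in enumerate(matrix.marker_ids):
        model = models[mid]
        model = ClusterModel(
            model.category, model.states, spec.error_rate, model.prior
        )
        fractions = model.adjusted_fractions()
        dosage_to_state = {
            model.dosage_of(label): k for k, (label, _) in enumerate(model.states)
        }
        col = matrix.calls[:, j]
        depths = _draw_depths(rng, len(col), spec)
        for i, dosage in enumerate(col):
            if dosage == MISSING:
                continue
            try:
                k = dosage_to_state[int(dosage)]
            except KeyError:
                raise ValueError(
                    f"marker {mid}: dosage {dosage} has no state in its model"
                ) from None
            depth = int(depths[i])
            alt = int(rng.binomial(depth, fractions[k])) if depth else 0
            rows.append(
                {
                    "sample_id": matrix.sample_ids[i],
                    "marker_id": mid,
                    "ref_reads": depth - alt,
                    "alt_reads": alt,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "marker_id", "ref_reads", "alt_reads"])


def simulate_state_reads(
    model: ClusterModel,
    state_label: str,
    n: int,
    depth: float = 100.0,
    error_rate: float = 0.0,
    seed: int = 0,
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """Replicate read counts from a single known genotype state.

    Used for cluster-mean checks: with error rate 0 the mean
    alt/(ref+alt) fraction converges to the state's expected cluster
    mean. Depth is Poisson around *depth* unless a negative-binomial
    dispersion is given.
    """
    rng = np.random.default_rng(seed)
    model = ClusterModel(model.category, model.states, error_rate, model.prior)
    idx = [label for label, _ in model.states].index(state_label)
    f = model.adjusted_fractions()[idx]
    spec = ReadSimSpec(mean_depth=depth, depth_dispersion=dispersion,
                       error_rate=error_rate, seed=seed)
    depths = _draw_depths(rng, n, spec)
    depths = np.maximum(depths, 1)  # zero-depth replicates carry no signal
    alts = rng.binomial(depths, f)
    return pd.DataFrame(
        {
            "sample_id": [f"rep{i + 1}" for i in range(n)],
            "marker_id": state_label,
            "ref_reads": depths - alts,
            "alt_reads": alts,
        }
    )


@dataclass
class BackcrossSpec:
    """Configuration for :func:`simulate_backcross`.

    ``n_backcrosses=3`` with ``n_selfs=3`` corresponds to a BC3F4 line
    (the third backcross product is the F1 of that cross; three selfing
    generations take it to F4). ``recomb_per_chrom`` is the expected
    crossover count per chromosome per meiosis (1.0 approximates a
    100 cM chromosome).
    """

    n_backcrosses: int = 3
    n_selfs: int = 3
    recomb_per_chrom: float = 1.0
    n_lines: int = 50
    seed: int = 0


def _meiosis(
    haplotypes: tuple[np.ndarray, np.ndarray],
    chrom_slices: list[slice],
    rel_pos: list[np.ndarray],
    recomb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: per chromosome, Poisson crossovers uniform in map
    position, random starting phase."""
    h0, h1 = haplotypes
    gamete = np.empty_like(h0)
    for sl, pos in zip(chrom_slices, rel_pos):
        n_x = rng.poisson(recomb)
        breaks = np.sort(rng.uniform(0.0, 1.0, size=n_x))
        phase = rng.integers(0, 2)
        # phase flips at each crossover
        segment_phase = (phase + np.searchsorted(breaks, pos)) % 2
        gamete[sl] = np.where(segment_phase == 0, h0[sl], h1[sl])
    return gamete


def simulate_backcross(
    markers: Sequence[MarkerDef],
    spec: BackcrossSpec,
    donor_name: str = "donor",
    recurrent_name: str = "recurrent",
) -> GenotypeMatrix:
    """Simulate backcross-then-self lines at polymorphic markers.

    Parents are homozygous: the donor carries the alternate allele
    (dosage 2) everywhere, the recurrent parent the reference (0). The
    output matrix holds the parents followed by the simulated lines,
    with dosages counting donor alleles, so a line's donor-genome
    fraction is mean(dosage)/2 and the expectation after n backcrosses
    is 0.5^(n+1).
    """
    rng = np.random.default_rng(spec.seed)
    markers = sorted(markers, key=lambda m: (m.chromosome, m.position, m.marker_id))
    chrom_slices: list[slice] = []
    rel_pos: list[np.ndarray] = []
    start = 0
    m = len(markers)
    for i in range(1, m + 1):
        if i == m or markers[i].chromosome != markers[start].chromosome:
            sl = slice(start, i)
            pos = np.array([mk.position for mk in markers[start:i]], dtype=float)
            span = pos.max() - pos.min()
            rel = (pos - pos.min()) / span if span > 0 else np.zeros_like(pos)
            chrom_slices.append(sl)
            rel_pos.append(rel)
            start = i

    donor_h = np.ones(m, dtype=np.int16)
    recur_h = np.zeros(m, dtype=np.int16)

    rows = [donor_h * 2, recur_h * 2]
    sample_ids = [donor_name, recurrent_name]
    labels = ["parent", "parent"]
    for line in range(spec.n_lines):
        plant = (donor_h.copy(), recur_h.copy())  # F1
        for _ in range(spec.n_backcrosses):
            gamete = _meiosis(plant, chrom_slices, rel_pos,
                              spec.recomb_per_chrom, rng)
            plant = (gamete, recur_h.copy())
        for _ in range(spec.n_selfs):
            g1 = _meiosis(plant, chrom_slices, rel_pos, spec.recomb_per_chrom, rng)
            g2 = _meiosis(plant, chrom_slices, rel_pos, spec.recomb_per_chrom, rng)
            plant = (g1, g2)
        rows.append((plant[0] + plant[1]).astype(np.int16))
        sample_ids.append(f"line_{line + 1:03d}")
        labels.append("line")

    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=[mk.marker_id for mk in markers],
        calls=np.vstack(rows),
        ploidy_scale=np.full(m, 2, dtype=np.int16),
        set_labels=labels,
        chromosomes=[mk.chromosome for mk in markers],
        positions=np.array([mk.position for mk in markers], dtype=np.int64),
        alleles=["A/G"] * m,
    )
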