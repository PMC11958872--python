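"""Bayesian dosage-cluster genotype calling from amplicon read counts.

Targeted amplicon sequencing of a fixed marker panel yields, per sample
and marker, the number of reads supporting the reference and alternate
alleles. Genotype states form clusters in alt-read-fraction space whose
expected centres depend on the marker category:

* Category 1 (single sub-genome amplicon, diploid pattern):
  AA 0.0, AB 0.5, BB 1.0;
* Category 2 (both homoeologous loci amplified, tetraploid pattern),
  with one sub-genome fixed: either the high set AABB 0.5, ABBB 0.75,
  BBBB 1.0 or the mirrored low set AAAA 0.0, AAAB 0.25, AABB 0.5. A
  full five-state model (0, 0.25, 0.5, 0.75, 1) is available for
  markers segregating in both sub-genomes.

The caller evaluates, for each state with expected alt fraction ``f``,
a binomial likelihood Bin(alt | depth, f') with the sequencing error
rate folded into the cluster mean, f' = f(1-e) + (1-f)e, multiplies by
the state prior, and normalizes. Calls below a minimum depth (default
5x) or a minimum posterior (default 0.95) become no-calls with the
reason recorded. Panel QC follows amplicon-sequencing practice: per
sample mean depth, 5x fraction, uniformity (fraction of observations at
>= 0.2x the mean depth), and per-marker call rate with markers below
90% flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

from .marker_catalog import MISSING, GenotypeMatrix

#: dosage of each known state label (count of alternate-allele copies)
STATE_DOSAGE = {
    "AA": 0, "AB": 1, "BB": 2,
    "AAAA": 0, "AAAB": 1, "AABB": 2, "ABBB": 3, "BBBB": 4,
}


@dataclass
class ClusterModel:
    """Category-specific expected alt-read fractions per genotype state."""

    category: str
    states: list[tuple[str, float]]
    error_rate: float = 0.01
    prior: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("model must define at least one state")
        fractions = [f for _, f in self.states]
        if any(b <= a for a, b in zip(fractions, fractions[1:])):
            raise ValueError("expected fractions must be strictly increasing")
        if self.prior is None:
            self.prior = np.full(len(self.states), 1.0 / len(self.states))
        else:
            self.prior = np.asarray(self.prior, dtype=float)
            if abs(self.prior.sum() - 1.0) > 1e-9:
                raise ValueError("prior must sum to 1")

    @property
    def ploidy_scale(self) -> int:
        return 2 if self.category == "cat1" else 4

    def adjusted_fractions(self) -> np.ndarray:
        """Cluster means with the error rate folded in."""
        f = np.array([frac for _, frac in self.states])
        e = self.error_rate
        return f * (1 - e) + (1 - f) * e

    def dosage_of(self, label: str) -> int:
        return STATE_DOSAGE[label]

    def state_for_dosage(self, dosage: int) -> Optional[str]:
        for label, _ in self.states:
            if STATE_DOSAGE[label] == dosage:
                return label
        return None

    def mirrored(self) -> "ClusterModel":
        """Swap ref/alt: fractions f -> 1-f, state order reversed."""
        states = [(label, 1.0 - f) for label, f in reversed(self.states)]
        prior = None if self.prior is None else self.prior[::-1].copy()
        return ClusterModel(self.category, states, self.error_rate, prior)

    # ---- standard model factories -------------------------------------
    @classmethod
    def diploid(cls, error_rate: float = 0.01) -> "ClusterModel":
        return cls("cat1", [("AA", 0.0), ("AB", 0.5), ("BB", 1.0)], error_rate)

    @classmethod
    def tetraploid_high(cls, error_rate: float = 0.01) -> "ClusterModel":
        """Category 2 with the second sub-genome fixed for the alt allele."""
        return cls(
            "cat2", [("AABB", 0.5), ("ABBB", 0.75), ("BBBB", 1.0)], error_rate
        )

    @classmethod
    def tetraploid_low(cls, error_rate: float = 0.01) -> "ClusterModel":
        """Category 2 with the second sub-genome fixed for the reference."""
        return cls(
            "cat2", [("AAAA", 0.0), ("AAAB", 0.25), ("AABB", 0.5)], error_rate
        )

    @classmethod
    def tetraploid_full(cls, error_rate: float = 0.01) -> "ClusterModel":
        """Five-state Category 2 model for markers segregating in both
        sub-genomes."""
        return cls(
            "cat2",
            [("AAAA", 0.0), ("AAAB", 0.25), ("AABB", 0.5),
             ("ABBB", 0.75), ("BBBB", 1.0)],
            error_rate,
        )


@dataclass
class ReadCountRecord:
    """Ref/alt allele read counts for one sample at one amplicon."""

    sample_id: str
    marker_id: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class GenotypeCall:
    state_label: Optional[str]
    dosage: int
    posterior: Optional[float]
    depth: int
    no_call_reason: Optional[str] = None
    posteriors: Optional[np.ndarray] = None

    @property
    def called(self) -> bool:
        return self.no_call_reason is None


def call_genotype(
    record: ReadCountRecord,
    model: ClusterModel,
    min_depth: int = 5,
    min_posterior: float = 0.95,
) -> GenotypeCall:
    """Call one genotype from allele read counts.

    Depth below ``min_depth`` yields no_call(low_depth); otherwise the
    posterior-maximizing state is taken and reported, unless its
    posterior is below ``min_posterior`` (no_call(low_posterior), with
    the full posterior vector still attached).
    """
    depth = record.depth
    if depth < min_depth:
        return GenotypeCall(None, MISSING, None, depth, "low_depth")
    f = model.adjusted_fractions()
    log_post = np.log(model.prior) + binom.logpmf(record.alt_reads, depth, f)
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    best = int(np.argmax(post))
    label = model.states[best][0]
    if post[best] < min_posterior:
        return GenotypeCall(
            None, MISSING, None, depth, "low_posterior", posteriors=post
        )
    return GenotypeCall(
        label, model.dosage_of(label), float(post[best]), depth, posteriors=post
    )


@dataclass
class AmpliconQC:
    """Panel/sample QC metrics from an amplicon run."""

    mean_depth: float
    depth_ge5_fraction: float
    uniformity_0p2x: float
    marker_call_rate: dict[str, float]
    flagged_markers: list[str]
    per_sample_mean_depth: dict[str, float]
    per_sample_uniformity: dict[str, float]
    on_target_fraction: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": list(self.marker_call_rate),
                "call_rate": list(self.marker_call_rate.values()),
                "flagged": [
                    m in set(self.flagged_markers) for m in self.marker_call_rate
                ],
            }
        )


def uniformity(depths: np.ndarray) -> float:
    """Fraction of observations with depth >= 0.2x the mean depth."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        return float("nan")
    return float((depths >= 0.2 * depths.mean()).mean())


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "marker_id": r.marker_id,
                "ref_reads": r.ref_reads,
                "alt_reads": r.alt_reads,
            }
            for r in records
        ]
    )


def call_matrix(
    records: Iterable[ReadCountRecord] | pd.DataFrame,
    models: Mapping[str, ClusterModel],
    min_depth: int = 5,
    min_posterior: float = 0.95,
    call_rate_flag: float = 0.90,
) -> tuple[GenotypeMatrix, AmpliconQC]:
    """Call a full samples x markers matrix and compute run QC.

    Every record's marker must have a model. Markers whose call rate
    falls below ``call_rate_flag`` are flagged, not dropped. Sample and
    marker order follows first appearance in the record stream.
    """
    df = _records_frame(records)
    missing_models = set(df["marker_id"]) - set(models)
    if missing_models:
        raise KeyError(f"no cluster model for markers: {sorted(missing_models)}")

    sample_ids = list(dict.fromkeys(df["sample_id"]))
    marker_ids = list(dict.fromkeys(df["marker_id"]))
    s_index = {s: i for i, s in enumerate(sample_ids)}
    m_index = {m: j for j, m in enumerate(marker_ids)}

    calls = np.full((len(sample_ids), len(marker_ids)), MISSING, dtype=np.int16)
    depths = np.zeros_like(calls, dtype=np.int64)
    observed = np.zeros_like(calls, dtype=bool)
    for row in df.itertuples(index=False):
        rec = ReadCountRecord(
            row.sample_id, row.marker_id, int(row.ref_reads), int(row.alt_reads)
        )
        call = call_genotype(rec, models[rec.marker_id], min_depth, min_posterior)
        i, j = s_index[rec.sample_id], m_index[rec.marker_id]
        calls[i, j] = call.dosage if call.called else MISSING
        depths[i, j] = rec.depth
        observed[i, j] = True

    ploidy = np.array(
        [models[m].ploidy_scale for m in marker_ids], dtype=np.int16
    )
    matrix = GenotypeMatrix(
        sample_ids=sample_ids, marker_ids=marker_ids,
        calls=calls, ploidy_scale=ploidy,
    )

    call_rate = {
        m: float((calls[:, j] != MISSING).mean()) for m, j in m_index.items()
    }
    flagged = sorted(m for m, r in call_rate.items() if r < call_rate_flag)
    all_depths = depths[observed]
    per_sample_depth = {}
    per_sample_unif = {}
    for s, i in s_index.items():
        d = depths[i][observed[i]]
        per_sample_depth[s] = float(d.mean()) if d.size else float("nan")
        per_sample_unif[s] = uniformity(d)
    qc = AmpliconQC(
        mean_depth=float(all_depths.mean()) if all_depths.size else float("nan"),
        depth_ge5_fraction=float((all_depths >= 5).mean())
        if all_depths.size else float("nan"),
        uniformity_0p2x=uniformity(all_depths),
        marker_call_rate=call_rate,
        flagged_markers=flagged,
        per_sample_mean_depth=per_sample_depth,
        per_sample_uniformity=per_sample_unif,
    )
    return matrix, qc


@dataclass
class ConcordanceResult:
    overall: Optional[float]
    per_sample: dict[str, Optional[float]]
    n_markers_shared: int


def concordance(
    calls_a: GenotypeMatrix, calls_b: GenotypeMatrix
) -> ConcordanceResult:
    """Agreement between two call sets over shared samples and markers.

    Computed over cells non-missing in both matrices; samples (or the
    whole comparison) with no such cells report None. Used for
    duplicated-sample consistency checks.
    """
    shared_markers = [m for m in calls_a.marker_ids if m in set(calls_b.marker_ids)]
    if not shared_markers:
        raise ValueError("matrices share no markers")
    shared_samples = [s for s in calls_a.sample_ids if s in set(calls_b.sample_ids)]

    ja = [calls_a.marker_ids.index(m) for m in shared_markers]
    jb = [calls_b.marker_ids.index(m) for m in shared_markers]
    per_sample: dict[str, Optional[float]] = {}
    agree_total = 0
    n_total = 0
    for s in shared_samples:
        ra = calls_a.calls[calls_a.sample_ids.index(s)][ja]
        rb = calls_b.calls[calls_b.sample_ids.index(s)][jb]
        both = (ra != MISSING) & (rb != MISSING)
        n = int(both.sum())
        if n == 0:
            per_sample[s] = None
            continue
        agree = int((ra[both] == rb[both]).sum())
        per_sample[s] = agree / n
        agree_total += agree
        n_total += n
    overall = agree_total / n_total if n_total else None
    return ConcordanceResult(overall, per_sample, len(shared_markers))
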