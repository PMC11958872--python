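"""Genetic-diversity analysis chain for genotype matrices.

Mirrors the standard mid-density-assay workflow: preset-based site and
sample filtering, per-set diversity indices, an identity-by-state (IBS)
distance matrix, classical (Torgerson) multidimensional scaling with
per-axis variance explained, and Saitou-Nei neighbor-joining trees with
newick export.

The two filtering presets are kept exactly as published for this assay:
``strict`` keeps sites with >= 2,000 calls then samples with >= 95% of
sites present; ``less_strict`` keeps sites with >= 2,700 calls then
samples with >= 90% present. (That the "less strict" preset carries the
higher site-call threshold is how the presets were published; both are
reproduced verbatim.) Sites are always filtered before samples.

The IBS similarity between samples i and j at a marker is
``1 - |d_i - d_j| / ploidy``, so intermediate tetraploid dosages
contribute partial sharing; the distance is one minus the mean
similarity over pairwise non-missing markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .marker_catalog import MISSING, GenotypeMatrix
from .panel_design import compute_marker_stats


@dataclass(frozen=True)
class FilterSpec:
    """Site-then-sample filtering thresholds."""

    min_site_calls: int
    min_sample_present_fraction: float
    name: str = "custom"


STRICT = FilterSpec(2000, 0.95, "strict")
LESS_STRICT = FilterSpec(2700, 0.90, "less_strict")
PRESETS = {"strict": STRICT, "less_strict": LESS_STRICT}


@dataclass
class FilterLedger:
    spec_name: str
    n_sites_in: int
    n_sites_removed: int
    n_samples_in: int
    n_samples_removed: int


class EmptyFilterResult(ValueError):
    """Raised when filtering removes every site or every sample."""


def filter_dataset(
    matrix: GenotypeMatrix, spec: FilterSpec
) -> tuple[GenotypeMatrix, FilterLedger]:
    """Filter sites, then samples.

    Sites with fewer than ``min_site_calls`` called samples are removed
    first; then samples whose fraction of present calls over the
    *surviving* sites is below ``min_sample_present_fraction`` are
    removed.
    """
    called = matrix.calls != MISSING
    site_keep = np.flatnonzero(called.sum(axis=0) >= spec.min_site_calls)
    if site_keep.size == 0:
        raise EmptyFilterResult(
            f"{spec.name}: no site has >= {spec.min_site_calls} calls"
        )
    sub = matrix.subset(marker_idx=site_keep)
    present = (sub.calls != MISSING).mean(axis=1)
    sample_keep = np.flatnonzero(present >= spec.min_sample_present_fraction)
    if sample_keep.size == 0:
        raise EmptyFilterResult(
            f"{spec.name}: no sample has >= {spec.min_sample_present_fraction:.0%} "
            "of surviving sites present"
        )
    out = sub.subset(sample_idx=sample_keep)
    ledger = FilterLedger(
        spec_name=spec.name,
        n_sites_in=matrix.n_markers,
        n_sites_removed=matrix.n_markers - site_keep.size,
        n_samples_in=matrix.n_samples,
        n_samples_removed=matrix.n_samples - sample_keep.size,
    )
    return out, ledger


def per_set_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Mean diversity indices per sample set (plus an 'all' row).

    For each set, marker statistics are computed over the set's samples
    and averaged over markers with defined values: PIC, mean MAF,
    proportion missing / not missing, and proportion heterozygous.
    """
    if matrix.set_labels is None:
        labels = ["all"] * matrix.n_samples
    else:
        labels = matrix.set_labels
    groups = {"all": list(range(matrix.n_samples))}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    if "all" in set(labels):  # avoid double counting if a set is named 'all'
        groups = {lab: [i for i, l2 in enumerate(labels) if l2 == lab]
                  for lab in dict.fromkeys(labels)}

    rows = []
    for label, idx in groups.items():
        if not idx:
            rows.append({"set": label, "n_samples": 0})
            continue
        sub = matrix.calls[idx, :]
        stats = [
            compute_marker_stats(sub[:, j], int(matrix.ploidy_scale[j]))
            for j in range(matrix.n_markers)
        ]
        pics = [s.pic for s in stats if s.pic is not None]
        mafs = [s.maf for s in stats if s.maf is not None]
        hets = [s.het_proportion for s in stats if s.het_proportion is not None]
        miss = [s.missing_proportion for s in stats]
        rows.append(
            {
                "set": label,
                "n_samples": len(idx),
                "pic": float(np.mean(pics)) if pics else np.nan,
                "maf": float(np.mean(mafs)) if mafs else np.nan,
                "proportion_missing": float(np.mean(miss)),
                "proportion_not_missing": 1.0 - float(np.mean(miss)),
                "proportion_heterozygous": float(np.mean(hets)) if hets else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Identity-by-state distance: 1 - mean per-marker dosage sharing.

    Sharing at a marker is ``1 - |d_i - d_j| / ploidy`` over markers
    called in both samples. Pairs with no shared called marker get NaN
    (reported via ``has_missing``).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = matrix.calls.astype(float)
    called = matrix.calls != MISSING
    ploidy = matrix.ploidy_scale.astype(float)
    n = matrix.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(calls[i][None, :] - calls[i:])  # (n-i, m)
        both = called[i][None, :] & called[i:]
        share = 1.0 - diff / ploidy[None, :]
        overlap = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - np.where(both, share, 0.0).sum(axis=1) / overlap
        d = np.where(overlap > 0, d, np.nan)
        dist[i, i:] = d
        dist[i:, i] = d
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(matrix.sample_ids), dist)


@dataclass
class OrdinationResult:
    """Classical-MDS coordinates with per-axis variance explained (%)."""

    sample_ids: list[str]
    coordinates: np.ndarray
    variance_explained_percent: np.ndarray
    n_negative_eigenvalues: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"PC{k + 1}": self.coordinates[:, k]
            for k in range(self.coordinates.shape[1])
        }
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def classical_mds(dist: DistanceMatrix, k: int = 3) -> OrdinationResult:
    """Torgerson principal-coordinates analysis of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and keeps the
    top ``k`` axes with positive eigenvalues. Variance explained is each
    eigenvalue over the sum of positive eigenvalues; negative
    eigenvalues (non-Euclidean input) are excluded from the denominator
    and counted in the result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if dist.has_missing:
        raise ValueError(
            "distance matrix has missing entries; drop the affected pairs "
            "or impute before ordination"
        )
    d2 = dist.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-12 * max(abs(eigvals[0]), 1.0)
    n_neg = int((eigvals < -1e-12 * max(abs(eigvals[0]), 1.0)).sum())
    pos_vals = eigvals[positive]
    k_eff = min(k, pos_vals.size)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    variance = 100.0 * eigvals[:k_eff] / pos_vals.sum() if pos_vals.size else np.zeros(0)
    return OrdinationResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        variance_explained_percent=np.asarray(variance),
        n_negative_eigenvalues=n_neg,
    )


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining tree from a complete distance matrix.

    Additive matrices are recovered exactly (tree path lengths equal the
    input distances). Q-matrix ties break on the smallest (i, j) index
    pair for determinism. Negative limb lengths are clamped to zero with
    the deficit moved to the sibling limb (their sum is preserved when
    possible); the tree is returned unrooted (trifurcating root) as a
    scikit-bio ``TreeNode``.
    """
    if dist.has_missing:
        raise ValueError("neighbor joining needs a complete distance matrix")
    n = len(dist.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dist.sample_ids]
    active = list(range(n))
    dm = dist.values.astype(float).copy()

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q, ties broken by smallest (i, j)
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = sorted(best)
        dij = sub[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        child_i, child_j = nodes[active[i]], nodes[active[j]]
        child_i.length = float(max(li, 0.0))
        child_j.length = float(max(lj, 0.0))
        parent.extend([child_i, child_j])

        # distances from the new node to the remaining ones
        new_d = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        dm_new = np.zeros((dm.shape[0] + 1, dm.shape[1] + 1))
        dm_new[:-1, :-1] = dm
        for pos, g in enumerate(active):
            dm_new[-1, g] = dm_new[g, -1] = new_d[pos]
        dm = dm_new
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [dm.shape[0] - 1]

    # final 3-node star join, closed form
    sub = dm[np.ix_(active, active)]
    la = 0.5 * (sub[0, 1] + sub[0, 2] - sub[1, 2])
    lb = 0.5 * (sub[0, 1] + sub[1, 2] - sub[0, 2])
    lc = 0.5 * (sub[0, 2] + sub[1, 2] - sub[0, 1])
    root = TreeNode()
    for g, length in zip(active, (la, lb, lc)):
        nodes[g].length = float(max(length, 0.0))
        root.append(nodes[g])
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_ordination(result: OrdinationResult, path: str | Path) -> None:
    """Coordinate CSV; the header comment carries per-axis variance %."""
    percents = ", ".join(
        f"PC{k + 1}={v:.2f}%" for k, v in
        enumerate(result.variance_explained_percent)
    )
    with open(path, "w") as fh:
        fh.write(f"# variance explained: {percents}\n")
        result.to_frame().to_csv(fh, index=False)


def read_ordination(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
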