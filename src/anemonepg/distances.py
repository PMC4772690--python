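"""Between-sample genetic distances and hierarchical clustering.

Two distances are defined over the genotype matrix, both with pairwise
deletion of missing data and per-pair normalisation:

* half-weight Hamming — heterozygous vs either homozygote scores 0.5,
  opposite homozygotes score 1, identical states 0.  Not guaranteed to be
  a metric (the triangle inequality is not asserted).
* homozygous p-distance — the fraction of mutually-called homozygous-only
  sites with different states, for export to phylogenetic-network software.

Clustering is standard agglomerative linkage (complete by default) with
Newick export; cutting the dendrogram recovers sample groupings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .callset import HET, MISSING, CallSet


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray            # symmetric, zero diagonal; NaN when no shared sites
    n_compared: np.ndarray   # per-pair count of sites used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.samples.index(a), self.samples.index(b)])


def _pairwise(callset: CallSet, score) -> DistanceMatrix:
    n = callset.n_samples
    d = np.zeros((n, n))
    n_comp = np.zeros((n, n), dtype=np.int64)
    gt = callset.gt
    for i in range(n):
        for j in range(i + 1, n):
            both = (gt[:, i] != MISSING) & (gt[:, j] != MISSING)
            m = int(both.sum())
            n_comp[i, j] = n_comp[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            total = score(gt[both, i], gt[both, j])
            d[i, j] = d[j, i] = total / m
    return DistanceMatrix(list(callset.samples), d, n_comp)


def half_weight_hamming(callset: CallSet) -> DistanceMatrix:
    """Heterozygote-aware Hamming distance, normalised per pair.

    With genotype codes 0/1/2 the per-site score is |a - b| / 2: same
    state 0, het vs homozygote 0.5, opposite homozygotes 1.
    """
    return _pairwise(
        callset, lambda a, b: float(np.abs(a.astype(int) - b.astype(int)).sum()) / 2.0)


def p_distance_homozygous(callset: CallSet) -> DistanceMatrix:
    """Uncorrected p-distance over a homozygous-only call-set."""
    if (callset.gt == HET).any():
        raise ValueError(
            "p_distance_homozygous requires a homozygous-only call-set "
            "(run extract_homozygous_only first)")
    return _pairwise(callset, lambda a, b: float((a != b).sum()))


@dataclass
class DendrogramNode:
    """Binary dendrogram node: a leaf (sample id) or a merge at a height."""

    height: float
    sample: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.sample is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.sample]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.sample
        else:
            body = "(" + ",".join(c._newick(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{max(parent_height - self.height, 0.0):.8g}"


@dataclass
class ClusteringResult:
    tree: DendrogramNode
    linkage_matrix: np.ndarray
    samples: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels (1..k) per sample."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(x) for x in labels)))

    def merge_order(self) -> list[frozenset[str]]:
        """Leaf sets merged at each agglomeration step, first merge first."""
        nodes: list[set[str]] = [{s} for s in self.samples]
        out = []
        for row in self.linkage_matrix:
            merged = nodes[int(row[0])] | nodes[int(row[1])]
            nodes.append(merged)
            out.append(frozenset(merged))
        return out


def hierarchical_cluster(matrix: DistanceMatrix,
                         linkage: str = "complete") -> ClusteringResult:
    """Agglomerative clustering of the distance matrix.

    ``linkage`` is one of complete (default), average, single.  Samples are
    ordered lexicographically before linkage so tie-breaking (scipy breaks
    ties by candidate index) is deterministic and label-stable.
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage: {linkage}")
    if np.isnan(matrix.d).any():
        i, j = map(int, np.argwhere(np.isnan(matrix.d))[0])
        raise ValueError(
            f"missing distance between {matrix.samples[i]} and "
            f"{matrix.samples[j]}")
    order = sorted(range(len(matrix.samples)), key=lambda i: matrix.samples[i])
    samples = [matrix.samples[i] for i in order]
    d = matrix.d[np.ix_(order, order)]
    condensed = d[np.triu_indices(len(samples), k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)

    nodes = [DendrogramNode(height=0.0, sample=s) for s in samples]
    for a, b, h, _ in Z:
        nodes.append(DendrogramNode(height=float(h),
                                    children=(nodes[int(a)], nodes[int(b)])))
    return ClusteringResult(tree=nodes[-1], linkage_matrix=Z, samples=samples)


# ---------------------------------------------------------------------------
# exports

def write_phylip(matrix: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"    {len(matrix.samples)}\n")
        for i, s in enumerate(matrix.samples):
            row = "  ".join(f"{matrix.d[i, j]:.6f}"
                            for j in range(len(matrix.samples)))
            fh.write(f"{s:<10}  {row}\n")


def write_nexus_distances(matrix: DistanceMatrix, path) -> None:
    """NEXUS Distances block (for phylogenetic-network software)."""
    n = len(matrix.samples)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for s in matrix.samples:
            fh.write(f"  {s}\n")
        fh.write(";\nEND;\n\nBEGIN Distances;\n")
        fh.write(f"DIMENSIONS ntax={n};\n")
        fh.write("FORMAT labels=left diagonal triangle=both;\nMATRIX\n")
        for i, s in enumerate(matrix.samples):
            row = " ".join(f"{matrix.d[i, j]:.6f}" for j in range(n))
            fh.write(f"  {s} {row}\n")
        fh.write(";\nEND;\n")


def concatenated_fasta(callset: CallSet, path) -> None:
    """One pseudo-sequence per sample over homozygous-only sites.

    Homozygous reference emits the ref base, homozygous alternate the alt
    base, missing emits N.  Per-pair mismatch fractions on this alignment
    (ignoring N) equal :func:`p_distance_homozygous`.
    """
    if (callset.gt == HET).any():
        raise ValueError("concatenated export requires a homozygous-only call-set")
    ref = callset.sites["ref"].to_numpy()
    alt = callset.sites["alt"].to_numpy()
    with open(path, "w") as fh:
        for j, sample in enumerate(callset.samples):
            gt = callset.gt[:, j]
            seq = np.where(gt == MISSING, "N", np.where(gt == 0, ref, alt))
            fh.write(f">{sample}\n{''.join(seq)}\n")
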