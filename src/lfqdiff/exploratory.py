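"""Replicate-aware unsupervised structure: clustering, PCA, replicate shift.

Technical replicates of the same lysate should sit next to each other in an
average-linkage dendrogram and differ only by a run-order batch direction in
PCA space; these utilities quantify both, and can subtract a batch-dominated
component from the score space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import IntensityMatrix, StudyDesign


@dataclass
class Dendrogram:
    """Average-linkage (UPGMA) dendrogram over samples, Euclidean metric.

    ``merges`` is a SciPy linkage matrix: row r merges clusters ``merges[r,0]``
    and ``merges[r,1]`` (indices < n are original leaves) at height
    ``merges[r,2]``.
    """

    merges: np.ndarray
    samples: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.samples)

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.samples[i] for i in order]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def to_newick(self) -> str:
        """Newick text with branch lengths derived from merge heights."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.samples[i] for i in range(n)}
        for r, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node = n + r
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            height[node] = h
        return text[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(matrix: IntensityMatrix) -> Dendrogram:
    """UPGMA dendrogram of samples using Euclidean distance between columns."""
    if not matrix.is_complete:
        raise ValueError("clustering requires a complete matrix")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(matrix.values.T, method="average", metric="euclidean")
    return Dendrogram(merges=Z, samples=list(matrix.samples))


def technical_pair_concordance(
    dendrogram: Dendrogram, design: StudyDesign
) -> tuple[float, dict[str, bool]]:
    """Fraction of technical pairs that are each other's first merge.

    A patient's pair is concordant iff its two samples form a two-leaf
    cluster, i.e. some merge joins the two original leaves directly.
    """
    leaf_index = {s: i for i, s in enumerate(dendrogram.samples)}
    n = dendrogram.n_leaves
    direct_pairs = {
        frozenset((int(a), int(b)))
        for a, b, _, _ in dendrogram.merges
        if a < n and b < n
    }
    flags: dict[str, bool] = {}
    for patient in design.patients:
        pair = design.samples_of(patient)
        if len(pair) != 2:
            raise ValueError(
                f"patient {patient!r} has {len(pair)} samples; concordance needs exactly 2"
            )
        absent = [s for s in pair if s not in leaf_index]
        if absent:
            raise ValueError(
                f"patient {patient!r}: samples {absent} not among clustered leaves"
            )
        idx = frozenset(leaf_index[s] for s in pair)
        flags[patient] = idx in direct_pairs
    frac = sum(flags.values()) / len(flags)
    return frac, flags


@dataclass
class PcaResult:
    """Principal components of samples (observations) over proteins (variables).

    ``scores`` has shape (n_samples, n_components); each column has mean 0.
    Component signs are fixed by forcing the largest-magnitude protein
    loading positive.
    """

    scores: np.ndarray
    loadings: np.ndarray  # (n_components, n_proteins)
    explained_variance_ratio: np.ndarray
    samples: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


def pca(matrix: IntensityMatrix) -> PcaResult:
    """Full PCA of the sample column vectors.

    The (already row-standardised or log2) protein dimension is centred but
    not rescaled; keeping all components gives a complete decomposition whose
    explained-variance fractions sum to 1.
    """
    if not matrix.is_complete:
        raise ValueError("PCA requires a complete matrix")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    X = matrix.values.T  # samples x proteins
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var = S**2
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(
        scores=scores,
        loadings=Vt,
        explained_variance_ratio=evr,
        samples=list(matrix.samples),
    )


@dataclass
class ReplicateShift:
    """Per-pair replicate displacement in PCA space and its removal."""

    per_pair: pd.DataFrame  # patients x components, signed score differences
    mean_abs_shift: np.ndarray  # per component
    intra_inter_ratio_before: float
    intra_inter_ratio_after: float
    reduced: PcaResult


def replicate_shift_and_subtract(
    pca_result: PcaResult, design: StudyDesign, component: int = 0
) -> ReplicateShift:
    """Measure replicate-pair score shifts and remove one component.

    ``component`` is a 0-based index.  The reduced result zeroes that
    component's scores, mimicking "subtracting" a batch-dominated direction.
    The intra/inter ratio compares the mean within-pair distance to the mean
    distance between patient centroids, before and after removal.
    """
    k = pca_result.n_components
    if not (0 <= component < k):
        raise IndexError(f"component {component} out of range [0, {k})")
    sample_row = {s: i for i, s in enumerate(pca_result.samples)}
    pairs: dict[str, tuple[int, int]] = {}
    for patient in design.patients:
        ss = design.samples_of(patient)
        if len(ss) != 2:
            raise ValueError(f"patient {patient!r} does not have exactly 2 replicates")
        pairs[patient] = (sample_row[ss[0]], sample_row[ss[1]])

    diffs = np.array(
        [pca_result.scores[i] - pca_result.scores[j] for i, j in pairs.values()]
    )
    per_pair = pd.DataFrame(
        diffs, index=list(pairs), columns=[f"PC{c + 1}" for c in range(k)]
    )

    def _ratio(scores: np.ndarray) -> float:
        intra = np.mean(
            [np.linalg.norm(scores[i] - scores[j]) for i, j in pairs.values()]
        )
        centroids = np.array(
            [(scores[i] + scores[j]) / 2 for i, j in pairs.values()]
        )
        inter = np.mean(pdist(centroids)) if len(centroids) > 1 else np.nan
        return float(intra / inter) if inter and inter > 0 else float("nan")

    reduced_scores = pca_result.scores.copy()
    reduced_scores[:, component] = 0.0
    evr = pca_result.explained_variance_ratio.copy()
    evr[component] = 0.0
    reduced = PcaResult(
        scores=reduced_scores,
        loadings=pca_result.loadings.copy(),
        explained_variance_ratio=evr,
        samples=list(pca_result.samples),
    )
    return ReplicateShift(
        per_pair=per_pair,
        mean_abs_shift=np.abs(diffs).mean(axis=0),
        intra_inter_ratio_before=_ratio(pca_result.scores),
        intra_inter_ratio_after=_ratio(reduced_scores),
        reduced=reduced,
    )
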