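"""Expression-pattern clustering of spots of interest.

Spots are clustered by how their abundance varies over the 12 biological
samples (6 patients x high/low), using Gower's dissimilarity (range-scaled
mean absolute difference -- on all-numeric profiles, a range-normalized
Manhattan distance) and Ward's minimum-variance agglomeration.  Because
Gower dissimilarities are not Euclidean, the Ward recurrence is applied via
the Lance-Williams update; the default works on squared dissimilarities
(the "D2" convention, matching scipy's ward on a distance matrix) with the
unsquared "D1" variant selectable.

The tree is cut to a fixed number of groups, cluster reproducibility is
estimated by leaving out one sample column at a time (LOOCV), and clusters
are labelled with cell-type marker panels (e.g. the erythrocyte panel
HBA1/HBB/CAT/CA1/BLVRB) whose per-patient summary ratios can be correlated
against external histology measurements such as blood-vessel length ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from .io import DigeError, SpotAnnotation

WARD_D2 = "D2"
WARD_D1 = "D1"
DEFAULT_K = 37


@dataclass(frozen=True)
class MarkerPanel:
    """A named panel of cell-type marker gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise DigeError(f"marker panel {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


#: cell-type panels used to label expression-pattern clusters
DEFAULT_MARKER_PANELS = (
    MarkerPanel("erythrocyte", frozenset({"HBA1", "HBB", "CAT", "CA1", "BLVRB"})),
    MarkerPanel("fibrinogen", frozenset({"FGB", "FGG"})),
    MarkerPanel("smooth_muscle", frozenset({"TPM1", "TPM2", "TAGLN"})),
    MarkerPanel("plasma", frozenset({"ALB", "APOA1", "APOD"})),
)


@dataclass
class ClusterResult:
    """Dissimilarities, linkage tree, cut assignment and cluster annotations."""

    dissimilarity: pd.DataFrame
    linkage: np.ndarray
    assignment: pd.Series
    k: int
    stability: pd.Series | None = None
    labels: dict[int, str] = field(default_factory=dict)


def gower_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity between spot profiles.

    ``d(i, j) = mean_s |x_is - x_js| / range_s`` where ``range_s`` is the
    observed range of sample ``s`` over all spots.  Samples with zero range
    carry no pattern information and are dropped from the mean with a
    warning.  The result is symmetric with a zero diagonal and values in
    [0, 1], and is invariant to rescaling any sample column by a positive
    constant.
    """
    if profiles.shape[0] < 2:
        raise DigeError("Gower dissimilarity requires >= 2 spots")
    x = profiles.to_numpy(dtype=float)
    ranges = x.max(axis=0) - x.min(axis=0)
    keep = ranges > 0
    if not keep.all():
        dropped = list(profiles.columns[~keep])
        warnings.warn(
            f"samples with zero range dropped from Gower mean: {dropped}",
            stacklevel=2,
        )
        if not keep.any():
            # every profile is identical: all dissimilarities are zero
            z = np.zeros((x.shape[0], x.shape[0]))
            return pd.DataFrame(z, index=profiles.index, columns=profiles.index)
        x = x[:, keep]
        ranges = ranges[keep]
    scaled = x / ranges
    d = np.abs(scaled[:, None, :] - scaled[None, :, :]).mean(axis=2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def ward_linkage(dissimilarity: pd.DataFrame | np.ndarray,
                 variant: str = WARD_D2) -> np.ndarray:
    """Agglomerative Ward tree from a dissimilarity matrix.

    Lance-Williams recurrence ``d(k, i+j)^2 = ((n_i+n_k) d_ik^2 +
    (n_j+n_k) d_jk^2 - n_k d_ij^2) / (n_i+n_j+n_k)`` applied to squared
    dissimilarities for the default ``"D2"`` variant, or to the
    dissimilarities themselves for ``"D1"``.  Merges pick the globally
    closest active pair, breaking ties by the lowest (i, j) index pair, so
    the tree is deterministic.  Returns a scipy-style linkage matrix
    (children, height, size); heights are non-decreasing.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DigeError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T):
        raise DigeError("dissimilarity matrix is not symmetric")
    if (d < 0).any():
        raise DigeError("dissimilarity matrix has negative entries")
    n = d.shape[0]
    if n < 2:
        raise DigeError("need at least two observations")
    if variant not in (WARD_D1, WARD_D2):
        raise DigeError(f"unknown Ward variant {variant!r}")

    w = d.astype(float).copy()
    if variant == WARD_D2:
        w = w ** 2
    np.fill_diagonal(w, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)          # scipy node id of each active row
    active = np.ones(n, dtype=bool)
    z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        # dead rows/cols are held at inf, so the matrix argmin scans active
        # pairs only; row-major argmin == lowest (i, j) tie-break
        i, j = np.unravel_index(int(np.argmin(w)), w.shape)
        if i > j:
            i, j = j, i
        dist = w[i, j]
        height = float(np.sqrt(dist)) if variant == WARD_D2 else float(dist)
        ni, nj = sizes[i], sizes[j]
        z[step] = (cluster_id[i], cluster_id[j], height, ni + nj)
        # Lance-Williams update of every other active cluster against i+j
        others = active.copy()
        others[[i, j]] = False
        nk = sizes[others]
        w_new = ((ni + nk) * w[i, others] + (nj + nk) * w[j, others]
                 - nk * dist) / (ni + nj + nk)
        w[i, others] = w_new
        w[others, i] = w_new
        sizes[i] = ni + nj
        active[j] = False
        w[j, :] = np.inf
        w[:, j] = np.inf
        cluster_id[i] = n + step
    return z


def cut_to_k(linkage: np.ndarray, k: int, index: pd.Index | None = None) -> pd.Series:
    """Partition obtained by cutting the tree's k-1 tallest surviving merges."""
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise DigeError(f"k={k} out of range 1..{n}")
    labels = fcluster(linkage, t=k, criterion="maxclust")
    if index is None:
        index = pd.RangeIndex(n)
    return pd.Series(labels, index=index, name="cluster")


def cluster_profiles(profiles: pd.DataFrame, k: int = DEFAULT_K,
                     variant: str = WARD_D2) -> ClusterResult:
    """Gower -> Ward -> cut pipeline on a spots x samples profile frame."""
    d = gower_matrix(profiles)
    z = ward_linkage(d, variant=variant)
    assignment = cut_to_k(z, k, index=profiles.index)
    return ClusterResult(dissimilarity=d, linkage=z, assignment=assignment, k=k)


def _pair_set(assignment: pd.Series, members: pd.Index) -> set[tuple]:
    pairs = set()
    items = list(members)
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            pairs.add((items[a], items[b]))
    return pairs


def loocv_stability(profiles: pd.DataFrame, k: int,
                    variant: str = WARD_D2) -> pd.Series:
    """Leave-one-sample-out co-assignment stability per cluster.

    For every left-out sample column the remaining columns are re-clustered
    at the same k; a cluster's stability is the mean, over leave-outs, of
    the fraction of its spot pairs still co-assigned.  Singleton clusters
    have no pairs and are reported as 1.0.
    """
    if profiles.shape[1] < 3:
        raise DigeError("LOOCV needs at least 3 sample columns")
    full = cluster_profiles(profiles, k=k, variant=variant).assignment
    clusters = sorted(full.unique())
    frac_sums = {c: [] for c in clusters}
    for col in profiles.columns:
        reduced = profiles.drop(columns=[col])
        redux = cluster_profiles(reduced, k=k, variant=variant).assignment
        for c in clusters:
            members = full.index[full == c]
            if len(members) < 2:
                frac_sums[c].append(1.0)
                continue
            sub = redux.loc[members].to_numpy()
            same = (sub[:, None] == sub[None, :])
            iu = np.triu_indices(len(members), k=1)
            frac_sums[c].append(float(same[iu].mean()))
    return pd.Series({c: float(np.mean(v)) for c, v in frac_sums.items()},
                     name="stability")


def marker_cluster_score(
    assignment: pd.Series,
    annotation: SpotAnnotation,
    panels=DEFAULT_MARKER_PANELS,
    hl_ratios: pd.DataFrame | None = None,
    min_markers: int = 2,
    aggregate: str = "median",
):
    """Label clusters by marker panels and summarize their H/L ratios.

    A cluster is labelled with a panel when at least ``min_markers`` distinct
    panel genes occur among its member spots (the panel with the most genes
    wins ties).  With ``hl_ratios`` (spots x patients high/low abundance
    ratios) each cluster also gets a per-patient summary: the median (or
    mean) of its member spots' ratios.

    Returns ``(labels, scores)`` where ``labels`` maps cluster id -> panel
    name and ``scores`` is clusters x patients (None if no ratios given).
    """
    if aggregate not in ("median", "mean"):
        raise DigeError(f"unknown aggregate {aggregate!r}")
    gene_of = annotation.gene_of()
    labels: dict[int, str] = {}
    for cluster in sorted(assignment.unique()):
        members = assignment.index[assignment == cluster]
        genes = set(gene_of.reindex(members).dropna())
        best_name, best_hits = None, 0
        for panel in panels:
            hits = len(genes & panel.genes)
            if hits >= min_markers and hits > best_hits:
                best_name, best_hits = panel.name, hits
        if best_name is not None:
            labels[int(cluster)] = best_name
    scores = None
    if hl_ratios is not None:
        agg = np.median if aggregate == "median" else np.mean
        rows = {}
        for cluster in sorted(assignment.unique()):
            members = assignment.index[assignment == cluster]
            sub = hl_ratios.reindex(members).dropna(how="all")
            rows[int(cluster)] = sub.apply(lambda col: agg(col.dropna()))
        scores = pd.DataFrame(rows).T
        scores.index.name = "cluster"
    return labels, scores


def correlate_cluster_with_external(
    scores: pd.Series, external: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of per-patient cluster scores with an external
    per-patient measure (e.g. stained blood-vessel length ratio).

    Patients missing from either series are dropped, mirroring studies where
    a tissue block is unavailable for staining.  Requires >= 3 complete
    pairs; a constant input has no defined correlation and raises.
    """
    joined = pd.concat([scores, external], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise DigeError(f"need >= 3 paired patients, got {len(joined)}")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DigeError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Render a linkage tree as a Newick string with branch lengths."""
    n = linkage.shape[0] + 1
    labels = list(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + step
        nodes[node] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node] = h
        del nodes[a], nodes[b]
    (root,) = nodes.values()
    return root + ";"
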