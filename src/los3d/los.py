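"""Approximate convex decomposition by Lines-of-Sight (LoS) clustering.

A Line-of-Sight is a segment between two surface points of an object that
never leaves the object's interior; its endpoints are mutually visible.  In a
convex object every surface-point pair is mutually visible; in a clump of
touching nuclei, lines crossing a concave neck are blocked.  Clustering the
surviving lines therefore groups surface points that belong to the same
approximately convex part, and the grouping is propagated from lines to
surface points to interior voxels.

The decomposition of one clump runs in seven steps:

(i)    collect surface points (foreground voxels with a background 6-neighbor);
(ii)   sample surface points (10 % below 1000 points, 3 % up to 100000,
       2 % above) and form all pairs of the sample;
(iii)  keep the pairs whose connecting segment, probed every 0.1 % of its
       length, stays in the foreground — the Lines-of-Sight;
(iv)   cluster the LoS into *k* groups by Ward agglomeration on chessboard
       (Chebyshev) distances between lines, each line treated as its
       unordered endpoint pair;
(v)    label each surface point with the majority cluster label of its
       incident lines (ties drawn with the seeded generator);
(vi)   smooth the surface labelling: every point takes the majority label of
       its 18 nearest labelled surface points;
(vii)  label every foreground voxel with the majority label of its 18 nearest
       surface points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .clumps import Clump
from .errors import ClusteringError, DegenerateClumpError, ValidationError
from .image import check_binary


@dataclass
class SamplingPolicy:
    """Surface-point sampling and line-probing parameters.

    The sample rate drops as the surface grows so the all-pairs line set stays
    tractable: 10 % of surface points below ``lower_bound`` points, 3 % between
    the bounds (inclusive), 2 % above ``upper_bound``.  ``line_step_fraction``
    is the probing interval along each line as a fraction of its length.
    """

    lower_bound: int = 1000
    upper_bound: int = 100_000
    rate_below: float = 0.10
    rate_between: float = 0.03
    rate_above: float = 0.02
    line_step_fraction: float = 0.001
    n_neighbors: int = 18
    optimize_iterations: int = 1

    def __post_init__(self) -> None:
        for name in ("rate_below", "rate_between", "rate_above"):
            r = getattr(self, name)
            if not 0 < r <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {r}")
        if self.lower_bound >= self.upper_bound:
            raise ValidationError("lower_bound must be < upper_bound")
        if not 0 < self.line_step_fraction <= 1:
            raise ValidationError("line_step_fraction must be in (0, 1]")

    def sample_rate(self, n_points: int) -> float:
        if n_points < self.lower_bound:
            return self.rate_below
        if n_points > self.upper_bound:
            return self.rate_above
        return self.rate_between

    def sample_count(self, n_points: int) -> int:
        return max(2, int(round(self.sample_rate(n_points) * n_points)))


@dataclass
class SurfacePointSet:
    """Surface points of one clump, clump-local coordinates, with labels.

    ``labels`` holds one integer per point; 0 means unlabelled.
    """

    points: np.ndarray  # (n, 3) int, lexicographic order
    labels: np.ndarray  # (n,) int, 0 = unlabelled

    @property
    def n(self) -> int:
        return len(self.points)


def surface_points(clump: Clump) -> SurfacePointSet:
    """Foreground voxels with at least one background 6-neighbor.

    Bounding-box faces are padded as background.  Points come out in
    lexicographic (z, y, x) order.
    """
    mask = check_binary(clump.mask)
    if not mask.any():
        raise ValidationError("clump is empty")
    padded = np.pad(mask, 1)
    interior = ndimage.binary_erosion(
        padded, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    pts = np.argwhere(padded & ~interior) - 1
    return SurfacePointSet(points=pts, labels=np.zeros(len(pts), int))


def sample_pairs(
    sps: SurfacePointSet, policy: SamplingPolicy | None = None, rng_seed: int = 0
) -> np.ndarray:
    """Draw the policy's sample of surface points and return all unordered
    pairs of the sample as an (n_pairs, 2, 3) coordinate array."""
    policy = policy or SamplingPolicy()
    n = sps.n
    if n < 2:
        raise DegenerateClumpError(f"need >= 2 surface points, got {n}")
    m = min(policy.sample_count(n), n)
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    pts = sps.points[idx]
    iu, ju = np.triu_indices(m, k=1)
    return np.stack([pts[iu], pts[ju]], axis=1)


def _canonicalize(pairs: np.ndarray) -> np.ndarray:
    """Order each pair so endpoint a <= b lexicographically."""
    a, b = pairs[:, 0], pairs[:, 1]
    # lexicographic comparison on (z, y, x)
    gt = np.zeros(len(pairs), bool)
    undecided = np.ones(len(pairs), bool)
    for axis in range(3):
        col_a, col_b = a[:, axis], b[:, axis]
        gt |= undecided & (col_a > col_b)
        undecided &= col_a == col_b
    out = pairs.copy()
    out[gt, 0], out[gt, 1] = pairs[gt, 1], pairs[gt, 0]
    return out


def select_los(
    clump: Clump, pairs: np.ndarray, step_fraction: float = 0.001, chunk: int = 2048
) -> np.ndarray:
    """Keep the pairs whose segment stays inside the clump foreground.

    Each segment is probed at ``t = 0, step, 2*step, ..., 1`` of its length;
    every probe is rounded to the nearest voxel and must be foreground.
    Returns the surviving lines in input order with endpoints canonically
    ordered (a <= b lexicographically), shape (n_los, 2, 3).
    """
    mask = clump.mask
    pairs = np.asarray(pairs)
    if pairs.size == 0:
        return pairs.reshape(0, 2, 3)
    t = np.arange(0.0, 1.0 + step_fraction / 2, step_fraction)
    keep = np.zeros(len(pairs), bool)
    for start in range(0, len(pairs), chunk):
        block = pairs[start : start + chunk].astype(float)
        a, b = block[:, 0], block[:, 1]
        probes = a[:, None, :] + t[None, :, None] * (b - a)[:, None, :]
        idx = np.rint(probes).astype(int)
        vals = mask[idx[..., 0], idx[..., 1], idx[..., 2]]
        keep[start : start + chunk] = vals.all(axis=1)
    return _canonicalize(pairs[keep])


def line_distances(lines: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Condensed chessboard distance matrix between lines as unordered
    endpoint pairs.

    The dissimilarity of two lines is the smaller, over the two ways of
    pairing their endpoints, of the larger endpoint-to-endpoint Chebyshev
    distance.  This treats a line as the unordered set of its endpoints, so
    no arbitrary endpoint ordering leaks into the geometry: two lines are
    close exactly when both endpoints of one lie near respective endpoints
    of the other.
    """
    lines = np.asarray(lines)
    a = lines[:, 0, :].astype(float)
    b = lines[:, 1, :].astype(float)
    n = len(lines)
    out = np.empty(n * (n - 1) // 2)
    pos = 0
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        # rows i0..i1 against all columns j > i
        daa = np.abs(a[i0:i1, None] - a[None, :]).max(-1)
        dbb = np.abs(b[i0:i1, None] - b[None, :]).max(-1)
        dab = np.abs(a[i0:i1, None] - b[None, :]).max(-1)
        dba = np.abs(b[i0:i1, None] - a[None, :]).max(-1)
        block = np.minimum(np.maximum(daa, dbb), np.maximum(dab, dba))
        for row in range(i0, i1):
            cnt = n - row - 1
            out[pos : pos + cnt] = block[row - i0, row + 1 :]
            pos += cnt
    return out


def cluster_los(lines: np.ndarray, k: int) -> np.ndarray:
    """Ward agglomeration of lines under chessboard distance into *k* clusters.

    Pairwise dissimilarity is the endpoint-pairing chessboard distance of
    :func:`line_distances`; merging follows the Ward (Lance-Williams) update
    applied to those dissimilarities and stops at exactly *k* clusters.
    Returns labels 1..k, numbered by ascending lexicographic order of cluster
    centroids (centroid of the canonically ordered endpoint 6-vectors).
    """
    lines = np.asarray(lines)
    n = len(lines)
    if not 1 <= k <= n:
        raise ClusteringError(f"cannot form {k} clusters from {n} lines")
    vecs = lines.reshape(n, 6).astype(float)
    if k == 1:
        return np.ones(n, int)
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(line_distances(lines), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust").astype(int)
    # renumber by ascending centroid lexicographic order
    uniq = np.unique(labels)
    centroids = np.array([vecs[labels == u].mean(axis=0) for u in uniq])
    order = np.lexsort(centroids.T[::-1])
    remap = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], int)


def _majority(counts: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Row-wise argmax over label counts; ties go to the smallest label or,
    when a generator is given, to a seeded draw among the tied labels."""
    top = counts.max(axis=1, keepdims=True)
    is_top = (counts == top) & (top > 0)
    winners = is_top.argmax(axis=1)
    if rng is not None:
        n_top = is_top.sum(axis=1)
        for row in np.flatnonzero(n_top > 1):
            winners[row] = rng.choice(np.flatnonzero(is_top[row]))
    return winners


def label_surface_points(
    sps: SurfacePointSet, lines: np.ndarray, line_labels: np.ndarray, rng_seed: int = 0
) -> SurfacePointSet:
    """Step (v): per surface point, the majority cluster label of incident lines.

    Ties are drawn uniformly from the tied labels with the seeded generator;
    points with no incident line stay unlabelled (label 0) and are resolved by
    :func:`optimize_surface_labels`.
    """
    rng = np.random.default_rng(rng_seed)
    index = {tuple(p): i for i, p in enumerate(sps.points)}
    kmax = int(line_labels.max()) if len(line_labels) else 0
    counts = np.zeros((sps.n, kmax + 1), int)
    for (a, b), lab in zip(lines, line_labels):
        counts[index[tuple(a)], lab] += 1
        counts[index[tuple(b)], lab] += 1
    labels = _majority(counts, rng)
    labels[counts.sum(axis=1) == 0] = 0
    # a cluster whose lines all lose their per-point majorities would end up
    # with no anchor at all and could never form a part; keep its
    # strongest-voting surface point as the anchor
    for cluster in range(1, kmax + 1):
        if not (labels == cluster).any() and counts[:, cluster].any():
            labels[int(np.argmax(counts[:, cluster]))] = cluster
    return SurfacePointSet(points=sps.points, labels=labels)


def _knn_indices(targets: np.ndarray, refs: np.ndarray, k: int, exclude_self: bool) -> list[np.ndarray]:
    """Indices into ``refs`` of the k nearest reference points per target.

    Euclidean distance in voxel units; distance ties are broken by
    lexicographic (z, y, x) order of the reference coordinates.  With
    ``exclude_self`` a reference at distance 0 (the target itself) is skipped.
    """
    refs_f = refs.astype(float)
    tree = cKDTree(refs_f)
    kq = min(len(refs), k + int(exclude_self) + 16)
    dist, idx = tree.query(targets.astype(float), k=kq)
    if kq == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = []
    for row in range(len(targets)):
        d, i = dist[row], idx[row]
        if exclude_self:
            keep = d > 0
            d, i = d[keep], i[keep]
        need = min(k, len(refs) - int(exclude_self))
        if len(d) > need and d[need - 1] == d[-1] and kq < len(refs):
            # tie group may extend beyond the query window: fall back to full scan
            d = np.linalg.norm(refs_f - targets[row].astype(float), axis=1)
            i = np.arange(len(refs))
            if exclude_self:
                keep = d > 0
                d, i = d[keep], i[keep]
        coords = refs[i]
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d))
        out.append(i[order][:need])
    return out


def optimize_surface_labels(
    sps: SurfacePointSet, n_neighbors: int = 18, max_passes: int = 50
) -> SurfacePointSet:
    """Step (vi): every surface point takes the majority label among the
    labelled ones of its ``n_neighbors`` nearest surface points.

    Synchronous passes of a strictly local rule: a point's neighborhood is
    its 18 nearest surface points (self excluded, labelled or not); only the
    labelled neighbors vote, majority ties go to the smallest label, and a
    point with no labelled neighbor keeps its current state.  Because line
    sampling labels only a subset of the surface, the pass is repeated until
    the labelling is complete and stable (capped at ``max_passes``), which
    grows each label region outward from its anchors instead of letting a
    larger faraway region outvote a smaller local one.  Points on surface
    islands the propagation cannot reach fall back to their nearest labelled
    point.  The result has no unlabelled points.
    """
    labels = sps.labels.copy()
    if not (labels > 0).any():
        raise ValidationError("no labelled surface points to optimize from")
    kmax = int(labels.max())
    neigh = _knn_indices(sps.points, sps.points, n_neighbors, exclude_self=True)
    for _ in range(max_passes):
        counts = np.zeros((sps.n, kmax + 1), int)
        for row, ids in enumerate(neigh):
            votes = labels[ids]
            votes = votes[votes > 0]
            np.add.at(counts[row], votes, 1)
        new = _majority(counts, rng=None)
        no_vote = counts.sum(axis=1) == 0
        new[no_vote] = labels[no_vote]
        if np.array_equal(new, labels):
            break
        labels = new
    if (labels == 0).any():  # disconnected islands: nearest labelled point
        has = labels > 0
        tree = cKDTree(sps.points[has].astype(float))
        _, idx = tree.query(sps.points[~has].astype(float), k=1)
        labels[~has] = labels[has][idx]
    return SurfacePointSet(points=sps.points, labels=labels)


def label_voxels(
    clump: Clump, sps: SurfacePointSet, n_neighbors: int = 18, rng_seed: int = 0
) -> np.ndarray:
    """Step (vii): every foreground voxel takes the majority label of its
    ``n_neighbors`` nearest surface points (ties drawn with the seeded
    generator).  Returns a clump-local label grid; background stays 0."""
    if (sps.labels <= 0).any():
        raise ValidationError("surface points must be fully labelled")
    rng = np.random.default_rng(rng_seed)
    vox = np.argwhere(clump.mask)
    kmax = int(sps.labels.max())
    neigh = _knn_indices(vox, sps.points, n_neighbors, exclude_self=False)
    counts = np.zeros((len(vox), kmax + 1), int)
    for row, ids in enumerate(neigh):
        np.add.at(counts[row], sps.labels[ids], 1)
    winners = _majority(counts, rng)
    out = np.zeros(clump.mask.shape, int)
    out[vox[:, 0], vox[:, 1], vox[:, 2]] = winners
    return out


def _compact_labels(grid: np.ndarray) -> np.ndarray:
    uniq = np.unique(grid)
    uniq = uniq[uniq > 0]
    remap = np.zeros(int(grid.max()) + 1, int)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[grid]


def decompose_clump(
    clump: Clump,
    k: int,
    policy: SamplingPolicy | None = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Run steps (i)-(vii) on one clump; returns clump-local labels 1..k'.

    k' <= k: clusters that end up owning no voxels are compacted away.
    Degenerate clumps (fewer than 2 surface points, or no surviving line)
    are returned unsplit with a warning.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValidationError(f"decomposition needs k >= 2, got {k}")
    policy = policy or SamplingPolicy()
    sps = surface_points(clump)
    if sps.n < 2:
        warnings.warn("degenerate clump (<2 surface points); returned unsplit", stacklevel=2)
        return clump.mask.astype(int)
    pairs = sample_pairs(sps, policy, rng_seed)
    lines = select_los(clump, pairs, policy.line_step_fraction)
    if len(lines) == 0:
        warnings.warn("no Line-of-Sight survived; clump returned unsplit", stacklevel=2)
        return clump.mask.astype(int)
    k_eff = min(k, len(lines))
    if k_eff < k:
        warnings.warn(
            f"only {len(lines)} lines for k={k}; clustering into {k_eff} parts",
            stacklevel=2,
        )
    line_labels = cluster_los(lines, k_eff)
    sps = label_surface_points(sps, lines, line_labels, rng_seed)
    for _ in range(max(1, policy.optimize_iterations)):
        new = optimize_surface_labels(sps, policy.n_neighbors)
        if np.array_equal(new.labels, sps.labels):
            sps = new
            break
        sps = new
    grid = label_voxels(clump, sps, policy.n_neighbors, rng_seed)
    return _compact_labels(grid)
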