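"""Normalized-Cut spectral segmentation of pixel graphs.

An image becomes a locally connected weighted graph: vertices are pixels,
edge weights combine colour similarity and spatial proximity.  The
normalized cut of a bipartition (A, B) is

    Ncut(A, B) = cut(A, B) / assoc(A, V) + cut(A, B) / assoc(B, V)

minimised approximately through the second-smallest generalized eigenvector
of (D - W) y = lambda D y followed by a threshold sweep.  Recursive two-way
cutting produces exactly ``p`` regions per image; each region is packaged as
its black-padded minimum covering rectangle for feature extraction.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from skimage.measure import label as _cc_label

from .dataset_io import RasterImage

__all__ = [
    "NCutParams",
    "PixelGraph",
    "Partition",
    "Region",
    "build_pixel_graph",
    "ncut_value",
    "bipartition",
    "segment_image",
    "segment_hierarchy",
    "min_covering_rect",
]

# Vertices with at most this count get a dense eigensolve; sparse Lanczos is
# unreliable for very small matrices.
_DENSE_EIG_MAX = 128
# All distinct eigenvector values are swept up to this vertex count, beyond it
# 50 evenly spaced quantiles are used.
_FULL_SWEEP_MAX = 5000
_N_QUANTILES = 50


@dataclass(frozen=True)
class NCutParams:
    """Tunables of the pixel-graph construction and recursive cutting.

    sigma_i : colour bandwidth of the similarity kernel, on [0, 1] RGB.
    sigma_x : spatial bandwidth in pixels.
    radius  : connection radius in pixels; pairs at distance >= radius get
              weight zero (strict inequality).
    min_fragment : connected components smaller than this fraction of the
              image area are preferred for merging during connectivity repair.
    """

    sigma_i: float = 0.1
    sigma_x: float = 4.0
    radius: float = 5.0
    min_fragment: float = 0.005


@dataclass
class PixelGraph:
    """Sparse symmetric pixel-affinity graph (zero diagonal)."""

    weights: sp.csr_matrix
    shape: tuple[int, int]  # (H, W) of the source image

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()


@dataclass
class Partition:
    """A binary vertex split: ``indicator[v]`` is True when v is in side A."""

    indicator: np.ndarray
    value: float | None = None

    def sides(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(self.indicator.size)
        return idx[self.indicator], idx[~self.indicator]


@dataclass
class Region:
    """An irregular 4-connected pixel set from one image.

    ``rect`` is the axis-aligned minimum covering rectangle with non-region
    pixels padded pure black; ``mask`` marks which rectangle pixels belong to
    the original region.  Both are ``None`` until
    :func:`min_covering_rect` is applied.
    """

    image_id: str
    pixel_set: np.ndarray  # (N, 2) int (row, col)
    colors: np.ndarray = field(repr=False)  # (N, 3) floats in [0,1]
    rect: np.ndarray | None = field(default=None, repr=False)
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixel_set = np.asarray(self.pixel_set, dtype=int)
        self.colors = np.asarray(self.colors, dtype=float)
        if self.pixel_set.size == 0:
            raise ValueError("region pixel_set may not be empty")
        if self.colors.shape != (self.pixel_set.shape[0], 3):
            raise ValueError("colors must align with pixel_set")

    @property
    def n_pixels(self) -> int:
        return self.pixel_set.shape[0]


def build_pixel_graph(img: RasterImage, sigma_i: float = 0.1,
                      sigma_x: float = 4.0, radius: float = 5.0) -> PixelGraph:
    """Construct the locally connected pixel-affinity graph.

    Pixels u, v within spatial distance < ``radius`` are joined by

        w(u, v) = exp(-||F(u)-F(v)||^2 / sigma_i^2)
                  * exp(-||X(u)-X(v)||^2 / sigma_x^2)

    with F the RGB colour and X the (row, col) coordinates.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    h, w = img.height, img.width
    n = h * w
    colors = img.pixels.reshape(n, 3)

    # Enumerate neighbour offsets in the upper half-plane only; symmetrize at
    # the end.  Strict inequality: distance must be < radius.
    r_int = int(np.ceil(radius)) - (1 if float(radius).is_integer() else 0)
    offsets = []
    for dr in range(0, r_int + 1):
        for dc in range(-r_int, r_int + 1):
            if dr == 0 and dc <= 0:
                continue
            if dr * dr + dc * dc < radius * radius:
                offsets.append((dr, dc))
    if not offsets:
        raise ValueError("empty graph: radius admits no pixel pairs")

    rows_idx, cols_idx = np.mgrid[0:h, 0:w]
    flat = (rows_idx * w + cols_idx)
    data_parts, i_parts, j_parts = [], [], []
    for dr, dc in offsets:
        src = flat[max(0, -dr): h - max(0, dr), max(0, -dc): w - max(0, dc)].ravel()
        dst = flat[max(0, dr): h + min(0, dr) or h, max(0, dc): w + min(0, dc) or w].ravel()
        # slice arithmetic above: dst = src shifted by (dr, dc)
        dcol = colors[src] - colors[dst]
        wgt = np.exp(-np.einsum("ij,ij->i", dcol, dcol) / sigma_i ** 2)
        wgt = wgt * np.exp(-(dr * dr + dc * dc) / sigma_x ** 2)
        data_parts.append(wgt)
        i_parts.append(src)
        j_parts.append(dst)
    data = np.concatenate(data_parts)
    i = np.concatenate(i_parts)
    j = np.concatenate(j_parts)
    W = sp.coo_matrix((np.concatenate([data, data]),
                       (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n, n)).tocsr()
    return PixelGraph(weights=W, shape=(h, w))


def ncut_value(g: PixelGraph | sp.spmatrix, part: Partition) -> float:
    """Evaluate the normalized-cut objective of a bipartition.

    Symmetric in the two sides; 0 for a split along disconnected components;
    bounded by 2.
    """
    W = g.weights if isinstance(g, PixelGraph) else sp.csr_matrix(g)
    ind = np.asarray(part.indicator, dtype=bool)
    if ind.all() or not ind.any():
        raise ValueError("both sides of the partition must be non-empty")
    d = np.asarray(W.sum(axis=1)).ravel()
    assoc_a = d[ind].sum()
    assoc_b = d[~ind].sum()
    if assoc_a <= 0 or assoc_b <= 0:
        raise ValueError("Ncut undefined: a side has zero association")
    cut = ind @ (W @ (~ind).astype(float))
    return float(cut / assoc_a + cut / assoc_b)


def _second_eigvec(W: sp.csr_matrix, d: np.ndarray) -> np.ndarray:
    """Second-smallest generalized eigenvector of (D-W) y = lambda D y.

    Solved as the second-LARGEST eigenvector z of the normalized affinity
    D^{-1/2} W D^{-1/2}, mapped back through y = D^{-1/2} z.  Deterministic:
    the Lanczos start vector is fixed.
    """
    n = W.shape[0]
    inv_sqrt_d = 1.0 / np.sqrt(d)
    Dn = sp.diags(inv_sqrt_d) @ W @ sp.diags(inv_sqrt_d)
    if n <= _DENSE_EIG_MAX:
        vals, vecs = np.linalg.eigh(Dn.toarray())
        z = vecs[:, -2]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        try:
            vals, vecs = spla.eigsh(Dn, k=2, which="LA", v0=v0, tol=1e-8)
        except (spla.ArpackNoConvergence, spla.ArpackError) as exc:
            raise ArithmeticError(
                f"eigensolver failed on {n}-vertex graph: {exc}") from exc
        z = vecs[:, np.argsort(vals)[-2]]
    return inv_sqrt_d * z


def _sweep(W: sp.csr_matrix, d: np.ndarray, y: np.ndarray) -> Partition:
    """Exhaustive incremental threshold sweep of the eigenvector ``y``.

    Vertices enter side A in increasing order of y; cut and association are
    updated in O(deg) per vertex, so the whole sweep is O(|E|).
    """
    n = y.size
    order = np.argsort(y, kind="stable")
    y_sorted = y[order]
    total_assoc = d.sum()
    indptr, indices, data = W.indptr, W.indices, W.data

    if n > _FULL_SWEEP_MAX:
        qs = np.quantile(y, np.linspace(0, 1, _N_QUANTILES + 2)[1:-1])
        candidate = np.zeros(n, dtype=bool)
        for q in qs:
            k = int(np.searchsorted(y_sorted, q, side="right"))
            if 0 < k < n:
                candidate[k - 1] = True
    else:
        # cut only between distinct eigenvector values
        candidate = np.ones(n, dtype=bool)
        candidate[:-1] = y_sorted[:-1] != y_sorted[1:]
        candidate[-1] = False

    in_a = np.zeros(n, dtype=bool)
    cut = 0.0
    assoc_a = 0.0
    best_k, best_val = -1, np.inf
    for k in range(n - 1):
        v = order[k]
        w_to_a = 0.0
        for t in range(indptr[v], indptr[v + 1]):
            if in_a[indices[t]]:
                w_to_a += data[t]
        cut += d[v] - 2.0 * w_to_a
        assoc_a += d[v]
        in_a[v] = True
        if not candidate[k]:
            continue
        assoc_b = total_assoc - assoc_a
        if assoc_a <= 0 or assoc_b <= 0:
            continue
        val = cut / assoc_a + cut / assoc_b
        if val < best_val:
            best_val, best_k = val, k
    if best_k < 0:
        raise ArithmeticError("threshold sweep found no admissible split")
    indicator = np.zeros(n, dtype=bool)
    indicator[order[: best_k + 1]] = True
    return Partition(indicator=indicator, value=float(best_val))


def bipartition(g: PixelGraph | sp.spmatrix) -> Partition:
    """Best two-way normalized cut of a graph.

    Disconnected graphs split along components (Ncut exactly 0); otherwise
    the relaxed eigenproblem is solved and candidate thresholds of the second
    eigenvector are swept, returning the split with the smallest Ncut value.
    """
    W = g.weights if isinstance(g, PixelGraph) else sp.csr_matrix(g)
    n = W.shape[0]
    if n < 2:
        raise ValueError("bipartition needs at least 2 vertices")
    n_comp, comp = connected_components(W, directed=False)
    if n_comp > 1:
        # peel off the smallest component: exact zero-cut split
        sizes = np.bincount(comp)
        smallest = int(np.argmin(sizes))
        indicator = comp == smallest
        return Partition(indicator=indicator, value=0.0)
    d = np.asarray(W.sum(axis=1)).ravel()
    y = _second_eigvec(W, d)
    return _sweep(W, d, y)


# ---------------------------------------------------------------------------
# Recursive two-way cutting


def _best_split(W: sp.csr_matrix, members: np.ndarray):
    """Best split of the induced subgraph, or None when unsplittable."""
    if members.size < 2:
        return None
    sub = W[members][:, members]
    if sub.nnz == 0 and members.size >= 2:
        # no internal edges: any split has zero assoc; split off one vertex
        ind = np.zeros(members.size, dtype=bool)
        ind[0] = True
        return Partition(indicator=ind, value=0.0)
    try:
        return bipartition(sub)
    except (ValueError, ArithmeticError):
        return None


def _recursive_cut_labels(graph: PixelGraph, p: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Greedy recursive two-way cuts until ``p`` segments exist.

    Returns the final label vector and the label vectors after every split,
    so nested granularities (p' < p) are recoverable from one run.
    """
    n = graph.n_vertices
    W = graph.weights
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > n:
        raise ValueError(f"p={p} exceeds the {n} available pixels")
    segments: dict[int, np.ndarray] = {0: np.arange(n)}
    labels = np.zeros(n, dtype=int)
    snapshots = [labels.copy()]
    heap: list[tuple[float, int]] = []
    counter = 0
    split = _best_split(W, segments[0])
    if split is not None:
        heapq.heappush(heap, (split.value, counter, 0, split))
    next_label = 1
    while len(segments) < p:
        if not heap:
            raise ValueError(
                f"cannot reach p={p} segments: best achievable is {len(segments)}")
        _, _, seg_id, part = heapq.heappop(heap)
        if seg_id not in segments:
            continue
        members = segments.pop(seg_id)
        side_a = members[part.indicator]
        side_b = members[~part.indicator]
        id_a, id_b = seg_id, next_label
        next_label += 1
        segments[id_a] = side_a
        segments[id_b] = side_b
        labels[side_b] = id_b
        snapshots.append(labels.copy())
        for sid, mem in ((id_a, side_a), (id_b, side_b)):
            s = _best_split(W, mem)
            if s is not None:
                counter += 1
                heapq.heappush(heap, (s.value, counter, sid, s))
    return labels, snapshots


def _repair_connectivity(labels_img: np.ndarray, p: int, min_fragment: float) -> np.ndarray:
    """Split segments into 4-connected components and merge back to ``p``.

    The smallest component is repeatedly merged into the spatial neighbour
    with the longest shared boundary until exactly ``p`` regions remain.
    """
    comp = _cc_label(labels_img, connectivity=1)
    comp -= comp.min()  # 0-based
    n_comp = comp.max() + 1
    h, w = comp.shape
    while n_comp > p:
        sizes = np.bincount(comp.ravel(), minlength=n_comp)
        victim = int(np.argmin(sizes))
        # boundary length with each neighbouring component
        mask = comp == victim
        border = np.zeros(n_comp, dtype=int)
        for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            shifted = np.roll(comp, shift, axis=axis)
            valid = np.ones_like(mask)
            if axis == 0:
                valid[0 if shift == 1 else h - 1, :] = False
            else:
                valid[:, 0 if shift == 1 else w - 1] = False
            sel = mask & valid & (shifted != victim)
            if sel.any():
                border += np.bincount(shifted[sel], minlength=n_comp)
        border[victim] = 0
        target = int(np.argmax(border))
        if border[target] == 0:  # isolated (should not happen on images)
            others = [c for c in range(n_comp) if c != victim and sizes[c] > 0]
            target = others[0]
        comp[mask] = target
        # compact labels
        remap = -np.ones(n_comp, dtype=int)
        kept = np.unique(comp)
        remap[kept] = np.arange(kept.size)
        comp = remap[comp]
        n_comp = kept.size
    return comp


def labels_to_regions(img: RasterImage, labels_img: np.ndarray,
                      with_rect: bool = True) -> list[Region]:
    """Package a label image as a list of :class:`Region` objects."""
    regions = []
    for lab in np.unique(labels_img):
        rr, cc = np.nonzero(labels_img == lab)
        pixel_set = np.column_stack([rr, cc])
        reg = Region(image_id=img.id, pixel_set=pixel_set,
                     colors=img.pixels[rr, cc])
        regions.append(min_covering_rect(reg) if with_rect else reg)
    return regions


def segment_image(img: RasterImage, p: int,
                  params: NCutParams = NCutParams()) -> list[Region]:
    """Segment an image into exactly ``p`` disjoint 4-connected regions.

    Recursive two-way normalized cuts (always splitting the segment whose
    best split has the lowest Ncut value) followed by connectivity repair.
    Regions partition the image: every pixel belongs to exactly one region.
    """
    return segment_hierarchy(img, [p], params)[p]


def segment_hierarchy(img: RasterImage, p_list: list[int],
                      params: NCutParams = NCutParams()) -> dict[int, list[Region]]:
    """Segment one image at several granularities from a single cut sequence.

    Because recursive cutting is greedy and deterministic, the partition at a
    smaller ``p`` is a prefix of the one at a larger ``p``; one eigensolve
    sequence serves every requested granularity.
    """
    p_list = sorted(set(int(p) for p in p_list))
    if p_list[0] < 1:
        raise ValueError("p must be >= 1")
    h, w = img.height, img.width
    graph = build_pixel_graph(img, params.sigma_i, params.sigma_x, params.radius)
    _, snapshots = _recursive_cut_labels(graph, p_list[-1])
    out: dict[int, list[Region]] = {}
    for p in p_list:
        labels_img = snapshots[p - 1].reshape(h, w)
        labels_img = _repair_connectivity(labels_img, p, params.min_fragment)
        out[p] = labels_to_regions(img, labels_img)
    return out


def min_covering_rect(region: Region) -> Region:
    """Populate the black-padded minimum covering rectangle and its mask.

    The rectangle is the tight axis-aligned bounding box of the pixel set,
    edges parallel to the image; pixels outside the region are exactly
    (0, 0, 0) and the mask distinguishes original from padding pixels.
    """
    rows = region.pixel_set[:, 0]
    cols = region.pixel_set[:, 1]
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    rect = np.zeros((r1 - r0 + 1, c1 - c0 + 1, 3), dtype=float)
    mask = np.zeros(rect.shape[:2], dtype=bool)
    rect[rows - r0, cols - c0] = region.colors
    mask[rows - r0, cols - c0] = True
    region.rect = rect
    region.mask = mask
    return region
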