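"""Bags of region instances and the average Hausdorff bag distance.

A bag is one image's set of region feature vectors; the average Hausdorff
distance (AHD) between bags A and B is

    AHD(A, B) = [ sum_{a in A} min_{b in B} d(a, b)
                + sum_{b in B} min_{a in A} d(b, a) ] / (|A| + |B|)

with d the Euclidean distance in instance space.  AHD is symmetric, zero on
identical bags and invariant to instance order, but is not a metric (the
triangle inequality can fail); nothing downstream assumes it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataset_io import AnnotationMatrix

__all__ = ["Bag", "BagDataset", "make_bag", "ahd", "AHDCalculator", "Standardizer"]


@dataclass
class Bag:
    """One image as a set of instances (region feature vectors)."""

    image_id: str
    instances: np.ndarray  # (n_instances, dim)
    scheme: str = "DWT9"

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=float))
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")
        if not np.isfinite(self.instances).all():
            raise ValueError("bag instances must be finite")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def dim(self) -> int:
        return self.instances.shape[1]


@dataclass
class BagDataset:
    """Aligned bags + annotation matrix; the multi-label MIL dataset."""

    bags: list[Bag]
    terms: list[str]
    annotation: AnnotationMatrix
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bags) != self.annotation.n_images:
            raise ValueError("one annotation row per bag required")
        bag_ids = [b.image_id for b in self.bags]
        if bag_ids != self.annotation.image_ids:
            raise ValueError("bag order must match annotation image order")
        if list(self.terms) != list(self.annotation.terms):
            raise ValueError("term lists disagree")

    def __len__(self) -> int:
        return len(self.bags)

    def labels(self, term: str) -> np.ndarray:
        return self.annotation.column(term)

    def subset(self, indices: np.ndarray) -> "BagDataset":
        indices = np.asarray(indices, dtype=int)
        ann = AnnotationMatrix(
            image_ids=[self.annotation.image_ids[i] for i in indices],
            terms=list(self.terms),
            values=self.annotation.values[indices],
        )
        return BagDataset(bags=[self.bags[i] for i in indices], terms=list(self.terms),
                          annotation=ann, metadata=dict(self.metadata))


def make_bag(regions, scheme: str = "DWT9", m: int = 4) -> Bag:
    """Assemble one image's regions into a bag, one instance per region."""
    from .features import extract_dwt9, extract_sift

    regions = list(regions)
    if not regions:
        raise ValueError("cannot build a bag from zero regions")
    if scheme == "DWT9":
        vecs = [extract_dwt9(r, m=m).values for r in regions]
    elif scheme == "SIFT128":
        vecs = [extract_sift(r).values for r in regions]
    else:
        raise ValueError(f"unknown feature scheme {scheme!r}")
    return Bag(image_id=regions[0].image_id, instances=np.stack(vecs), scheme=scheme)


def ahd(a: Bag | np.ndarray, b: Bag | np.ndarray) -> float:
    """Average Hausdorff distance between two bags."""
    xa = a.instances if isinstance(a, Bag) else np.atleast_2d(np.asarray(a, dtype=float))
    xb = b.instances if isinstance(b, Bag) else np.atleast_2d(np.asarray(b, dtype=float))
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"instance dimension mismatch: {xa.shape[1]} vs {xb.shape[1]}")
    d = cdist(xa, xb)
    return float((d.min(axis=1).sum() + d.min(axis=0).sum()) / (xa.shape[0] + xb.shape[0]))


class Standardizer:
    """Optional per-dimension z-scoring fitted on training bags.

    The 9 wavelet-descriptor dimensions live on incommensurate scales
    (L* in [0,100], sub-band energies near 0); standardizing before the
    Euclidean instance distance keeps no single dimension dominant.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, bags: list[Bag]) -> "Standardizer":
        x = np.vstack([b.instances for b in bags])
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, bag: Bag) -> Bag:
        if self.mean_ is None:
            raise ValueError("Standardizer not fitted")
        return Bag(image_id=bag.image_id,
                   instances=(bag.instances - self.mean_) / self.scale_,
                   scheme=bag.scheme)

    def transform_all(self, bags: list[Bag]) -> list[Bag]:
        return [self.transform(b) for b in bags]


class AHDCalculator:
    """AHD with an evaluation counter.

    The counter lets complexity assertions (e.g. the locality-matrix build
    cost staying O(n^2) AHD calls) be checked directly.
    """

    def __init__(self) -> None:
        self.n_calls = 0

    def __call__(self, a: Bag, b: Bag) -> float:
        self.n_calls += 1
        return ahd(a, b)

    def pairwise(self, bags_a: list[Bag], bags_b: list[Bag]) -> np.ndarray:
        out = np.empty((len(bags_a), len(bags_b)))
        for i, a in enumerate(bags_a):
            for j, b in enumerate(bags_b):
                out[i, j] = self(a, b)
        return out
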