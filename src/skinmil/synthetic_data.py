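"""Synthetic layered tissue images and bag-level MIL samplers.

The image generator emulates the statistical structure the annotation
method assumes, not histology itself: each image is a stack of three
horizontal bands with distinct base colours (standing in for epidermis,
dermis and subcutaneous fat), and every *term* corresponds to a texture
motif — oriented stripes, a checkerboard, or a blob field, each with its
own colour cast — painted into at least one local patch of positive images.
The image-level annotation bit is therefore the OR of its patches' term
bits, which is exactly the standard MIL assumption.

``generate_bags`` skips the imaging stage entirely and samples feature-space
bags directly: negative instances from N(0, I), witness instances from
N(mu, I) with a chosen separation ||mu||, so learner behaviour can be tested
against a known decision structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import AnnotationMatrix, RasterImage
from .mil_core import Bag, BagDataset

__all__ = [
    "Motif",
    "SyntheticSpec",
    "GroundTruth",
    "default_motifs",
    "generate_images",
    "generate_bags",
]

_BAND_COLORS = [
    (0.88, 0.72, 0.78),   # epidermis: pale pink
    (0.72, 0.42, 0.55),   # dermis: darker pink
    (0.93, 0.88, 0.72),   # subcutaneous fat: pale yellow
]


@dataclass(frozen=True)
class Motif:
    """A texture patch tied to one annotation term.

    ``kind`` is one of stripes / checkerboard / blobs; ``period`` is the
    texture wavelength in pixels, ``orientation`` ("h"/"v") applies to
    stripes, and ``color`` is the bright phase of the texture.
    """

    kind: str
    period: int
    color: tuple[float, float, float]
    orientation: str = "v"
    contrast: float = 0.85   # dark phase = contrast * color; mild, so the
    # patch stays internally coherent under the colour-sensitive affinity
    # and is segmented as one region rather than phase-separated combs

    def paint(self, patch_h: int, patch_w: int) -> np.ndarray:
        dark = np.array(self.color) * self.contrast
        bright = np.asarray(self.color, dtype=float)
        rr, cc = np.mgrid[0:patch_h, 0:patch_w]
        if self.kind == "stripes":
            axis = cc if self.orientation == "v" else rr
            phase = (axis // self.period) % 2
        elif self.kind == "checkerboard":
            phase = ((rr // self.period) + (cc // self.period)) % 2
        elif self.kind == "blobs":
            phase = (((rr % (2 * self.period)) < self.period)
                     & ((cc % (2 * self.period)) < self.period)).astype(int)
        else:
            raise ValueError(f"unknown motif kind {self.kind!r}")
        return np.where(phase[..., None] == 1, bright, dark)


def default_motifs(n_terms: int) -> list[Motif]:
    """A catalogue of pairwise distinguishable motifs (orientation/scale/colour)."""
    base = [
        Motif("stripes", period=2, orientation="v", color=(0.85, 0.15, 0.15)),
        Motif("stripes", period=2, orientation="h", color=(0.15, 0.25, 0.85)),
        Motif("checkerboard", period=2, color=(0.15, 0.75, 0.25)),
        Motif("blobs", period=3, color=(0.95, 0.85, 0.15)),
        Motif("stripes", period=4, orientation="v", color=(0.75, 0.15, 0.75)),
        Motif("stripes", period=4, orientation="h", color=(0.15, 0.75, 0.75)),
        Motif("checkerboard", period=4, color=(0.95, 0.55, 0.15)),
        Motif("blobs", period=5, color=(0.45, 0.45, 0.95)),
    ]
    if n_terms > len(base):
        raise ValueError(f"at most {len(base)} distinguishable motifs available")
    return base[:n_terms]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the layered-image benchmark."""

    n_images: int = 80
    image_size: tuple[int, int] = (64, 48)      # (width, height)
    n_terms: int = 4
    motifs: tuple[Motif, ...] | None = None
    n_layers: int = 3
    noise_sd: float = 0.02
    term_prevalence: tuple[float, ...] | None = None   # default 0.5 each
    patch_size: tuple[int, int] = (12, 18)      # (height, width) of motif patches
    seed: int = 0

    def resolved_motifs(self) -> list[Motif]:
        return list(self.motifs) if self.motifs else default_motifs(self.n_terms)

    def resolved_prevalence(self) -> np.ndarray:
        if self.term_prevalence is None:
            return np.full(self.n_terms, 0.5)
        prev = np.asarray(self.term_prevalence, dtype=float)
        if prev.shape != (self.n_terms,) or (prev <= 0).any() or (prev >= 1).any():
            raise ValueError("term prevalences must be in (0, 1), one per term")
        return prev


@dataclass
class GroundTruth:
    """Annotation matrix plus which painted patch carries which term."""

    annotation: AnnotationMatrix
    patch_map: dict[str, list[tuple[str, tuple[int, int, int, int]]]]
    # image_id -> [(term, (row0, col0, height, width)), ...]


# Neutral filler: a patch corresponding to no term (such regions exist in
# real annotated images, where some regions carry no annotation at all).
_FILLER = Motif("checkerboard", period=3, color=(0.55, 0.55, 0.58), contrast=0.9)


def _patch_slots(w: int, h: int, n_layers: int, ph: int, pw: int) -> list[tuple[int, int]]:
    """Fixed non-overlapping patch anchors (row0, col0), two per wide band."""
    band_h = h // n_layers
    slots = []
    margin = max(2, (band_h - ph) // 2)
    for layer in range(n_layers):
        r0 = layer * band_h + margin
        if w >= 2 * pw + 12:
            slots.append((r0, (w // 2 - pw) // 2))
            slots.append((r0, w // 2 + (w // 2 - pw) // 2))
        else:
            slots.append((r0, (w - pw) // 2))
    return slots


def generate_images(spec: SyntheticSpec) -> tuple[list[RasterImage], GroundTruth]:
    """Sample layered images with term-linked motif patches.

    Patches occupy a fixed grid of non-overlapping slots (two per band, the
    bottom band holding one in the default geometry); each positive term's
    motif is assigned to a uniformly random slot, so WHERE a term appears is
    ambiguous — the multi-instance setting — while the slot geometry itself
    is reproducible across images and can never overwrite another term's
    witness patch.  Slots not used by a positive term receive the neutral
    filler motif (a region corresponding to no term).  Gaussian pixel noise
    of standard deviation ``noise_sd`` is added and clipped to [0, 1].
    Fully reproducible from ``spec.seed``.
    """
    w, h = spec.image_size
    ph, pw = spec.patch_size
    band_h = h // spec.n_layers
    if ph > band_h - 2 or pw > w - 2:
        raise ValueError(
            f"motif patch {ph}x{pw} does not fit a {band_h}-pixel band of a "
            f"{h}x{w} image")
    slots = _patch_slots(w, h, spec.n_layers, ph, pw)
    # drop one bottom slot so the natural segment count (bands + patches)
    # sits at the lower end of the p range the ensemble spans
    if len(slots) > spec.n_terms + 1:
        slots = slots[: spec.n_terms + 1]
    motifs = spec.resolved_motifs()
    prevalence = spec.resolved_prevalence()
    terms = [f"t{i + 1}" for i in range(spec.n_terms)]
    rng = np.random.default_rng(spec.seed)
    images: list[RasterImage] = []
    values = np.zeros((spec.n_images, spec.n_terms), dtype=int)
    patch_map: dict[str, list[tuple[str, tuple[int, int, int, int]]]] = {}
    ids = [f"img{i:04d}" for i in range(spec.n_images)]
    for i, img_id in enumerate(ids):
        pixels = np.empty((h, w, 3))
        for layer in range(spec.n_layers):
            r0 = layer * band_h
            r1 = h if layer == spec.n_layers - 1 else (layer + 1) * band_h
            pixels[r0:r1] = _BAND_COLORS[layer % len(_BAND_COLORS)]
        patches = []
        bits = rng.random(spec.n_terms) < prevalence
        pos_terms = list(np.nonzero(bits)[0])[: len(slots)]
        paint_list = ([(terms[j], motifs[j]) for j in pos_terms]
                      + [(None, _FILLER)] * (len(slots) - len(pos_terms)))
        slot_order = rng.permutation(len(slots))
        for k, (term, motif) in enumerate(paint_list):
            r0, c0 = slots[slot_order[k]]
            pixels[r0:r0 + ph, c0:c0 + pw] = motif.paint(ph, pw)
            if term is not None:
                patches.append((term, (r0, c0, ph, pw)))
        for j in pos_terms:
            values[i, j] = 1
        if spec.noise_sd > 0:
            pixels = pixels + rng.normal(0.0, spec.noise_sd, pixels.shape)
        images.append(RasterImage(id=img_id, pixels=np.clip(pixels, 0.0, 1.0)))
        patch_map[img_id] = patches
    ann = AnnotationMatrix(image_ids=ids, terms=terms, values=values)
    return images, GroundTruth(annotation=ann, patch_map=patch_map)


def generate_bags(n_pos: int, n_neg: int, dim: int = 5, separation: float = 6.0,
                  witness_rate: float = 0.3, seed: int = 0,
                  instances_per_bag: tuple[int, int] = (4, 8),
                  term: str = "t1") -> BagDataset:
    """Feature-space MIL sampler under the standard bag assumption.

    Negative bags draw every instance from N(0, I).  Positive bags replace
    each instance independently with probability ``witness_rate`` by a draw
    from N(mu, I) with ||mu|| = ``separation``; the witness mask is redrawn
    until at least one witness exists, so every positive bag is guaranteed a
    positive instance.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if not 0 < witness_rate <= 1:
        raise ValueError("witness_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mu = np.zeros(dim)
    mu[0] = separation
    bags: list[Bag] = []
    labels: list[int] = []
    witness_masks: list[list[bool]] = []
    lo, hi = instances_per_bag
    for k in range(n_pos + n_neg):
        positive = k < n_pos
        m = int(rng.integers(lo, hi + 1))
        x = rng.normal(size=(m, dim))
        witness = np.zeros(m, dtype=bool)
        if positive:
            witness = rng.random(m) < witness_rate
            while not witness.any():
                witness = rng.random(m) < witness_rate
            x[witness] += mu
        bags.append(Bag(image_id=f"bag{k:04d}", instances=x, scheme="synthetic"))
        labels.append(int(positive))
        witness_masks.append(witness.tolist())
    # fixed shuffle so class blocks do not align with index order
    order = rng.permutation(len(bags))
    bags = [bags[i] for i in order]
    labels = [labels[i] for i in order]
    witness_masks = [witness_masks[i] for i in order]
    ann = AnnotationMatrix(image_ids=[b.image_id for b in bags], terms=[term],
                           values=np.asarray(labels)[:, None])
    return BagDataset(bags=bags, terms=[term], annotation=ann,
                      metadata={"separation": separation,
                                "witness_rate": witness_rate, "dim": dim,
                                "witness_masks": witness_masks})
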