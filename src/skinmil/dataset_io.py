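"""Image and annotation-matrix I/O.

Images are held internally as float arrays in [0, 1] (H x W x 3) and written
back to disk as 8-bit PNG/TIFF/JPEG.  Annotation matrices are binary
image-by-term tables stored as TSV: first column ``image_id``, remaining
columns term names, cells 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

__all__ = [
    "RasterImage",
    "AnnotationMatrix",
    "load_image",
    "save_image",
    "rescale",
    "load_annotations",
    "save_annotations",
    "save_bags",
    "load_bags",
]


@dataclass
class RasterImage:
    """An RGB image with an identifier.

    Parameters
    ----------
    id : str
        Image identifier (by convention, the file stem).
    pixels : ndarray, shape (H, W, 3)
        RGB values as floats in [0, 1].
    """

    id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        h, w = self.pixels.shape[:2]
        if h < 2 or w < 2:
            raise ValueError(f"image must be at least 2x2, got {h}x{w}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AnnotationMatrix:
    """Binary image-by-term annotation table.

    ``values[i, j] == 1`` means image ``image_ids[i]`` carries term
    ``terms[j]``.
    """

    image_ids: list[str]
    terms: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.image_ids = [str(i) for i in self.image_ids]
        self.terms = [str(t) for t in self.terms]
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.image_ids), len(self.terms)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.image_ids)} images x {len(self.terms)} terms"
            )
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("duplicate image IDs in annotation matrix")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary annotation value {self.values[i, j]!r} at "
                f"image {self.image_ids[i]!r}, term {self.terms[j]!r}"
            )

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def column(self, term: str) -> np.ndarray:
        """Binary label vector for one term, in image order."""
        return self.values[:, self.terms.index(term)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.image_ids, name="image_id"),
                            columns=self.terms)


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG/TIFF/JPEG file into a :class:`RasterImage`.

    The image id is the file stem; pixels are scaled to [0, 1].
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    return RasterImage(id=path.stem, pixels=arr)


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write a :class:`RasterImage` to disk as an 8-bit image."""
    arr = np.clip(np.rint(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


def rescale(img: RasterImage, w: int, h: int) -> RasterImage:
    """Resize to exactly ``h`` rows by ``w`` columns.

    Bilinear interpolation, with Gaussian anti-aliasing when downscaling.
    Resizing to the current size is the identity.
    """
    if w < 2 or h < 2:
        raise ValueError(f"target size must be at least 2x2, got {w}x{h}")
    if (img.height, img.width) == (h, w):
        return RasterImage(id=img.id, pixels=img.pixels.copy())
    shrinking = h < img.height or w < img.width
    out = _sk_resize(img.pixels, (h, w), order=1, mode="reflect",
                     anti_aliasing=shrinking, preserve_range=True)
    return RasterImage(id=img.id, pixels=np.clip(out, 0.0, 1.0))


def load_annotations(path: str | Path) -> AnnotationMatrix:
    """Read an annotation matrix from TSV.

    Expects a header row whose first column is ``image_id`` and whose
    remaining columns are term names; every cell must be 0 or 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected an image_id column plus >=1 term column")
    id_col = df.columns[0]
    terms = list(df.columns[1:])
    ids = df[id_col].astype(str).tolist()
    values = np.empty((len(ids), len(terms)), dtype=int)
    for j, t in enumerate(terms):
        for i, cell in enumerate(df[t]):
            s = str(cell).strip()
            if s not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at row {i + 1} "
                    f"(image {ids[i]!r}), column {t!r}"
                )
            values[i, j] = int(s)
    return AnnotationMatrix(image_ids=ids, terms=terms, values=values)


def save_annotations(ann: AnnotationMatrix, path: str | Path) -> None:
    ann.to_frame().to_csv(Path(path), sep="\t")


# ---------------------------------------------------------------------------
# Bag archives: a versioned JSON container so trained models and feature bags
# round-trip byte-stable across runs.

_BAG_FORMAT_VERSION = 1


def save_bags(dataset, path: str | Path) -> None:
    """Serialize a :class:`~skinmil.mil_core.BagDataset` to a JSON archive."""
    payload = {
        "format": "skinmil-bags",
        "version": _BAG_FORMAT_VERSION,
        "terms": list(dataset.terms),
        "metadata": dict(dataset.metadata),
        "bags": [
            {
                "image_id": b.image_id,
                "scheme": b.scheme,
                "instances": np.asarray(b.instances).tolist(),
            }
            for b in dataset.bags
        ],
        "annotation": {
            "image_ids": dataset.annotation.image_ids,
            "terms": dataset.annotation.terms,
            "values": dataset.annotation.values.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_bags(path: str | Path):
    """Load a bag archive written by :func:`save_bags`."""
    from .mil_core import Bag, BagDataset

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "skinmil-bags":
        raise ValueError(f"{path}: not a skinmil bag archive")
    if payload.get("version") != _BAG_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported bag archive version {payload.get('version')}")
    ann = AnnotationMatrix(
        image_ids=payload["annotation"]["image_ids"],
        terms=payload["annotation"]["terms"],
        values=np.asarray(payload["annotation"]["values"]),
    )
    bags = [
        Bag(image_id=b["image_id"],
            instances=np.asarray(b["instances"], dtype=float),
            scheme=b["scheme"])
        for b in payload["bags"]
    ]
    return BagDataset(bags=bags, terms=payload["terms"], annotation=ann,
                      metadata=payload.get("metadata", {}))
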