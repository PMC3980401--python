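"""End-to-end plumbing: images -> regions -> feature bags at several p."""

from __future__ import annotations

from typing import Iterable, Mapping

from .dataset_io import AnnotationMatrix, RasterImage
from .mil_core import BagDataset, make_bag
from .segmentation import NCutParams, segment_hierarchy

__all__ = ["images_to_bags"]


def images_to_bags(images: Iterable[RasterImage], annotation: AnnotationMatrix,
                   p_list: list[int], params: NCutParams = NCutParams(),
                   scheme: str = "DWT9", m: int = 4) -> Mapping[int, BagDataset]:
    """Segment each image at every requested granularity and build bags.

    Returns one :class:`BagDataset` per region count p, all covering the
    same images in annotation order.  A single recursive-cut sequence per
    image serves every p (the cuts are nested), so the cost is dominated by
    the largest p.
    """
    images = {img.id: img for img in images}
    missing = [i for i in annotation.image_ids if i not in images]
    if missing:
        raise ValueError(f"images missing for annotated ids: {missing[:5]}")
    bags_by_p: dict[int, list] = {p: [] for p in p_list}
    for img_id in annotation.image_ids:
        regions_by_p = segment_hierarchy(images[img_id], p_list, params)
        for p in p_list:
            bags_by_p[p].append(make_bag(regions_by_p[p], scheme=scheme, m=m))
    return {
        p: BagDataset(bags=bags_by_p[p], terms=list(annotation.terms),
                      annotation=annotation,
                      metadata={"p": p, "scheme": scheme, "block_size": m})
        for p in p_list
    }
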