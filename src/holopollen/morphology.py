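"""Deterministic morphological prefilter applied before the classifier.

Non-biological particles (debris, aggregates, fibres) are rejected from
simple silhouette descriptors — equivalent diameter, solidity and
eccentricity — computed on the first hologram, before any neural network
sees the event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .datatypes import EventRecord


@dataclass(frozen=True)
class MorphDescriptors:
    """Silhouette descriptors of one event; ``None`` for an empty frame."""

    equivalent_diameter: float  # um
    solidity: float             # area / convex hull area, in (0, 1]
    eccentricity: float         # ellipse-fit eccentricity, in [0, 1)


@dataclass(frozen=True)
class PrefilterBounds:
    """Acceptance box for the deterministic prefilter."""

    d_min: float = 5.0     # um
    d_max: float = 150.0   # um
    s_min: float = 0.8     # minimum solidity
    e_max: float = 0.95    # maximum eccentricity


#: Sentinel returned when thresholding finds no particle silhouette.
EMPTY_FRAME = None


def morphological_descriptors(
    record: EventRecord,
) -> Optional[MorphDescriptors]:
    """Descriptors of the largest connected component of hologram 0.

    The silhouette is obtained by Otsu intensity thresholding; returns
    :data:`EMPTY_FRAME` when no component is found (near-constant frame).
    """
    img = record.holograms[0]
    if img.max() - img.min() < 1e-6:
        return EMPTY_FRAME
    mask = img > threshold_otsu(img)
    lab = label(mask)
    props = regionprops(lab)
    if not props:
        return EMPTY_FRAME
    largest = max(props, key=lambda p: p.area)
    if largest.area < 4:
        return EMPTY_FRAME
    diameter = record.pixel_scale * 2.0 * math.sqrt(largest.area / math.pi)
    return MorphDescriptors(
        equivalent_diameter=diameter,
        solidity=float(largest.solidity),
        eccentricity=float(largest.eccentricity),
    )


def prefilter_event(
    record: EventRecord, bounds: PrefilterBounds = PrefilterBounds()
) -> tuple:
    """Deterministically accept or reject an event on morphology.

    Returns ``(True, None)`` on acceptance or ``(False, reason)`` with
    reason code ``"empty"``, ``"size"``, ``"solidity"`` or
    ``"eccentricity"``.
    """
    desc = morphological_descriptors(record)
    if desc is EMPTY_FRAME:
        return False, "empty"
    if not bounds.d_min <= desc.equivalent_diameter <= bounds.d_max:
        return False, "size"
    if desc.solidity < bounds.s_min:
        return False, "solidity"
    if desc.eccentricity > bounds.e_max:
        return False, "eccentricity"
    return True, None
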