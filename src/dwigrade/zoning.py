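"""Per-(slice, zone) patch extraction.

Each anatomical zone present in a slice is cropped at the tight bounding
box of its pixels, out-of-zone pixels are masked with a modality-specific
fill (ADC: 3949, the maximum ADC value, so masked pixels look maximally
benign; CHB: 0, so masked pixels look minimally suspicious), and the result
is bilinear-resized to 32x32. The in-zone indicator mask is resized
alongside and re-binarized at 0.5. The original in-zone pixel values are
kept on the patch so intensity heuristics can operate on pre-resize pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize

__all__ = ["ZonePatch", "extract_zone_patches", "ADC_FILL", "CHB_FILL",
           "PATCH_SIZE", "MODALITY_FILL"]

logger = logging.getLogger(__name__)

PATCH_SIZE = 32
ADC_FILL = 3949.0   # maximum ADC value; out-of-zone fill for ADC patches
CHB_FILL = 0.0      # out-of-zone fill for CHB patches
MODALITY_FILL = {"ADC": ADC_FILL, "CHB": CHB_FILL}


@dataclass
class ZonePatch:
    """One 32x32 masked, resized zone image plus its provenance."""

    pixels: np.ndarray                 # (32, 32) float
    mask: np.ndarray                   # (32, 32) bool, in-zone indicator
    modality: str                      # "ADC" | "CHB"
    patient_id: str
    slice_index: int
    zone_id: int
    label: Optional[int] = None        # 0/1 pathology grade, None if unknown
    zone_values: Optional[np.ndarray] = None   # original in-zone pixels, 1-D

    def __post_init__(self) -> None:
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError("patch pixels must be 32x32")
        if not self.mask.any():
            raise ValueError("patch mask is empty")


def _resize_bilinear(img: np.ndarray, out_shape) -> np.ndarray:
    # half-pixel-centered bilinear (align-corners off), no antialiasing,
    # so a constant image stays exactly constant
    return resize(img.astype(float), out_shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def extract_zone_patches(image: np.ndarray, zone_map: np.ndarray, modality: str,
                         patient_id: str = "", slice_index: int = 0,
                         labels: Optional[dict] = None) -> list[ZonePatch]:
    """Extract one patch per nonzero zone label present in the slice.

    Parameters
    ----------
    image, zone_map
        Same-shape 2D arrays; ``zone_map`` holds integer labels, 0 = background.
    modality
        ``"ADC"`` or ``"CHB"``; selects the out-of-zone fill value.
    labels
        Optional ``{zone_id: 0/1}`` pathology grades to attach.
    """
    if modality not in MODALITY_FILL:
        raise ValueError(f"unknown modality {modality!r}")
    image = np.asarray(image, dtype=float)
    zone_map = np.asarray(zone_map)
    if image.shape != zone_map.shape:
        raise ValueError("image and zone_map shapes differ")
    fill = MODALITY_FILL[modality]

    patches = []
    for zone_id in np.unique(zone_map[zone_map > 0]):
        mask = zone_map == zone_id
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        crop = image[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].copy()
        mcrop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        zone_values = crop[mcrop].copy()
        crop[~mcrop] = fill

        if min(crop.shape) < 2:   # bilinear undefined: nearest-neighbor pre-pass
            reps = (max(2 - crop.shape[0] + 1, 1), max(2 - crop.shape[1] + 1, 1))
            crop = np.repeat(np.repeat(crop, reps[0], axis=0), reps[1], axis=1)
            mcrop = np.repeat(np.repeat(mcrop, reps[0], axis=0), reps[1], axis=1)

        pixels = _resize_bilinear(crop, (PATCH_SIZE, PATCH_SIZE))
        rmask = _resize_bilinear(mcrop.astype(float), (PATCH_SIZE, PATCH_SIZE)) >= 0.5
        if not rmask.any():       # guarantee a nonempty mask for tiny zones
            rmask = np.zeros_like(rmask)
            rmask[PATCH_SIZE // 2, PATCH_SIZE // 2] = True
        label = labels.get(int(zone_id)) if labels else None
        patches.append(ZonePatch(pixels=pixels, mask=rmask, modality=modality,
                                 patient_id=patient_id, slice_index=slice_index,
                                 zone_id=int(zone_id), label=label,
                                 zone_values=zone_values))
    requested = set(labels) if labels else set()
    missing = requested - {p.zone_id for p in patches}
    for z in sorted(missing):
        logger.info("zone %d empty in slice %d of %s; skipped",
                    z, slice_index, patient_id)
    return patches
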