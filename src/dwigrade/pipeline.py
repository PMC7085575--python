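"""Glue from cohorts to modality images, zone patches, and feature tables.

ADC maps are reported in the conventional display unit of 1e-6 mm^2/s
(so typical prostate tissue reads ~700-2000 and the map is clipped at the
conventional maximum 3949); computed high-b images keep raw signal units.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phantom import DEFAULT_CHB_TARGET, PhantomCase
from .radiomics import DEFAULT_CONFIG, RadiomicsConfig, extract_sequence, feature_names
from .signal_model import fit_adc, synthesize_chb
from .zoning import ADC_FILL, ZonePatch, extract_zone_patches

__all__ = ["ADC_SCALE", "slice_modality_image", "cohort_patches",
           "featurize_patches", "patch_stack"]

ADC_SCALE = 1e6   # mm^2/s -> display units (1e-6 mm^2/s)


def slice_modality_image(volume, modality: str,
                         chb_target: float = DEFAULT_CHB_TARGET,
                         fit_method: str = "loglinear") -> np.ndarray:
    """Compute the ADC map (display units) or CHB image for one slice."""
    adc = fit_adc(volume, method=fit_method)
    if modality == "ADC":
        return np.clip(adc.d_map * ADC_SCALE, 0.0, ADC_FILL)
    if modality == "CHB":
        i_ref = int(np.argmin(volume.protocol.b_values))
        b_alpha = volume.protocol.b_values[i_ref]
        return synthesize_chb(adc, volume.signals[i_ref], b_alpha, chb_target)
    raise ValueError(f"unknown modality {modality!r}")


def cohort_patches(cohort: Sequence[PhantomCase], modality: str,
                   chb_target: float = DEFAULT_CHB_TARGET,
                   fit_method: str = "loglinear") -> list[ZonePatch]:
    """All per-(slice, zone) patches of a cohort for one modality."""
    patches: list[ZonePatch] = []
    for case in cohort:
        for s, (vol, zmap) in enumerate(zip(case.volumes, case.zone_maps)):
            img = slice_modality_image(vol, modality, chb_target, fit_method)
            labels = {z: y for (si, z), y in case.labels.items() if si == s}
            patches.extend(extract_zone_patches(
                img, zmap, modality, patient_id=case.patient_id,
                slice_index=s, labels=labels))
    return patches


def featurize_patches(patches: Iterable[ZonePatch],
                      config: RadiomicsConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """One row per patch: manifest keys + the 96 named radiomic features."""
    rows = []
    cols = feature_names(config)
    for p in patches:
        seq = extract_sequence(p, config)
        row = {"patient_id": p.patient_id, "slice_index": p.slice_index,
               "zone_id": p.zone_id, "modality": p.modality, "label": p.label}
        row.update(zip(cols, seq.values))
        rows.append(row)
    return pd.DataFrame(rows)


def patch_stack(patches: Sequence[ZonePatch]) -> np.ndarray:
    """Pixel stack (n, 32, 32) in patch order."""
    return np.stack([p.pixels for p in patches], axis=0)
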