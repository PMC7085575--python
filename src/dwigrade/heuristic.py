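"""Clinical-heuristics baseline grader.

Clinical practice flags a zone as suspicious when its minimum ADC drops
below 1000 (cancer restricts diffusion) or when its maximum computed
high-b intensity rises above 1000 (cancer is hyperintense at high b). The
corresponding continuous scores normalize those extrema to [0, 1]:

    p_ADC = 1 - min(zone) / M_ADC        p_CHB = max(zone) / M_CHB

where M_ADC is the maximum ADC value (3949 by convention) and M_CHB the
maximum CHB intensity of the dataset. Zone statistics are taken over the
in-mask pixels of the original (pre-resize) zone region, so the out-of-zone
fill cannot corrupt the extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .zoning import ADC_FILL

__all__ = ["HeuristicConfig", "adc_zone_probability", "chb_zone_probability",
           "heuristic_grade"]


@dataclass(frozen=True)
class HeuristicConfig:
    m_adc: float = ADC_FILL     # maximum ADC value, 3949
    m_chb: float = 1000.0       # dataset maximum CHB intensity
    adc_cut: float = 1000.0     # positive iff min ADC strictly below
    chb_cut: float = 1000.0     # positive iff max CHB strictly above

    def __post_init__(self) -> None:
        if self.m_adc <= 0 or self.m_chb <= 0:
            raise ValueError("normalizing maxima must be positive")


def _check_zone(zone_pixels) -> np.ndarray:
    z = np.asarray(zone_pixels, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty zone")
    return z


def adc_zone_probability(zone_pixels, config: HeuristicConfig = HeuristicConfig()) -> float:
    """Estimated cancer probability of an ADC zone: 1 - min/M_ADC."""
    z = _check_zone(zone_pixels)
    return 1.0 - float(z.min()) / config.m_adc


def chb_zone_probability(zone_pixels, config: HeuristicConfig = HeuristicConfig()) -> float:
    """Estimated cancer probability of a CHB zone: max/M_CHB."""
    z = _check_zone(zone_pixels)
    return float(z.max()) / config.m_chb


def heuristic_grade(zone_pixels, modality: str,
                    config: HeuristicConfig = HeuristicConfig()) -> int:
    """Binary grade from the clinical cutoffs (strict inequalities)."""
    z = _check_zone(zone_pixels)
    if modality == "ADC":
        return int(float(z.min()) < config.adc_cut)
    if modality == "CHB":
        return int(float(z.max()) > config.chb_cut)
    raise ValueError(f"unknown modality {modality!r}")
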