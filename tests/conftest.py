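import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))   # for the shared test oracles

from dwigrade.phantom import PhantomConfig, generate_cohort
from dwigrade.zoning import ZonePatch


@pytest.fixture
def make_patch():
    """Factory for ZonePatch objects from a pixel array (full mask default)."""
    def _make(pixels, mask=None, modality="ADC", label=None, zone_values=None):
        pixels = np.asarray(pixels, dtype=float)
        if mask is None:
            mask = np.ones(pixels.shape, dtype=bool)
        if zone_values is None:
            zone_values = pixels[mask]
        return ZonePatch(pixels=pixels, mask=np.asarray(mask, bool),
                         modality=modality, patient_id="T", slice_index=0,
                         zone_id=1, label=label, zone_values=zone_values)
    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with both label classes for pipeline-level tests."""
    config = PhantomConfig(seed=7, image_size=64, slices_per_patient=(2, 3),
                           positive_patient_rate=0.5, positive_zone_rate=0.3)
    cohort = generate_cohort(config, 6)
    assert any(sum(c.labels.values()) > 0 for c in cohort)
    return cohort
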