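"""Seeded synthetic prostate DWI cohort generator.

Emulates the structure of a zone-level prostate DWI study: each synthetic
patient contributes 18–34 coronal slices, each slice carries a schematic
10-zone label map (sectors of an ellipse — region structure, not anatomy),
and each (slice, zone) region has a binary pathology grade. Positive grades
are rare (~1% of zones) and clustered within a subset of "positive"
patients, mirroring how biopsy-verified tumours concentrate in a minority
of a screening cohort.

Signals follow the mono-exponential decay model with zone-dependent ADC
truth: cancerous zones receive a lower mean ADC, so they are dark on ADC
maps and hyperintense on computed high-b images. Within-zone texture is a
multiplicative smoothed-noise field; an optional *texture-only* cancer mode
gives cancerous zones the same mean ADC as healthy tissue but a finer
spatial grain, producing a cohort where min/max intensity heuristics carry
little signal while texture statistics do. Magnitude-MRI noise is Rician by
default (Gaussian offered for estimator unit tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter

from .signal_model import BValueProtocol, MultiBVolume, forward_signal

__all__ = ["PhantomConfig", "PhantomCase", "generate_zone_map", "generate_cohort"]

DEFAULT_B_VALUES = (0.0, 100.0, 400.0, 1000.0)
DEFAULT_CHB_TARGET = 1600.0


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation parameters. ``seed`` fixes all randomness."""

    image_size: int = 96
    slices_per_patient: tuple[int, int] = (18, 34)
    n_zones: int = 10
    healthy_adc: tuple[float, float] = (1.6e-3, 1.5e-4)   # mean, sd in mm^2/s
    cancer_adc: tuple[float, float] = (0.8e-3, 1.0e-4)
    s0: float = 800.0
    noise_model: str = "rician"           # "rician" | "gaussian" | "none"
    noise_sigma: float = 15.0             # intensity units
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    positive_zone_rate: float = 0.026     # per (slice, zone) within positive patients
    positive_patient_rate: float = 0.41
    texture_amplitude: float = 0.08       # relative sd of the multiplicative field
    texture_corr_healthy: float = 3.0     # smoothing sigma, pixels
    texture_corr_cancer: float = 1.0      # used only in texture_only mode
    texture_only: bool = False            # cancer differs in texture, not mean ADC
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.texture_only and self.cancer_adc[0] >= self.healthy_adc[0]:
            raise ValueError("cancer mean ADC must be below healthy mean ADC")
        for r in (self.positive_zone_rate, self.positive_patient_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        lo, hi = self.slices_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("invalid slices_per_patient range")

    @property
    def protocol(self) -> BValueProtocol:
        return BValueProtocol(self.b_values)


@dataclass
class PhantomCase:
    """One synthetic patient: per-slice multi-b volumes, zone maps, labels."""

    patient_id: str
    volumes: list[MultiBVolume]            # one per slice
    zone_maps: list[np.ndarray]            # int labels, 0 = background
    labels: dict[tuple[int, int], int]     # (slice_index, zone_id) -> 0/1
    is_positive: bool
    adc_truth: list[np.ndarray] = field(default_factory=list)  # per-slice D, mm^2/s

    @property
    def n_slices(self) -> int:
        return len(self.volumes)

    def label_rows(self) -> Iterable[tuple[str, int, int, int]]:
        for (s, z), y in sorted(self.labels.items()):
            yield self.patient_id, s, z, y


def generate_zone_map(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Partition an elliptical 'prostate' into ``n_zones`` contiguous sectors.

    Up to 5 zones: one angular ring. More: two concentric rings split at
    equal area, inner ``n_zones // 2`` sectors, outer the rest. Geometry is
    jittered (center, axes, rotation) per call from ``rng``.
    """
    n = config.image_size
    if config.n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    cy = n / 2 + rng.uniform(-0.03, 0.03) * n
    cx = n / 2 + rng.uniform(-0.03, 0.03) * n
    ay = n * rng.uniform(0.34, 0.40)          # semi-axes
    ax = n * rng.uniform(0.30, 0.36)
    phi = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - cy, xx - cx
    ry = (dy * np.cos(phi) + dx * np.sin(phi)) / ay
    rx = (-dy * np.sin(phi) + dx * np.cos(phi)) / ax
    r2 = ry**2 + rx**2
    inside = r2 <= 1.0
    theta = np.mod(np.arctan2(ry, rx), 2 * np.pi)

    labels = np.zeros((n, n), dtype=np.int32)
    if config.n_zones <= 5:
        n_inner, n_outer = 0, config.n_zones
    else:
        n_inner = config.n_zones // 2
        n_outer = config.n_zones - n_inner
    inner = inside & (r2 <= 0.5) if n_inner else np.zeros_like(inside)
    outer = inside & ~inner
    if n_inner:
        sector = np.minimum((theta / (2 * np.pi) * n_inner).astype(int), n_inner - 1)
        labels[inner] = 1 + sector[inner]
    sector = np.minimum((theta / (2 * np.pi) * n_outer).astype(int), n_outer - 1)
    labels[outer] = 1 + n_inner + sector[outer]

    present = np.unique(labels[labels > 0])
    if len(present) != config.n_zones:
        raise ValueError(
            f"image size {n} too small to host {config.n_zones} nonempty zones")
    return labels


def _texture_field(shape, amplitude, corr_sigma, rng):
    """Multiplicative field 1 + amplitude * (smoothed unit-variance noise)."""
    g = gaussian_filter(rng.standard_normal(shape), corr_sigma)
    sd = g.std()
    if sd > 0:
        g /= sd
    return np.clip(1.0 + amplitude * g, 0.05, None)


def _add_noise(signal, config, rng):
    if config.noise_model == "none" or config.noise_sigma == 0:
        return signal
    n1 = rng.normal(0.0, config.noise_sigma, signal.shape)
    if config.noise_model == "gaussian":
        return np.clip(signal + n1, 0.0, None)
    n2 = rng.normal(0.0, config.noise_sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def generate_cohort(config: PhantomConfig, n_patients: int) -> list[PhantomCase]:
    """Simulate ``n_patients`` cases under ``config``; fully seeded."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(config.seed)
    b = np.asarray(config.b_values)
    cases: list[PhantomCase] = []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        positive_patient = bool(rng.random() < config.positive_patient_rate)
        zone_map = generate_zone_map(config, rng)
        zone_masks = {z: zone_map == z for z in range(1, config.n_zones + 1)}
        n_slices = int(rng.integers(config.slices_per_patient[0],
                                    config.slices_per_patient[1] + 1))
        volumes, zone_maps, adc_truth = [], [], []
        labels: dict[tuple[int, int], int] = {}
        for s in range(n_slices):
            d_map = np.full(zone_map.shape, config.healthy_adc[0])
            s0_map = config.s0 * _texture_field(
                zone_map.shape, config.texture_amplitude / 2,
                config.texture_corr_healthy, rng)
            s0_map[zone_map == 0] *= 0.5      # darker background
            for z, mask in zone_masks.items():
                y = int(positive_patient and rng.random() < config.positive_zone_rate)
                labels[(s, z)] = y
                if y and not config.texture_only:
                    mean = max(rng.normal(*config.cancer_adc), 1e-5)
                    corr = config.texture_corr_healthy
                elif y:       # texture-only: same mean ADC, finer grain
                    mean = max(rng.normal(*config.healthy_adc), 1e-5)
                    corr = config.texture_corr_cancer
                else:
                    mean = max(rng.normal(*config.healthy_adc), 1e-5)
                    corr = config.texture_corr_healthy
                tex = _texture_field(zone_map.shape, config.texture_amplitude,
                                     corr, rng)
                d_map[mask] = mean * tex[mask]
            signals = [_add_noise(forward_signal(s0_map, d_map, bi), config, rng)
                       for bi in b]
            volumes.append(MultiBVolume(signals=signals, protocol=config.protocol))
            zone_maps.append(zone_map)
            adc_truth.append(d_map)
        cases.append(PhantomCase(patient_id=pid, volumes=volumes,
                                 zone_maps=zone_maps, labels=labels,
                                 is_positive=positive_patient,
                                 adc_truth=adc_truth))
    return cases
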