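"""Cohort persistence: NIfTI volumes and label maps, CSV label tables.

Layout of a cohort directory::

    cohort/
      config.json                  # generator config snapshot + seed
      labels.csv                   # patient_id, slice_index, zone_id, label
      P0000_dwi.nii                # (H, W, n_slices, n_b) multi-b volume
      P0000_dwi.json               # sidecar: b_values in acquisition order
      P0000_zones.nii              # (H, W, n_slices) integer zone labels

Slices are taken along the third stored axis (the coronal stack axis).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomCase, PhantomConfig
from .signal_model import BValueProtocol, MultiBVolume
from .zoning import ZonePatch

__all__ = ["save_cohort", "load_cohort", "save_patches", "load_patches"]


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data), np.eye(4))


def save_cohort(cohort: Sequence[PhantomCase], config: PhantomConfig,
                outdir: str | Path, force: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_path = outdir / "config.json"
    if cfg_path.exists() and not force:
        raise FileExistsError(f"{cfg_path} exists; pass force=True to overwrite")
    cfg_path.write_text(json.dumps(dataclasses.asdict(config), indent=2))

    rows = []
    for case in cohort:
        vol = np.stack([v.stack() for v in case.volumes], axis=-1)  # (B,H,W,S)
        vol = np.transpose(vol, (1, 2, 3, 0))                       # (H,W,S,B)
        nib.save(_nifti(vol.astype(np.float64)), str(outdir / f"{case.patient_id}_dwi.nii"))
        (outdir / f"{case.patient_id}_dwi.json").write_text(
            json.dumps({"b_values": list(case.volumes[0].protocol.b_values)}))
        zmaps = np.stack(case.zone_maps, axis=-1).astype(np.int16)
        nib.save(_nifti(zmaps), str(outdir / f"{case.patient_id}_zones.nii"))
        rows.extend(case.label_rows())
    pd.DataFrame(rows, columns=["patient_id", "slice_index", "zone_id", "label"]) \
        .to_csv(outdir / "labels.csv", index=False)


def load_cohort(outdir: str | Path) -> tuple[list[PhantomCase], dict]:
    outdir = Path(outdir)
    cfg_path = outdir / "config.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"no cohort at {outdir}: missing {cfg_path}")
    config = json.loads(cfg_path.read_text())
    labels = pd.read_csv(outdir / "labels.csv")
    cases = []
    for pid, sub in labels.groupby("patient_id", sort=True):
        data = np.asarray(nib.load(str(outdir / f"{pid}_dwi.nii")).dataobj)
        b_values = json.loads((outdir / f"{pid}_dwi.json").read_text())["b_values"]
        zmaps = np.asarray(nib.load(str(outdir / f"{pid}_zones.nii")).dataobj)
        protocol = BValueProtocol(b_values)
        volumes = [MultiBVolume(signals=[data[:, :, s, i] for i in range(len(b_values))],
                                protocol=protocol)
                   for s in range(data.shape[2])]
        zone_maps = [zmaps[:, :, s].astype(np.int32) for s in range(zmaps.shape[2])]
        lab = {(int(r.slice_index), int(r.zone_id)): int(r.label)
               for r in sub.itertuples()}
        cases.append(PhantomCase(patient_id=str(pid), volumes=volumes,
                                 zone_maps=zone_maps, labels=lab,
                                 is_positive=bool(sub.label.any())))
    return cases, config


def save_patches(patches: Sequence[ZonePatch], path_prefix: str | Path,
                 force: bool = False) -> tuple[Path, Path]:
    """Write a patch stack (.npz) and its CSV manifest; returns both paths."""
    prefix = Path(path_prefix)
    stack_path = prefix.with_suffix(".npz")
    manifest_path = prefix.parent / (prefix.name + "_manifest.csv")
    if stack_path.exists() and not force:
        raise FileExistsError(f"{stack_path} exists; use force to overwrite")
    np.savez_compressed(stack_path,
                        pixels=np.stack([p.pixels for p in patches]),
                        mask=np.stack([p.mask for p in patches]))
    pd.DataFrame([{
        "patient_id": p.patient_id, "slice_index": p.slice_index,
        "zone_id": p.zone_id, "modality": p.modality,
        "label": -1 if p.label is None else p.label,
        "zone_min": float(np.min(p.zone_values)),
        "zone_max": float(np.max(p.zone_values)),
    } for p in patches]).to_csv(manifest_path, index=False)
    return stack_path, manifest_path


def load_patches(path_prefix: str | Path) -> list[ZonePatch]:
    prefix = Path(path_prefix)
    with np.load(prefix.with_suffix(".npz")) as data:
        pixels, mask = data["pixels"], data["mask"]
    manifest = pd.read_csv(prefix.parent / (prefix.name + "_manifest.csv"))
    patches = []
    for i, r in enumerate(manifest.itertuples()):
        patches.append(ZonePatch(
            pixels=pixels[i], mask=mask[i].astype(bool), modality=str(r.modality),
            patient_id=str(r.patient_id), slice_index=int(r.slice_index),
            zone_id=int(r.zone_id), label=None if r.label < 0 else int(r.label),
            zone_values=np.array([r.zone_min, r.zone_max])))
    return patches
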