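"""Per-region dual-energy statistics and per-patient feature assembly.

For every region (tumor, layers, VOIs) the pipeline reports:

``mean_hu``
    mean mixed-energy attenuation over the region;
``total_ic``
    mean iodine concentration (mg/mL) over all region voxels;
``vital_ic``
    mean iodine concentration over the *enhancing* voxels only, defined as
    voxels with iodine above a configurable vital threshold (default
    0.5 mg/mL); zero if no voxel enhances;
``nic``
    normalized iodine concentration: ``vital_ic`` divided by the mean
    aortic iodine concentration, removing inter-patient variation in
    contrast dose and timing;
``hu_ratio``
    region mean HU over normal-parenchyma mean HU (ratio > 1 for
    hyper-enhancing regions; the orientation is recorded here once).

Empty regions yield missing statistics (NaN), never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import (
    EmptyRegionError,
    NormalizationError,
    ParenchymaUndefinedError,
    ValidationError,
)
from .layers import RegionSet


@dataclass
class RegionStats:
    region_name: str
    n_voxels: int
    volume_ml: float
    mean_hu: float
    total_ic: float
    vital_ic: float
    nic: float
    iodine_mass_mg: float
    hu_ratio: float  # region mean HU / parenchyma mean HU
    missing: bool = False

    def to_dict(self):
        return asdict(self)


def _missing_stats(name: str) -> RegionStats:
    nan = float("nan")
    return RegionStats(region_name=name, n_voxels=0, volume_ml=0.0,
                       mean_hu=nan, total_ic=nan, vital_ic=nan, nic=nan,
                       iodine_mass_mg=nan, hu_ratio=nan, missing=True)


def region_stats(
    name: str,
    mask: np.ndarray,
    mixed: np.ndarray,
    iodine: np.ndarray,
    aorta_ic: float,
    spacing,
    parenchyma: np.ndarray | None = None,
    vital_threshold: float = 0.5,
) -> RegionStats:
    """First-order dual-energy statistics of one region."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(mixed).shape or mask.shape != np.asarray(iodine).shape:
        raise ValidationError("region mask and images are on different grids")
    if aorta_ic <= 0:
        raise NormalizationError(f"aortic iodine must be positive, got {aorta_ic}")
    if not mask.any():
        return _missing_stats(name)

    voxel_volume_ml = float(np.prod(spacing)) / 1000.0
    n = int(mask.sum())
    mean_hu = float(np.asarray(mixed, dtype=float)[mask].mean())
    region_iodine = np.asarray(iodine, dtype=float)[mask]
    total_ic = float(region_iodine.mean())
    vital = region_iodine[region_iodine > vital_threshold]
    vital_ic = float(vital.mean()) if vital.size else 0.0
    nic = vital_ic / aorta_ic

    hu_ratio = float("nan")
    if parenchyma is not None:
        parenchyma = np.asarray(parenchyma, dtype=bool)
        if parenchyma.any():
            hu_ratio = mean_hu / float(np.asarray(mixed, dtype=float)[parenchyma].mean())

    return RegionStats(
        region_name=name, n_voxels=n, volume_ml=n * voxel_volume_ml,
        mean_hu=mean_hu, total_ic=total_ic, vital_ic=vital_ic, nic=nic,
        iodine_mass_mg=total_ic * n * voxel_volume_ml, hu_ratio=hu_ratio,
    )


def parenchyma_mask(
    liver: np.ndarray,
    tumor: np.ndarray,
    outer_layers=(),
    exclusion: np.ndarray | None = None,
) -> np.ndarray:
    """Normal liver parenchyma: liver minus tumor, outer layers and exclusions."""
    liver = np.asarray(liver, dtype=bool)
    out = liver & ~np.asarray(tumor, dtype=bool)
    for layer in outer_layers:
        out &= ~np.asarray(layer, dtype=bool)
    if exclusion is not None:
        out &= ~np.asarray(exclusion, dtype=bool)
    if not out.any():
        raise ParenchymaUndefinedError(
            "no liver parenchyma remains outside tumor, layers and exclusions"
        )
    return out


def region_set_stats(
    regions: RegionSet,
    mixed: np.ndarray,
    iodine: np.ndarray,
    aorta_ic: float,
    spacing,
    parenchyma: np.ndarray,
    vital_threshold: float = 0.5,
):
    """``region_stats`` for every region of a peeled RegionSet."""
    return [
        region_stats(name, mask, mixed, iodine, aorta_ic, spacing,
                     parenchyma=parenchyma, vital_threshold=vital_threshold)
        for name, mask in regions.regions()
    ]


_ROW_METRICS = ("nic", "mean_hu", "total_ic", "vital_ic", "hu_ratio")


def patient_features(
    stats_by_thickness: dict,
    qualitative: dict | None = None,
    patient_id: str | None = None,
    extra: dict | None = None,
) -> dict:
    """Flatten per-region statistics into one feature row.

    ``stats_by_thickness`` maps a layer thickness in mm to a list of
    RegionStats; columns are named ``{metric}_{region}_{thickness}mm``
    (e.g. ``nic_outer1_2mm``). Missing regions yield NaN cells; the row is
    retained. Optional qualitative flags (e.g. ``peritumoral_enhancement``,
    ``nonsmooth_margin``) are appended verbatim.
    """
    row: dict = {}
    if patient_id is not None:
        row["patient_id"] = patient_id
    for thickness, stats in stats_by_thickness.items():
        names = [s.region_name for s in stats]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate region names: {sorted(names)}")
        tkey = f"{thickness:g}mm"
        for s in stats:
            for metric in _ROW_METRICS:
                row[f"{metric}_{s.region_name}_{tkey}"] = getattr(s, metric)
    if qualitative:
        row.update(qualitative)
    if extra:
        row.update(extra)
    return row


def classify_nic(nic: float, cutoff: float) -> int:
    """Dichotomize an NIC value at a cutoff (1 = predicted MVI-positive)."""
    if math.isnan(nic):
        raise ValidationError("cannot classify a missing NIC value")
    return int(nic > cutoff)
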