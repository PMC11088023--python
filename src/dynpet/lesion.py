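"""SUV computation, threshold lesion segmentation, per-lesion records.

SUV normalises tissue activity by injected dose per body weight and is
unitless.  Lesions are segmented semi-automatically: the connected set of
voxels (26-neighbourhood) above 40% of the lesion's hottest voxel, grown
from that local maximum.  The segmented volume of interest (VOI) is then
applied to the K1/k2/k3/Ki parametric maps to extract the per-lesion
quantitative measurements fed to the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .framing import ValidationError
from .kinetics import ParametricMaps

__all__ = [
    "LesionRecord",
    "VOIMask",
    "suv_volume",
    "segment_lesion",
    "extract_lesion_record",
    "COHORT_COLUMNS",
]

MALIGNANCY = {"benign", "malignant"}
HISTOLOGY = {"AC", "SCC", "other", "none"}
EGFR = {"positive", "negative", "untested"}

#: column order of exported cohort CSVs
COHORT_COLUMNS = [
    "lesion_id",
    "suv_max",
    "k1",
    "k2",
    "k3",
    "ki",
    "malignancy",
    "histology",
    "egfr",
    "long_diameter_cm",
    "short_diameter_cm",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class LesionRecord:
    """Per-lesion quantitative measurements and class labels.

    ``ki`` is the VOI summary of the Ki map; note that for VOI-averaged map
    values ki == k1*k3/(k2+k3) does NOT hold exactly (the mean of a ratio
    is not the ratio of means) — the identity is guaranteed only for fits
    of a single TAC.
    """

    lesion_id: str
    suv_max: float
    k1: float
    k2: float
    k3: float
    ki: float
    malignancy: str = "malignant"
    histology: str = "none"
    egfr: str = "untested"
    long_diameter_cm: float | None = None
    short_diameter_cm: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.suv_max < 0 or min(self.k1, self.k2, self.k3, self.ki) < 0:
            raise ValidationError("SUVmax and kinetic fields must be non-negative")
        if self.malignancy not in MALIGNANCY:
            raise ValidationError(f"malignancy must be one of {sorted(MALIGNANCY)}")
        if self.histology not in HISTOLOGY:
            raise ValidationError(f"histology must be one of {sorted(HISTOLOGY)}")
        if self.egfr not in EGFR:
            raise ValidationError(f"egfr must be one of {sorted(EGFR)}")

    def as_row(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "suv_max": self.suv_max,
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
            "ki": self.ki,
            "malignancy": self.malignancy,
            "histology": self.histology,
            "egfr": self.egfr,
            "long_diameter_cm": self.long_diameter_cm,
            "short_diameter_cm": self.short_diameter_cm,
        }


@dataclass
class VOIMask:
    """Single connected 3D lesion mask with segmentation provenance."""

    mask: np.ndarray
    threshold_fraction: float
    seed: tuple[int, int, int]
    touches_boundary: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValidationError("VOI mask is empty")
        n_comp = ndimage.label(self.mask, structure=_STRUCT_26)[1]
        if n_comp != 1:
            raise ValidationError(f"VOI mask must be a single connected component, got {n_comp}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def suv_volume(activity: np.ndarray, dose_MBq: float | None, weight_kg: float | None) -> np.ndarray:
    """Body-weight SUV: activity [kBq/ml] / (dose [kBq] / weight [g]).

    With dose in MBq and weight in kg the normaliser is dose*1000/(weight*1000)
    kBq/g, i.e. SUV = activity * weight_kg / (dose_MBq * 1000) * 1000.
    """
    if dose_MBq is None or weight_kg is None:
        raise ValidationError(
            "SUV requires injected_dose_MBq and body_weight_kg; one or both are missing"
        )
    if dose_MBq <= 0 or weight_kg <= 0:
        raise ValidationError("dose and weight must be positive")
    dose_per_gram = dose_MBq * 1000.0 / (weight_kg * 1000.0)  # kBq/g
    return np.asarray(activity, dtype=float) / dose_per_gram


def segment_lesion(
    suv: np.ndarray,
    seed: tuple[int, int, int] | None = None,
    bbox: tuple[slice, slice, slice] | None = None,
    fraction: float = 0.40,
) -> VOIMask:
    """Relative-threshold lesion segmentation around a seed or bounding box.

    Finds the local maximum M inside ``bbox`` (or at/around ``seed``; a
    seed is dilated to a 3-voxel-halfwidth search box), then returns the
    26-connected component containing that maximum among voxels with
    value >= fraction*M.  A component touching the search-region boundary
    is flagged (possible spill into adjacent structures), not rejected.
    """
    suv = np.asarray(suv, dtype=float)
    if suv.ndim != 3:
        raise ValidationError("segment_lesion expects a 3D volume")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie in (0, 1)")
    if bbox is None:
        if seed is None:
            raise ValidationError("provide a seed voxel or a bounding box")
        if not all(0 <= seed[a] < suv.shape[a] for a in range(3)):
            raise ValidationError("seed outside the image grid")
        bbox = tuple(
            slice(max(0, seed[a] - 3), min(suv.shape[a], seed[a] + 4)) for a in range(3)
        )
    region = suv[bbox]
    if region.size == 0:
        raise ValidationError("bounding box outside the image grid")
    if not np.any(region > 0):
        raise ValidationError("segmentation region contains no positive values")
    # lowest linear index wins ties -> deterministic
    local = np.unravel_index(int(np.argmax(region)), region.shape)
    offset = tuple(sl.start or 0 for sl in bbox)
    peak = tuple(local[a] + offset[a] for a in range(3))
    m = float(suv[peak])
    above = suv >= fraction * m
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    mask = labels == labels[peak]
    touches = _touches_bbox_boundary(mask, bbox, suv.shape)
    return VOIMask(mask=mask, threshold_fraction=fraction, seed=peak, touches_boundary=touches)


def _touches_bbox_boundary(mask, bbox, shape) -> bool:
    for a in range(3):
        lo = bbox[a].start or 0
        hi = bbox[a].stop if bbox[a].stop is not None else shape[a]
        idx = np.where(mask.any(axis=tuple(b for b in range(3) if b != a)))[0]
        if idx.size and (idx.min() <= lo or idx.max() >= hi - 1):
            if 0 < lo or hi < shape[a]:  # only meaningful if bbox is interior
                return True
    return False


def extract_lesion_record(
    maps: ParametricMaps,
    suv: np.ndarray,
    voi: VOIMask,
    labels: dict | None = None,
    lesion_id: str = "lesion",
) -> LesionRecord:
    """Summarise SUV and kinetic maps inside a lesion VOI.

    suv_max is the hottest voxel in the VOI; kinetic fields are VOI means
    of the parametric maps (the primary summary; medians are retained in
    ``extras`` for sensitivity analysis).
    """
    suv = np.asarray(suv, dtype=float)
    if suv.shape != voi.mask.shape or maps.k1_map.shape != voi.mask.shape:
        raise ValidationError("SUV volume, parametric maps and VOI must share one grid")
    m = voi.mask
    labels = labels or {}
    medians = {
        "k1_median": float(np.median(maps.k1_map[m])),
        "k2_median": float(np.median(maps.k2_map[m])),
        "k3_median": float(np.median(maps.k3_map[m])),
        "ki_median": float(np.median(maps.ki_map[m])),
        "n_voxels": voi.n_voxels,
    }
    return LesionRecord(
        lesion_id=lesion_id,
        suv_max=float(suv[m].max()),
        k1=float(maps.k1_map[m].mean()),
        k2=float(maps.k2_map[m].mean()),
        k3=float(maps.k3_map[m].mean()),
        ki=float(maps.ki_map[m].mean()),
        malignancy=labels.get("malignancy", "malignant"),
        histology=labels.get("histology", "none"),
        egfr=labels.get("egfr", "untested"),
        long_diameter_cm=labels.get("long_diameter_cm"),
        short_diameter_cm=labels.get("short_diameter_cm"),
        extras=medians,
    )
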