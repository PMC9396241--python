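"""Zonal quantification of en-face OCT biomarker thickness maps.

The input to this module is a set of 2D en-face thickness maps (one per
biomarker, values in micrometres) on a fovea-centred 6 x 6 mm grid, as
produced by upstream retinal layer/fluid segmentation.  Five biomarkers are
handled: intraretinal fluid (IRF), subretinal fluid (SRF), pigment epithelial
detachment (PED), hyperreflective foci (HRF), and the photoreceptor (PR)
layer.  Maps are resampled to a canonical isotropic analysis grid, divided
into the three concentric ETDRS regions (central 1 mm disc, 1-3 mm
parafoveal ring, 3-6 mm perifoveal ring), and summarised per zone: fluid
compartments and HRF as volumes in nanolitres, PR as mean thickness in µm.

Two visits (baseline M0 and the 4-week follow-up M1) plus their difference
yield 5 biomarkers x 3 zones x 3 time blocks = 45 imaging features; with
BCVA at both visits, its change, age and sex the predictor vector has
exactly 50 entries in a fixed, documented order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import ContractError, MissingDataError

FLUID_BIOMARKERS: Tuple[str, ...] = ("IRF", "SRF", "PED", "HRF")
BIOMARKERS: Tuple[str, ...] = FLUID_BIOMARKERS + ("PR",)
ZONES: Tuple[str, ...] = ("central_1mm", "para_1_3mm", "peri_3_6mm")
#: half-open radial bands [r_lo, r_hi) in mm from the grid centre
ZONE_RADII_MM: Dict[str, Tuple[float, float]] = {
    "central_1mm": (0.0, 0.5),
    "para_1_3mm": (0.5, 1.5),
    "peri_3_6mm": (1.5, 3.0),
}
TIME_BLOCKS: Tuple[str, ...] = ("M0", "M1", "change")
EXTENT_MM: Tuple[float, float] = (6.0, 6.0)
#: canonical isotropic analysis grid (rows, cols) over the 6 x 6 mm extent
CANONICAL_SHAPE: Tuple[int, int] = (128, 128)

N_IMAGING_FEATURES = len(BIOMARKERS) * len(ZONES) * len(TIME_BLOCKS)
CLINICAL_FEATURES: Tuple[str, ...] = ("bcva_M0", "bcva_M1", "bcva_change", "age", "sex")
N_FEATURES = N_IMAGING_FEATURES + len(CLINICAL_FEATURES)


def feature_names() -> Tuple[str, ...]:
    """Fixed predictor ordering: time-block major, biomarker, zone; then clinical."""
    imaging = tuple(
        f"{b}_{z}_{t}" for t in TIME_BLOCKS for b in BIOMARKERS for z in ZONES
    )
    return imaging + CLINICAL_FEATURES


@dataclass
class EnFaceMapSet:
    """Per-eye, per-visit stack of the five biomarker thickness maps (µm)."""

    eye_id: str
    visit_label: str  # "M0" or "M1"
    maps: Dict[str, np.ndarray]
    extent_mm: Tuple[float, float] = EXTENT_MM

    def __post_init__(self) -> None:
        missing = [b for b in BIOMARKERS if b not in self.maps]
        if missing:
            raise MissingDataError(f"map set {self.eye_id}/{self.visit_label} lacks {missing}")
        shapes = {self.maps[b].shape for b in BIOMARKERS}
        if len(shapes) != 1:
            raise ContractError(f"inconsistent map shapes: {shapes}")
        for b in BIOMARKERS:
            m = np.asarray(self.maps[b], dtype=float)
            if not np.all(np.isfinite(m)) or np.any(m < 0):
                raise ContractError(f"{b} map must be finite and non-negative")
            self.maps[b] = m

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.maps[BIOMARKERS[0]].shape


@dataclass
class ZonalFeatures:
    """Per-visit zonal summaries: (biomarker, zone) -> value.

    Units are nanolitres for IRF/SRF/PED/HRF and micrometres for PR.
    """

    eye_id: str
    visit_label: str  # "M0", "M1" or "change"
    values: Dict[Tuple[str, str], float]

    def __post_init__(self) -> None:
        expected = {(b, z) for b in BIOMARKERS for z in ZONES}
        if set(self.values) != expected:
            raise MissingDataError(
                f"zonal features for {self.eye_id}/{self.visit_label} must have "
                f"exactly {len(expected)} (biomarker, zone) entries"
            )


@dataclass
class FeatureVector:
    """The ordered 50-element predictor vector for one eye."""

    eye_id: str
    values: np.ndarray
    names: Tuple[str, ...] = field(default_factory=feature_names)
    label_extendable: Optional[bool] = None
    label_responder: Optional[bool] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ContractError(f"feature vector must have length {N_FEATURES}")
        if len(self.names) != N_FEATURES:
            raise ContractError("names/values length mismatch")


def pixel_centers(n: int, extent: float) -> np.ndarray:
    """Coordinates (mm) of pixel centres along one axis of length ``extent``."""
    return (np.arange(n) + 0.5) * (extent / n)


def pixel_area_mm2(rows: int, cols: int, extent_mm: Tuple[float, float] = EXTENT_MM) -> float:
    return (extent_mm[0] / rows) * (extent_mm[1] / cols)


def resample_map(
    arr: np.ndarray,
    target_rows: int,
    target_cols: int,
    extent_mm: Tuple[float, float] = EXTENT_MM,
) -> np.ndarray:
    """Bilinear resampling on pixel-centre coordinates over a fixed extent.

    Source and target grids span the same physical 6 x 6 mm field; target
    pixel centres outside the source-centre bounding box are clamped to the
    edge, so constant fields are preserved exactly.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ContractError("source map must be at least 2x2")
    if target_rows < 1 or target_cols < 1:
        raise ContractError("target shape must be positive")
    ry = pixel_centers(arr.shape[0], extent_mm[0])
    rx = pixel_centers(arr.shape[1], extent_mm[1])
    ty = np.clip(pixel_centers(target_rows, extent_mm[0]), ry[0], ry[-1])
    tx = np.clip(pixel_centers(target_cols, extent_mm[1]), rx[0], rx[-1])
    interp = RegularGridInterpolator((ry, rx), arr, method="linear")
    yy, xx = np.meshgrid(ty, tx, indexing="ij")
    out = interp(np.column_stack([yy.ravel(), xx.ravel()]))
    return out.reshape(target_rows, target_cols)


def etdrs_zone_masks(
    rows: int, cols: int, extent_mm: Tuple[float, float] = EXTENT_MM
) -> Dict[str, np.ndarray]:
    """Boolean masks for the three ETDRS zones on a rows x cols grid.

    A pixel belongs to a zone iff the Euclidean distance of its centre from
    the geometric grid centre falls in the zone's half-open radial band.
    Pixels at 3 mm or farther belong to no zone; masks are pairwise disjoint.
    """
    if extent_mm[0] <= 0 or extent_mm[1] <= 0:
        raise ContractError("extent must be positive")
    if rows < 8 or cols < 8:
        raise ContractError("grid must be at least 8x8")
    cy, cx = extent_mm[0] / 2.0, extent_mm[1] / 2.0
    yy = pixel_centers(rows, extent_mm[0])[:, None] - cy
    xx = pixel_centers(cols, extent_mm[1])[None, :] - cx
    d = np.hypot(yy, xx)
    return {z: (d >= lo) & (d < hi) for z, (lo, hi) in ZONE_RADII_MM.items()}


def zonal_volume(map_um: np.ndarray, mask: np.ndarray, pixel_area_mm2: float) -> float:
    """Volume (nl) of a thickness map (µm) over a mask.

    thickness_µm x area_mm² x 1e-3 mm/µm gives mm³; 1 mm³ = 1000 nl, so the
    conversion factors cancel and the volume in nl is numerically
    sum(thickness_µm) x pixel_area_mm².
    """
    map_um = np.asarray(map_um, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if map_um.shape != mask.shape:
        raise ContractError("map and mask shapes differ")
    return float(map_um[mask].sum() * pixel_area_mm2)


def zonal_mean_thickness(map_um: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean thickness (µm) of masked pixels."""
    map_um = np.asarray(map_um, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if map_um.shape != mask.shape:
        raise ContractError("map and mask shapes differ")
    if not mask.any():
        raise ContractError("mask is empty")
    return float(map_um[mask].mean())


def compute_zonal_features(
    mapset: EnFaceMapSet, canonical_shape: Tuple[int, int] = CANONICAL_SHAPE
) -> ZonalFeatures:
    """Resample all maps to the canonical grid and summarise per ETDRS zone."""
    rows, cols = canonical_shape
    masks = etdrs_zone_masks(rows, cols, mapset.extent_mm)
    area = pixel_area_mm2(rows, cols, mapset.extent_mm)
    values: Dict[Tuple[str, str], float] = {}
    for b in BIOMARKERS:
        m = mapset.maps[b]
        if m.shape != (rows, cols):
            m = resample_map(m, rows, cols, mapset.extent_mm)
        for z in ZONES:
            if b == "PR":
                values[(b, z)] = zonal_mean_thickness(m, masks[z])
            else:
                values[(b, z)] = zonal_volume(m, masks[z], area)
    return ZonalFeatures(eye_id=mapset.eye_id, visit_label=mapset.visit_label, values=values)


def change_features(m0: ZonalFeatures, m1: ZonalFeatures) -> ZonalFeatures:
    """Follow-up minus baseline, computed on zonal aggregates.

    By linearity of the zonal integrals this equals aggregating the
    pixel-wise difference maps.
    """
    if m0.eye_id != m1.eye_id:
        raise ContractError(f"eye mismatch: {m0.eye_id} vs {m1.eye_id}")
    if (m0.visit_label, m1.visit_label) != ("M0", "M1"):
        raise ContractError("change_features expects visit labels M0 and M1")
    values = {k: m1.values[k] - m0.values[k] for k in m0.values}
    return ZonalFeatures(eye_id=m0.eye_id, visit_label="change", values=values)


def encode_sex(sex) -> float:
    """female=1, male=0 (arbitrary but fixed; inert for tree models)."""
    if isinstance(sex, str):
        s = sex.lower()
        if s not in ("female", "male"):
            raise ContractError(f"unrecognised sex {sex!r}")
        return 1.0 if s == "female" else 0.0
    v = float(sex)
    if v not in (0.0, 1.0):
        raise ContractError("numeric sex must be 0 or 1")
    return v


def assemble_feature_vector(
    m0: ZonalFeatures,
    m1: ZonalFeatures,
    change: ZonalFeatures,
    bcva_m0: float,
    bcva_m1: float,
    age: float,
    sex,
) -> FeatureVector:
    """Assemble the 50-dimensional predictor in the fixed documented order."""
    blocks = {"M0": m0, "M1": m1, "change": change}
    for label, zf in blocks.items():
        if zf.visit_label != label:
            raise ContractError(f"expected visit label {label}, got {zf.visit_label}")
        if zf.eye_id != m0.eye_id:
            raise ContractError("zonal feature blocks belong to different eyes")
    vals = []
    for t in TIME_BLOCKS:
        zf = blocks[t]
        for b in BIOMARKERS:
            for z in ZONES:
                v = zf.values.get((b, z))
                if v is None or not np.isfinite(v):
                    raise MissingDataError(f"missing imaging feature {b}/{z}/{t} for {m0.eye_id}")
                vals.append(float(v))
    for v, name in ((bcva_m0, "bcva_M0"), (bcva_m1, "bcva_M1"), (age, "age")):
        if v is None or not np.isfinite(float(v)):
            raise MissingDataError(f"missing clinical value {name} for {m0.eye_id}")
    vals += [float(bcva_m0), float(bcva_m1), float(bcva_m1) - float(bcva_m0),
             float(age), encode_sex(sex)]
    return FeatureVector(eye_id=m0.eye_id, values=np.array(vals))


def feature_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame indexed by eye_id."""
    vectors = list(vectors)
    if not vectors:
        raise ContractError("no feature vectors")
    names = vectors[0].names
    rows = {fv.eye_id: fv.values for fv in vectors}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(names)).rename_axis("eye_id")


def write_feature_table(df: pd.DataFrame, csv_path, schema_path=None) -> None:
    """Write the feature table with a sidecar schema (names, units, order)."""
    df.to_csv(csv_path)
    if schema_path is not None:
        units = {}
        for name in df.columns:
            if name.startswith("PR_"):
                units[name] = "um"
            elif name.startswith(tuple(f"{b}_" for b in FLUID_BIOMARKERS)):
                units[name] = "nl"
            elif name.startswith("bcva"):
                units[name] = "letters"
            elif name == "age":
                units[name] = "years"
            else:
                units[name] = "binary (female=1)"
        schema = {"columns": list(df.columns), "units": units}
        with open(schema_path, "w") as fh:
            json.dump(schema, fh, indent=2)


def read_feature_table(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path, index_col="eye_id")
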