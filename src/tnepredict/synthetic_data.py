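"""Seeded synthetic nAMD treat-and-extend cohorts.

Real inputs to this pipeline (per-visit en-face biomarker thickness maps,
BCVA, injection records, demographics from a treat-and-extend trial arm) are
not publicly available, so this module generates cohorts with the same data
structure and the qualitative disease kinetics the downstream stages assume:

* a loading phase of two consecutive monthly injections;
* per-injection multiplicative fluid clearance with IRF resolving fastest,
  SRF more slowly, and PED responding only partially and persisting at a
  strictly positive floor;
* Bernoulli per-week fluid recurrence between visits, with the hazard
  coupled to SRF retention so that persistent SRF drives non-extendability;
* latent-class-structured quadratic BCVA trajectories forming responder and
  non-responder shapes at high and low baseline acuity strata;
* two scanner grid resolutions (49x768 and 128x512 maps) for the en-face
  rendering, which downstream code resamples to a canonical grid.

Every random draw descends from ``(config.seed, crc32(eye_id))`` so cohorts
are bit-reproducible and stable under eye reordering.  Ground-truth state
(latent class, retention factors, hazards) is retained on each ``EyeState``
and exportable for recovery tests.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from . import oct_features as of

WEEKS_PER_MONTH = 52.0 / 12.0

GRID_SHAPES: Dict[str, Tuple[int, int]] = {
    "grid_49x768": (49, 768),
    "grid_128x512": (128, 512),
}

#: printed latent-class sizes of the six BCVA trajectory groups, used as the
#: default mixing proportions of the generator (sizes 4,173,58,12,15,8 of 270)
DEFAULT_CLASS_SIZES = (4, 173, 58, 12, 15, 8)

#: default class quadratics (letters vs months): responder shapes (classes 2
#: and 5, 12-month gain >= +5 letters) at high and low baseline strata,
#: non-responder shapes elsewhere
DEFAULT_CLASS_COEFFS = (
    (67.0, -1.0, 0.01),
    (62.0, 1.5, -0.06),
    (44.0, 0.2, -0.02),
    (74.0, 0.1, -0.01),
    (40.0, 2.2, -0.09),
    (33.0, -0.7, 0.0),
)

#: default exclusion tallies at n=270, mirroring a trial-sized T&E arm
DEFAULT_EXCLUSION_COUNTS = {
    "missing_scan": 10,
    "lost_to_followup": 22,
    "bad_quality": 5,
    "protocol_deviation": 5,
}

#: mean fraction of each fluid's total volume falling in the three ETDRS
#: zones (central, parafoveal, perifoveal); SRF predominantly extrafoveal,
#: IRF centre-weighted
ZONE_WEIGHT_MEANS = {
    "IRF": (0.50, 0.35, 0.15),
    "SRF": (0.12, 0.43, 0.45),
    "PED": (0.25, 0.45, 0.30),
    "HRF": (0.30, 0.40, 0.30),
}


@dataclass
class EyeState:
    """Ground-truth generative state of one synthetic eye."""

    eye_id: str
    latent_class: int  # 1-based
    baseline_bcva: float
    bcva_coeffs: Tuple[float, float, float]  # letters vs months
    random_intercept: float
    baseline_volumes: Dict[str, float]  # biomarker -> nl
    pr_baseline_thickness: float  # µm
    decay_rate: Dict[str, float]  # per-injection retention factor in [0, 1]
    recurrence_hazard: float  # per-week probability of fluid regrowth
    age: float
    sex: str
    seed: int  # root of this eye's private random streams
    noise_sd: float = 3.0  # BCVA measurement noise (letters)
    regrowth_fraction: float = 0.25  # regrown volume per event, x baseline
    scanner: str = "grid_128x512"
    zone_weights: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)
    exclusion: str = "none"

    def __post_init__(self) -> None:
        d = self.decay_rate
        if not (d["IRF"] <= d["SRF"] <= d["PED"]):
            raise ContractError("retention factors must satisfy IRF <= SRF <= PED")
        if any(v < 0 for v in self.baseline_volumes.values()):
            raise ContractError("baseline volumes must be non-negative")
        if not np.all(np.isfinite(self.bcva_coeffs)):
            raise ContractError("BCVA coefficients must be finite")

    @property
    def is_responder_truth(self) -> bool:
        """Ground truth: model-implied 12-month gain of the eye's class."""
        _, b1, b2 = self.bcva_coeffs
        return b1 * 12.0 + b2 * 144.0 >= 5.0


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_eyes: int = 270
    k_classes: int = 6
    class_proportions: Optional[Sequence[float]] = None
    class_bcva_coeffs: Sequence[Tuple[float, float, float]] = DEFAULT_CLASS_COEFFS
    sigma_intercept: float = 4.0
    sigma_noise: float = 3.0
    scanner_mix: Dict[str, float] = field(
        default_factory=lambda: {"grid_49x768": 0.65, "grid_128x512": 0.35}
    )
    seed: int = 0
    horizon_weeks: int = 52
    coupling: float = 1.0  # strength of the class<->IRF and SRF<->hazard links
    exclusion_counts: Optional[Dict[str, int]] = None  # None -> scaled defaults

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            sizes = np.asarray(DEFAULT_CLASS_SIZES[: self.k_classes], dtype=float)
            if len(sizes) < self.k_classes:
                raise ConfigurationError("no default proportions for this k_classes")
            self.class_proportions = tuple(sizes / sizes.sum())
        p = np.asarray(self.class_proportions, dtype=float)
        if len(p) != self.k_classes or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must be a simplex vector of length k_classes")
        if len(self.class_bcva_coeffs) < self.k_classes:
            raise ConfigurationError("need one coefficient triple per class")
        if self.n_eyes < 2 * self.k_classes:
            raise ConfigurationError("n_eyes must be at least 2 * k_classes")
        mix = np.asarray(list(self.scanner_mix.values()), dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("scanner_mix must be a simplex")

    def scaled_exclusion_counts(self) -> Dict[str, int]:
        if self.exclusion_counts is not None:
            return dict(self.exclusion_counts)
        scale = self.n_eyes / 270.0
        return {k: int(round(v * scale)) for k, v in DEFAULT_EXCLUSION_COUNTS.items()}


def _eye_rng(seed: int, eye_id: str, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(eye_id.encode()), stream])


def generate_cohort(config: CohortConfig) -> List[EyeState]:
    """Draw ``config.n_eyes`` independent eye states.

    Identical config (including seed) yields a bit-identical cohort; each
    eye's draws come from its own stream, so the cohort is stable under
    reordering.  With ``coupling=1`` responder classes receive faster IRF
    clearance and the recurrence hazard grows with SRF retention; with
    ``coupling=0`` retention factors and hazards are drawn independently of
    the latent class.
    """
    K = config.k_classes
    p = np.asarray(config.class_proportions, dtype=float)
    responder_class = [
        b1 * 12.0 + b2 * 144.0 >= 5.0 for (_, b1, b2) in config.class_bcva_coeffs[:K]
    ]
    scanners = list(config.scanner_mix)
    scanner_p = np.asarray([config.scanner_mix[s] for s in scanners], dtype=float)

    eyes: List[EyeState] = []
    for i in range(config.n_eyes):
        eye_id = f"eye_{i:04d}"
        rng = _eye_rng(config.seed, eye_id, 0)
        g = int(rng.choice(K, p=p))
        beta = tuple(float(x) for x in config.class_bcva_coeffs[g])
        intercept = float(rng.normal(0.0, config.sigma_intercept))
        baseline_bcva = float(np.clip(beta[0] + intercept, 0.0, 100.0))

        irf0 = 0.0 if rng.random() < 0.15 else float(rng.lognormal(np.log(80.0), 0.8))
        srf0 = 0.0 if rng.random() < 0.10 else float(rng.lognormal(np.log(120.0), 0.7))
        ped0 = float(rng.lognormal(np.log(250.0), 0.6))
        hrf0 = float(rng.lognormal(np.log(5.0), 0.8))

        c = float(config.coupling)
        if c > 0 and responder_class[g]:
            irf_ret = float(rng.uniform(0.02, 0.10))
        elif c > 0:
            irf_ret = float(rng.uniform(0.12, 0.30))
        else:
            irf_ret = float(rng.uniform(0.02, 0.30))
        srf_ret = float(max(rng.uniform(0.25, 0.75), irf_ret + 0.05))
        ped_ret = float(max(rng.uniform(0.85, 0.98), srf_ret))
        hrf_ret = float(rng.uniform(0.30, 0.60))
        if c > 0:
            hazard = 0.004 + 0.10 * c * (srf_ret - 0.25) / 0.50 + rng.normal(0.0, 0.005)
        else:
            hazard = rng.uniform(0.004, 0.12)
        hazard = float(np.clip(hazard, 0.0, 0.35))

        zone_weights = {
            b: tuple(rng.dirichlet(np.asarray(w) * 25.0))
            for b, w in ZONE_WEIGHT_MEANS.items()
        }
        eyes.append(
            EyeState(
                eye_id=eye_id,
                latent_class=g + 1,
                baseline_bcva=baseline_bcva,
                bcva_coeffs=beta,
                random_intercept=intercept,
                baseline_volumes={"IRF": irf0, "SRF": srf0, "PED": ped0, "HRF": hrf0},
                pr_baseline_thickness=float(np.clip(rng.normal(45.0, 8.0), 10.0, None)),
                decay_rate={"IRF": irf_ret, "SRF": srf_ret, "PED": ped_ret, "HRF": hrf_ret},
                recurrence_hazard=hazard,
                age=float(np.clip(rng.normal(75.2, 8.2), 51.0, 95.0)),
                sex="female" if rng.random() < 0.55 else "male",
                seed=int(zlib.crc32(f"{config.seed}:{eye_id}".encode()) & 0x7FFFFFFF),
                noise_sd=config.sigma_noise,
                regrowth_fraction=float(rng.uniform(0.15, 0.35)),
                scanner=str(rng.choice(scanners, p=scanner_p)),
                zone_weights=zone_weights,
            )
        )

    # assign exclusion categories to distinct eyes, in the filter's rule order
    counts = config.scaled_exclusion_counts()
    rng0 = np.random.default_rng([config.seed, 0xE])
    order = rng0.permutation(config.n_eyes)
    pos = 0
    for rule in ("missing_scan", "lost_to_followup", "bad_quality", "protocol_deviation"):
        for j in order[pos : pos + counts.get(rule, 0)]:
            eyes[j].exclusion = rule
        pos += counts.get(rule, 0)
    return eyes


def simulate_bcva(eye: EyeState, visit_weeks: Sequence[float]) -> np.ndarray:
    """Quadratic class trajectory + random intercept + per-visit noise.

    y(t) = b0 + b1 t + b2 t^2 + intercept + eps, t in months, truncated to
    [0, 100] letters.  The noise stream is seeded per eye, so the same visit
    schedule always yields the same letters.
    """
    weeks = np.asarray(visit_weeks, dtype=float)
    t = weeks / WEEKS_PER_MONTH
    b0, b1, b2 = eye.bcva_coeffs
    rng = np.random.default_rng([eye.seed, 1])
    noise = rng.normal(0.0, eye.noise_sd, size=t.shape) if eye.noise_sd > 0 else 0.0
    y = b0 + b1 * t + b2 * t**2 + eye.random_intercept + noise
    return np.clip(y, 0.0, 100.0)


class FluidKinetics:
    """Incremental fluid state of one eye under injections and recurrence.

    At an injection every compartment is multiplied by its retention factor
    (PED floored at a strictly positive fraction of baseline).  Between
    visits a Bernoulli(hazard) event per week regrows SRF — the clinically
    dominant recurring compartment under this regimen — by a fixed per-eye
    fraction of baseline, and with probability 0.3 per event also IRF.
    """

    PED_FLOOR_FRACTION = 0.25
    IRF_REGROWTH_PROB = 0.3

    def __init__(self, eye: EyeState, seed: Optional[int] = None):
        self.eye = eye
        self.rng = np.random.default_rng([seed if seed is not None else eye.seed, 2])
        self.volumes = dict(eye.baseline_volumes)
        self._ped_floor = self.PED_FLOOR_FRACTION * eye.baseline_volumes.get("PED", 0.0)

    def observe(self) -> Dict[str, float]:
        return dict(self.volumes)

    def inject(self) -> None:
        for b in of.FLUID_BIOMARKERS:
            self.volumes[b] *= self.eye.decay_rate[b]
        if self._ped_floor > 0:
            self.volumes["PED"] = max(self.volumes["PED"], self._ped_floor)

    def advance(self, n_weeks: int) -> None:
        base = self.eye.baseline_volumes
        for _ in range(int(n_weeks)):
            event = self.rng.random() < self.eye.recurrence_hazard
            irf_too = self.rng.random() < self.IRF_REGROWTH_PROB
            if event:
                if base.get("SRF", 0.0) > 0:
                    self.volumes["SRF"] += self.eye.regrowth_fraction * base["SRF"]
                if irf_too and base.get("IRF", 0.0) > 0:
                    self.volumes["IRF"] += self.eye.regrowth_fraction * base["IRF"]


def simulate_fluid_course(
    eye: EyeState,
    course_weeks: Sequence[float],
    injections: Sequence[bool],
    seed: Optional[int] = None,
) -> List[Dict[str, float]]:
    """Per-visit pre-injection volumes (nl) along a fixed visit schedule."""
    if len(course_weeks) != len(injections):
        raise ContractError("course_weeks and injections must be aligned")
    fk = FluidKinetics(eye, seed=seed)
    out: List[Dict[str, float]] = []
    prev = None
    for week, inj in zip(course_weeks, injections):
        if prev is not None:
            if week < prev:
                raise ContractError("course weeks must be non-decreasing")
            fk.advance(int(round(week - prev)))
        out.append(fk.observe())
        if inj:
            fk.inject()
        prev = week
    return out


def _bump_field(
    rng: np.random.Generator, rows: int, cols: int, n_bumps: int = 3
) -> np.ndarray:
    """Sum of isotropic 2D Gaussian bumps with per-eye fixed geometry (mm)."""
    yy = of.pixel_centers(rows, of.EXTENT_MM[0])[:, None]
    xx = of.pixel_centers(cols, of.EXTENT_MM[1])[None, :]
    field = np.zeros((rows, cols))
    for _ in range(n_bumps):
        r = rng.uniform(0.0, 2.6)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cy = 3.0 + r * np.sin(theta)
        cx = 3.0 + r * np.cos(theta)
        sigma = rng.uniform(0.4, 0.9)
        amp = rng.uniform(0.5, 1.5)
        field += amp * np.exp(-(((yy - cy) ** 2) + ((xx - cx) ** 2)) / (2.0 * sigma**2))
    return field


def render_maps(
    eye: EyeState,
    visit_label: str,
    volumes: Dict[str, float],
    grid: Optional[str] = None,
    tol: float = 0.003,
    max_iter: int = 8,
) -> of.EnFaceMapSet:
    """Render per-biomarker thickness maps whose zonal volumes match targets.

    Each fluid map is a sum of Gaussian bumps (geometry fixed per eye, so
    the same eye rendered on both scanner grids shows the same field),
    rescaled per ETDRS zone until the zonal volumes measured on the
    canonical analysis grid match ``volumes`` split by the eye's zone
    weights to within ``tol`` relative error.  PR is rendered as a smooth
    thickness field around its baseline value.
    """
    grid = grid or eye.scanner
    if grid not in GRID_SHAPES:
        raise ContractError(f"unknown grid {grid!r}")
    rows, cols = GRID_SHAPES[grid]
    native_masks = of.etdrs_zone_masks(rows, cols)
    native_area = of.pixel_area_mm2(rows, cols)
    canon_masks = of.etdrs_zone_masks(*of.CANONICAL_SHAPE)
    canon_area = of.pixel_area_mm2(*of.CANONICAL_SHAPE)
    outside = ~np.logical_or.reduce([native_masks[z] for z in of.ZONES])

    rng = np.random.default_rng([eye.seed, 3])
    maps: Dict[str, np.ndarray] = {}
    for b in of.FLUID_BIOMARKERS:
        total = float(volumes.get(b, 0.0))
        if total < 0:
            raise ContractError(f"negative target volume for {b}")
        field = _bump_field(rng, rows, cols)
        field[outside] = 0.0
        weights = eye.zone_weights.get(b, ZONE_WEIGHT_MEANS[b])
        targets = {z: total * w for z, w in zip(of.ZONES, weights)}
        for _ in range(max_iter):
            canon = of.resample_map(field, *of.CANONICAL_SHAPE)
            done = True
            for z in of.ZONES:
                tgt = targets[z]
                if tgt <= 0:
                    field[native_masks[z]] = 0.0
                    continue
                meas = of.zonal_volume(canon, canon_masks[z], canon_area)
                if meas <= 1e-12:
                    npix = int(native_masks[z].sum())
                    field[native_masks[z]] += tgt / (npix * native_area)
                    done = False
                    continue
                ratio = tgt / meas
                if abs(ratio - 1.0) > tol:
                    done = False
                field[native_masks[z]] *= ratio
            if done:
                break
        maps[b] = np.maximum(field, 0.0)

    pr = eye.pr_baseline_thickness + 4.0 * (_bump_field(rng, rows, cols) - 1.0)
    maps["PR"] = np.clip(pr, 0.0, None)
    return of.EnFaceMapSet(eye_id=eye.eye_id, visit_label=visit_label, maps=maps)


def cohort_truth_table(eyes: Sequence[EyeState]) -> pd.DataFrame:
    """Ground-truth export: latent class, retention factors, hazards, labels."""
    rows = []
    for e in eyes:
        rows.append(
            {
                "eye_id": e.eye_id,
                "latent_class": e.latent_class,
                "responder_truth": e.is_responder_truth,
                "baseline_bcva": e.baseline_bcva,
                "beta0": e.bcva_coeffs[0],
                "beta1": e.bcva_coeffs[1],
                "beta2": e.bcva_coeffs[2],
                "random_intercept": e.random_intercept,
                "retention_IRF": e.decay_rate["IRF"],
                "retention_SRF": e.decay_rate["SRF"],
                "retention_PED": e.decay_rate["PED"],
                "retention_HRF": e.decay_rate["HRF"],
                "recurrence_hazard": e.recurrence_hazard,
                "baseline_IRF_nl": e.baseline_volumes["IRF"],
                "baseline_SRF_nl": e.baseline_volumes["SRF"],
                "baseline_PED_nl": e.baseline_volumes["PED"],
                "baseline_HRF_nl": e.baseline_volumes["HRF"],
                "pr_baseline_um": e.pr_baseline_thickness,
                "age": e.age,
                "sex": e.sex,
                "scanner": e.scanner,
                "exclusion": e.exclusion,
            }
        )
    return pd.DataFrame(rows).set_index("eye_id")
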