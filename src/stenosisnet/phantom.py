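"""Synthetic CMRA-like vessel phantoms.

Real whole-heart coronary MRA volumes show bright tubular coronary lumina on a
darker myocardial/blood-pool background; a significant stenosis appears as a
focal drop of the luminal signal profile. This module generates volumes with
that structure — straight-to-mildly-curved tubes of configurable radius and
contrast, focal diameter reductions for the positive class, Gaussian blur and
additive (Gaussian or Rician) noise — grouped into synthetic "patients", plus
the ground-truth annotation tables the downstream pipeline consumes.

Everything is a pure function of (config, seed): identical inputs give
bit-identical volumes and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dataset import SegmentRecord, POSITIVE_CATEGORIES

# Stenosis-grade bins and their observed frequencies in a 951-segment coronary
# dataset (counts over 0-24 / 25-49 / 50-69 / 70-99 / 100 % diameter reduction).
GRADE_BINS = ("0-24", "25-49", "50-69", "70-99", "100")
NEGATIVE_GRADE_COUNTS = {"0-24": 852, "25-49": 15}
POSITIVE_GRADE_COUNTS = {"50-69": 37, "70-99": 40, "100": 7}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a high-contrast, low-noise cohort of 60 patients with
    about 12 annotated segments each and ~10% stenosis prevalence.

    ``stenosis_fraction_range`` is the *diameter* reduction of positive
    segments; its lower bound must be >= 0.5 so every positive meets the
    >=50% definition of significant stenosis.
    """

    n_patients: int = 60
    segments_per_patient: int = 12
    stenosis_prevalence: float = 0.10
    vessel_radius: float = 3.0
    lumen_intensity: float = 300.0
    background_intensity: float = 60.0
    stenosis_fraction_range: tuple[float, float] = (0.5, 1.0)
    blur_sigma: float = 0.6
    noise_sigma: float = 8.0
    volume_shape: tuple[int, int, int] = (72, 72, 72)
    # maximum in-plane deviation (voxels) of the quadratic centerline bend
    curvature_max: float = 2.0
    # half-extent (voxels along the tube) of the focal radius reduction
    stenosis_extent: float = 4.0
    # focal intensity drop co-located with the stenosis, as a fraction of the
    # lumen-background contrast (0 disables)
    stenosis_intensity_drop: float = 0.0
    # per-patient multiplicative intensity scale ~ N(1, sigma^2); exercises
    # the patient-mean normalization downstream
    patient_scale_sigma: float = 0.05
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_intensity <= self.background_intensity:
            raise ValueError("lumen_intensity must exceed background_intensity")
        lo, hi = self.stenosis_fraction_range
        if not (0.5 <= lo <= hi <= 1.0):
            raise ValueError(
                "stenosis_fraction_range must satisfy 0.5 <= lo <= hi <= 1.0 "
                "(positives are defined by >=50% diameter reduction)"
            )
        if self.vessel_radius <= 0:
            raise ValueError("vessel_radius must be > 0")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")
        if len(self.volume_shape) != 3 or any(s < 21 for s in self.volume_shape):
            raise ValueError(
                "volume_shape must be a triple with every side >= 21 so a "
                "21^3 patch fits around an annotation"
            )
        if not (0.0 <= self.stenosis_prevalence <= 1.0):
            raise ValueError("stenosis_prevalence must be in [0, 1]")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one synthetic segment."""

    patient_id: str
    segment_id: str
    annotation: tuple[int, int, int]
    stenosis_fraction: float  # true diameter reduction in [0, 1]
    label: int  # 1 iff stenosis_fraction >= 0.5
    has_stent: bool = False
    visible_on_cmra: bool = True

    def __post_init__(self) -> None:
        expected = int(self.stenosis_fraction >= 0.5)
        if self.label != expected:
            raise ValueError("label must equal (stenosis_fraction >= 0.5)")


def _lane_centers(n: int, shape: tuple[int, int, int], margin: float) -> list[tuple[float, float]]:
    """Place n non-overlapping tube lanes on an in-plane grid."""
    nx = math.ceil(math.sqrt(n))
    ny = math.ceil(n / nx)
    xs = np.linspace(margin, shape[0] - 1 - margin, nx)
    ys = np.linspace(margin, shape[1] - 1 - margin, ny)
    if nx > 1 and (xs[1] - xs[0]) < 2 * margin:
        raise ValueError("volume_shape too small for the requested number of segments")
    if ny > 1 and (ys[1] - ys[0]) < 2 * margin:
        raise ValueError("volume_shape too small for the requested number of segments")
    return [(xs[i % nx], ys[i // nx]) for i in range(n)]


def _radius_profile(
    z: np.ndarray, radius: float, fraction: float, z0: int, extent: float
) -> np.ndarray:
    """Tube radius along the axis: focal reduction by `fraction` centered at z0.

    The bump is a raised cosine; at z0 the diameter is reduced by exactly
    `fraction`, tapering smoothly to the nominal radius over +-extent voxels.
    """
    u = np.clip(np.abs(z - z0) / max(extent, 1e-9), 0.0, 1.0)
    bump = np.cos(np.pi * u / 2.0) ** 2
    return radius * (1.0 - fraction * bump)


def generate_patient_volume(
    config: PhantomConfig, patient_seed: int
) -> tuple[np.ndarray, list[PhantomTruth]]:
    """Render one synthetic patient volume and its truth records.

    Tubes run along the z axis on separated in-plane lanes, each with a mild
    quadratic in-plane bend (<= ``curvature_max`` voxels). Positive segments
    carry a focal radius reduction drawn from ``stenosis_fraction_range``,
    centered at the annotation; negative segments are annotated at a uniform
    point on the centerline.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, patient_seed)))
    sx, sy, sz = config.volume_shape
    n_seg = config.segments_per_patient
    margin = config.vessel_radius + config.curvature_max + 2.0
    lanes = _lane_centers(n_seg, config.volume_shape, margin)

    vol = np.full(config.volume_shape, float(config.background_intensity))
    z = np.arange(sz, dtype=float)
    # annotations stay >= 10 voxels from the axial faces so a 21^3 patch fits
    z_lo, z_hi = 10, sz - 11
    pid = f"P{patient_seed:04d}"
    truths: list[PhantomTruth] = []

    yy, xx = np.meshgrid(np.arange(sy, dtype=float), np.arange(sx, dtype=float))

    for k, (x0, y0) in enumerate(lanes):
        stenotic = rng.random() < config.stenosis_prevalence
        if stenotic:
            lo, hi = config.stenosis_fraction_range
            fraction = float(rng.uniform(lo, hi))
        else:
            # mild non-significant irregularity
            fraction = float(rng.uniform(0.0, 0.25))
        z0 = int(rng.integers(z_lo, z_hi + 1))

        # quadratic in-plane bend, zero at the volume faces, peak amp mid-tube
        amp_x = float(rng.uniform(-config.curvature_max, config.curvature_max))
        amp_y = float(rng.uniform(-config.curvature_max, config.curvature_max))
        tnorm = z / max(sz - 1, 1)
        cx = x0 + amp_x * 4.0 * tnorm * (1.0 - tnorm)
        cy = y0 + amp_y * 4.0 * tnorm * (1.0 - tnorm)

        radii = _radius_profile(z, config.vessel_radius, fraction, z0, config.stenosis_extent)
        drop = config.stenosis_intensity_drop * (
            config.lumen_intensity - config.background_intensity
        )

        # rasterize slice by slice inside the lane's bounding box
        r_max = config.vessel_radius + 1.0
        x_lo = max(int(np.floor(cx.min() - r_max)), 0)
        x_hi = min(int(np.ceil(cx.max() + r_max)) + 1, sx)
        y_lo = max(int(np.floor(cy.min() - r_max)), 0)
        y_hi = min(int(np.ceil(cy.max() + r_max)) + 1, sy)
        sub_xx = xx[x_lo:x_hi, y_lo:y_hi]
        sub_yy = yy[x_lo:x_hi, y_lo:y_hi]
        for zi in range(sz):
            r = radii[zi]
            if r <= 0:
                continue
            dist2 = (sub_xx - cx[zi]) ** 2 + (sub_yy - cy[zi]) ** 2
            mask = dist2 < r * r
            if not mask.any():
                continue
            level = config.lumen_intensity
            if drop > 0:
                u = min(abs(zi - z0) / max(config.stenosis_extent, 1e-9), 1.0)
                level = level - drop * math.cos(math.pi * u / 2.0) ** 2
            block = vol[x_lo:x_hi, y_lo:y_hi, zi]
            np.maximum(block, np.where(mask, level, config.background_intensity), out=block)

        ann = (int(round(cx[z0])), int(round(cy[z0])), z0)
        truths.append(
            PhantomTruth(
                patient_id=pid,
                segment_id=f"{pid}_S{k:02d}",
                annotation=ann,
                stenosis_fraction=fraction,
                label=int(fraction >= 0.5),
            )
        )

    scale = 1.0
    if config.patient_scale_sigma > 0:
        scale = float(rng.normal(1.0, config.patient_scale_sigma))
        scale = max(scale, 0.1)
    vol *= scale

    if config.blur_sigma > 0:
        vol = gaussian_filter(vol, config.blur_sigma)
    if config.noise_sigma > 0:
        if config.noise_model == "gaussian":
            vol = vol + rng.normal(0.0, config.noise_sigma, vol.shape)
        else:  # Rician magnitude noise
            re = vol + rng.normal(0.0, config.noise_sigma, vol.shape)
            im = rng.normal(0.0, config.noise_sigma, vol.shape)
            vol = np.hypot(re, im)
    return vol, truths


def generate_cohort(
    config: PhantomConfig,
) -> list[tuple[str, np.ndarray, list[PhantomTruth]]]:
    """Generate the full synthetic cohort: (patient_id, volume, truths) per patient."""
    cohort = []
    for p in range(config.n_patients):
        vol, truths = generate_patient_volume(config, p)
        cohort.append((truths[0].patient_id if truths else f"P{p:04d}", vol, truths))
    return cohort


def truths_to_records(truths: list[PhantomTruth]) -> list[SegmentRecord]:
    """Convert phantom truths to segment records (grade bin from the true fraction)."""
    records = []
    for i, t in enumerate(truths):
        f = t.stenosis_fraction * 100
        if f < 25:
            cat = "0-24"
        elif f < 50:
            cat = "25-49"
        elif f < 70:
            cat = "50-69"
        elif f < 100:
            cat = "70-99"
        else:
            cat = "100"
        records.append(
            SegmentRecord(
                patient_id=t.patient_id,
                scct_segment=(i % 18) + 1,
                annotation=t.annotation,
                stenosis_percent_category=cat,
                has_stent=t.has_stent,
                visible_on_cmra=t.visible_on_cmra,
            )
        )
    return records


def truths_to_table(truths: list[PhantomTruth]) -> pd.DataFrame:
    """Annotation table with the documented CSV header (0-based voxel indices)."""
    rows = [
        {
            "patient_id": t.patient_id,
            "segment_id": t.segment_id,
            "x": t.annotation[0],
            "y": t.annotation[1],
            "z": t.annotation[2],
            "stenosis_fraction": t.stenosis_fraction,
            "label": t.label,
            "has_stent": int(t.has_stent),
            "visible_on_cmra": int(t.visible_on_cmra),
        }
        for t in truths
    ]
    return pd.DataFrame(rows)


def _allocate_largest_remainder(total: int, weights: dict[str, int]) -> dict[str, int]:
    """Split `total` across categories proportionally to integer weights."""
    wsum = sum(weights.values())
    exact = {k: total * w / wsum for k, w in weights.items()}
    counts = {k: int(math.floor(v)) for k, v in exact.items()}
    short = total - sum(counts.values())
    order = sorted(weights, key=lambda k: exact[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_dataset_fixture(
    n_total_visible_on_ica: int,
    n_stented: int,
    n_invisible: int,
    n_stenotic: int,
    seed: int,
    n_patients: int = 75,
) -> list[SegmentRecord]:
    """Build a segment table with exactly the requested exclusion structure.

    The stented / CMRA-invisible / stenotic subsets are mutually exclusive;
    stenotic records are drawn from the retained (includable) pool. Grades of
    stenotic records follow the observed 37:40:7 split over the 50-69 / 70-99 /
    100% bins; retained negatives follow the 852:15 split over 0-24 / 25-49.
    """
    if n_stented + n_invisible > n_total_visible_on_ica:
        raise ValueError("excluded counts exceed the total")
    n_retained = n_total_visible_on_ica - n_stented - n_invisible
    if n_stenotic > n_retained:
        raise ValueError("n_stenotic exceeds the retained count")
    if n_total_visible_on_ica > 18 * n_patients:
        raise ValueError("more segments than 18 per patient allows")

    rng = np.random.default_rng(seed)

    pos_counts = _allocate_largest_remainder(n_stenotic, POSITIVE_GRADE_COUNTS)
    neg_counts = _allocate_largest_remainder(n_retained - n_stenotic, NEGATIVE_GRADE_COUNTS)

    grades: list[str] = []
    flags: list[tuple[bool, bool]] = []  # (has_stent, visible_on_cmra)
    for cat, n in pos_counts.items():
        grades += [cat] * n
        flags += [(False, True)] * n
    for cat, n in neg_counts.items():
        grades += [cat] * n
        flags += [(False, True)] * n
    # excluded records: grade drawn from the negative bins
    excl_grades = list(
        rng.choice(
            list(NEGATIVE_GRADE_COUNTS),
            size=n_stented + n_invisible,
            p=np.array(list(NEGATIVE_GRADE_COUNTS.values()), dtype=float)
            / sum(NEGATIVE_GRADE_COUNTS.values()),
        )
    )
    grades += excl_grades
    flags += [(True, True)] * n_stented + [(False, False)] * n_invisible

    order = rng.permutation(len(grades))
    records = []
    for i, idx in enumerate(order):
        records.append(
            SegmentRecord(
                patient_id=f"P{i % n_patients:03d}",
                scct_segment=(i // n_patients) % 18 + 1,
                annotation=(10, 10, 10),
                stenosis_percent_category=grades[idx],
                has_stent=flags[idx][0],
                visible_on_cmra=flags[idx][1],
            )
        )
    return records
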