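"""Segment records, inclusion filtering, VOI extraction and fold assignment.

The unit of analysis is a coronary segment (18-segment SCCT scheme) with a
manually placed annotation voxel. Around each annotation a 21x21x21 volume of
interest (VOI) is cut out and normalized by the patient's mean signal; VOIs
with significant stenosis are augmented by 90-degree rotations; patients are
split into four stenosis-balanced folds for cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

VOI_SIDE = 21
VOI_HALF = VOI_SIDE // 2

STENOSIS_CATEGORIES = ("0-24", "25-49", "50-69", "70-99", "100")
POSITIVE_CATEGORIES = frozenset({"50-69", "70-99", "100"})

AUGMENTATION_TAGS = ("original", "rot_x", "rot_y", "rot_z")
# 90-degree rotation about each axis: counterclockwise viewed from the
# positive axis end, remaining axes taken in index order
_ROT_AXES = {"rot_x": (1, 2), "rot_y": (2, 0), "rot_z": (0, 1)}


@dataclass(frozen=True)
class SegmentRecord:
    """One coronary segment: identity, grade, exclusion flags, annotation."""

    patient_id: str
    scct_segment: int
    annotation: tuple[int, int, int]
    stenosis_percent_category: str
    has_stent: bool = False
    visible_on_cmra: bool = True
    segment_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.scct_segment <= 18:
            raise ValueError(f"scct_segment must be in [1, 18], got {self.scct_segment}")
        if self.stenosis_percent_category not in STENOSIS_CATEGORIES:
            raise ValueError(
                f"unknown stenosis category {self.stenosis_percent_category!r}"
            )
        if not self.segment_id:
            object.__setattr__(
                self, "segment_id", f"{self.patient_id}_seg{self.scct_segment:02d}"
            )

    @property
    def label(self) -> int:
        """1 iff the graded diameter reduction is >= 50%."""
        return int(self.stenosis_percent_category in POSITIVE_CATEGORIES)


@dataclass
class Voi:
    """A normalized 21^3 patch with its label and provenance."""

    values: np.ndarray
    label: int
    patient_id: str
    segment_id: str
    augmentation_tag: str = "original"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (VOI_SIDE,) * 3:
            raise ValueError(f"VOI must be {VOI_SIDE}^3, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("VOI values must be finite and >= 0")
        if self.augmentation_tag not in AUGMENTATION_TAGS:
            raise ValueError(f"unknown augmentation tag {self.augmentation_tag!r}")


def apply_inclusion_filter(records: list[SegmentRecord]) -> list[SegmentRecord]:
    """Drop stented and CMRA-invisible segments; order preserved. Idempotent."""
    return [r for r in records if not r.has_stent and r.visible_on_cmra]


def extract_voi(
    volume: np.ndarray,
    annotation: tuple[int, int, int],
    border: str = "replicate",
) -> np.ndarray:
    """Cut the 21^3 patch centered on an annotation voxel.

    Annotations closer than 10 voxels to a face are handled per ``border``:
    "replicate" pads by edge replication (a warning is recorded), "strict"
    rejects. An annotation outside the volume is always rejected.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D")
    ann = tuple(int(a) for a in annotation)
    if any(a < 0 or a >= s for a, s in zip(ann, volume.shape)):
        raise ValueError(f"annotation {ann} outside volume of shape {volume.shape}")
    lo = [a - VOI_HALF for a in ann]
    hi = [a + VOI_HALF + 1 for a in ann]
    pad_lo = [max(0, -l) for l in lo]
    pad_hi = [max(0, h - s) for h, s in zip(hi, volume.shape)]
    if any(pad_lo) or any(pad_hi):
        if border == "strict":
            raise ValueError(f"annotation {ann} too close to the border for a 21^3 patch")
        warnings.warn(
            f"annotation {ann} within {VOI_HALF} voxels of a border; "
            "edge-replication padding applied",
            stacklevel=2,
        )
    core = volume[
        max(lo[0], 0) : hi[0], max(lo[1], 0) : hi[1], max(lo[2], 0) : hi[2]
    ]
    patch = np.pad(core, list(zip(pad_lo, pad_hi)), mode="edge")
    assert patch.shape == (VOI_SIDE,) * 3
    return patch


def patient_volume_mean(volume: np.ndarray, body_mask: np.ndarray | None = None) -> float:
    """Average signal of a patient volume; optionally restricted to a mask."""
    volume = np.asarray(volume, dtype=float)
    if body_mask is not None:
        return float(volume[body_mask].mean())
    return float(volume.mean())


def normalize_voi(patch: np.ndarray, patient_volume_mean: float) -> np.ndarray:
    """Divide every voxel by the patient's mean signal value."""
    if not patient_volume_mean > 0:
        raise ValueError("patient_volume_mean must be > 0")
    return np.asarray(patch, dtype=float) / patient_volume_mean


def augment_positive(voi: Voi) -> list[Voi]:
    """Original plus one 90-degree rotation about each axis (positives only)."""
    if voi.label != 1:
        raise ValueError("only VOIs with significant stenosis are augmented")
    out = [replace(voi, values=voi.values.copy(), augmentation_tag="original")]
    for tag, axes in _ROT_AXES.items():
        out.append(
            Voi(
                values=np.rot90(voi.values, k=1, axes=axes).copy(),
                label=voi.label,
                patient_id=voi.patient_id,
                segment_id=voi.segment_id,
                augmentation_tag=tag,
            )
        )
    return out


@dataclass(frozen=True)
class FoldAssignment:
    """Patient -> fold map for patient-level cross-validation."""

    mapping: dict[str, int]
    n_folds: int = 4

    def patients_in_fold(self, fold: int) -> set[str]:
        return {p for p, f in self.mapping.items() if f == fold}

    def fold_of(self, patient_id: str) -> int:
        return self.mapping[patient_id]


def assign_folds(
    records: list[SegmentRecord], n_folds: int = 4, seed: int = 0
) -> FoldAssignment:
    """Greedy stenosis-balanced patient-level split.

    Patients are sorted by descending positive-segment count (ties broken by a
    seeded shuffle) and each is assigned to the fold currently holding the
    fewest positives (secondary tie-break: fewest segments, then lowest index).
    The residual positive-count spread across folds is bounded by the largest
    single patient's positive count.
    """
    patients: dict[str, list[SegmentRecord]] = {}
    for r in records:
        patients.setdefault(r.patient_id, []).append(r)
    if len(patients) < n_folds:
        raise ValueError(f"need at least {n_folds} patients, got {len(patients)}")

    rng = np.random.default_rng(seed)
    ids = list(patients)
    ids = [ids[i] for i in rng.permutation(len(ids))]
    ids.sort(key=lambda p: -sum(r.label for r in patients[p]))  # stable

    fold_pos = [0] * n_folds
    fold_tot = [0] * n_folds
    mapping: dict[str, int] = {}
    for p in ids:
        f = min(range(n_folds), key=lambda k: (fold_pos[k], fold_tot[k], k))
        mapping[p] = f
        fold_pos[f] += sum(r.label for r in patients[p])
        fold_tot[f] += len(patients[p])
    return FoldAssignment(mapping=mapping, n_folds=n_folds)


def make_cv_splits(
    assignment: FoldAssignment,
) -> list[tuple[set[str], set[str], set[str]]]:
    """Four (train, validation, test) patient-set rotations.

    Rotation r tests on fold r, validates on fold (r+1) mod 4 and trains on
    the remaining two folds; each fold serves as test exactly once.
    """
    if assignment.n_folds != 4:
        raise ValueError("cross-validation rotations are defined for 4 folds")
    splits = []
    for r in range(4):
        test = assignment.patients_in_fold(r)
        val = assignment.patients_in_fold((r + 1) % 4)
        train = set()
        for f in range(4):
            if f not in (r, (r + 1) % 4):
                train |= assignment.patients_in_fold(f)
        splits.append((train, val, test))
    return splits
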