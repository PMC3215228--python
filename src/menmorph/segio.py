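"""Segmentation volume and morphometry-table I/O.

The in-memory container is :class:`VoxelSegmentation`: an integer label grid
with world-coordinate metadata.  Axis convention (fixed throughout the
package):

* axis 0 = ``x``, medio-lateral (right-knee convention: medial side at
  smaller ``x``),
* axis 1 = ``y``, antero-posterior — the coronal slice axis,
* axis 2 = ``z``, inferior-superior.

World coordinates are voxel centres, ``world = origin + index * spacing``
with 0-based indices.  Left knees are mirrored to the right-knee convention
at read time so downstream side-aware logic is single-cased.

Two on-disk dialects are supported: NIfTI (``.nii``/``.nii.gz``, axis-aligned
affines only) and a raw ``.npy`` array with a JSON sidecar carrying
``spacing``, ``origin``, ``label_map`` and ``laterality``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input fails a structural or semantic check (CLI exit code 2)."""


class StructureMissingError(ValidationError):
    """A required structure label is absent from the segmentation."""


#: Canonical structure names.  ``MT``/``LT`` = medial/lateral tibia,
#: ``MM``/``LM`` = medial/lateral meniscus.  ``ACdAB`` is the total area of
#: subchondral bone (cartilage surface including denuded bone); ``TA``/``FA``/
#: ``EA`` are the tibial, femoral and external meniscus surfaces.
KNOWN_STRUCTURES = (
    "MT_ACdAB", "LT_ACdAB", "MM", "LM",
    "MM_TA", "MM_FA", "MM_EA", "LM_TA", "LM_FA", "LM_EA",
)

DEFAULT_LABEL_MAP = {name: i + 1 for i, name in enumerate(KNOWN_STRUCTURES)}

#: Labels forming the meniscus solid per compartment (surface sub-labels, if
#: present, tag the boundary shell of the same solid).
SOLID_GROUPS = {
    "MM": ("MM", "MM_TA", "MM_FA", "MM_EA"),
    "LM": ("LM", "LM_TA", "LM_FA", "LM_EA"),
}

CARTILAGE_LABEL = {"medial": "MT_ACdAB", "lateral": "LT_ACdAB"}
MENISCUS_LABEL = {"medial": "MM", "lateral": "LM"}


@dataclass
class VoxelSegmentation:
    """Labelled 3D grid with world-coordinate metadata."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    laterality: str = "right"
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.laterality not in ("right", "left"):
            raise ValidationError(f"laterality must be 'right' or 'left', got {self.laterality!r}")
        present = set(np.unique(self.labels)) - {0}
        unknown = sorted(present - set(self.label_map.values()))
        if unknown:
            raise ValidationError(f"labels present but not in label_map: {unknown}")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world(self, index: Sequence[float]) -> np.ndarray:
        """World (mm) coordinate of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def y_mm(self, iy: int) -> float:
        return self.origin[1] + iy * self.spacing[1]

    @property
    def voxel_volume(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    # -- label access -----------------------------------------------------
    def has_structure(self, name: str) -> bool:
        lab = self.label_map.get(name)
        return lab is not None and bool((self.labels == lab).any())

    def mask(self, structure: str | Iterable[str]) -> np.ndarray:
        """Boolean mask of one structure or the union of several."""
        names = [structure] if isinstance(structure, str) else list(structure)
        out = np.zeros(self.shape, dtype=bool)
        for name in names:
            lab = self.label_map.get(name)
            if lab is not None:
                out |= self.labels == lab
        return out

    def solid_mask(self, compartment: str) -> np.ndarray:
        """Meniscus solid of a compartment (core plus any surface shell labels)."""
        return self.mask(SOLID_GROUPS[MENISCUS_LABEL[compartment]])

    def is_prepartitioned(self, compartment: str) -> bool:
        men = MENISCUS_LABEL[compartment]
        return any(self.has_structure(f"{men}_{s}") for s in ("TA", "FA", "EA"))

    def mirrored_x(self) -> "VoxelSegmentation":
        """Mirror about the world ``x = 0`` plane (left/right conversion)."""
        nx = self.shape[0]
        x_last = self.origin[0] + (nx - 1) * self.spacing[0]
        return VoxelSegmentation(
            labels=self.labels[::-1].copy(),
            spacing=self.spacing,
            origin=(-x_last, self.origin[1], self.origin[2]),
            label_map=dict(self.label_map),
            laterality="right",
            mirrored=True,
        )


# ---------------------------------------------------------------------------
# volume I/O


def write_segmentation(seg: VoxelSegmentation, path: str | Path, fmt: str | None = None) -> Path:
    """Write a segmentation as NIfTI or ``.npy`` + JSON sidecar.

    ``fmt`` is inferred from the suffix when not given ("nifti" for
    ``.nii``/``.nii.gz``, otherwise "npy").
    """
    path = Path(path)
    if fmt is None:
        fmt = "nifti" if path.name.endswith((".nii", ".nii.gz")) else "npy"
    if fmt == "nifti":
        affine = np.diag(list(seg.spacing) + [1.0])
        affine[:3, 3] = seg.origin
        img = nib.Nifti1Image(seg.labels.astype(np.int16), affine)
        # laterality / label map travel in a sidecar next to the image
        nib.save(img, path)
        _write_sidecar(seg, _sidecar_path(path), include_array_meta=False)
        return path
    if fmt == "npy":
        if path.suffix != ".npy":
            path = path.with_suffix(".npy")
        np.save(path, seg.labels.astype(np.int16))
        _write_sidecar(seg, _sidecar_path(path), include_array_meta=True)
        return path
    raise ValidationError(f"unknown segmentation format {fmt!r}")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".npy"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _write_sidecar(seg: VoxelSegmentation, path: Path, include_array_meta: bool) -> None:
    meta: dict = {"label_map": seg.label_map, "laterality": seg.laterality}
    if include_array_meta:
        meta["spacing"] = list(seg.spacing)
        meta["origin"] = list(seg.origin)
    path.write_text(json.dumps(meta, indent=2))


def read_segmentation(path: str | Path, format_hint: str | None = None) -> VoxelSegmentation:
    """Read a segmentation volume, normalising axes to the package convention.

    NIfTI inputs must have an axis-aligned affine (a signed permutation of
    scaled axes); flipped or permuted axes are reordered to +x, +y, +z.
    Missing spacing metadata is an error — isotropy is never assumed.  Left
    knees are mirrored to the right-knee convention, with ``mirrored=True``
    recorded on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = "nifti" if path.name.endswith((".nii", ".nii.gz")) else "npy"

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    if fmt == "nifti":
        img = nib.load(str(path))
        labels, spacing, origin = _canonicalize_nifti(img)
    elif fmt == "npy":
        labels = np.load(path)
        for key in ("spacing", "origin"):
            if key not in meta:
                raise ValidationError(f"sidecar {sidecar.name} is missing required field '{key}'")
            if len(meta[key]) != 3 or any(v is None for v in meta[key]):
                raise ValidationError(
                    f"sidecar field '{key}' must have 3 entries (dx, dy, dz), got {meta[key]}"
                )
        spacing = tuple(float(v) for v in meta["spacing"])
        origin = tuple(float(v) for v in meta["origin"])
    else:
        raise ValidationError(f"unknown segmentation format {fmt!r}")

    label_map = meta.get("label_map", dict(DEFAULT_LABEL_MAP))
    label_map = {str(k): int(v) for k, v in label_map.items()}
    seg = VoxelSegmentation(
        labels=labels,
        spacing=spacing,
        origin=origin,
        label_map=label_map,
        laterality=meta.get("laterality", "right"),
    )
    if seg.laterality == "left":
        seg = seg.mirrored_x()
    return seg


def _canonicalize_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    affine = np.asarray(img.affine, dtype=float)
    lin = affine[:3, :3]
    if np.count_nonzero(lin) != 3 or any(np.count_nonzero(lin[i]) != 1 for i in range(3)):
        raise ValidationError("only axis-aligned NIfTI affines are supported")
    data = np.asarray(img.dataobj).astype(np.int16)
    if data.ndim != 3:
        raise ValidationError("expected a 3D NIfTI volume")
    # world axis w is fed by voxel axis perm[w] with sign sgn[w]
    perm = [int(np.nonzero(lin[w])[0][0]) for w in range(3)]
    if sorted(perm) != [0, 1, 2]:
        raise ValidationError("NIfTI affine is not a signed permutation of the axes")
    sgn = [1 if lin[w, perm[w]] > 0 else -1 for w in range(3)]
    spacing = tuple(abs(lin[w, perm[w]]) for w in range(3))
    data = np.transpose(data, perm)
    origin_idx = [0, 0, 0]
    for w in range(3):
        if sgn[w] < 0:
            data = np.flip(data, axis=w)
            origin_idx[perm[w]] = img.shape[perm[w]] - 1
    origin = tuple((affine @ np.array(origin_idx + [1.0]))[:3])
    return np.ascontiguousarray(data), spacing, origin


# ---------------------------------------------------------------------------
# per-subject morphometry record


@dataclass
class MeniscusRecord:
    """All size and position measures of one subject's meniscus compartment.

    Areas in mm², volume in mm³, distances/thickness/width in mm, coverage
    and uncovered fractions in percent.  ``Ex_Me`` and the overlap distances
    are signed: positive extrusion means the meniscus reaches beyond the
    tibial plateau rim, negative overlap distance means the meniscal inner
    rim lies internal to the plateau rim.
    """

    subject_id: str
    compartment: str
    sex: str | None = None
    age: float | None = None
    height: float | None = None
    weight: float | None = None
    ACdAB: float = math.nan
    TA: float = math.nan
    FA: float = math.nan
    EA: float = math.nan
    TOT_A: float = math.nan
    TOTA_over_ACdAB: float = math.nan
    V: float = math.nan
    Th_Me: float = math.nan
    Th_Max: float = math.nan
    Wid_Me: float = math.nan
    Wid_Max: float = math.nan
    TA_Uncov: float = math.nan
    TA_Uncovp: float = math.nan
    ACdAB_Cov: float = math.nan
    ACdAB_Covp: float = math.nan
    Ex_Me: float = math.nan
    Ex_Max: float = math.nan
    OvD_Me: float = math.nan
    OvD_Max: float = math.nan

    def validate(self) -> None:
        if self.compartment not in ("medial", "lateral"):
            raise ValidationError(f"compartment must be medial/lateral, got {self.compartment!r}")
        tot = self.TA + self.FA + self.EA
        if np.isfinite(tot) and abs(tot - self.TOT_A) > 1e-6 * max(1.0, abs(tot)):
            raise ValidationError("TOT_A must equal TA + FA + EA")
        for name in ("ACdAB_Covp", "TA_Uncovp"):
            v = getattr(self, name)
            if np.isfinite(v) and not (-1e-9 <= v <= 100 + 1e-9):
                raise ValidationError(f"{name} must be within [0, 100], got {v}")
        for lo, hi in (("Th_Me", "Th_Max"), ("Wid_Me", "Wid_Max"), ("Ex_Me", "Ex_Max"),
                       ("OvD_Me", "OvD_Max")):
            a, b = getattr(self, lo), getattr(self, hi)
            if np.isfinite(a) and np.isfinite(b) and b < a - 1e-9:
                raise ValidationError(f"{hi} must be >= {lo}")


RECORD_COLUMNS = [f.name for f in dc_fields(MeniscusRecord)]


def write_records_csv(records: Sequence[MeniscusRecord], path: str | Path) -> Path:
    """Write one row per subject x compartment, sorted, with a stable column order."""
    path = Path(path)
    keys = [(r.subject_id, r.compartment) for r in records]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ValidationError(f"duplicate (subject, compartment) rows: {sorted(dupes)}")
    df = pd.DataFrame([{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records],
                      columns=RECORD_COLUMNS)
    df = df.sort_values(["subject_id", "compartment"]).reset_index(drop=True)
    df.to_csv(path, index=False)
    return path


def read_records_csv(path: str | Path) -> list[MeniscusRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in RECORD_COLUMNS if c in df.columns}
        for opt in ("sex", "age", "height", "weight"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        records.append(MeniscusRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# label validation


@dataclass
class ValidationReport:
    voxel_counts: dict[str, int]
    slice_extents: dict[str, tuple[int, int] | None]
    missing_structures: list[str]
    mode: dict[str, str]          # per compartment: "pre-partitioned" | "solid" | "absent"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "voxel_counts": self.voxel_counts,
            "slice_extents": {k: list(v) if v else None for k, v in self.slice_extents.items()},
            "missing_structures": self.missing_structures,
            "mode": self.mode,
        }, indent=2))
        return path


def validate_labels(seg: VoxelSegmentation) -> ValidationReport:
    """Per-structure voxel counts, coronal slice extents and partition mode."""
    counts: dict[str, int] = {}
    extents: dict[str, tuple[int, int] | None] = {}
    for name, lab in seg.label_map.items():
        mask = seg.labels == lab
        n = int(mask.sum())
        counts[name] = n
        if n:
            ys = np.nonzero(mask.any(axis=(0, 2)))[0]
            extents[name] = (int(ys[0]), int(ys[-1]))
        else:
            extents[name] = None
    missing = [s for s in ("MT_ACdAB", "LT_ACdAB", "MM", "LM")
               if counts.get(s, 0) == 0 and not (
                   s in SOLID_GROUPS and any(counts.get(x, 0) for x in SOLID_GROUPS[s][1:]))]
    mode = {}
    for comp in ("medial", "lateral"):
        men = MENISCUS_LABEL[comp]
        if seg.is_prepartitioned(comp):
            mode[comp] = "pre-partitioned"
        elif counts.get(men, 0):
            mode[comp] = "solid"
        else:
            mode[comp] = "absent"
    return ValidationReport(counts, extents, missing, mode)
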