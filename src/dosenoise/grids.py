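"""Dose grids, structure masks, resampling and file I/O.

The package operates on 3D absorbed-dose distributions scored on isotropic
cubic voxel lattices, the way Monte Carlo treatment-planning systems score
dose.  The voxel edge length (``spacing_cm``) *is* the dose voxel size (DVS)
setting under study; voxel volume in cc is exactly ``spacing_cm ** 3``.

Two on-disk representations are supported:

* a neutral NRRD container (raw little-endian lattice plus a text header
  carrying geometry and the plan label), and
* DICOM RT Dose, the format clinical systems export, via pydicom.

Axis convention: arrays are indexed ``[z, y, x]`` with z the slowest (axial)
axis; ``origin_cm`` is the position of the first voxel *center*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger("dosenoise")

__all__ = [
    "DoseGrid",
    "StructureMask",
    "DimensionError",
    "UnsupportedGeometryError",
    "FormatError",
    "downsample",
    "downsample_mask",
    "fractional_voxel_count",
    "read_dose",
    "write_dose",
    "read_mask",
    "write_mask",
]


class DimensionError(ValueError):
    """Lattice dimensions incompatible with the requested resampling."""


class UnsupportedGeometryError(ValueError):
    """Grid geometry outside the supported class (anisotropic / non-uniform)."""


class FormatError(ValueError):
    """File lacks required metadata or is not a recognised container."""


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed dose (Gy) on an isotropic cubic voxel lattice.

    Parameters
    ----------
    values
        3D array of non-negative, finite doses in Gy, indexed ``[z, y, x]``.
    spacing_cm
        Isotropic voxel edge length in cm (the DVS).
    origin_cm
        Position of the first voxel center, cm, as ``(z, y, x)``.
    plan_id
        Opaque plan label carried through the pipeline.
    """

    values: np.ndarray
    spacing_cm: float
    origin_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plan_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"dose lattice must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("dose values must be finite")
        if np.any(values < 0):
            raise ValueError("dose values must be non-negative")
        if not self.spacing_cm > 0:
            raise ValueError(f"spacing_cm must be > 0, got {self.spacing_cm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "origin_cm", tuple(float(c) for c in self.origin_cm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        return self.spacing_cm**3

    @property
    def max_dose(self) -> float:
        """Single maximum voxel dose (Dmax)."""
        return float(self.values.max())

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """Same geometry and label, new dose lattice."""
        return replace(self, values=values)


@dataclass(frozen=True)
class StructureMask:
    """Boolean voxel mask congruent with a :class:`DoseGrid`.

    ``name`` labels the anatomical structure (GTV, PTV, cord, PRV, body).
    """

    name: str
    mask: np.ndarray
    spacing_cm: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={mask.ndim}")
        if not self.spacing_cm > 0:
            raise ValueError(f"spacing_cm must be > 0, got {self.spacing_cm}")
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.spacing_cm**3


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def downsample(grid: DoseGrid, factor: int, *, strict: bool = True) -> DoseGrid:
    """Block volume-average a dose grid onto a coarser lattice.

    Emulates scoring the same distribution at a DVS of
    ``grid.spacing_cm * factor``: each coarse voxel is the arithmetic mean of
    its ``factor**3`` source voxels, so the grid-wide mean dose (and hence the
    integral dose) is preserved exactly for divisible shapes.

    Parameters
    ----------
    grid
        Source grid.
    factor
        Integer edge-length ratio between the coarse and fine lattices.
    strict
        If True (default), non-divisible lattice dimensions raise
        :class:`DimensionError`; if False, trailing voxels are cropped and the
        cropped extent logged.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return grid
    shape = np.array(grid.shape)
    rem = shape % factor
    if rem.any():
        if strict:
            raise DimensionError(
                f"grid shape {grid.shape} not divisible by factor {factor}"
            )
        crop = shape - rem
        logger.warning(
            "downsample cropping trailing voxels: shape %s -> %s (factor %d)",
            tuple(shape), tuple(crop), factor,
        )
        values = grid.values[: crop[0], : crop[1], : crop[2]]
    else:
        values = grid.values
    nz, ny, nx = (s // factor for s in values.shape)
    blocks = values.reshape(nz, factor, ny, factor, nx, factor)
    coarse = blocks.mean(axis=(1, 3, 5))
    # origin moves to the center of the first coarse block
    shift = 0.5 * (factor - 1) * grid.spacing_cm
    origin = tuple(c + shift for c in grid.origin_cm)
    return DoseGrid(
        values=coarse,
        spacing_cm=grid.spacing_cm * factor,
        origin_cm=origin,
        plan_id=grid.plan_id,
    )


def downsample_mask(
    structure: StructureMask, factor: int, *, strict: bool = True
) -> StructureMask:
    """Downsample a structure mask by majority occupancy of each block.

    A coarse voxel belongs to the structure when at least half of its source
    voxels do, the voxel-occupancy analogue of re-voxelising the contour on
    the coarse lattice.
    """
    fine = DoseGrid(
        values=structure.mask.astype(np.float64), spacing_cm=structure.spacing_cm
    )
    coarse = downsample(fine, factor, strict=strict)
    return StructureMask(
        name=structure.name, mask=coarse.values >= 0.5, spacing_cm=coarse.spacing_cm
    )


def fractional_voxel_count(volume_cc: float, spacing_cm: float) -> float:
    """Number of (possibly fractional) voxels contained in a volume.

    ``volume_cc / spacing_cm**3`` — e.g. 0.035 cc holds 35 voxels at 0.1 cm
    spacing but only 4.375 at 0.2 cm, which is why near-maximum dose
    definitions behave differently across DVS settings.
    """
    if not volume_cc > 0:
        raise ValueError(f"volume_cc must be > 0, got {volume_cc}")
    if not spacing_cm > 0:
        raise ValueError(f"spacing_cm must be > 0, got {spacing_cm}")
    return volume_cc / spacing_cm**3


# ---------------------------------------------------------------------------
# Neutral NRRD container
# ---------------------------------------------------------------------------
# Minimal NRRD0004 raw-encoding reader/writer covering the subset this
# package emits: 3D float32 (dose) or uint8 (mask) lattices, isotropic
# spacings, little-endian raw data, plan label as a key-value field.

_NRRD_MAGIC = "NRRD0004"
_NRRD_TYPES = {"float": np.dtype("<f4"), "uint8": np.dtype("u1")}


def _write_nrrd(path: Path, array: np.ndarray, spacing_cm: float,
                origin_cm: tuple[float, float, float], plan_id: str,
                nrrd_type: str) -> None:
    dtype = _NRRD_TYPES[nrrd_type]
    data = np.ascontiguousarray(array, dtype=dtype)
    # NRRD sizes are fastest-first; our arrays are [z, y, x] (C order) so the
    # fastest-varying axis is x.
    sizes = " ".join(str(s) for s in reversed(array.shape))
    spacings = " ".join(f"{spacing_cm:.17g}" for _ in range(3))
    origin = ", ".join(f"{c:.17g}" for c in reversed(origin_cm))
    header = "\n".join(
        [
            _NRRD_MAGIC,
            f"type: {nrrd_type}",
            "dimension: 3",
            f"sizes: {sizes}",
            f"spacings: {spacings}",
            "endian: little",
            "encoding: raw",
            f"space origin: ({origin})",
            "units: \"cm\" \"cm\" \"cm\"",
            f"dose units:=Gy" if nrrd_type == "float" else "mask values:=0 1",
            f"plan id:={plan_id}",
            "",
            "",
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.tobytes())


def _read_nrrd(path: Path) -> tuple[np.ndarray, float, tuple[float, float, float], str]:
    with open(path, "rb") as fh:
        raw = fh.read()
    eoh = raw.find(b"\n\n")
    if not raw.startswith(_NRRD_MAGIC.encode()) or eoh < 0:
        raise FormatError(f"{path}: not a supported NRRD file")
    fields: dict[str, str] = {}
    for line in raw[:eoh].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or not line.strip():
            continue
        if ":=" in line:
            key, val = line.split(":=", 1)
        else:
            key, val = line.split(":", 1)
        fields[key.strip().lower()] = val.strip()
    for required in ("type", "sizes", "spacings", "encoding"):
        if required not in fields:
            raise FormatError(f"{path}: NRRD header missing '{required}'")
    if fields["encoding"] != "raw":
        raise FormatError(f"{path}: only raw NRRD encoding supported")
    if fields["type"] not in _NRRD_TYPES:
        raise FormatError(f"{path}: unsupported NRRD type {fields['type']!r}")
    dtype = _NRRD_TYPES[fields["type"]]
    sizes = [int(s) for s in fields["sizes"].split()]
    spacings = [float(s) for s in fields["spacings"].split()]
    if len(sizes) != 3 or len(spacings) != 3:
        raise UnsupportedGeometryError(f"{path}: only 3D grids supported")
    if not np.allclose(spacings, spacings[0], rtol=1e-9):
        raise UnsupportedGeometryError(f"{path}: anisotropic spacings {spacings}")
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        xyz = [float(c) for c in fields["space origin"].strip("() ").split(",")]
        origin = tuple(reversed(xyz))
    data = np.frombuffer(raw[eoh + 2 :], dtype=dtype)
    expected = sizes[0] * sizes[1] * sizes[2]
    if data.size != expected:
        raise FormatError(f"{path}: payload has {data.size} values, expected {expected}")
    array = data.reshape(tuple(reversed(sizes)))  # [z, y, x]
    return array, spacings[0], origin, fields.get("plan id", "")


# ---------------------------------------------------------------------------
# DICOM RT Dose
# ---------------------------------------------------------------------------

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


def _write_dicom(path: Path, grid: DoseGrid) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesDescription = grid.plan_id
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.PatientID = grid.plan_id or "ANON"
    ds.PatientName = grid.plan_id or "ANON"

    nz, ny, nx = grid.shape
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    spacing_mm = grid.spacing_cm * 10.0
    ds.PixelSpacing = [spacing_mm, spacing_mm]
    ds.SliceThickness = spacing_mm
    ds.GridFrameOffsetVector = [i * spacing_mm for i in range(nz)]
    oz, oy, ox = grid.origin_cm
    ds.ImagePositionPatient = [ox * 10.0, oy * 10.0, oz * 10.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]

    # 32-bit unsigned scaled integers, scaling chosen to span the dose range
    dmax = grid.max_dose
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    quantized = np.round(grid.values / scaling).astype(np.uint32)
    ds.PixelData = quantized.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _read_dicom(path: Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose object")
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path}: missing DoseGridScaling")
    spacing = [float(s) for s in ds.PixelSpacing]
    if not np.isclose(spacing[0], spacing[1], rtol=1e-6):
        raise UnsupportedGeometryError(f"{path}: anisotropic PixelSpacing {spacing}")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    gaps = np.diff(offsets)
    if len(gaps) and not np.allclose(gaps, gaps[0], rtol=1e-6, atol=1e-9):
        raise UnsupportedGeometryError(
            f"{path}: GridFrameOffsetVector is not uniform"
        )
    if len(gaps) and not np.isclose(gaps[0], spacing[0], rtol=1e-6):
        raise UnsupportedGeometryError(
            f"{path}: slice spacing {gaps[0]} differs from pixel spacing {spacing[0]}"
        )
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    values = ds.pixel_array.reshape(nz, ny, nx) * float(ds.DoseGridScaling)
    pos = [float(c) for c in ds.ImagePositionPatient]
    origin_cm = (pos[2] / 10.0, pos[1] / 10.0, pos[0] / 10.0)
    plan_id = str(getattr(ds, "SeriesDescription", "") or "")
    return DoseGrid(
        values=values.astype(np.float64),
        spacing_cm=spacing[0] / 10.0,
        origin_cm=origin_cm,
        plan_id=plan_id,
    )


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return True
    if path.suffix.lower() == ".nrrd":
        return False
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_dose(path: str | Path) -> DoseGrid:
    """Read a dose grid from NRRD or DICOM RT Dose (sniffed by content)."""
    path = Path(path)
    if _is_dicom(path):
        return _read_dicom(path)
    array, spacing, origin, plan_id = _read_nrrd(path)
    return DoseGrid(
        values=array.astype(np.float64),
        spacing_cm=spacing,
        origin_cm=origin,
        plan_id=plan_id,
    )


def write_dose(grid: DoseGrid, path: str | Path) -> None:
    """Write a dose grid; ``.dcm`` writes DICOM RT Dose, otherwise NRRD."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        _write_dicom(path, grid)
    else:
        _write_nrrd(path, grid.values, grid.spacing_cm, grid.origin_cm,
                    grid.plan_id, "float")


def read_mask(path: str | Path) -> StructureMask:
    """Read a 0/1 byte NRRD structure mask; name taken from the file stem."""
    path = Path(path)
    array, spacing, _origin, plan_id = _read_nrrd(path)
    return StructureMask(name=path.stem, mask=array > 0, spacing_cm=spacing)


def write_mask(structure: StructureMask, path: str | Path,
               origin_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    """Write a structure mask as a 0/1 byte NRRD with dose-grid geometry."""
    _write_nrrd(Path(path), structure.mask.astype(np.uint8), structure.spacing_cm,
                origin_cm, structure.name, "uint8")
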