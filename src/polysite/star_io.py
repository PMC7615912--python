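"""Reading and writing particle pose tables in the STAR text format.

Supports both dialects produced by subtomogram-averaging workflows:

* the modern two-block layout (a ``data_optics`` block carrying the pixel
  size plus a ``data_particles`` block with one row per particle), and
* the legacy single-block layout with every column in one loop.

Coordinates are stored in voxels, origin shifts in Å (``_rlnOriginXAngst``)
or voxels (``_rlnOriginX``), orientations as ZYZ Euler angles in degrees.
Absolute positions follow the subtraction convention of the refinement
software::

    position_Å = coordinate_vox * pixel_size − origin_shift_Å

Unknown columns are carried through verbatim so that read→write round-trips
are value-identical.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd

from .rigid_geometry import Pose, euler_to_matrix, normalize_angles

__all__ = ["ParticleRecord", "ParticleSet", "StarFormatError", "read_particles", "write_particles", "absolute_positions"]

COORD_COLS = ("rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ")
ANGLE_COLS = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
ORIGIN_ANGST_COLS = ("rlnOriginXAngst", "rlnOriginYAngst", "rlnOriginZAngst")
ORIGIN_VOX_COLS = ("rlnOriginX", "rlnOriginY", "rlnOriginZ")
DEFAULT_TOMO_COLS = ("rlnTomoName", "rlnMicrographName")
CLASS_COL = "rlnClassNumber"
PIXEL_COLS = ("rlnImagePixelSize", "rlnPixelSize", "rlnDetectorPixelSize")


class StarFormatError(ValueError):
    """Raised when a STAR table is missing required columns or malformed."""


@dataclass(frozen=True)
class ParticleRecord:
    """One picked/refined particle: pose in a named tomogram."""

    particle_id: str
    tomogram_id: str
    coord_vox: np.ndarray
    origin_shift: np.ndarray  # Å
    euler_deg: tuple[float, float, float]  # (rot, tilt, psi)
    pixel_size: float  # Å/voxel
    class_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord_vox", np.asarray(self.coord_vox, float).reshape(3))
        object.__setattr__(self, "origin_shift", np.asarray(self.origin_shift, float).reshape(3))
        if not np.all(np.isfinite(self.coord_vox)):
            raise ValueError(f"particle {self.particle_id}: non-finite coordinates")
        if not (self.pixel_size > 0):
            raise ValueError(f"particle {self.particle_id}: pixel size must be > 0")
        object.__setattr__(self, "euler_deg", normalize_angles(*self.euler_deg))

    @property
    def position(self) -> np.ndarray:
        """Absolute position in Å (subtraction convention)."""
        return self.coord_vox * self.pixel_size - self.origin_shift

    @property
    def pose(self) -> Pose:
        return Pose(self.position, euler_to_matrix(*self.euler_deg).T)


@dataclass
class ParticleSet:
    """Ordered collection of :class:`ParticleRecord` with pass-through metadata.

    ``extra`` holds unrecognized per-particle columns (same row order) and
    ``metadata`` global/optics fields, so writing reproduces the input table.
    """

    records: list[ParticleRecord]
    extra: pd.DataFrame | None = None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.particle_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate particle_id(s): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)

    def poses(self) -> list[Pose]:
        return [r.pose for r in self.records]

    def ids(self) -> list[str]:
        return [r.particle_id for r in self.records]

    def tomogram_ids(self) -> list[str]:
        return [r.tomogram_id for r in self.records]

    def by_tomogram(self) -> dict[str, list[int]]:
        """Record indices grouped by tomogram, in first-seen order."""
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            groups.setdefault(rec.tomogram_id, []).append(i)
        return groups

    def class_labels(self) -> list[str | None]:
        return [r.class_label for r in self.records]


def _find_particle_block(doc: gemmi.cif.Document) -> gemmi.cif.Block:
    for name in ("particles", "Particles"):
        blk = doc.find_block(name)
        if blk is not None:
            return blk
    for blk in doc:  # legacy: first block that has coordinate columns
        if blk.find_loop("_" + COORD_COLS[0]):
            return blk
    raise StarFormatError("no particles data block with coordinate columns found")


def _block_columns(blk: gemmi.cif.Block) -> dict[str, list[str]]:
    cols: dict[str, list[str]] = {}
    for item in blk:
        if item.loop is not None:
            loop = item.loop
            w, n = loop.width(), loop.length()
            for j, tag in enumerate(loop.tags):
                cols[tag.lstrip("_")] = [loop.values[i * w + j] for i in range(n)]
    return cols


def _optics_pixel_size(doc: gemmi.cif.Document) -> float | None:
    blk = doc.find_block("optics")
    if blk is None:
        return None
    for col in PIXEL_COLS:
        loop = blk.find_loop("_" + col)
        vals = list(loop)
        if vals:
            return float(vals[0])
        pair = blk.find_pair("_" + col)
        if pair is not None:
            return float(pair[1])
    return None


def _to_float(cols: dict[str, list[str]], name: str) -> np.ndarray:
    out = np.empty(len(cols[name]))
    for i, v in enumerate(cols[name]):
        try:
            out[i] = float(v)
        except ValueError as exc:
            raise StarFormatError(f"column {name}, row {i}: non-numeric value {v!r}") from exc
    return out


def read_particles(
    source: str | Path | io.IOBase,
    pixel_size_override: float | None = None,
    tomogram_column: str | None = None,
    apply_origin_shifts: bool = True,
) -> ParticleSet:
    """Parse a STAR particle table into a :class:`ParticleSet`.

    Parameters
    ----------
    source : path or text stream containing STAR data.
    pixel_size_override : Å/voxel; takes precedence over any value in the file.
    tomogram_column : grouping column name; defaults to ``rlnTomoName`` then
        ``rlnMicrographName``. Rows lacking it are an error, never pooled.
    apply_origin_shifts : if False, origin shifts are read but zeroed in the
        records (positions become ``coord * apix``).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        src_name = str(source)
    else:
        text = source.read()
        src_name = "<stream>"
    doc = gemmi.cif.read_string(text)
    blk = _find_particle_block(doc)
    cols = _block_columns(blk)
    if not cols or not cols.get(COORD_COLS[0]):
        raise StarFormatError("empty particle table")

    for name in COORD_COLS + ANGLE_COLS:
        if name not in cols:
            raise StarFormatError(f"required column _{name} missing from particle table")

    n = len(cols[COORD_COLS[0]])
    coords = np.column_stack([_to_float(cols, c) for c in COORD_COLS])
    angles = np.column_stack([_to_float(cols, c) for c in ANGLE_COLS])

    pixel_size = pixel_size_override
    if pixel_size is None:
        pixel_size = _optics_pixel_size(doc)
    if pixel_size is None:
        for col in PIXEL_COLS:
            if col in cols:
                pixel_size = float(_to_float(cols, col)[0])
                break
    if pixel_size is None:
        raise StarFormatError(
            "pixel size not found (no optics block, no per-row pixel-size column); "
            "pass pixel_size_override"
        )

    if all(c in cols for c in ORIGIN_ANGST_COLS):
        shifts = np.column_stack([_to_float(cols, c) for c in ORIGIN_ANGST_COLS])
    elif all(c in cols for c in ORIGIN_VOX_COLS):
        shifts = np.column_stack([_to_float(cols, c) for c in ORIGIN_VOX_COLS]) * pixel_size
    else:
        shifts = np.zeros((n, 3))
    if not apply_origin_shifts:
        shifts = np.zeros((n, 3))

    tomo_candidates = (tomogram_column,) if tomogram_column else DEFAULT_TOMO_COLS
    tomo_col = next((c for c in tomo_candidates if c and c in cols), None)
    if tomo_col is None:
        raise StarFormatError(
            f"tomogram grouping column not found (looked for {tomo_candidates}); "
            "refusing to pool rows silently"
        )
    tomo_ids = cols[tomo_col]

    if "polysiteParticleId" in cols:
        pids = cols["polysiteParticleId"]
    else:
        pids = [f"p{i:06d}" for i in range(n)]
    labels = cols.get(CLASS_COL)
    if labels is not None:
        labels = [None if v in ("-", ".", "?") else v for v in labels]

    known = set(COORD_COLS + ANGLE_COLS + ORIGIN_ANGST_COLS + ORIGIN_VOX_COLS) | {
        tomo_col, CLASS_COL, "polysiteParticleId"
    }
    extra_cols = {k: v for k, v in cols.items() if k not in known}
    extra = pd.DataFrame(extra_cols) if extra_cols else None

    records = [
        ParticleRecord(
            particle_id=pids[i],
            tomogram_id=tomo_ids[i],
            coord_vox=coords[i],
            origin_shift=shifts[i],
            euler_deg=tuple(angles[i]),
            pixel_size=float(pixel_size),
            class_label=None if labels is None else labels[i],
        )
        for i in range(n)
    ]
    meta = {
        "pixel_size": float(pixel_size),
        "source": src_name,
        "tomogram_column": tomo_col,
        "origin_shifts_applied": apply_origin_shifts,
    }
    return ParticleSet(records, extra=extra, metadata=meta)


def write_particles(ps: ParticleSet, dest: str | Path | io.IOBase | None = None) -> str:
    """Serialize a :class:`ParticleSet` as two-block STAR text.

    Floating-point values are written with 6 decimal places; the emitted table
    re-reads value-identically via :func:`read_particles`.
    """
    if len(ps) == 0:
        raise ValueError("refusing to write an empty particle set")
    pixel_size = ps.metadata.get("pixel_size", ps.records[0].pixel_size)
    tomo_col = ps.metadata.get("tomogram_column") or DEFAULT_TOMO_COLS[0]

    lines = [
        "",
        "data_optics",
        "",
        "loop_",
        "_rlnOpticsGroup #1",
        "_rlnImagePixelSize #2",
        f"1 {pixel_size:.6f}",
        "",
        "data_particles",
        "",
        "loop_",
    ]
    tags = ["polysiteParticleId", tomo_col, *COORD_COLS, *ORIGIN_ANGST_COLS, *ANGLE_COLS]
    has_labels = any(r.class_label is not None for r in ps.records)
    if has_labels:
        tags.append(CLASS_COL)
    extra_tags = list(ps.extra.columns) if ps.extra is not None else []
    tags.extend(extra_tags)
    lines.extend(f"_{t} #{i + 1}" for i, t in enumerate(tags))

    for i, r in enumerate(ps.records):
        vals = [r.particle_id, r.tomogram_id]
        vals += [f"{v:.6f}" for v in r.coord_vox]
        vals += [f"{v:.6f}" for v in r.origin_shift]
        vals += [f"{v:.6f}" for v in r.euler_deg]
        if has_labels:
            vals.append(str(r.class_label) if r.class_label is not None else "-")
        vals += [str(ps.extra.iloc[i][t]) for t in extra_tags]
        lines.append(" ".join(vals))
    lines.append("")
    text = "\n".join(lines)

    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


def absolute_positions(ps: ParticleSet) -> np.ndarray:
    """Per-particle absolute positions in Å, ``coord*apix − origin_shift``,
    in record order (n×3)."""
    return np.array([r.position for r in ps.records]).reshape(len(ps), 3)
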