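"""Rigid-body pose algebra for subtomogram particles.

A refined particle carries three Euler angles (rot, tilt, psi) and a position.
The angles follow the intrinsic ZYZ convention of the refinement software:

    A = Rz(psi) @ Ry(tilt) @ Rz(rot)

``A`` rotates tomogram-frame vectors into the reference (subtomogram-average)
frame; the reference->tomogram rotation stored on a :class:`Pose` is therefore
``R = A.T``.  All positions and offsets are in Angstrom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "RelativePose",
    "SiteDefinition",
    "euler_to_matrix",
    "matrix_to_euler",
    "normalize_angles",
    "site_world",
    "relative_pose",
    "compose",
    "rotation_angle",
    "load_sites",
]

_ORTHO_TOL = 1e-9


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {R.shape}")
    err = np.linalg.norm(R.T @ R - np.eye(3))
    if err > tol or abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError(
            f"matrix is not a proper rotation (orthonormality error {err:.2e}, "
            f"det {np.linalg.det(R):.6f})"
        )
    return R


@dataclass(frozen=True)
class Pose:
    """Particle pose: position (Å, tomogram frame) and reference->tomogram rotation."""

    position: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        object.__setattr__(self, "R", _check_rotation(self.R))

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.eye(3))

    @classmethod
    def from_euler(cls, position, rot: float, tilt: float, psi: float) -> "Pose":
        return cls(np.asarray(position, dtype=float), euler_to_matrix(rot, tilt, psi).T)


@dataclass(frozen=True)
class RelativePose:
    """Neighbor pose expressed in an anchor particle's reference frame.

    ``t`` is the neighbor position (Å) and ``Rrel`` its orientation, both in
    the anchor frame; invariant under any global rigid motion of the field.
    """

    t: np.ndarray
    Rrel: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))
        object.__setattr__(self, "Rrel", _check_rotation(self.Rrel))

    @classmethod
    def identity(cls) -> "RelativePose":
        return cls(np.zeros(3), np.eye(3))


@dataclass(frozen=True)
class SiteDefinition:
    """A named point of interest fixed in the reference frame (e.g. the mRNA
    entry channel opening on the 40S subunit), as an offset in Å."""

    name: str
    offset_ref: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        off = np.asarray(self.offset_ref, dtype=float).reshape(3)
        if not np.all(np.isfinite(off)):
            raise ValueError(f"site {self.name!r} has non-finite offset {off}")
        object.__setattr__(self, "offset_ref", off)


def normalize_angles(rot: float, tilt: float, psi: float) -> tuple[float, float, float]:
    """Map Euler angles into canonical ranges: tilt in [0, 180], rot/psi in
    (-180, 180] (ties at ±180 -> +180)."""

    def _wrap(a: float) -> float:
        a = ((a + 180.0) % 360.0) - 180.0
        return 180.0 if a == -180.0 else a

    tilt_w = _wrap(tilt)
    if tilt_w < 0:
        # (rot, -tilt, psi) is equivalent to (rot+180, tilt, psi+180) in ZYZ
        return _wrap(rot + 180.0), -tilt_w, _wrap(psi + 180.0)
    return _wrap(rot), tilt_w, _wrap(psi)


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix A = Rz(psi) @ Ry(tilt) @ Rz(rot) (tomogram->reference)."""
    if not np.all(np.isfinite([rot, tilt, psi])):
        raise ValueError("Euler angles must be finite")
    # extrinsic z-y-z with angles (rot, tilt, psi) composes exactly this product
    return Rotation.from_euler("zyz", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(A: np.ndarray, tol: float = 1e-6) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`, canonical ranges.

    At gimbal lock (tilt ~ 0 or 180) rot is set to 0 and psi absorbs the
    residual in-plane rotation.
    """
    A = np.asarray(A, dtype=float)
    _check_rotation(A, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock; handled below
        rot, tilt, psi = Rotation.from_matrix(A).as_euler("zyz", degrees=True)
    if tilt < 0:  # scipy may return tilt in [-180, 0) for zyz; canonicalize
        rot, tilt, psi = rot + 180.0, -tilt, psi + 180.0
    rot, tilt, psi = normalize_angles(rot, tilt, psi)
    if min(tilt, 180.0 - tilt) < 1e-7:  # gimbal lock: fold rot into psi
        if tilt < 90.0:
            psi = psi + rot
        else:
            psi = psi - rot
        rot = 0.0
        rot, tilt, psi = normalize_angles(rot, tilt, psi)
    return rot, tilt, psi


def site_world(pose: Pose, site: SiteDefinition | np.ndarray) -> np.ndarray:
    """Map a reference-frame site offset into tomogram coordinates (Å)."""
    offset = site.offset_ref if isinstance(site, SiteDefinition) else np.asarray(site, float)
    return pose.position + pose.R @ offset


def relative_pose(anchor: Pose, neighbor: Pose) -> RelativePose:
    """Express ``neighbor`` in ``anchor``'s reference frame."""
    t = anchor.R.T @ (neighbor.position - anchor.position)
    Rrel = anchor.R.T @ neighbor.R
    return RelativePose(t, Rrel)


def compose(anchor: Pose, rel: RelativePose) -> Pose:
    """Apply a relative pose to an anchor pose; inverse of :func:`relative_pose`."""
    return Pose(anchor.position + anchor.R @ rel.t, anchor.R @ rel.Rrel)


def rotation_angle(rel: RelativePose | np.ndarray) -> float:
    """Geodesic rotation angle of a relative pose, degrees in [0, 180]."""
    R = rel.Rrel if isinstance(rel, RelativePose) else _check_rotation(rel)
    cos = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def load_sites(source: str | Path | dict) -> dict[str, SiteDefinition]:
    """Load site definitions from a ``{name: [x, y, z]}`` JSON mapping (Å).

    Entries whose value is not a 3-vector (e.g. a provenance note) are skipped.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = json.load(fh)
    else:
        raw = source
    sites: dict[str, SiteDefinition] = {}
    for name, value in raw.items():
        if isinstance(value, str):
            continue
        vec = np.asarray(value, dtype=float)
        if vec.shape != (3,):
            raise ValueError(f"site {name!r}: expected a 3-vector, got {value!r}")
        sites[name] = SiteDefinition(name, vec)
    if not sites:
        raise ValueError("no site definitions found")
    return sites


def require_sites(sites: dict[str, SiteDefinition], *names: str) -> list[SiteDefinition]:
    """Fetch named sites, raising with the configured names on a miss."""
    missing = [n for n in names if n not in sites]
    if missing:
        raise KeyError(
            f"site(s) {missing} not defined; configured sites: {sorted(sites)}"
        )
    return [sites[n] for n in names]
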