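"""Coarse-grained steric modeling of polysome arrangements.

Each ribosome's excluded volume is a small union of spheres fixed in its
reference frame (by default one large-subunit sphere and one small-subunit
sphere, calibrated so consecutive ribosomes of the canonical collided
arrangement are in contact without overlapping).  Iterating a relative pose
extrapolates an idealized queue; counting when non-adjacent members first
collide gives the maximal sterically allowed polysome length for that
arrangement.  Factor footprints (e.g. GCN1 bridging a disome) are tested the
same way against the trailing ribosome's envelope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rigid_geometry import Pose, RelativePose, compose

__all__ = [
    "Envelope",
    "FactorFootprint",
    "clash",
    "pair_overlap",
    "extrapolate_queue",
    "max_queue_length",
    "factor_accommodation",
    "load_envelope",
    "load_footprint",
]

#: adjacent queue members genuinely touch in a collision; allow this much overlap (Å)
ADJACENT_CONTACT_TOLERANCE = 5.0


@dataclass(frozen=True)
class Envelope:
    """Multi-sphere excluded-volume model in the reference frame."""

    name: str
    centers: np.ndarray  # (k,3) Å
    radii: np.ndarray  # (k,) Å

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        r = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(c) != len(r) or len(c) == 0:
            raise ValueError("envelope needs >=1 sphere with matching centers/radii")
        if np.any(r <= 0):
            raise ValueError("sphere radii must be positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)

    def world_centers(self, pose: Pose) -> np.ndarray:
        return pose.position + self.centers @ pose.R.T


class FactorFootprint(Envelope):
    """Excluded volume of a bound factor, in the frame of the ribosome it is
    anchored on (for GCN1: the leading/stalled ribosome of a disome)."""


def pair_overlap(
    poseA: Pose, poseB: Pose, envA: Envelope, envB: Envelope | None = None
) -> float:
    """Worst sphere-sphere penetration between two placed envelopes (Å).

    Positive = overlap depth, negative = clearance between closest spheres.
    """
    envB = envA if envB is None else envB
    ca, cb = envA.world_centers(poseA), envB.world_centers(poseB)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    pen = envA.radii[:, None] + envB.radii[None, :] - d
    return float(pen.max())


def clash(poseA: Pose, poseB: Pose, env: Envelope, tolerance: float = 0.0) -> bool:
    """True iff any sphere of A overlaps any sphere of B by more than
    ``tolerance``.  Symmetric in A and B."""
    return pair_overlap(poseA, poseB, env) > tolerance


def extrapolate_queue(seed: Pose, rel: RelativePose, n: int) -> list[Pose]:
    """Iterate ``rel`` from ``seed``: pose_1 = seed, pose_k = pose_{k-1} ∘ rel."""
    if n < 1:
        raise ValueError("queue length must be >= 1")
    poses = [seed]
    for _ in range(n - 1):
        poses.append(compose(poses[-1], rel))
    return poses


def max_queue_length(
    rel: RelativePose,
    env: Envelope,
    n_max: int = 50,
    adjacent_tolerance: float = ADJACENT_CONTACT_TOLERANCE,
) -> int:
    """Largest queue length L ≤ n_max free of steric clashes.

    Consecutive members may overlap up to ``adjacent_tolerance`` (they are in
    contact in a genuine collision); all other pairs use zero tolerance.
    Returns ``n_max`` if the arrangement never self-clashes (e.g. a helix).
    """
    poses = extrapolate_queue(Pose.identity(), rel, n_max)
    for L in range(2, n_max + 1):
        new = poses[L - 1]
        for j in range(L - 1):
            tol = adjacent_tolerance if j == L - 2 else 0.0
            if clash(poses[j], new, env, tolerance=tol):
                return L - 1
    return n_max


def factor_accommodation(
    fp: FactorFootprint,
    lead: Pose,
    rel_trailing: RelativePose,
    env: Envelope,
) -> dict:
    """Can a factor anchored on the leading ribosome coexist with the trailing
    ribosome placed by ``rel_trailing``?

    Returns ``compatible`` (no footprint sphere penetrates the trailing
    envelope) and ``min_overlap``, the worst penetration in Å (negative =
    clearance)."""
    trailing = compose(lead, rel_trailing)
    worst = pair_overlap(lead, trailing, fp, env)
    return {"compatible": worst <= 0.0, "min_overlap": worst}


def _load_spheres(entry: dict) -> tuple[np.ndarray, np.ndarray]:
    spheres = entry["spheres"]
    centers = np.array([s["center"] for s in spheres], dtype=float)
    radii = np.array([s["radius"] for s in spheres], dtype=float)
    return centers, radii


def load_envelope(source: str | Path | dict, name: str) -> Envelope:
    """Load a named envelope from an ``envelopes.json``-style mapping."""
    raw = json.loads(Path(source).read_text()) if isinstance(source, (str, Path)) else source
    if name not in raw:
        avail = sorted(k for k in raw if not k.startswith("_"))
        raise KeyError(f"envelope {name!r} not found; available: {avail}")
    centers, radii = _load_spheres(raw[name])
    return Envelope(name, centers, radii)


def load_footprint(source: str | Path | dict, name: str) -> FactorFootprint:
    """Load a named factor footprint from a ``footprints.json``-style mapping."""
    raw = json.loads(Path(source).read_text()) if isinstance(source, (str, Path)) else source
    if name not in raw:
        avail = sorted(k for k in raw if not k.startswith("_"))
        raise KeyError(f"footprint {name!r} not found; available: {avail}")
    centers, radii = _load_spheres(raw[name])
    return FactorFootprint(name, centers, radii)
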