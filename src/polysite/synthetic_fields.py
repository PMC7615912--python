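"""Synthetic ribosome fields with ground truth.

Emulates the particle tables a subtomogram-averaging workflow would produce
for lamella tomograms: each tomogram is a thin slab holding a few hundred
ribosomes organized as monosomes and polysomes.  Consecutive-ribosome
geometry is drawn per polysome from one of three presets — ``loose``
(untreated-like spacing, inter-site gap ~ Normal(70 Å, 15 Å), random
accepted orientations), ``collided`` (canonical collided-disome transform),
or ``helical`` (canonical compact-helix transform) — then rotational and
translational pose noise and optional picking false positives/negatives are
applied.  Every field carries per-particle and per-link ground truth so the
whole analysis pipeline can be benchmarked.

Named scenario presets encode the study conditions: their collided+helical
particle fractions are calibrated so the *expected* fraction of particles
with a close (<6 nm) neighbor equals the design value for that condition
(untreated 4.4%, 20 min stress 9.2%, 1 h 30%, 4 h 19%, ZNF598-KO 61%).
The calibration uses the generative link model itself (noncentral-χ
analytics for fixture links, seeded Monte Carlo for rejection-sampled loose
links); it never looks at pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .rigid_geometry import Pose, compose, matrix_to_euler, site_world
from .star_io import ParticleRecord, ParticleSet
from .steric_model import ADJACENT_CONTACT_TOLERANCE, Envelope
from . import resources

__all__ = [
    "Scenario",
    "SyntheticField",
    "simulate_polysome",
    "simulate_field",
    "scenario_preset",
    "PRESET_CLOSE_FRACTIONS",
    "expected_close_fraction",
]

DEFAULT_PIXEL_SIZE = 2.17  # Å/voxel, typical tomographic acquisition
CLOSE_CUTOFF = 60.0  # Å; geometric proxy for a "defined close neighbor"

#: non-consecutive entry/exit site pairs are kept beyond this distance so the
#: 12 nm nearest-neighbor search can only ever find the true link partner
IDENTIFIABILITY_MARGIN = 126.0

GEOM_LOOSE = "loose"
GEOM_COLLIDED = "collided"
GEOM_HELICAL = "helical"
GEOM_MONOSOME = "monosome"
GEOM_FALSE_POSITIVE = "false_positive"

#: design close-neighbor particle fractions per condition
PRESET_CLOSE_FRACTIONS = {
    "untreated": 0.044,
    "ans20min": 0.092,
    "ans1h": 0.30,
    "ans4h": 0.19,
    "znf598ko": 0.61,
}


@dataclass(frozen=True)
class Scenario:
    """Generation parameters for one simulated condition."""

    box_nm: tuple[float, float, float] = (800.0, 800.0, 180.0)
    n_tomograms: int = 20
    particles_per_tomogram: int = 300
    fractions: dict = field(
        default_factory=lambda: {GEOM_LOOSE: 0.0, GEOM_COLLIDED: 0.0, GEOM_HELICAL: 0.0}
    )
    # latent inter-site gap law for loose polysomes; the mean is calibrated
    # once so the *observed* nearest-distance distribution (which, like real
    # measurements, includes pose noise) peaks at 7.0 nm under default noise
    loose_gap: tuple[float, float] = (68.8, 15.0)  # Å (mean, sd)
    pose_noise: tuple[float, float] = (5.0, 2.0)  # (sigma_t Å, sigma_r deg)
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    seed: int = 0
    name: str = "custom"
    design_close_fraction: float | None = None

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(v < 0 for v in self.fractions.values()) or total > 1.0 + 1e-9:
            raise ValueError(f"fractions must be >=0 and sum to <=1, got {self.fractions}")
        if not (0 <= self.false_positive_rate < 1 and 0 <= self.false_negative_rate < 1):
            raise ValueError("false positive/negative rates must be in [0, 1)")
        if any(b <= 0 for b in self.box_nm):
            raise ValueError("box dimensions must be positive")


#: chain-length laws per geometry (sampler + mean length)
def _sample_length(geometry: str, rng: np.random.Generator) -> int:
    if geometry == GEOM_LOOSE:
        return 2 + rng.geometric(0.25) - 1  # support >=2, mean 5
    if geometry == GEOM_COLLIDED:
        return int(rng.integers(2, 5))  # queues of 2-4
    if geometry == GEOM_HELICAL:
        return int(rng.integers(4, 11))  # 4-10
    raise ValueError(f"unknown polysome geometry {geometry!r}")


_MEAN_LENGTH = {GEOM_LOOSE: 5.0, GEOM_COLLIDED: 3.0, GEOM_HELICAL: 7.0}
_MIN_LENGTH = {GEOM_LOOSE: 2, GEOM_COLLIDED: 2, GEOM_HELICAL: 4}


@dataclass
class SyntheticField:
    """A generated field: emittable particle table plus ground truth."""

    particles: ParticleSet
    truth: pd.DataFrame  # particle_id, tomogram_id, polysome_id, chain_index, geometry, is_false_positive
    links: pd.DataFrame  # tomogram_id, leading_id, trailing_id, geometry
    scenario: Scenario


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def _noise_rotation(sigma_r_deg: float, rng: np.random.Generator) -> np.ndarray:
    angle = abs(rng.normal(0.0, np.radians(sigma_r_deg)))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _members_clash(poses: list[Pose], candidate: Pose, env: Envelope) -> bool:
    """Clash of a candidate trailing member against existing chain members
    (adjacent pair exempt up to contact tolerance)."""
    for j, p in enumerate(poses):
        tol = ADJACENT_CONTACT_TOLERANCE if j == len(poses) - 1 else 0.0
        ca, cb = env.world_centers(p), env.world_centers(candidate)
        d = np.linalg.norm(ca[:, None] - cb[None, :], axis=-1)
        if np.any(env.radii[:, None] + env.radii[None, :] - d > tol):
            return True
    return False


def simulate_polysome(
    geometry: str,
    length: int,
    rng: np.random.Generator,
    sites: dict | None = None,
    envelope: Envelope | None = None,
    pose_library=None,
    loose_gap: tuple[float, float] = (68.8, 15.0),
    max_tries: int = 10_000,
) -> tuple[list[Pose], list[tuple[int, int]]]:
    """Build one polysome in a local frame (leading ribosome at the origin).

    Returns member poses ordered leading(3′)-first and links as
    ``(leading_index, trailing_index)`` over that ordering.  ``collided`` and
    ``helical`` apply the canonical fixture transform exactly; ``loose``
    draws the inter-site gap from ``Normal(loose_gap)`` and a uniform random
    relative orientation, rejection-sampled against the envelope so members
    never overlap (adjacent members may touch).
    """
    if length < 1:
        raise ValueError("polysome length must be >= 1")
    sites = sites if sites is not None else resources.default_sites()
    envelope = envelope if envelope is not None else resources.default_envelope()
    entry = sites["mrna_entry"].offset_ref
    exit_ = sites["mrna_exit"].offset_ref
    gap_mean, gap_sd = loose_gap

    poses = [Pose.identity()]
    links = []
    for k in range(1, length):
        if geometry in (GEOM_COLLIDED, GEOM_HELICAL):
            if pose_library is None:
                pose_library = resources.default_pose_library()
            rel = pose_library[GEOM_COLLIDED if geometry == GEOM_COLLIDED else GEOM_HELICAL]
            candidate = compose(poses[-1], rel)
        elif geometry == GEOM_LOOSE:
            entries = np.array([site_world(p, entry) for p in poses])
            exits = np.array([site_world(p, exit_) for p in poses])
            anchor = poses[-1]
            mem_centers = np.concatenate([envelope.world_centers(p) for p in poses])
            mem_radii = np.tile(envelope.radii, len(poses))
            # adjacent member may touch (contact tolerance); earlier ones not
            tol = np.zeros(len(mem_radii))
            tol[-len(envelope.radii):] = ADJACENT_CONTACT_TOLERANCE
            candidate = None
            tries = 0
            while candidate is None and tries < max_tries:
                # the gap is drawn once, then the orientation is rejection-
                # sampled *given* that gap, so the realized gap law stays
                # exactly Normal(loose_gap)
                g = rng.normal(gap_mean, gap_sd)
                if g < 5.0:
                    tries += 1
                    continue
                B = 128  # orientation batch per drawn gap
                for _ in range(16):
                    tries += B
                    u = rng.normal(size=(B, 3))
                    u /= np.linalg.norm(u, axis=1, keepdims=True)
                    Rm = Rotation.random(B, rng=rng).as_matrix()
                    t_loc = exit_ + g * u - np.einsum("bij,j->bi", Rm, entry)
                    pos = anchor.position + t_loc @ anchor.R.T
                    Rw = np.einsum("ij,bjk->bik", anchor.R, Rm)
                    cand_centers = pos[:, None, :] + np.einsum(
                        "bij,kj->bki", Rw, envelope.centers
                    )  # (B, k, 3)
                    d = np.linalg.norm(
                        cand_centers[:, :, None, :] - mem_centers[None, None, :, :], axis=-1
                    )  # (B, k, m)
                    pen = envelope.radii[None, :, None] + mem_radii[None, None, :] - d
                    ok = ~np.any(pen > tol[None, None, :], axis=(1, 2))
                    # identifiability: only the true link may fall inside the
                    # nearest-neighbor search radius
                    ce = pos + np.einsum("bij,j->bi", Rw, entry)
                    cx = pos + np.einsum("bij,j->bi", Rw, exit_)
                    if len(exits) > 1:
                        d_wrong = np.linalg.norm(
                            ce[:, None, :] - exits[None, :-1, :], axis=-1
                        )
                        ok &= d_wrong.min(axis=1) > IDENTIFIABILITY_MARGIN
                    d_rev = np.linalg.norm(cx[:, None, :] - entries[None, :, :], axis=-1)
                    ok &= d_rev.min(axis=1) > IDENTIFIABILITY_MARGIN
                    hits = np.flatnonzero(ok)
                    if hits.size:
                        b = int(hits[0])
                        candidate = Pose(pos[b], Rw[b])
                        break
                    if tries >= max_tries:
                        break
            if candidate is None:
                raise RuntimeError(
                    f"loose-link rejection sampling failed after {max_tries} tries "
                    "(infeasible gap/envelope preset)"
                )
        else:
            raise ValueError(f"unknown polysome geometry {geometry!r}")
        poses.append(candidate)
        links.append((k - 1, k))  # (leading_index, trailing_index)
    return poses, links


def _partition_particles(n: int, fractions: dict, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Split a tomogram's particle budget into polysomes (geometry, length)
    plus monosomes; conserves the total count exactly."""
    jobs: list[tuple[str, int]] = []
    used = 0
    max_len = {GEOM_LOOSE: 15, GEOM_COLLIDED: 4, GEOM_HELICAL: 10}
    for geom in (GEOM_COLLIDED, GEOM_HELICAL, GEOM_LOOSE):
        quota = int(round(fractions.get(geom, 0.0) * n))
        lo, hi = _MIN_LENGTH[geom], max_len[geom]
        placed = 0
        while quota - placed >= lo:
            remaining = quota - placed
            L = _sample_length(geom, rng)
            if remaining <= hi:
                # close out the quota exactly with one final feasible chain
                L = remaining if remaining >= lo else lo
            elif 0 < remaining - L < lo:
                L = remaining - lo  # leave room for a minimal final chain
            L = min(L, remaining)
            jobs.append((geom, L))
            placed += L
        used += placed
    jobs.extend((GEOM_MONOSOME, 1) for _ in range(n - used))
    return jobs


def simulate_field(sc: Scenario) -> SyntheticField:
    """Generate all tomograms of a scenario; reproducible from ``sc.seed``."""
    rng = np.random.default_rng(sc.seed)
    sites = resources.default_sites()
    envelope = resources.default_envelope()
    pose_library = resources.default_pose_library()
    box = np.asarray(sc.box_nm, dtype=float) * 10.0  # Å
    margin_z = float(np.max(np.linalg.norm(envelope.centers, axis=1) + envelope.radii))
    if box[2] <= 2 * margin_z:
        raise ValueError("slab too thin for the envelope")
    sigma_t, sigma_r = sc.pose_noise

    records: list[ParticleRecord] = []
    truth_rows: list[dict] = []
    link_rows: list[dict] = []
    pid_counter = 0

    for tomo_i in range(sc.n_tomograms):
        tomo_id = f"tomo_{tomo_i + 1:03d}"
        jobs = _partition_particles(sc.particles_per_tomogram, sc.fractions, rng)
        placed_centers: list[np.ndarray] = []
        placed_radii: list[float] = []
        placed_entries: list[np.ndarray] = []
        placed_exits: list[np.ndarray] = []
        entry_off = sites["mrna_entry"].offset_ref
        exit_off = sites["mrna_exit"].offset_ref
        tree: cKDTree | None = None
        entry_tree: cKDTree | None = None
        exit_tree: cKDTree | None = None
        query_r = 2.0 * float(np.max(np.linalg.norm(envelope.centers, axis=1) + envelope.radii))
        attempts_left = 100_000
        poly_counter = 0

        tomo_particles: list[tuple[Pose, str, str, int]] = []  # pose, polysome_id, geometry, chain_index

        for geom, length in jobs:
            if geom == GEOM_MONOSOME:
                local, links = [Pose.identity()], []
            else:
                # a long loose chain can fold into a dead end; rebuild it
                for attempt in range(50):
                    try:
                        local, links = simulate_polysome(
                            geom, length, rng, sites=sites, envelope=envelope,
                            pose_library=pose_library, loose_gap=sc.loose_gap,
                        )
                        break
                    except RuntimeError:
                        if attempt == 49:
                            raise
            # whole-polysome placement with rejection on inter-polysome clash
            while True:
                attempts_left -= 1
                if attempts_left <= 0:
                    raise RuntimeError(
                        "particle density infeasible for the box (placement attempts exhausted)"
                    )
                Rw = _random_rotation(rng)
                pos = rng.uniform([0, 0, margin_z], [box[0], box[1], box[2] - margin_z])
                world = [Pose(pos + Rw @ p.position, Rw @ p.R) for p in local]
                if any(p.position[2] < margin_z or p.position[2] > box[2] - margin_z
                       for p in world):
                    continue
                if any(np.any(p.position[:2] < 0) or np.any(p.position[:2] > box[:2])
                       for p in world):
                    continue
                centers = np.concatenate([envelope.world_centers(p) for p in world])
                radii = np.tile(envelope.radii, len(world))
                if tree is not None:
                    hit = False
                    for c, r in zip(centers, radii):
                        for j in tree.query_ball_point(c, r=query_r):
                            if np.linalg.norm(placed_centers[j] - c) < placed_radii[j] + r:
                                hit = True
                                break
                        if hit:
                            break
                    if hit:
                        continue
                # cross-polysome identifiability: no foreign entry/exit pair
                # may enter the nearest-neighbor search radius
                new_entries = np.array([site_world(p, entry_off) for p in world])
                new_exits = np.array([site_world(p, exit_off) for p in world])
                if exit_tree is not None:
                    de, _ = exit_tree.query(new_entries, k=1)
                    dx, _ = entry_tree.query(new_exits, k=1)
                    if min(de.min(), dx.min()) <= IDENTIFIABILITY_MARGIN:
                        continue
                break
            placed_centers.extend(centers)
            placed_radii.extend(radii)
            placed_entries.extend(new_entries)
            placed_exits.extend(new_exits)
            tree = cKDTree(np.asarray(placed_centers))
            entry_tree = cKDTree(np.asarray(placed_entries))
            exit_tree = cKDTree(np.asarray(placed_exits))

            poly_id = f"{tomo_id}_poly{poly_counter:04d}"
            poly_counter += 1
            # ground-truth chain order is 5'->3' (trailing end first)
            n_mem = len(world)
            ids_here = []
            for local_idx, pose in enumerate(world):
                chain_index = (n_mem - 1) - local_idx  # leading-most gets the last index
                tomo_particles.append((pose, poly_id, geom, chain_index))
                ids_here.append(pid_counter + local_idx)
            for lead_idx, trail_idx in links:
                link_rows.append(
                    {
                        "tomogram_id": tomo_id,
                        "leading_id": f"s{ids_here[lead_idx]:06d}",
                        "trailing_id": f"s{ids_here[trail_idx]:06d}",
                        "geometry": geom,
                    }
                )
            pid_counter += n_mem

        # false positives: spurious picks, uniform over the box and SO(3)
        n_fp = int(round(sc.false_positive_rate * sc.particles_per_tomogram))
        for _ in range(n_fp):
            pos = rng.uniform([0, 0, 0], box)
            tomo_particles.append(
                (Pose(pos, _random_rotation(rng)), f"{tomo_id}_fp{pid_counter}", GEOM_FALSE_POSITIVE, 0)
            )
            pid_counter += 1

        # pose noise, then false negatives; ids follow generation order
        base = pid_counter - len(tomo_particles)
        for i, (pose, poly_id, geom, chain_index) in enumerate(tomo_particles):
            pid = f"s{base + i:06d}"
            dropped = sc.false_negative_rate > 0 and rng.random() < sc.false_negative_rate
            noisy_pos = pose.position + rng.normal(0.0, sigma_t, size=3)
            noisy_R = _noise_rotation(sigma_r, rng) @ pose.R
            if not dropped:
                rot, tilt, psi = matrix_to_euler(noisy_R.T)
                records.append(
                    ParticleRecord(
                        particle_id=pid,
                        tomogram_id=tomo_id,
                        coord_vox=noisy_pos / DEFAULT_PIXEL_SIZE,
                        origin_shift=np.zeros(3),
                        euler_deg=(rot, tilt, psi),
                        pixel_size=DEFAULT_PIXEL_SIZE,
                        class_label=geom,
                    )
                )
            truth_rows.append(
                {
                    "particle_id": pid,
                    "tomogram_id": tomo_id,
                    "polysome_id": poly_id,
                    "chain_index": chain_index,
                    "geometry": geom,
                    "is_false_positive": geom == GEOM_FALSE_POSITIVE,
                    "picked": not dropped,
                }
            )

    truth = pd.DataFrame(truth_rows)
    links_df = pd.DataFrame(link_rows, columns=["tomogram_id", "leading_id", "trailing_id", "geometry"])
    picked = set(truth.loc[truth["picked"], "particle_id"])
    if len(links_df):
        # links through deleted particles are broken in the observable truth
        links_df["observable"] = links_df["leading_id"].isin(picked) & links_df[
            "trailing_id"
        ].isin(picked)
    ps = ParticleSet(
        records,
        metadata={
            "pixel_size": DEFAULT_PIXEL_SIZE,
            "tomogram_column": "rlnTomoName",
            "scenario": sc.name,
        },
    )
    return SyntheticField(ps, truth, links_df, sc)


# ---------------------------------------------------------------------------
# close-neighbor design-value calibration

def _site_levers() -> tuple[float, float, float]:
    sites = resources.default_sites()
    e = sites["mrna_entry"].offset_ref
    x = sites["mrna_exit"].offset_ref
    lib = resources.default_pose_library()
    rel = lib[GEOM_COLLIDED]
    lead, trail = Pose.identity(), compose(Pose.identity(), rel)
    gap = float(np.linalg.norm(site_world(trail, e) - site_world(lead, x)))
    return float(np.linalg.norm(e)), float(np.linalg.norm(x)), gap


def _noise_sigma2(sigma_t: float, sigma_r_deg: float) -> float:
    """Per-axis variance of the noisy inter-site vector: two independent
    particle translations plus small-rotation site displacement at levers
    |entry|, |exit| (E|Δ|² ≈ (2/3)L²σ_r² for a random-axis rotation)."""
    L_e, L_x, _ = _site_levers()
    s2_rot = (2.0 / 9.0) * np.radians(sigma_r_deg) ** 2 * (L_e**2 + L_x**2)
    return 2.0 * sigma_t**2 + s2_rot


def _q_link_fixture(sigma_t: float, sigma_r: float, cutoff: float) -> float:
    """P(noisy link distance < cutoff) for a canonical fixture link
    (noncentral-χ² model)."""
    _, _, gap = _site_levers()
    s2 = _noise_sigma2(sigma_t, sigma_r)
    return float(stats.ncx2.cdf(cutoff**2 / s2, df=3, nc=gap**2 / s2))


@lru_cache(maxsize=32)
def _q_link_loose(
    gap_mean: float, gap_sd: float, sigma_t: float, sigma_r: float, cutoff: float
) -> float:
    """P(noisy link distance < cutoff) for a loose link.

    The generator draws the gap from Normal(gap_mean, gap_sd) and rejection-
    samples only the orientation given that gap, so the noisy distance given
    g follows a noncentral-χ law; integrate it over the gap density."""
    s2 = _noise_sigma2(sigma_t, sigma_r)
    g = np.linspace(max(5.0, gap_mean - 6 * gap_sd), gap_mean + 6 * gap_sd, 2001)
    w = stats.norm.pdf(g, gap_mean, gap_sd)
    p = stats.ncx2.cdf(cutoff**2 / s2, df=3, nc=g**2 / s2)
    return float(np.trapezoid(w * p, g) / np.trapezoid(w, g))


def _member_close_prob(q1: float, mean_length: float) -> float:
    """Per-member probability of >=1 close link: chain ends carry one link,
    interior members two (links treated as independent)."""
    q2 = 1.0 - (1.0 - q1) ** 2
    return (2.0 * q1 + (mean_length - 2.0) * q2) / mean_length


def expected_close_fraction(sc: Scenario, cutoff: float = CLOSE_CUTOFF) -> float:
    """Design expectation of the close-neighbor particle fraction for a
    scenario, from the generative link model (no field is simulated)."""
    sigma_t, sigma_r = sc.pose_noise
    q_fix = _q_link_fixture(sigma_t, sigma_r, cutoff)
    total = 0.0
    for geom in (GEOM_COLLIDED, GEOM_HELICAL):
        f = sc.fractions.get(geom, 0.0)
        if f > 0:
            total += f * _member_close_prob(q_fix, _MEAN_LENGTH[geom])
    f_loose = sc.fractions.get(GEOM_LOOSE, 0.0)
    if f_loose > 0:
        q_l = _q_link_loose(*sc.loose_gap, sigma_t, sigma_r, cutoff)
        total += f_loose * _member_close_prob(q_l, _MEAN_LENGTH[GEOM_LOOSE])
    return total


#: per-preset recipe: (design close fraction, loose particle fraction,
#: collided share of the tight fraction)
_PRESET_RECIPES = {
    "untreated": (PRESET_CLOSE_FRACTIONS["untreated"], 0.08, 1.0),
    "ans20min": (PRESET_CLOSE_FRACTIONS["ans20min"], 0.10, 1.0),
    "ans1h": (PRESET_CLOSE_FRACTIONS["ans1h"], 0.10, 0.6),
    "ans4h": (PRESET_CLOSE_FRACTIONS["ans4h"], 0.10, 0.5),
    "znf598ko": (PRESET_CLOSE_FRACTIONS["znf598ko"], 0.05, 0.5),
}


def scenario_preset(name: str, seed: int = 0, **overrides) -> Scenario:
    """Named study-condition presets.

    ``untreated | ans20min | ans1h | ans4h | znf598ko`` calibrate the
    collided+helical particle fractions so the expected close-neighbor
    fraction equals the condition's design value; ``all_collided`` /
    ``all_loose`` are single-geometry fields for distribution benchmarks.
    """
    base = Scenario(seed=seed, name=name)
    if name == "all_collided":
        sc = replace(base, fractions={GEOM_COLLIDED: 1.0}, **overrides)
        return replace(sc, design_close_fraction=expected_close_fraction(sc))
    if name == "all_loose":
        sc = replace(base, fractions={GEOM_LOOSE: 1.0}, **overrides)
        return replace(sc, design_close_fraction=expected_close_fraction(sc))
    if name not in _PRESET_RECIPES:
        raise ValueError(
            f"unknown preset {name!r}; available: "
            f"{sorted(_PRESET_RECIPES) + ['all_collided', 'all_loose']}"
        )
    target, f_loose, collided_share = _PRESET_RECIPES[name]
    sigma_t, sigma_r = base.pose_noise
    q_fix = _q_link_fixture(sigma_t, sigma_r, CLOSE_CUTOFF)
    q_l = _q_link_loose(*base.loose_gap, sigma_t, sigma_r, CLOSE_CUTOFF)
    loose_term = f_loose * _member_close_prob(q_l, _MEAN_LENGTH[GEOM_LOOSE])
    qm_c = _member_close_prob(q_fix, _MEAN_LENGTH[GEOM_COLLIDED])
    qm_h = _member_close_prob(q_fix, _MEAN_LENGTH[GEOM_HELICAL])
    qm_mix = collided_share * qm_c + (1.0 - collided_share) * qm_h
    f_tight = max(0.0, (target - loose_term) / qm_mix)
    fractions = {
        GEOM_LOOSE: f_loose,
        GEOM_COLLIDED: collided_share * f_tight,
        GEOM_HELICAL: (1.0 - collided_share) * f_tight,
    }
    sc = replace(base, fractions=fractions, design_close_fraction=target, **overrides)
    return sc
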