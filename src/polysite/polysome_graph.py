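"""From directional neighbor records to polysome pairs, chains and geometry.

Two directional searches (trailing entry → leading exit, and the mirror)
are reconciled by mutual-nearest matching: a pair is kept only when each
particle is the other's nearest in the appropriate direction, taken greedily
in ascending distance so each particle is used at most once as leading and
once as trailing.  Accepted links are followed 5′→3′ into maximal simple
chains.  Each link's relative pose is compared against canonical reference
poses (purified-collided-disome-like vs. compact-helical) to label its
geometry; links matching neither stay "loose".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .neighbor_analysis import ENTRY_TO_EXIT, EXIT_TO_ENTRY, NeighborRecords
from .rigid_geometry import RelativePose, relative_pose, rotation_angle
from .star_io import ParticleSet

__all__ = [
    "ReferencePoseLibrary",
    "match_pairs",
    "annotate_pairs",
    "classify_pair",
    "trace_chains",
    "chain_summary",
    "load_pose_library",
]

PAIR_COLUMNS = ["leading_id", "trailing_id", "distance", "tomogram_id"]

LABEL_COLLIDED = "collided"
LABEL_HELICAL = "helical"
LABEL_LOOSE = "loose"


@dataclass(frozen=True)
class ReferencePoseLibrary:
    """Named canonical relative poses with acceptance thresholds.

    ``poses`` maps a geometry label to (RelativePose, max translation
    deviation Å, max rotation deviation deg); ``order`` fixes evaluation
    priority (collided before helical).
    """

    poses: dict[str, tuple[RelativePose, float, float]]
    order: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("reference pose library is empty")
        for name, (rel, tau_t, tau_r) in self.poses.items():
            if tau_t <= 0 or tau_r <= 0:
                raise ValueError(f"{name}: thresholds must be positive")

    def __getitem__(self, name: str) -> RelativePose:
        return self.poses[name][0]


def load_pose_library(source: str | Path | dict) -> ReferencePoseLibrary:
    """Load ``poses.json``: {name: {t: [..], Rrel: [[..]..], tau_t, tau_r}}."""
    raw = json.loads(Path(source).read_text()) if isinstance(source, (str, Path)) else source
    poses = {}
    order = []
    for name, entry in raw.items():
        if name.startswith("_"):
            continue
        rel = RelativePose(np.array(entry["t"]), np.array(entry["Rrel"]))
        poses[name] = (rel, float(entry.get("tau_t", 15.0)), float(entry.get("tau_r", 25.0)))
        order.append(name)
    return ReferencePoseLibrary(poses, tuple(order))


def match_pairs(fwd: NeighborRecords, rev: NeighborRecords) -> pd.DataFrame:
    """Mutual-nearest pair matching.

    ``fwd`` must be entry→exit records (anchor = trailing candidate, neighbor
    = leading candidate) and ``rev`` the exit→entry mirror.  A pair
    (trailing, leading) is accepted iff the leading is the trailing's nearest
    exit site AND the trailing is the leading's nearest entry site, taken in
    ascending distance with each particle used at most once per role.
    Deterministic given its input.
    """
    if set(fwd["direction"]) - {ENTRY_TO_EXIT} or set(rev["direction"]) - {EXIT_TO_ENTRY}:
        raise ValueError("match_pairs expects (entry_to_exit, exit_to_entry) records")
    f = fwd[fwd["distance"].notna()]
    tomo_of = dict(zip(fwd["anchor_id"], fwd["tomogram_id"]))
    for aid, tomo in zip(rev["anchor_id"], rev["tomogram_id"]):
        if aid in tomo_of and tomo_of[aid] != tomo:
            raise ValueError(f"particle {aid!r} appears in two tomograms; mixed records")
    rev_nearest = dict(zip(rev["anchor_id"], rev["neighbor_id"]))

    rows = []
    used_leading: set = set()
    used_trailing: set = set()
    for _, rec in f.sort_values(["distance", "anchor_id"], kind="mergesort").iterrows():
        trailing, leading = rec["anchor_id"], rec["neighbor_id"]
        if leading in used_leading or trailing in used_trailing:
            continue
        if rev_nearest.get(leading) != trailing:
            continue
        used_leading.add(leading)
        used_trailing.add(trailing)
        rows.append((leading, trailing, rec["distance"], rec["tomogram_id"]))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def classify_pair(rel: RelativePose, lib: ReferencePoseLibrary) -> str:
    """Label a link's geometry against the reference library.

    The first reference (in library order: collided, then helical) whose
    translation and rotation deviations are both within threshold wins;
    otherwise the link is "loose"."""
    for name in lib.order:
        ref, tau_t, tau_r = lib.poses[name]
        dt = float(np.linalg.norm(rel.t - ref.t))
        dr = rotation_angle(RelativePose(np.zeros(3), rel.Rrel @ ref.Rrel.T))
        if dt <= tau_t and dr <= tau_r:
            return name
    return LABEL_LOOSE


def annotate_pairs(
    pairs: pd.DataFrame, ps: ParticleSet, lib: ReferencePoseLibrary | None = None
) -> pd.DataFrame:
    """Attach the relative pose (trailing in leading frame), its rotation
    angle, and — when a library is given — the geometry label to each pair."""
    poses = dict(zip(ps.ids(), ps.poses()))
    rels, thetas, labels = [], [], []
    for _, row in pairs.iterrows():
        rel = relative_pose(poses[row["leading_id"]], poses[row["trailing_id"]])
        rels.append(rel)
        thetas.append(rotation_angle(rel))
        labels.append(classify_pair(rel, lib) if lib is not None else "unassigned")
    out = pairs.copy()
    out["rel"] = rels
    out["theta_deg"] = thetas
    out["geometry_label"] = labels
    return out


def trace_chains(pairs: pd.DataFrame, all_ids: list | None = None) -> dict:
    """Follow trailing→leading links into maximal simple paths.

    Returns ``chains`` (lists of particle ids ordered 5′→3′), per-chain link
    labels when present, and ``singletons`` (ids from ``all_ids`` that appear
    in no pair).  A cycle — possible under noise — is broken at its longest
    (weakest-evidence) link with a warning.
    """
    pairs = pairs.copy()
    if len(pairs) > 1:
        # break cycles: repeatedly drop the longest link of any cycle
        while True:
            cyc = _find_cycle(pairs)
            if cyc is None:
                break
            drop = max(cyc, key=lambda i: pairs.loc[i, "distance"])
            warnings.warn(
                f"cycle detected; broken at longest link "
                f"{pairs.loc[drop, 'trailing_id']}→{pairs.loc[drop, 'leading_id']} "
                f"({pairs.loc[drop, 'distance']:.1f} Å)"
            )
            pairs = pairs.drop(index=drop)

    next_of = dict(zip(pairs["trailing_id"], pairs["leading_id"]))  # 5'->3'
    label_of = {}
    if "geometry_label" in pairs.columns:
        label_of = {
            (t, l): g
            for t, l, g in zip(pairs["trailing_id"], pairs["leading_id"], pairs["geometry_label"])
        }
    has_prev = set(pairs["leading_id"])
    starts = [t for t in pairs["trailing_id"] if t not in has_prev]

    chains, chain_labels = [], []
    in_chain: set = set()
    for start in sorted(starts, key=str):
        chain = [start]
        while chain[-1] in next_of:
            chain.append(next_of[chain[-1]])
        chains.append(chain)
        in_chain.update(chain)
    order = sorted(range(len(chains)), key=lambda i: (-len(chains[i]), str(chains[i][0])))
    chains = [chains[i] for i in order]
    for chain in chains:
        chain_labels.append(
            [label_of.get((a, b), "unassigned") for a, b in zip(chain, chain[1:])]
        )
    singletons = []
    if all_ids is not None:
        singletons = [i for i in all_ids if i not in in_chain]
    return {"chains": chains, "link_labels": chain_labels, "singletons": singletons}


def _find_cycle(pairs: pd.DataFrame):
    """Return row indices of one cycle in the trailing→leading map, or None."""
    next_row = {t: i for i, t in pairs["leading_id"].items()}  # leading -> row where it is leading
    succ = dict(zip(pairs["trailing_id"], pairs["leading_id"]))
    visited: set = set()
    for node in list(succ):
        if node in visited:
            continue
        path = {}
        cur = node
        while cur in succ and cur not in visited:
            path[cur] = True
            visited.add(cur)
            cur = succ[cur]
            if cur in path:  # closed the loop
                rows = []
                n = cur
                while True:
                    idx = pairs.index[pairs["trailing_id"] == n][0]
                    rows.append(idx)
                    n = succ[n]
                    if n == cur:
                        break
                return rows
    return None


def chain_summary(traced: dict) -> pd.DataFrame:
    """Chain-length table with geometry composition; particle counts conserve.

    One row per observed length: count of chains, and how many of their links
    carry each geometry label.  Singletons are reported as length 1.
    """
    rows: dict[int, dict] = {}
    for chain, labels in zip(traced["chains"], traced["link_labels"]):
        row = rows.setdefault(len(chain), {"length": len(chain), "count": 0})
        row["count"] += 1
        for lab in labels:
            row[f"links_{lab}"] = row.get(f"links_{lab}", 0) + 1
    if traced.get("singletons"):
        rows[1] = {"length": 1, "count": len(traced["singletons"])}
    table = pd.DataFrame(sorted(rows.values(), key=lambda r: r["length"]))
    return table.fillna(0).astype({c: int for c in table.columns if c != "length"}) if len(table) else table
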