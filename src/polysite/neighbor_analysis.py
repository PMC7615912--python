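"""Nearest-neighbor statistics between mRNA entry and exit sites.

Consecutive ribosomes on one mRNA connect the trailing ribosome's entry
channel to the leading ribosome's exit channel, so the shortest
entry→exit distance within a cutoff (default 120 Å = 12 nm, compatible
with neighbors on the same polysome) identifies putative polysome links.
Both directions are computed: for each particle the nearest *other*
particle's exit site seen from its entry site, and vice versa.  Searches
are exact — a k-d tree is used only as an internal accelerator and a
brute-force scan gives identical results.

Distances are in Å internally; histogram exports convert to nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .rigid_geometry import SiteDefinition, require_sites
from .star_io import ParticleSet, absolute_positions

__all__ = [
    "NeighborRecords",
    "DistanceHistogram",
    "site_positions",
    "nearest_entry_to_exit",
    "nearest_exit_to_entry",
    "distance_histogram",
    "histogram_mode",
    "close_neighbor_fraction",
    "directional_neighbor_enrichment",
    "class_distance_correlation",
]

DEFAULT_CUTOFF = 120.0  # Å, the 12 nm same-polysome criterion
ENTRY_TO_EXIT = "entry_to_exit"
EXIT_TO_ENTRY = "exit_to_entry"

#: columns of a neighbor-record table
NEIGHBOR_COLUMNS = ["anchor_id", "neighbor_id", "direction", "distance", "tomogram_id"]

NeighborRecords = pd.DataFrame  # anchor_id, neighbor_id (None), direction, distance (NaN), tomogram_id


def site_positions(ps: ParticleSet, site: SiteDefinition) -> np.ndarray:
    """World coordinates (Å, n×3) of one named site on every particle."""
    pos = absolute_positions(ps)
    rots = np.stack([r.pose.R for r in ps.records])  # (n,3,3)
    return pos + rots @ site.offset_ref


def _nearest_directional(
    ps: ParticleSet,
    from_xyz: np.ndarray,
    to_xyz: np.ndarray,
    direction: str,
    cutoff: float,
) -> pd.DataFrame:
    ids = np.asarray(ps.ids(), dtype=object)
    tomos = np.asarray(ps.tomogram_ids(), dtype=object)
    n = len(ps)
    out_neighbor = np.full(n, None, dtype=object)
    out_dist = np.full(n, np.nan)

    for _, idx in ps.by_tomogram().items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        tree = cKDTree(to_xyz[idx])
        # exact search: every candidate within the cutoff, then min over non-self
        neighbor_lists = tree.query_ball_point(from_xyz[idx], r=cutoff)
        for local_i, cand in enumerate(neighbor_lists):
            cand = [c for c in cand if c != local_i]
            if not cand:
                continue
            d = np.linalg.norm(to_xyz[idx[cand]] - from_xyz[idx[local_i]], axis=1)
            j = int(np.argmin(d))
            if d[j] <= cutoff:
                out_neighbor[idx[local_i]] = ids[idx[cand[j]]]
                out_dist[idx[local_i]] = d[j]

    return pd.DataFrame(
        {
            "anchor_id": ids,
            "neighbor_id": out_neighbor,
            "direction": direction,
            "distance": out_dist,
            "tomogram_id": tomos,
        }
    )


def nearest_entry_to_exit(
    ps: ParticleSet,
    sites: dict[str, SiteDefinition],
    cutoff: float = DEFAULT_CUTOFF,
) -> NeighborRecords:
    """For each particle, the shortest distance from its mRNA entry site to
    any *other* same-tomogram particle's mRNA exit site; the neighbor is
    absent (NaN distance) if the minimum exceeds ``cutoff``."""
    entry, exit_ = require_sites(sites, "mrna_entry", "mrna_exit")
    return _nearest_directional(
        ps, site_positions(ps, entry), site_positions(ps, exit_), ENTRY_TO_EXIT, cutoff
    )


def nearest_exit_to_entry(
    ps: ParticleSet,
    sites: dict[str, SiteDefinition],
    cutoff: float = DEFAULT_CUTOFF,
) -> NeighborRecords:
    """Mirror search: shortest distance from each particle's exit site to any
    other particle's entry site."""
    entry, exit_ = require_sites(sites, "mrna_entry", "mrna_exit")
    return _nearest_directional(
        ps, site_positions(ps, exit_), site_positions(ps, entry), EXIT_TO_ENTRY, cutoff
    )


@dataclass(frozen=True)
class DistanceHistogram:
    """Binned shortest-distance distribution (half-open bins [lo, lo+w))."""

    bin_edges: np.ndarray  # Å, len = nbins+1
    counts: np.ndarray  # int, len = nbins
    n_total: int  # number of finite distances counted

    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Export with bin bounds in nm (columns bin_lo_nm, bin_hi_nm, count)."""
        return pd.DataFrame(
            {
                "bin_lo_nm": self.bin_edges[:-1] / 10.0,
                "bin_hi_nm": self.bin_edges[1:] / 10.0,
                "count": self.counts,
            }
        )


def distance_histogram(
    records: NeighborRecords,
    bin_width: float = 2.5,
    range_: tuple[float, float] = (0.0, DEFAULT_CUTOFF),
) -> DistanceHistogram:
    """Histogram the finite shortest distances over half-open bins."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = range_
    d = records["distance"].to_numpy(dtype=float)
    d = d[np.isfinite(d)]
    nbins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    # np.histogram closes the last bin; shift-and-floor keeps all bins half-open
    which = np.floor((d - lo) / bin_width).astype(int)
    ok = (which >= 0) & (which < nbins)
    counts = np.bincount(which[ok], minlength=nbins)
    return DistanceHistogram(edges, counts, int(ok.sum()))


def histogram_mode(h: DistanceHistogram) -> float:
    """Center (Å) of the maximal-count bin; ties resolve to the smaller
    distance."""
    if h.n_total < 1 or not np.any(h.counts > 0):
        raise ValueError("cannot take the mode of an empty histogram")
    i = int(np.argmax(h.counts))  # argmax returns the first (smallest-bin) tie
    return float(h.centers()[i])


def close_neighbor_fraction(
    ps: ParticleSet,
    sites: dict[str, SiteDefinition],
    cutoff_close: float = 60.0,
) -> dict:
    """Fraction of particles with a defined close neighbor, per tomogram.

    A particle counts as "close" when its nearest entry→exit OR exit→entry
    distance is within ``cutoff_close`` (default 60 Å, enclosing the ~4.5 nm
    collided-disome peak).  Returns per-tomogram fractions plus their
    unweighted mean and sample (n−1) standard deviation.
    """
    fwd = nearest_entry_to_exit(ps, sites, cutoff=cutoff_close)
    rev = nearest_exit_to_entry(ps, sites, cutoff=cutoff_close)
    close = fwd["distance"].notna().to_numpy() | rev["distance"].notna().to_numpy()
    tomos = np.asarray(ps.tomogram_ids(), dtype=object)

    fractions: dict[str, float] = {}
    for tomo, idx in ps.by_tomogram().items():
        if len(idx) == 0:
            warnings.warn(f"tomogram {tomo!r} has no particles; excluded")
            continue
        fractions[tomo] = float(close[np.asarray(idx)].mean())
    vals = np.array(list(fractions.values()))
    return {
        "per_tomogram": fractions,
        "mean": float(vals.mean()) if len(vals) else float("nan"),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "n_tomograms": len(vals),
    }


def directional_neighbor_enrichment(
    ps: ParticleSet,
    sites: dict[str, SiteDefinition],
    class_label: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict:
    """Among particles with a given class label, how often a neighbor sits on
    the entry side (leading, 3′-ward) vs. the exit side (trailing, 5′-ward).

    Returns ``entry_side_fraction``, ``exit_side_fraction`` and their ratio
    (entry/exit; inf when the exit side is empty).
    """
    labels = np.asarray([r.class_label for r in ps.records], dtype=object)
    mask = labels == class_label
    if not mask.any():
        present = sorted({l for l in labels if l is not None})
        raise ValueError(f"class label {class_label!r} absent; present labels: {present}")
    fwd = nearest_entry_to_exit(ps, sites, cutoff=cutoff)
    rev = nearest_exit_to_entry(ps, sites, cutoff=cutoff)
    entry_side = float(fwd.loc[mask, "distance"].notna().mean())
    exit_side = float(rev.loc[mask, "distance"].notna().mean())
    ratio = entry_side / exit_side if exit_side > 0 else float("inf")
    return {
        "entry_side_fraction": entry_side,
        "exit_side_fraction": exit_side,
        "ratio": ratio,
        "n": int(mask.sum()),
    }


def class_distance_correlation(
    ps: ParticleSet,
    sites: dict[str, SiteDefinition],
    class_label: str,
    covariate: np.ndarray | pd.Series,
    cutoff: float = float("inf"),
) -> dict:
    """Spearman rank correlation between each labeled particle's nearest-80S
    entry→exit distance and a per-particle covariate (e.g. a factor-density
    score).  Particles without a finite distance are dropped.  No p-value is
    interpreted; only rho and n are reported."""
    labels = np.asarray([r.class_label for r in ps.records], dtype=object)
    mask = labels == class_label
    if not mask.any():
        raise ValueError(f"class label {class_label!r} absent from particle set")
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != len(ps):
        raise ValueError("covariate must have one value per particle")
    fwd = nearest_entry_to_exit(ps, sites, cutoff=min(cutoff, 1e30))
    d = fwd["distance"].to_numpy(dtype=float)
    use = mask & np.isfinite(d) & np.isfinite(cov)
    if use.sum() < 3:
        raise ValueError(f"need at least 3 labeled particles with finite values, got {use.sum()}")
    rho, _ = spearmanr(d[use], cov[use])
    return {"rho": float(rho), "n": int(use.sum())}
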