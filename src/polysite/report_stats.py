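"""Condition-level summaries across tomograms.

Per-tomogram class proportions with unweighted mean and sample SD across
tomograms (the figure-caption convention: bar = mean, whisker = SD over
n tomograms, not a binomial SE), distance-distribution exports, and a
combined comparison table across conditions.  Plots are convenience
artifacts; every number is exported as CSV.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .neighbor_analysis import (
    DistanceHistogram,
    close_neighbor_fraction,
    distance_histogram,
    nearest_entry_to_exit,
)
from .polysome_graph import annotate_pairs, chain_summary, match_pairs, trace_chains
from .star_io import ParticleSet

__all__ = ["class_proportions", "condition_report", "analyze_condition"]

MIN_PARTICLES_PER_TOMOGRAM = 10


def class_proportions(
    labels: pd.DataFrame,
    condition: str,
    min_particles: int = MIN_PARTICLES_PER_TOMOGRAM,
) -> pd.DataFrame:
    """Per-tomogram class proportions plus mean/SD across tomograms.

    ``labels`` needs columns ``tomogram_id`` and ``class_label`` (one row per
    particle).  Within each tomogram the proportions over classes sum to 1.
    Tomograms with fewer than ``min_particles`` particles are excluded from
    the mean/SD to avoid degenerate fractions.  SD uses the n−1 denominator
    and is absent (NaN) for a single tomogram.
    """
    if labels["class_label"].isna().any():
        bad = labels.loc[labels["class_label"].isna()]
        ids = bad.get("particle_id", bad.index).tolist()[:10]
        raise ValueError(f"unlabeled particles: {ids}")
    counts = labels.groupby(["tomogram_id", "class_label"]).size().unstack(fill_value=0)
    totals = counts.sum(axis=1)
    keep = totals[totals >= min_particles].index
    counts = counts.loc[keep]
    counts = counts.loc[:, counts.sum(axis=0) > 0]  # classes seen only in excluded tomograms
    props = counts.div(totals.loc[keep], axis=0)

    rows = []
    for cls in props.columns:
        vals = props[cls].to_numpy(dtype=float)
        rows.append(
            {
                "condition": condition,
                "class_label": cls,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n_tomograms": len(vals),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["per_tomogram"] = props
    return table


def analyze_condition(
    ps: ParticleSet,
    sites: dict,
    pose_library=None,
    cutoff: float = 120.0,
    close_cutoff: float = 60.0,
    bin_width: float = 2.5,
) -> dict:
    """Run the standard spatial analysis for one condition's particle set."""
    from .neighbor_analysis import nearest_exit_to_entry

    fwd = nearest_entry_to_exit(ps, sites, cutoff=cutoff)
    rev = nearest_exit_to_entry(ps, sites, cutoff=cutoff)
    hist = distance_histogram(fwd, bin_width=bin_width, range_=(0.0, cutoff))
    close = close_neighbor_fraction(ps, sites, cutoff_close=close_cutoff)
    pairs = annotate_pairs(match_pairs(fwd, rev), ps, pose_library)
    traced = trace_chains(pairs, all_ids=ps.ids())
    chains = chain_summary(traced)
    return {
        "records_fwd": fwd,
        "records_rev": rev,
        "histogram": hist,
        "close": close,
        "pairs": pairs,
        "traced": traced,
        "chain_table": chains,
    }


def _plot_histogram(hist: DistanceHistogram, title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    frame = hist.to_frame()
    ax.bar(frame["bin_lo_nm"], frame["count"],
           width=frame["bin_hi_nm"] - frame["bin_lo_nm"], align="edge",
           color="#4878a8", edgecolor="none")
    ax.set_xlabel("nearest entry→exit distance (nm)")
    ax.set_ylabel("count")
    ax.set_title(f"{title} (n = {hist.n_total})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def condition_report(conditions: list[tuple[str, dict]], out_dir: str | Path) -> pd.DataFrame:
    """Write CSVs (+ figures) for analyzed conditions and return the summary.

    ``conditions`` is a list of (name, analyze_condition output).  Outputs per
    condition: ``hist_<name>.csv``, ``pairs_<name>.csv``, ``chains_<name>.csv``
    and a histogram figure; plus one combined ``summary.csv`` with the
    close-neighbor fraction (mean ± SD across tomograms), pair-geometry
    composition, and histogram mode.  Deterministic given its inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for name, res in conditions:
        hist: DistanceHistogram = res["histogram"]
        hist.to_frame().to_csv(out / f"hist_{name}.csv", index=False)
        pairs = res["pairs"]
        pairs_out = pairs.drop(columns=["rel"], errors="ignore").copy()
        if "distance" in pairs_out:
            pairs_out["distance_nm"] = pairs_out.pop("distance") / 10.0
        pairs_out.to_csv(out / f"pairs_{name}.csv", index=False)
        res["chain_table"].to_csv(out / f"chains_{name}.csv", index=False)
        _plot_histogram(hist, name, out / f"hist_{name}.png")

        geom = pairs["geometry_label"].value_counts() if len(pairs) else pd.Series(dtype=int)
        from .neighbor_analysis import histogram_mode

        row = {
            "condition": name,
            "n_particles": int(res["records_fwd"].shape[0]),
            "n_distances": hist.n_total,
            "mode_nm": histogram_mode(hist) / 10.0 if hist.n_total else float("nan"),
            "close_fraction_mean": res["close"]["mean"],
            "close_fraction_sd": res["close"]["sd"],
            "n_tomograms": res["close"]["n_tomograms"],
            "n_pairs": int(len(pairs)),
        }
        for label in ("collided", "helical", "loose"):
            row[f"pairs_{label}"] = int(geom.get(label, 0))
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.csv", index=False)
    return summary
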