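"""Access to packaged fixture data (sites, reference poses, envelopes,
footprints).

The fixtures are synthetic: stylized geometric constructions at realistic
80S length scales, engineered to reproduce the relative-geometry properties
of the collided-disome and compact-helical polysome arrangements (45 Å
inter-ribosome entry→exit gap, 4-ribosome steric queue limit for the
collided arc, unlimited helical queue, GCN1/P-stalk incompatibility).  They
are not derived from deposited atomic models.
"""

from __future__ import annotations

import json
from importlib import resources as _ilr

from .polysome_graph import ReferencePoseLibrary, load_pose_library
from .rigid_geometry import SiteDefinition, load_sites
from .steric_model import Envelope, FactorFootprint, load_envelope, load_footprint

__all__ = [
    "default_sites",
    "default_pose_library",
    "default_envelope",
    "default_footprint",
    "data_json",
]


def data_json(name: str) -> dict:
    """Load a packaged JSON fixture by file name."""
    with _ilr.files("polysite.data").joinpath(name).open() as fh:
        return json.load(fh)


def default_sites() -> dict[str, SiteDefinition]:
    """Reference-frame site offsets (mrna_entry, mrna_exit, p_stalk, ...)."""
    return load_sites(data_json("sites.json"))


def default_pose_library() -> ReferencePoseLibrary:
    """Canonical collided / helical relative poses with thresholds."""
    return load_pose_library(data_json("poses.json"))


def default_envelope(name: str = "ribosome_80s") -> Envelope:
    """Coarse 80S envelope; ``ribosome_80s_pstalk`` adds the P-stalk sphere."""
    return load_envelope(data_json("envelopes.json"), name)


def default_footprint(name: str = "GCN1") -> FactorFootprint:
    return load_footprint(data_json("footprints.json"), name)
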