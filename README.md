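# polysite

Spatial analysis of translating ribosomes from subtomogram-averaging
particle tables.

Cryo-electron tomography of cells yields, after template matching and
subtomogram refinement, a table of 80S ribosome particles per tomogram:
positions (voxels + refined origin shifts) and orientations (ZYZ Euler
angles). Because consecutive ribosomes on one mRNA connect the *trailing*
ribosome's mRNA **entry** channel to the *leading* ribosome's mRNA **exit**
channel, the spatial relation between these two sites carries the polysome
architecture: widely spaced neighbors on relaxed polysomes, a sharp ~4.5 nm
entry–exit gap in collided disomes, and compact helical arrangements under
persistent collision stress. `polysite` turns particle tables into these
readouts:

* **Site mapping** — for a particle with pose `(x, R)` and a site offset
  `s` in the reference frame, the site's tomogram position is `x + R·s`,
  with `R = A(rot, tilt, psi)ᵀ` and `A = Rz(psi)·Ry(tilt)·Rz(rot)`.
* **Directional nearest neighbors** — for every particle, the shortest
  distance from its entry site to any other same-tomogram particle's exit
  site (and the mirror search), retained within a 12 nm cutoff; distance
  histograms and their modes.
* **Pair matching and chain tracing** — mutual-nearest matching in
  ascending distance, 5′→3′ chain tracing, and classification of each
  link's relative pose `(t, R_rel)` against canonical collided-disome and
  helical-polysome transforms.
* **Coarse steric modeling** — multi-sphere 80S envelopes; iterating a
  relative pose extrapolates an idealized queue, giving the maximal
  polysome length before non-adjacent members clash (4 for the collided
  arc, unlimited for the helix) and testing whether a bound factor (GCN1)
  can coexist with the trailing ribosome (it clashes with the trailing
  P-stalk in the helical arrangement).
* **Synthetic fields** — a ground-truth-annotated generator that emulates
  lamella tomograms (thin slabs, hundreds of particles, monosomes plus
  loose/collided/helical polysomes, pose noise, picking errors), with
  presets whose expected close-neighbor fractions encode untreated
  (~4.4%), collision-stress time courses (~9.2%, ~30%, ~19%) and a
  surveillance-deficient condition (~61%).
* **Reports** — per-tomogram class proportions (mean ± SD across
  tomograms), histogram/pair/chain CSV bundles and figures.

## Worked example

```python
from polysite import resources
from polysite.neighbor_analysis import (nearest_entry_to_exit, nearest_exit_to_entry,
    distance_histogram, histogram_mode, close_neighbor_fraction)
from polysite.polysome_graph import annotate_pairs, match_pairs, trace_chains
from polysite.synthetic_fields import scenario_preset, simulate_field

sites = resources.default_sites()
lib = resources.default_pose_library()

sc = scenario_preset("ans1h", seed=42, n_tomograms=5)   # 1 h collision stress
field = simulate_field(sc)

fwd = nearest_entry_to_exit(field.particles, sites, cutoff=120.0)
rev = nearest_exit_to_entry(field.particles, sites, cutoff=120.0)
hist = distance_histogram(fwd, bin_width=2.5)
close = close_neighbor_fraction(field.particles, sites, cutoff_close=60.0)
pairs = annotate_pairs(match_pairs(fwd, rev), field.particles, lib)
```

This prints (seed 42):

```
simulated 1500 particles in 5 tomograms (design close-neighbor fraction 0.300)
nearest entry->exit distances: n = 436, mode = 4.62 nm
close-neighbor fraction: 0.302 +/- 0.015 (mean +/- SD over 5 tomograms)
matched pairs: 428  geometry: {'loose': 213, 'collided': 113, 'helical': 102}
```

The distance mode sits at the collided-disome spacing (~4.5 nm) because the
stressed preset is dominated by collided and helical queues; the realized
close-neighbor fraction (0.302) reproduces the preset's design value (0.30);
and the matched pairs split into canonical collided/helical links plus links
whose noisy pose falls outside the classification thresholds (labelled
loose). The same workflow runs from the shell:

```sh
polysite simulate --preset ans1h --seed 42 --out field.star --truth truth.csv
polysite neighbors --star field.star --cutoff-nm 12 --out records.csv --hist hist.csv
polysite chains --records records.csv --star field.star
polysite steric max-queue --pose collided     # -> 4
polysite steric factor --factor GCN1 --pose helical   # -> INCOMPATIBLE
polysite report --inputs stress=field.star --out report/
```

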