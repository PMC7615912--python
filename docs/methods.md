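# Methods

## Coordinate conventions

Particle tables store voxel coordinates, origin shifts and three Euler
angles per particle. Angles follow the refinement-software convention
`A = Rz(psi)·Ry(tilt)·Rz(rot)` (intrinsic ZYZ), where `A` maps
tomogram-frame vectors into the reference (subtomogram-average) frame; the
reference→tomogram rotation used throughout is `R = Aᵀ`. Absolute positions
use the subtraction convention `position_Å = coord_vox·apix − origin_Å`;
origin shifts are read from Å-unit columns when present, else voxel-unit
columns scaled by the pixel size, and their application can be disabled
(whether refined shifts were applied before site computation is not
observable from a table alone, so the default applies them and a flag turns
them off). Angles are normalized to `tilt ∈ [0, 180]`,
`rot, psi ∈ (−180, 180]`; at gimbal lock (`tilt ≈ 0` or `180`) `rot` is set
to 0 and `psi` absorbs the in-plane rotation. Both the modern two-block
STAR layout (optics + particles) and the legacy single-block layout are
read; unknown columns are carried through so read→write round-trips are
value-identical. All internal distances are Å; exported histograms use nm.

## Nearest-neighbor statistic

For each particle the shortest distance from its mRNA entry site to every
other same-tomogram particle's mRNA exit site is retained (and the mirror,
exit→entry), within a 120 Å cutoff — the spacing compatible with neighbors
on the same polysome. The search contract is exact: a k-d tree collects
candidates within the cutoff, and the minimum is taken explicitly, so
results equal an O(n²) scan bitwise (regression-tested on random fields).
Histograms use half-open bins ([lo, lo+w), default 2.5 Å) and report
`n_total` = number of finite distances; the mode is the center of the
maximal bin, ties resolved toward the smaller distance. The per-tomogram
"close neighbor" fraction counts particles whose entry- or exit-side
nearest neighbor lies within 60 Å — a geometric proxy chosen to enclose the
~4.5 nm collided peak; the experimental counts it models were obtained by
image classification, so this proxy is a declared substitute, and its
condition percentages are design values, not exact targets. Summary
statistics across tomograms are the unweighted mean and the n−1 SD,
matching how per-tomogram quantification is usually reported.

## Pairs, chains, geometry classes

Directional records are reconciled by greedy mutual-nearest matching in
ascending distance: a (trailing, leading) pair is accepted iff each is the
other's nearest in its direction and neither is already used in that role.
This is deterministic, permutation- and rigid-motion-invariant, and on
realistic densities nearly identical to optimal bipartite matching (the
strategy is isolated behind `match_pairs` and swappable). Accepted links
are followed trailing→leading into maximal simple paths (5′→3′); a cycle —
possible when noise lets a spurious link under the cutoff — is broken at
its longest (weakest-evidence) link with a warning.

Each link's relative pose (trailing expressed in the leading frame) is
classified against a library of canonical transforms: first collided, then
helical; a label is assigned when the translation deviation is ≤ τ_t = 15 Å
and the geodesic rotation deviation ≤ τ_r = 25°, else the link stays
"loose". The experimental discrimination was done by image classification;
these pose-metric thresholds are a geometric surrogate, set midway between
the fixtures' separation (Δt ≈ 64 Å, Δθ = 20°) and the default pose noise.
Under σ_t = 5 Å, σ_r = 2° a minority of true collided/helical links falls
outside the thresholds and is reported loose; that is intended behavior of
a hard threshold, not an error.

## Geometric fixtures (synthetic)

No atomic coordinates are bundled or required. The packaged fixtures are
stylized geometric constructions at realistic 80S length scales, engineered
to reproduce the relative-geometry facts the analysis depends on, and are
labelled synthetic in the JSON:

* **Sites**: entry `e = (50, −85, −50)` Å and exit `x = (−45, −85, −50)` Å
  place both channel openings on the small-subunit side, 95 Å apart,
  ~110 Å from the particle origin.
* **Envelope**: two spheres — "60S" at (55, 0, 0), r = 80 Å and "40S" at
  (−60, 0, 0), r = 55 Å (≈250 Å overall diameter). Radii were calibrated
  once so that consecutive ribosomes of the collided arc are in contact
  without overlapping (adjacent clearance ≈ −2 Å against the 5 Å contact
  allowance) while the 5th arc member clashes. A third "P-stalk" sphere at
  (30, 70, 35), r = 25 Å extends the envelope used for factor-accommodation
  tests.
* **Collided transform**: `R_rel = Rz(75°)`, translation chosen so the
  trailing entry sits 45 Å from the leading exit along an in-plane
  direction (azimuth 220°). Iterating it bends the queue into a planar arc
  whose 5th member hits the 1st: the maximal queue length is 4.
* **Helical transform**: `R_rel = Rz(95°)` with a 42 Å axial rise and the
  same 45 Å entry–exit gap. The screw never self-intersects: 50 members
  extrapolate without non-adjacent clash (worst clearance ≈ 13 Å).
* **GCN1 footprint**: two 20 Å spheres anchored on the leading ribosome,
  one bridging toward the trailing ribosome and one placed at the *helical*
  trailing ribosome's P-stalk position, pushed to ≥ 8 Å clearance from
  every sphere of the *collided* trailing ribosome. Accommodation is
  therefore compatible under the collided transform (clearance 8 Å) and
  incompatible under the helical one (penetration ≈ 35 Å at the P-stalk) —
  the modeling claim the fixture encodes.

Sensitivity: scaling all envelope radii ±10% is reported by the test suite.
At −10% both queue limits are unchanged (4 and ≥50); at +10% the adjacent
contact allowance is exhausted and both arrangements clash immediately —
the two-sphere envelope is calibrated to contact, so the collided limit of
4 is robust to shrinkage but not to uniform growth.

`scratch/` (not shipped) contains the construction script; the JSON files
under `src/polysite/data/` are its frozen output.

## Steric queue model

`max_queue_length` extrapolates `pose_k = pose_{k−1} ∘ rel` from the
identity and returns the largest length whose members are clash-free:
consecutive members may overlap up to 5 Å (ribosomes in a genuine collision
are in contact), all other pairs use zero tolerance. The search is an
exhaustive O(n²) sphere check (n ≤ 50). The limit is monotone
non-increasing as radii grow (tested). `factor_accommodation` places the
footprint via the leading pose and the trailing envelope via the relative
pose and reports the worst sphere penetration (negative = clearance).

## Synthetic fields

Each tomogram is a slab (default 800×800×180 nm — lamella-like thickness;
particle densities are order-of-magnitude choices, as no per-tomogram
density is published) holding a fixed number of particles (default 300)
partitioned into monosomes and polysomes by per-geometry particle
fractions. Chain lengths: loose — geometric with mean 5 (support 2–15);
collided — uniform 2–4; helical — uniform 4–10; the partitioner packs each
quota exactly by adjusting the final chain within the allowed range.
Collided/helical links apply the canonical transform exactly; loose links
draw the inter-site gap `g ~ Normal(68.8, 15) Å` (truncated ≥ 5 Å) and then
rejection-sample a uniform orientation and gap direction *given g*, so the
realized gap law is exactly the requested normal. Polysomes are placed with
uniform position and orientation, rejected on inter-polysome envelope
overlap; per-particle pose noise applies an isotropic `Normal(0, σ_t)`
translation and a rotation by `|Normal(0, σ_r)|` about a uniform axis
(defaults σ_t = 5 Å, σ_r = 2°, typical subtomogram alignment precision);
false positives are uniform over the box and SO(3), false negatives delete
particles and break the links through them (both default 0; picking-noise
behavior is exercised by tests that set them explicitly). Everything is
reproducible from one seed, down to byte-identical STAR output.

**Identifiability.** Real tight queues can curl until sites of
*non-consecutive* ribosomes enter the 12 nm search radius, which makes
ground-truth links ambiguous even without noise. Since the generator's
purpose is benchmarking, it enforces identifiability: the canonical
transforms were parameterized so all wrong-direction site pairs stay
> 126 Å apart (12.6 nm, 5% beyond the cutoff), and loose-link and
polysome-placement rejection apply the same margin. Noise-free fields are
therefore perfectly recoverable (pair precision = recall = 1, exact
chains), which the acceptance suite asserts. Consequences for realism: the
generator understates the pairing ambiguity of extremely compact real
polysome fields, so perfect noise-free recovery demonstrates correctness of
the pipeline, not that real assignments are unambiguous.

**Loose-gap calibration.** The loose preset exists to reproduce an observed
~7 nm nearest-distance peak. Measured distances include pose noise, which
shifts the distance mode of a latent gap `g` up by ≈ `s²/g` (per-axis site
noise `s² = 2σ_t² + (2/9)σ_r²(|e|² + |x|²)` ≈ 56.5 Ų at default noise). The
latent mean was therefore set once, from this noncentral-χ model, to
68.8 Å so the *observed* distribution peaks at 7.0 nm. Even so, the
observed density is nearly flat across the 6.5–8.0 nm bins, so the
maximal-bin mode at n ≈ 5000 distances alternates between 6.75 and
7.25 nm across seeds — an honest property of the statistic at this sample
size.

**Preset calibration.** For each named condition the collided+helical
particle fractions solve
`f_tight·q_tight + f_loose·q_loose = target`
where the per-member close probabilities `q` follow from the per-link
probability that a noisy link distance is < 60 Å (noncentral-χ², 3 dof,
integrated over the gap law for loose links) and the chain-length mix (ends
carry one link, interior members two). Presets fix the loose fraction
(8–10%, 5% for the surveillance-deficient condition) and split the tight
remainder (collided-only for mild conditions; 60/40 and 50/50
collided/helical under acute stress). Realized fractions over 20 tomograms
match the design values within sampling error (regression-tested at 3 SE).

## Reports

`class_proportions` computes per-tomogram class fractions (they sum to 1
within 1e−9), with unweighted mean and n−1 SD across tomograms; tomograms
with fewer than 10 particles are excluded from the summary to avoid
degenerate fractions, and SD is absent for a single tomogram.
`condition_report` writes per-condition histogram/pair/chain CSVs, a
combined summary CSV and PNG figures; all numbers come from the CSVs —
plots are artifacts. Outputs are byte-identical across reruns on identical
inputs.

## Numerical choices and limitations

* Exact neighbor search; spatial indexing is an internal accelerator with
  a brute-force equivalence guarantee.
* Rotation round-trips are accurate to < 1e−6°; gimbal-locked matrices are
  canonicalized deterministically.
* The mode estimator is the maximal histogram bin (ties → smaller); no
  kernel smoothing.
* Greedy mutual-nearest matching can drop a true link when noise reorders
  nearest neighbors; at σ_t = 10 Å, σ_r = 5° pair recall stays ≥ 0.95
  (regression-tested, fixed seed).
* mRNA is not modeled as a curve; only the inter-site gap statistic the
  analysis measures is controlled. No densities, missing wedge, CTF or
  membranes are simulated; class labels are consumed as input, never
  inferred from images.
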