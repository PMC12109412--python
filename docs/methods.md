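# Methods

## Scope and model of the assay

The package analyses the intramolecular cyclization of short
(~100 bp-scale) nucleic acid duplexes carrying mutually complementary
single-stranded 5′ overhangs. In the underlying assay, a donor dye sits
at one strand's 5′ end and an acceptor at the other's; the molecule is
tethered to a surface through an internal biotin. Before salt addition
the duplex is extended (no FRET); once a high-salt buffer screens the
backbone charge, transient loops are trapped by hybridization of the
overhangs, which is effectively irreversible on the experimental time
scale. The population-level observable is the per-timepoint FRET
efficiency histogram over a few thousand molecules.

The kinetic model is a single-exponential approach to a plateau:

    f(t) = A (1 − e^{−R t})

with `R` the looping rate (per minute) and `A` the plateau looped
fraction. The generative reading implemented in `synth_fret` is that a
fraction `1 − A` of molecules never loops (misfolded, mislabelled or
photobleached molecules) while loopers draw an exponential looping time
with rate `R`. Other readings (e.g. a looping/unlooping equilibrium)
produce the same `f(t)` but different single-trace statistics; the
package only relies on the population form.

### Synthetic data generator

`simulate_population_histograms` treats timepoints as independent
cross-sections of `n_molecules` molecules (the assay images different
fields of view at each timepoint). Each molecule is looped with
probability `f(t)`; its apparent efficiency is drawn from the state's
Gaussian, truncated to [0, 1]. Defaults: unlooped mean 0.15, looped mean
0.85, both SD 0.08, 2500 molecules per timepoint, timepoints every
10 min to 60 min — the scale of a well-separated two-population looping
experiment. `simulate_trace` emits single-molecule donor/acceptor
traces at 100 ms frames with optional Gaussian intensity noise at fixed
mean total intensity.

What the generator does **not** emulate: photophysics (blinking,
bleaching, spectral crosstalk), camera noise statistics, molecule
re-identification across timepoints, heterogeneity of `R` between
molecules, and any unlooping. Passing recovery tests therefore
demonstrates correctness of the analysis chain under the model's own
assumptions, not robustness to instrument artefacts.

### Kinetics analysis chain

Efficiency is `I_A / (I_D + I_A)`; histograms use bin width 0.02 on
[0, 1] by default (results are insensitive to the bin width in the
0.01–0.05 range because component areas are computed analytically as
`amplitude × σ × √(2π)`, not by bin summation). Histograms are fit by
least squares with a sum of two Gaussians; components are ordered by
mean. Initialization takes the two highest local maxima of the lightly
smoothed counts at least 0.2 apart, tie-broken toward the extremes. If
the free fit fails or is degenerate (means within `2·max(σ)` with both
components carrying ≥ 2% of the area), a second stage refits with the
components confined to the low ([0, 0.5)) and high ([0.5, 1]) halves of
the efficiency range — the structure of a looping assay. This matters
for early timepoints, where a nearly single-population histogram lets an
unconstrained optimizer split the low-FRET mode in two; the constrained
refit instead assigns ~zero area to the absent looped population. Data
failing both stages raise a fit-failure error carrying diagnostics.

The looped fraction is `A_H / (A_H + A_L)`. Kinetics are fit by
nonlinear least squares with `A` bounded to [0, 1]; standard errors come
from the fit covariance, and the looping time is exactly `1/R` (its SE by
first-order propagation, `se_R / R²`). Construct comparisons report the
ratio of mean looping times (means over replicates, SE = SD/√n, n ≥ 2;
a single replicate reports SE as undefined, never zero) with
delta-method SEs; the alternative estimator (mean of per-replicate
ratios) differs at second order and is not reported.

## Sequence analysis

GC skew is `(G − C)/(G + C)` counted on an explicitly chosen strand
orientation; the skew of a strand is minus the skew of its complement.
R-loop-prone promoter regions are conventionally summarized by the skew
of the G-rich (non-template) strand, which for the printed C-rich
template oligos means the `complement` orientation. The annealer
searches ungapped antiparallel registers only (the constructs are
designed perfectly complementary; indel alignment is out of scope) and
reports the maximal contiguous Watson–Crick run, the 5′ overhang
lengths, whether the overhangs are mutually complementary
(looping-competent), and the looped circumference. The internal
biotin-dT counts as an ordinary thymine in all sequence statistics.

## Frame algebra and helical parameters

A base-pair frame is an origin plus a right-handed orthonormal triad
(x toward the major groove, y toward the strand-I backbone, z along the
helix advance), 1-based along strand I, angles in degrees and lengths in
Å. All rotational parameter sets use one scheme: the rotation between
two triads is expressed as a single rotation vector, whose components
along the **mid-frame** axes (the frame halfway along the rotation
geodesic) are the three angular parameters, and the origin displacement
expressed in the mid-frame gives the three translational parameters.
For steps this yields (shift, slide, rise, tilt, roll, twist); for
paired bases, with the strand-II frame pre-flipped by 180° about x,
(shear, stretch, stagger, buckle, propeller, opening). A pair whose
frames differ by a rotation ≥ 90° is flagged broken.

This scheme is chosen because it is exactly self-inverse: the builders
compose steps by the same rule, so rebuild-then-extract is the identity
to machine precision, which is what the round-trip acceptance checks
exercise. It is close to, but not identical with, hinge-decomposition
schemes and curvilinear-axis programs; absolute values can differ from
those programs by small systematic offsets (sub-degree at physiological
bends), and no equivalence with any external program is claimed.

Axis/helical parameters come from the screw decomposition of each step's
lab-frame transform: H-twist and H-rise are the rotation about and
advance along the screw axis; the bp-frame origin's offset from the axis
gives Xdisp/Ydisp in bp coordinates; inclination and tip are
`atan2(u_y, u_z)` and `atan2(−u_x, √(u_y² + u_z²))` for the axis
direction `u` in bp coordinates. The local axis at bp *i* averages the
screw axes of the adjacent steps (window configurable). A step with
near-zero rotation has no defined screw axis; the translation direction
is used and the row flagged. On a constant-step path the decomposition
is exact, which is how the builders' prescribed Xdisp/inclination values
are recovered to 1e-6.

`parameter_series` discards an equilibration prefix (default the first
third of the trajectory, e.g. 100 of 300 ns) and returns a tidy table.
`fluctuation_summary` fits each parameter's pooled distribution by
maximum likelihood (sample mean and SD), reports ΔSD against a reference
ensemble, and estimates uncertainties from SDs recomputed in 10 equal
time blocks (SE = SD of block values / √10); fewer snapshots than blocks
disables the block analysis and flags it. Constant series (SD ≤ 1e-9)
are flagged degenerate rather than fit.

### Base templates

The atom templates used for embedding and frame fitting are synthetic
idealized geometries: planar regular hexagon/pentagon ring systems with
1.39 Å bonds, a C1′ marker on the glycosidic nitrogen and a single
idealized out-of-plane backbone P marker, expressed in the standard
frame convention (strand-II bases use the 180°-about-x flip). They are
deliberately self-consistent rather than crystallographic: every
analysis in the package depends only on the rigid-body relationship
between template and observed atoms. Frame fitting is Kabsch/SVD with a
proper-rotation constraint; collinear atom sets and genuinely
mirror-inverted bases (improper optimum with a non-degenerate third
singular value) are rejected.

## Minicircles and topology

`minicircle(n, turns, rise)` places origins uniformly on a circle of
radius `n·rise/2π` in a plane, local z tangent to the circle, and
accumulates a uniform material twist of `360·turns/n` degrees per step
about the tangent, starting with the bp x axis radial. Because `turns`
is an integer the frame orbit closes exactly. Note a geometric fact the
tests encode: on such a circle the *step parameters* are congruent but
not constant — rise, twist, bend magnitude √(tilt² + roll²) and shear
magnitude are identical at every cyclic step, while the bend direction
rotates through roll and tilt with the helical phase, as it must when a
twisting frame follows a fixed-plane bend. Per-step twist above 60°
triggers an overwinding warning.

Writhe uses the exact closed-form Gauss double integral over
non-adjacent segment pairs of the origin polygon. Twist, for topology,
is the ribbon twist of the bp x axes about the path tangent, computed by
parallel transport (minimal rotation) across each vertex. With these
definitions the discrete Călugăreanu–White identity Lk = Tw + Wr holds
to numerical precision for any closed path, which the tests verify
against the Gauss linking integral of the axis with an offset ribbon
curve; on the planar builder circle the ribbon twist equals the
construction twist exactly. (The sum of per-step *frame* twists differs
from the ribbon twist at third order on bent paths — about 0.003 turns
on the 93-bp circle — and is therefore not used for topology.)
`linking_number` reports real-valued Tw and Wr, the nearest-integer Lk
and the rounding residual; no self-intersection detection is attempted.

Curvature at a bp is the angle between the average incoming and outgoing
segment tangents (window configurable; degrees per step, 360/n exactly
on the ideal circle). Register is the local bend direction — the
component of the tangent change perpendicular to the mean tangent,
smoothed over three steps because single-step normals are noisy —
projected into the bp frame and reported as `atan2(b_x, b_y)` degrees:
−90° when the −x (major-groove) side faces the bend center, +90° for
the minor-groove side. Base pairs with curvature below a floor
(default 0.5°/step) have no defined bend direction and report NaN.

### Kink detection

Kink thresholds are calibration choices exposed as parameters, defaults:
roll below −30° sustained for a contiguous dwell of ≥ 100 snapshots
(1 ns at 10 ps sampling), propeller above +30° as disrupted-pairing
evidence, plus the broken-pair flag from the intra-bp analysis.
Adjacent flagged steps merge into one call. A call spanning ≥ 2 steps,
or showing a broken pair, is type II; a single sharply rolled step with
intact pairing is type I. Detection is monotone: loosening the roll
threshold or the dwell requirement never un-flags a step.

## Problem sizes and determinism

All stochastic components draw from explicit `numpy` generators seeded
through function arguments or the model's `seed` field, so every
simulation is bit-reproducible. The test suite validates the kinetics
pipeline on a 3×3 (A, R) grid with 50 seeds per point and 2500 molecules
per timepoint, the looping-time ratio on 100 seed pairs, White's theorem
on 50 random out-of-plane deformations of the 93-bp circle, and kink
detection on 150-snapshot 93-bp synthetic ensembles — sizes chosen so the
statistical tolerances are meaningful while the whole suite runs in a few
minutes on one CPU.

## Known limitations

* The helical-parameter scheme is self-consistent but not numerically
  identical to curvilinear-axis programs; only round-trip and oracle
  properties are guaranteed.
* The synthetic ensembles draw each step/bp parameter independently;
  real trajectories have inter-step correlations and sequence-dependent
  means, so fluctuation statistics on real data should be interpreted
  with the block uncertainties, not the independence assumption.
* Atom templates are idealized; PDB output is for geometry exchange, not
  stereochemically refined starting structures.
* The kinetics module does not model dwell-time analysis of single
  traces, j-factors, or salt dependence; the sequence module does not
  predict thermodynamic stability or secondary structure of the
  displaced strand.
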