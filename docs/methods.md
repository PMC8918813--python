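# Methods

This note documents the models, conventions and numerical choices behind
`vesseldyn`, and what the synthetic-data generators do and do not emulate.

## Coordinate frame and alignment

Raw 3D nucleus tracks arrive in an arbitrary microscope frame.  The canonical
frame is defined by the trunk anatomy: the dorsal aorta (DA) parallel to the
x-axis with its nucleus centroid at the origin, and the DLAV in the positive-y
half plane with its centroid in the y > 0, z ≈ 0 half-plane, so that y reads
out ventral→dorsal position directly.

The aorta axis is fitted to the pooled positions of all DA-labelled nuclei
over the whole recording.  The fit is orthogonal (total least squares — the
principal axis of the centred cloud via SVD) rather than an ordinary
regression of y on x, because OLS is not invariant to the unknown input
orientation; the OLS variant remains available (`method="ols"`) for parity
checks against pipelines that used it.  The rotation is the minimal rotation
taking the axis onto +x composed with a roll about x that places the DLAV
reference centroid at y > 0, z = 0.  A roll beyond 90° is recorded as
`dorsal_flip`.  Two quantities are genuinely unidentifiable from geometry
alone and are fixed by convention: the anterior–posterior sense of the axis
(kept in the input's +x hemisphere) and the x-origin (DA centroid → 0).
Neither affects the y read-out or any velocity, which is what downstream
analysis consumes.  Degenerate inputs fail loudly: a coincident DA cloud or a
DLAV reference lying on the axis raises an alignment error rather than
guessing.

## Region map and hysteretic state

The trunk is partitioned in the canonical (x, y) plane: a pooled PCV/DA band
(y < y_DA + δ), a DLAV band (y > y_DLAV − δ), and in between the ISV band,
sliced by nearest ISV x-slot.  δ = 5 µm guards both band edges so positional
noise (default 0.5 µm SD) cannot flip assignments.  Each cell carries a
*hysteretic state*: it starts in its first region and switches only when a
new raw assignment persists ≥ K consecutive frames (default K = 6 frames =
1 h at the 10 min frame interval).  Sub-K boundary flicker therefore never
produces spurious events, which makes exchange detection reproducible where
the original counting was done by expert inspection.

Exchange events are state transitions: DLAV→ISV_k is immigration from the
DLAV into vessel k, ISV_k→base-band is emigration to the PCV, and so on.
Direct base↔DLAV transitions and ISV↔ISV reassignments are not ISV-junction
events and are ignored.  Mitoses are lineage branchings (two daughter tracks
sharing a `parent_id`; the mother's track ends at the division frame) and are
attributed to the vessel holding the mother at her last observation.  Track
losses are treated as censoring.

## Windowed velocity

Per cell and window, velocity is the signed y-displacement between the cell's
first and last sample in a 2 h window divided by the window length, evaluated
on window centres every 10 min across 26–44 hpf; per-class means carry
percentile-bootstrap 95% CIs over cells (2000 resamples, seeded).  Three
filters keep the estimator an unbiased measure of *vessel-resident* drift:

* **Full-window coverage** (`require_full_window`, default on): the cell must
  have samples within half a frame of both window edges.  Dividing a partial
  track's displacement by the full 2 h — the naive reading — systematically
  biases cells that appear or disappear mid-window (daughters, mothers,
  transiting cells) toward zero; with coverage enforced the divisor is exact.
* **Constant state**: the cell's hysteretic state must be a single ISV across
  the window.
* **Settled residency** (`settle_h`, default 2 h): on any side where the cell
  changed vessels, its residency run must extend ≥ 2 h beyond the window.
  Without this, the translocation legs of immigrating/emigrating cells
  (tens of µm at ~40 µm/h) leak into the class mean and can shift it by
  several tenths of µm/h — larger than the arterial remodelling signal.

Future arterial/venous identity is assigned once at the final frame and
applied retroactively, mirroring end-point analysis: an ISV is venous when a
cell sits clearly below the DA plane (y < −δ, PCV territory) at its x-slot at
the end of the recording, arterial when it is populated but shows no ventral
connection, and unresolved (excluded from class statistics) when empty.

## Idealized ISV network and flow

The vessel graph has a DA chain (inlet → arterial base nodes → outlet), a
DLAV chain across all 30 apices, aISV edges (DA→DLAV) and vISV edges
(DLAV→terminal sink), alternating classes, ISVs at multiples of the measured
spacing.  Boundary conditions: the DA inlet at 201.3 Pa (adult DA
measurement), every venous terminal at 0 Pa — the PCV is hard to segment and
is treated as a pure flow sink — and the DA outlet from a prescribed axial
gradient: the inlet pressure dissipates over the whole-body length
L_fish = 2 mm, and that gradient applies to the modelled DA fraction,
P_out = P_in (1 − L_DA/L_fish).  The outlet rule is exposed as a configurable
hook (`da_outlet_pressure`) since other gradient estimates are plausible.

Each edge's conductance is G = πD⁴/(128 μL) with blood viscosity
μ = 3.5 mPa·s; a diameter of 0 encodes "no measurement" and maps to a 10⁻³⁰
conductance floor that keeps the system invertible while carrying negligible
flow (such edges report τ = 0).  Interior pressures solve the nodal
flow-balance (Kirchhoff) system — sparse symmetric solve with a dense
fallback — re-assembled at every time point from per-class diameter
interpolants (linear, clamped at the grid ends).  Per edge, Q = GΔp signed by
edge orientation (DA inlet flow positive) and τ = 32μ|Q|/(πD³), which equals
D|Δp|/(4L) identically; the test suite asserts both forms to 10⁻¹² and checks
the solver against a brute-force dense solve on randomized networks.

Everything internal is strict SI; micrometres are converted once at ingest,
because the D⁴ dependence turns a unit slip into a 10¹²-fold error.

One structural property deserves note: under fixed pressure boundary
conditions a *uniform* viscosity rescale leaves τ unchanged (G ∝ 1/μ leaves
{p} unchanged, Q ∝ 1/μ, τ ∝ μQ).  Experimentally lowering haematocrit lowers
WSS in vivo, but in this model that effect cannot enter through μ alone — it
would need changed boundary pressures.  The invariance is asserted as a test
so the model's scope is explicit, and no flow prediction is made for
reduced-viscosity conditions.

## Statistics

Per-ISV event counts are small integers with heavy ties, where the classical
KS null distribution is invalid.  The adapted discrete KS test computes D as
the sup ECDF difference over the pooled support and draws its p-value from
the conditional permutation distribution — full enumeration when
C(n_a+n_b, n_a) ≤ 10⁵, otherwise a seeded vectorized Monte-Carlo permutation
with the (1+c)/(1+B) estimator.  The test is exact-level but conservative
under heavy ties (measured type-I error ≈ 3–4% at nominal 5% for
Poisson(2) samples of 25); one-sample testing against a reference pmf is
available via parametric simulation.  Directionality data use the first
trigonometric moment (mean direction, resultant length R, circular
SD = √(−2 ln R); the mean is flagged undefined when R ≈ 0) and Watson's
two-sample U², computed in the rotation-invariant ECDF-difference form with
the asymptotic tail series 2Σ(−1)^{k−1}exp(−2k²π²U²) for n ≥ 8 per sample
and a permutation p otherwise.  Mean comparisons use Welch's
unequal-variance t (scipy).  All Monte-Carlo p-values are seeded and report
their resample count.

## Synthetic data: what it emulates, and what it does not

The embryo generator places DA nuclei along the axis, DLAV residents from
the anastomosis phase, three residents per ISV, and one basal "connection"
cell per ISV whose final position encodes the ventral identity (arterial:
stays at the DA wall; venous: settles below the DA plane during
remodelling).  Resident cells integrate a piecewise-constant dorsoventral
drift — vISV 5 → 2 → 3 → 0 µm/h and aISV 3.9 → 1 → −0.6 → 0 µm/h across the
sprouting/anastomosis/remodelling/quiescent phases with cut points at
30/33/40 hpf (the cut points are configurable; phase timing in vivo is not
sharp) — plus iid Gaussian observation noise on every coordinate.  Divisions
follow a per-cell exponential hazard with continuous birth times carried
across generations (frame-rounding the clock would bias the branching
process low by ~15%); hazards of 0.015/0.028 per cell-hour give ≈ 0.9 / 2.0
expected divisions per arterial/venous vessel over 18 h.  Exchange events
occur with per-vessel probabilities 0.60 (DLAV→aISV), 0.76 (vISV→DLAV) and
0.92 (PCV→vISV) of at least one event (two cells 30% of the time), injected
as continuous translocations at 40 µm/h — never teleports — with emigrants
drawn from lineage leaves so the division process is not censored.  ISV
spacing (75 µm) and length (100 µm) are typical trunk dimensions at these
stages.  Diameters grow linearly to ≈ 7 µm (aISV) and ≈ 8 µm (vISV) at
44 hpf with per-vessel offsets and measurement noise.  One RNG stream per
embryo, keyed by (seed, embryo id), makes cohorts reproducible element-wise.

The monolayer generator gives each cell a persistent direction — toward the
free space for control-like assays (small angular jitter), uniform for
knockdown-like ones — a speed scale, and random-walk step noise; the wound
area series follows the mean front advance of the configured motion.

Deliberate simplifications, hence what passing tests do and do not show:
no tip-cell conversion into the DLAV during anastomosis (final cell numbers
per ISV run ~1 cell higher than in vivo); per-vessel diameters are drawn
independently of that vessel's cellular events, so driver–diameter
correlations are null in synthetic cohorts (the correlation machinery is
validated on constructed examples and a permutation oracle instead); no cell
death; no flow-coupled migration feedback; isotropic monolayers close
essentially no wound area because proliferation-driven closure is not
modelled.  Passing recovery tests demonstrates that the estimators are
unbiased and the detectors exact under the stated motion-plus-noise model,
not that real segmentation/tracking errors are handled.

## Problem sizes

Default analyses run cohorts of 8–20 embryos of 10 ISVs (≈ 100k track
points), bootstrap CIs with 500–2000 resamples, permutation tests with
2000–10⁴ resamples, and 1000-replicate calibration runs; these sizes give
standard errors comfortably below the effects being measured while keeping
any single script in the seconds-to-minutes range on one CPU.
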