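# Methods

`chewfield` models how the electrical activity of the masticatory muscles
(chiefly the temporalis and medial pterygoid) propagates through the head
to the cerebral cortex, and predicts whether the resulting cortical
electric field (EF) during natural chewing reaches the ~0.2 V/m range that
has been reported to modulate ongoing neural activity. Because the
underlying clinical recordings (simultaneous scalp EEG and subdural ECoG in
implanted epilepsy patients) are not publicly available, the package pairs
the full analysis pipeline with a parametric head phantom and a synthetic
recording generator, so that every stage is testable end to end and every
headline number is recomputed at run time.

## The head phantom

The phantom is a concentric-sphere head: white matter (r < 66 mm), a gray
matter shell (66–78 mm), CSF (78–82 mm), skull (82–88 mm) and soft tissue
(88–94 mm), voxelized at 2 mm isotropic spacing (configurable). Onto this
substrate it places the structures that control extra-to-intracranial EMG
propagation:

* a **temporal-muscle compartment**: a 40° half-angle sector of the
  soft-tissue shell on the lateral (+x) side, plus a small **pterygoid
  compartment** at the skull base next to the foramen channel;
* **craniotomy defects**: two burr-hole cylinders (12 and 16 mm diameter)
  and a 3 mm saw-line slot, all CSF-filled and carrying their own label so
  head-model variants can close them;
* a **skull-base foramen**: a 4 mm cylinder through the skull filled at
  0.38 S/m (the mean of blood and white matter), the high-conductance
  tunnel that couples the pterygoid region to the intracranial space;
* an **insulating grid patch**: a spherical-cap sheet of silicone-like
  insulator on the gray/CSF interface carrying a 4×4 lattice of subdural
  contacts at 10 mm pitch (4 mm discs).

Three variants derive from one specification and differ *only* at defect
and grid voxels: HM1 (defects + grid, the implanted head), HM2 (grid only)
and HM3 (neither — the healthy head).

### Geometry choices that matter

The qualitative shielding result — closing the skull defects changes
sub-grid EMG power only mildly, while removing the insulating grid raises
it substantially — depends on the *relative placement* of muscle, grid and
defects, not merely on their presence:

* The grid faces ~40° superior to the muscle sector, as a fronto-parietal
  grid sits away from the temporal muscle in an implanted patient. With
  the grid centered over the muscle, current concentrating around the
  patch rim dominates the contact potentials and the shielding direction
  inverts.
* The defects lie along the grid's far (superior) edge, as real burr
  holes and saw lines border the craniotomy away from the muscle. Defects
  placed between muscle and grid act as current funnels and exaggerate
  their effect by an order of magnitude relative to the clinical report.
* The patch is pressed onto the cortex (`grid_gap_voxels = 0`). Lifting
  it one voxel leaves a 2 mm CSF film beneath that conducts the rim
  potential under the whole sheet ("antenna" behavior) — useful for
  studying the field-parallel boundary condition (see below), but not
  representative of contacts pressed against cortex.

With these defaults the phantom reproduces the reported regime: closing
defects changes peak sub-grid power by ~2 % (reported: ~6 %), and the
healthy head carries ~27 % more peak sub-grid EMG power than the implanted
head (reported: ~27 %).

The sub-grid power comparison uses the global zero-mean node potential as
reference. The clinical common average spanned on the order of a hundred
contacts distributed across the intracranial space, which a global
reference approximates; a common average over only the 16 phantom grid
contacts would subtract the local mean and distort the comparison.

## The synthetic recordings

`generate_recording` emulates the acquisition: 1024 Hz sampling, a nominal
1–344 Hz band, chewing bursts repeating at 1.2 Hz (configurable within the
reported 0.8–1.8 Hz range) with mild jitter. Each burst is band-limited
(30–500 Hz) Gaussian noise under a sharp-onset envelope (10 ms cosine
rise, exponential decay). Channels receive the burst through
inverse-square distance mixing from the muscle compartment — the scalp
topography is *not* constrained by any published map, only by the
requirement of plausibility — normalized so that the channel-median gain
is one; subdural channels receive it attenuated by the reported mean
factor 5.5. Background noise has a 1/f² power spectrum: the steep
high-frequency roll-off of ongoing EEG/ECoG matters because the burst
amplitude statistic works on 100 Hz high-passed data, and a flatter (1/f)
background would leak enough power above 100 Hz to bias the recovered
attenuation ratio from 5.5 down to ~4.

What passing tests on this generator do show: the analysis pipeline
(filtering, excerption, spectra, statistics, calibration) recovers the
quantities the generator encodes, at realistic SNR and trial counts. What
they cannot show: correctness of the generator itself as a model of real
EMG topography or of inter-patient variability — no per-channel scalp EMG
topography was ever published for this paradigm.

## Event-related analysis

Trials span −2 to +2 s around each event center (the arithmetic mean of
EMG onset and end). Sliding-window FFT power uses 250 ms rectangular
windows stepped by 24.41 ms (256 and 25 samples). Relative spectra divide
trial power by a baseline estimate per channel and frequency and take
log10.

**Baseline estimator.** The baseline period is a 200 ms pre-event window
centered in the silent gap before each event. Within one trial the
sliding windows overlap by ~90 %, so their power values are strongly
correlated: taking the median across time bins *within* a trial tracks
the trial's mean power (≈0.87× mean under white noise), while independent
periodogram draws have median ≈0.69× mean. Using the within-trial median
as the baseline therefore biases null relative spectra by −0.10 log10
units. The default here takes the median *across trials* (independent
draws — robust to outlier trials and calibrated against the null median)
and then averages across baseline time bins; the within-trial order
remains available as `SpectralParams.baseline_reduce`.

**Statistics.** Each time–frequency bin is tested with an exact two-tailed
sign test (zeros dropped, doubled smaller tail capped at 1). Multiple
testing uses Benjamini–Yekutieli FDR at q = 0.001 — the variant valid
under arbitrary dependence, appropriate for heavily correlated
neighboring bins. Because the sign test is discrete, its attainable level
at α = 0.05 is below 0.05 (0.0432 at n = 40); the validity tests compare
the empirical rejection rate against the exact attainable level, not
against α.

**Amplitude statistic.** The chewing-burst amplitude is the difference
between the 90th and 10th percentile (linear-interpolation percentiles) of
100 Hz high-passed data (4th-order zero-phase Butterworth) in a 100 ms
window around the event center. Variants: 55 Hz cutoff, windows 50–300 ms,
peak-to-peak. For a sinusoidal carrier this statistic returns 1.902× the
amplitude (arcsine-distribution quantiles), i.e. it deliberately
underestimates the true peak-to-peak swing — a conservative choice.

## Forward model

One trilinear hexahedral element per labeled voxel; Galerkin assembly with
the standard conductivity set (S/m): white 0.14, gray 0.33, CSF 1.54,
blood 0.63, skull 0.0063, muscle 0.11, soft tissue 0.17, internal air
0.002, foramen fill 0.38, defects as CSF. The grid insulator uses
1e−12 S/m — fourteen orders below tissue, i.e. a perfect insulator at
solver tolerance, while keeping the matrix numerically well scaled.

Dipoles enter through the St. Venant construction: monopole loads on the
nodes of the enclosing element and its vertex-neighbor elements, chosen to
minimize the second spatial moment (plus a 1e−6 Tikhonov term) under
*exact* zero-total-current and first-moment constraints, so the realized
dipole moment is correct to machine precision.

The singular Neumann system is grounded at one unloaded boundary node and
solved by conjugate gradients with Jacobi (diagonal) preconditioning to a
relative residual of 1e−9, then shifted to zero mean. Diagonal scaling
removes most of the damage done by the ~250× conductivity contrasts while
remaining exactly symmetric positive definite, which CG requires; a
428k-node four-layer solve takes seconds on one core. Electrode potentials
are trilinear interpolations at the contact centers (contacts that
rasterize just outside the mesh are nudged inward by up to half a
voxel); the electric field is the negative trilinear gradient at element
centers, reported for gray matter elements.

**Source models.** SM1: one dipole in the muscle belly. SM2: seven belly
dipoles spread along the muscle's long axis plus one in the thin superior
part. SM3: one dipole in the pterygoid compartment, oriented along the
foramen axis. SM1/SM2 orientations default to the muscle long axis; all
positions and orientations are configurable, and no anatomical fidelity
beyond compartment membership is claimed.

**Verification.** The independent oracle is the Legendre-series solution
for a dipole in a multilayer concentric sphere with insulating outer
boundary (layer coefficients from per-degree transfer systems; stable
P_n/P_n′ recurrences; truncation when new terms fall below 1e−12 of the
accumulated potential). The series itself is validated against closed
forms: the central-dipole surface potential 3p·cosθ/(4πσR²), the direct
infinite-medium dipole potential (large-sphere limit, both orientations),
and conductivity-scaling/zero-mean identities. FEM and series are compared
with RDM (topography) and lnMAG (magnitude): on the four-layer sphere
(radii 78/80/86/92 mm) with an eccentric dipole at 60 % radius and 2 mm
voxels, RDM ≈ 0.03 and |lnMAG| ≈ 0.07 for both orientations, and RDM
decreases under mesh refinement.

**Shield boundary condition.** Next to a near-zero-conductivity sheet the
normal current — hence the normal field on the conductive side — vanishes,
so the field in a conductive layer bounded by the shield runs parallel to
it. This is asserted quantitatively (median radial fraction ≤ 10 %) on a
phantom with a CSF film beneath the grid, where the adjacent conductive
layer is resolved at the mesh spacing; with the sheet pressed onto gray
matter the sub-voxel boundary layer is unresolved and the diagnostic mixes
in the currents diving beneath the patch.

## Grid reconstruction

The six-step reconstruction molds an electrode grid onto a cortical
surface: (1) a shrinkwrap hull — an enclosing icosphere shrunk radially
toward the surface's angular support function with Laplacian smoothing,
finished by smoothing-only passes and a uniform enclosing offset, so the
hull follows the envelope but not individual gyri (assumes a star-shaped
surface, which brains approximately are); (2–3) a patch cut from the hull
between four corner points, bounded by shortest edge paths and flood-filled
from the corner centroid; (4) an isomap embedding: classical MDS on
graph-geodesic distances, where the geodesic graph joins mesh edges with
all vertex pairs within 3 mean edge lengths — pure lattice edges
overestimate off-axis distances by up to ~40 %, the augmented graph brings
developable patches to ~2 % distortion (the chord radius must stay below
the local curvature scale); (5) a rigid lattice of contact centers at
10 mm pitch in the flat chart, each linked to its three nearest embedded
vertices with index-order tie-breaking; (6) barycentric back-projection to
3-D. A face-seal check guards the insulating property of any rasterized
grid: two insulator voxels meeting only along an edge or corner form a
current leak; the rasterizer repairs such contacts by adding bridging
voxels.

## Calibration and dosimetry

All forward quantities are linear in dipole moment, so one unit-moment
solve per (head model, source model) suffices:

1. **Calibrate** (implanted head, HM1): per-trial dipole strength
   `q_i = A_i / (2 · g)`, where `A_i` is the trial's intracranial burst
   amplitude (channel-median by default; channel-max available) and `g`
   the reduced simulated contact amplitude per unit moment. The factor 2
   converts the static forward potential to the full swing of a
   polarity-reversing burst.
2. **Healthy-head field** (HM3): `EF_i = q_i · k`, with `k` the peak gray
   matter field per unit moment; the peak locates in the cortex facing the
   muscle — the phantom analogue of the temporal pole.
3. **Condition scaling**: `EF_i,cond = EF_i · S_cond / M_i` with `S_cond`
   the mean scalp amplitude of a chewing condition (yoghurt 46.6, banana
   45.7, carrot 116.4, gum 107.3, candy 139.9, licorice 155.2 µV) and
   `M_i` the trial's median scalp amplitude. The condition mean over
   participants is used, matching how the scaling table is reported.
4. **Exceedance**: the percentage of trials with peak EF strictly above
   0.2 V/m, over the parameter sweep (high-pass 55/100 Hz × window
   50–300 ms × statistic × source model).

The EF peak is the magnitude of the field vector, with no spatial
smoothing.

**Recovery experiment.** Ground-truth strengths are drawn log-normally
(σ_ln = 0.6, median placed for ~30 % designed exceedance); synthetic
trials push them through the HM1 contact pattern under a 256 Hz square
carrier — the discrete tone whose samples are exactly ±1, so the
percentile statistic of a noise-free trial is exactly twice the static
pattern and the factor-2 convention is exact — plus 1/f² noise at
amplitude SNR 10. At n = 500 the pipeline recovers strengths with ~1 %
median relative error and the exceedance fraction within the 95 % binomial
confidence interval of the designed truth.

## Problem sizes and tolerances

Default phantom and oracle meshes run at 2 mm (≈0.4 M elements, ≈0.43 M
nodes); solver tolerance 1e−9 relative residual; series truncation 1e−12;
St. Venant moment error < 1e−8; statistical simulations use 2000 null bins
(type-I error) and 25 replicates × 200 bins (FDR control); recordings for
generator checks are 90 s (~100 chewing events). These sizes keep a full
validation run in minutes on a single core while leaving every mechanism
resolvable; all of them are parameters, not constants.

## Known limitations

* Spherical geometry: no gyri/sulci, no anisotropic or frequency-dependent
  conductivity, no metal contact discs, regular (not geometry-adapted)
  hexahedra. The shielding and tunneling mechanisms survive these
  simplifications; patient-specific percentages do not, and reproducing
  the clinical per-condition exceedance numbers is explicitly out of
  scope.
* The scalp mixing model of the generator is an inverse-square
  plausibility choice, not a validated EMG topography.
* The shrinkwrap hull assumes a star-shaped input surface.
* The isomap chord augmentation can shortcut across strongly curved,
  non-developable patches; grid-scale cortical patches are close enough to
  developable for percent-level accuracy.
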