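# Methods

This note records the models, parameter choices and numerical decisions
behind `crystafm`, in the order of the pipeline.

## Synthetic HS-AFM movies (`crystafm.synthetic`)

**What is emulated.** The generator reproduces the imaging situation of a
membrane-bound aegerolysin 2D crystal: a mica reference plane at 0 nm, a
supported bilayer patch 7 nm above mica (the measured height of the rigid
CPE/Chol bilayer), and a protein layer whose protrusions rise 5 nm above the
membrane (the monomer height implied by the crystal structures). Protein
occupies dimer-sized sites of a monoclinic lattice with defaults
a = 10.8 nm, b = 6.6 nm, γ = 100°; three dimer slots tile the a direction at
a pitch of a/3 = 3.6 nm, matching the three-dimer (hexameric) repeat unit.

**Repeat-unit footprints.** Only the head (≈6.5 × 5.1 nm) and neck
(≈5.1 × 2.8 nm) envelope ellipses are known from imaging, not per-dimer
geometry. The defaults render AB and CD as congruent 3.4 × 5.1 nm ellipses
with the major axis across the stripe (their union approximates the head)
and EF as a 5.1 × 2.8 nm ellipse with its major axis along the b direction,
giving the neck its visibly different orientation. Footprints are flat-topped:
with blur and noise disabled a rendered frame takes only the values
{0, 7, 12, 12 − drop} nm up to ellipse-edge discretisation, which the tests
exploit.

**Alternate-unit modulation.** The neck dimer is lowered by
`ef_alternate_drop` (default 0.3 nm — the order of the measured protrusion
height differences, comfortably above the 0.1 nm default noise) in alternate
repeat units, staggered by one unit between adjacent rows (`row_stagger`,
tunable). The real-space geometry behind the experimentally reported second
periodicity is not established, so the generator exposes the stagger rather
than claiming to reproduce a particular second spacing; see "Unit-cell
fitting" below for the consequence.

**Growth kinetics.** Stripes are contiguous slot runs in single lattice
rows. Per frame interval (default 2 s, the experimental frame time) each
stripe end gains Poisson(k_assoc) and loses Poisson(k_dissoc) dimers; only
the net change is applied and logged, because opposing events within one
frame interval are unobservable at the frame rate. An end sitting at the
allowed-slot limit is frozen. Transversal growth happens only by nucleation
of single-dimer stripes in rows adjacent to existing stripes
(rate k_nucleate per frame). Stripes whose row lies in the membrane-edge
band dissociate faster by `edge_instability_factor`, a deliberately simple
stand-in for the observed edge instability whose mechanism is not known.
The event log (frame, stripe, event, slots, length) is exact by
construction: final length = initial + Σassoc − Σdissoc per stripe.

**Instrument model.** Gaussian tip blur (default σ = 0.5 nm) and i.i.d.
Gaussian pixel noise (default σ = 0.1 nm), seeded and bit-reproducible.
Scan-line artifacts and drift are not modelled. Default scan: 0.5 nm/pixel,
256 × 256 — more than 10 pixels per 6.5 nm stripe period.

**What passing tests do not show.** Real movies have drift, scan-line noise,
curved or kinked stripes, and proteins wandering on the membrane before
crystallising; none of these are generated, so estimator performance here
bounds the idealised, not the general, case.

## Lattice analysis (`crystafm.lattice`)

**Autocorrelation.** Computed spectrally from the mean-subtracted,
Hann-windowed image and divided by the window's own autocorrelation
(an unbiased estimator), so lattice-translation peaks sit near 1 regardless
of lag instead of decaying with the window. Value 1 at zero lag; even under
lag negation; constant images are rejected (zero variance).

**Periodicity estimation.** Peaks of the Hann-windowed periodogram must be
strict 8-neighbour local maxima above both 5× the median power and a
Bonferroni-style ceiling mean·(ln N + 3). The ceiling matters: periodogram
bins of a noise image are approximately exponential, so a median-based
threshold alone fires on white noise, while the maximum of N exponential
bins concentrates near mean·ln N. Sub-pixel localisation uses a 3 × 3
power-weighted centroid; conjugate pairs are reported once; spacings at or
below the Nyquist limit are discarded.

**Unit-cell fitting.** The ACF of this crystal contains, besides true
lattice translations, partial-overlap maxima at a/3 (the dimer pitch —
two of the three dimer footprints are congruent). Several value-based
filters proved fragile, so the image-level fit works in reciprocal space
(`fit_unit_cell_from_image`): a perfect crystal's spectrum is supported on
the reciprocal lattice only, and the weak but sharp (1,0) reflection —
present because the three dimers are not exactly equivalent — pins the true
a period. Candidate reciprocal bases are Lagrange-reduced pairs of detected
peaks, required to (i) be detected peaks themselves after reduction and
(ii) have higher-order support (some peak at 2g or 3g), which screens out
envelope lobes of a finite patch. The basis explaining the most peaks at a
strict tolerance (8 % of the shortest generator) wins, ties resolved toward
the denser reciprocal basis (the smaller real cell), and is polished by
integer-indexed least squares with outlier rejection. Recovered cells on
synthetic full-coverage images are accurate to ~0.002 nm and ~0.04°
across orientations and noise at the default scan.

`fit_unit_cell` (operating on a given ACF peak set) keeps the classical
shortest-pair contract and inherits the sublattice caveat, documented in its
docstring.

**Decorated vs structural cell.** When the alternate-EF modulation is
resolved (sparse frames, low detection floor), the crystallographically
correct cell is the decorated one with b doubled, and the fit returns it;
on full-coverage frames the superstructure reflection stays below the
detection floor and the structural (a, b) cell is returned. This mirrors the
second periodicity visible in the experimental FFT. Setting
`ef_alternate_drop = 0` removes the decoration entirely.

Cell fitting needs a crystal spanning roughly ten repeats in both
directions; narrower patches produce finite-size envelope lobes comparable
in power to true reflections, and no automatic criterion can separate them
reliably.

## Profiles and statistics (`crystafm.profiles`)

Profiles are sampled bilinearly at pixel-size steps, averaged over `width`
parallel lines one pixel apart; bilinear sampling is exact on affine height
fields (tested). Protrusions are local maxima with prominence ≥ 0.05 nm and
separation ≥ 2.0 nm (below the 3.6 nm dimer pitch, above the noise scale;
the experimental criteria are unpublished, so these are documented package
defaults). Labels cycle 1, 2, 3, 1*, …; the label phase is the caller's
choice, with `phase_align` implementing the conventional assignment (label 3
on the recurrently lowest protrusion, as done by eye on the real data).

Notched boxes use Tukey hinges (median included in both halves for odd n)
and the McGill notch 1.57·(Q3 − Q1)/√n, an approximate 95 % confidence
interval of the median. The hinge convention is fixed and documented because
the convention of the original analysis software is unknown.

## Kinetics (`crystafm.kinetics`)

Stripe tracing assigns protein pixels (above the modal membrane level plus
2.5 nm, half the protein height) to lattice rows, then tests each candidate
slot with the mean height inside a quarter-pitch disc around the slot centre
— a disc that fits inside every dimer footprint, which makes end-slot
detection robust to blur and noise. Traces are maximal runs of occupied
slots; lengths are slot counts × a/3, i.e. projections onto the a axis, not
arc lengths (stripes are straight in the model).

Between consecutive frames, events are the connected components of the
set difference of occupied-slot intervals per row: components of t+1 \ t are
associations, of t \ t+1 dissociations; a gap opening inside a stripe is one
dissociation of the gap length, a new stripe one association of its full
length. Each component is attributed to the frame-t stripe it touches
(largest overlap first, deterministic), otherwise to a fresh id. With
blur/noise at defaults the measured per-frame totals equal the generator's
event log exactly (slot quantisation); this is asserted in the tests.
Coverage is the running sum of Σassoc − Σdissoc and may decrease. Frames may
be skipped by the caller; records carry their true frame indices and are
never interpolated.

The Gaussian fit utility is a plain 4-parameter least-squares
(offset + amplitude·exp(−(x−c)²/2w²), scipy curve_fit); the quantity to fit
is the caller's choice.

## Stability (`crystafm.stability`)

Per-pixel mean and population SD (ddof = 0 — the frames are the whole
population of interest, and the convention is fixed since the original is
unspecified) over a half-open frame range, with no registration (a
`register` flag reserves the option but is not implemented). Mean-of-profiles
equals profile-of-mean exactly (linearity), tested.

## Structures (`crystafm.structure`)

PDB files are read with biotite; altlocs resolve to the highest-occupancy
variant. Kabsch superposition is implemented directly (SVD with a
determinant correction enforcing a proper rotation) and cross-checked in the
tests against a quaternion-search brute force; correspondence is by residue
number + atom name, erroring on mismatches, with `common_backbone` to subset
two structures to their shared backbone. Vertical extent works on backbone
atoms after optional terminal-residue exclusion, along a caller axis or the
principal axis by default (for an elongated β-sandwich monomer the principal
axis is the height direction); Å→nm conversion happens only at this module
boundary. Crystal tiling translates copies by integer lattice combinations
in the xy plane and relabels chains.

Pseudo-AFM images are grayscale dilations of the hard-sphere upper envelope
(Bondi van der Waals radii, fixed in-repo for bit-stable rasterisation) by a
sphere-capped conical tip: profile R − √(R² − r²) out to r = R cos θ, then
the tangent cone of slope cot θ. The "cone angle of 8°" is interpreted as
the half-angle (configurable). Dilation is evaluated with
`scipy.ndimage.grey_dilation` over the exact tip support and verified
against an exhaustive max-search oracle on 64 × 64 grids. Depth contours are
`skimage.measure.find_contours` iso-lines at top − level.

## Problem sizes

The test suite and the acceptance script use 256 × 256 frames (0.5 nm/pixel,
a 128 nm field), movies of 12–30 frames, and toy structures of ≤ 30 atoms;
these sizes resolve every analysed feature (≥ 10 px per stripe period,
hundreds of logged events) while keeping the full suite under a minute.
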