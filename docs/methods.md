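# Methods

This note documents the models and estimators implemented in memshadow,
the synthetic data they are validated on, the parameter choices that were
genuinely open, and what the validation does and does not demonstrate.

## The co-localization statistic

A species' lateral distribution in one frame is reduced to a binary
occupancy ("shadow") matrix on a fixed grid over the membrane plane:
cell = 1 iff at least one selected bead's (x, y), wrapped into the box,
falls in the cell. The default spacing is 0.5 nm. Two shadows on the same
grid are compared by mean square error, which for binary matrices equals
the mismatched-cell fraction (bounded by [0, 1], symmetric, zero iff the
occupied sets coincide). For independent random matrices with occupancy
probabilities p and q the expected MSE is p(1−q) + q(1−p); this closed
form is the calibration null used in the tests.

Because the nanoparticles sit near the bilayer center between both tail
regions, shadows pool both leaflets by default. The ranked table reports
per-target mean ± SE of per-frame MSE values (per-frame-then-average is
the default; a time-averaged-occupancy mode exists), sorted ascending with
lexicographic tie-breaks, ties flagged.

Two properties of the statistic matter for interpretation and are visible
in the validation studies:

* **Abundance sensitivity.** MSE ≈ p + q − 2·overlap, so a target's own
  occupancy q enters directly: among targets with very different
  abundances the ranking mixes abundance with co-localization. The
  abundance-controlled studies therefore use compositions with equal
  copy numbers per tail species, where rank differences isolate the
  planted lateral signal.
* **Regime of sensitivity.** The statistic is most decisive when the
  favored-tail domains are compact and densely occupied and the
  reference species concentrates onto them — occupancies of the same
  order, overlapping sets. The generator's domain model (below) produces
  exactly this regime.

## The synthetic membrane

The generator emulates a coarse-grained plasma-membrane patch at the scale
of the systems the analyses are meant for: a 40 × 40 × 13 nm box, ~6200
lipids (15 species, 14 lipid + 1 sterol) split into two leaflets with the
inner leaflet enriched in 4-5 double-bond tails, 30 mol% sterol, and
single-bead nanoparticles (default 314; an optional 16-bead shell exists
for I/O realism). All randomness derives from one seed; identical specs
produce bit-identical frames.

**Lateral domains.** Each tail code gets an independent Gaussian random
field (white noise smoothed at a 5 nm correlation length, periodic); each
1 nm cell is assigned to the code whose shifted field is largest there,
with per-code shifts calibrated so domain areas track tail abundances.
This mosaic construction makes domains disjoint and fillable by their
species — overlapping thresholded fields cannot be simultaneously filled
when species compete for space, which would leave the planted signal
undetectable. Lipids sit on a jittered lattice (guarding packing at
≥ 0.45 nm² per phospholipid equivalent, sterols at half footprint;
denser specs raise an overcrowding error), and species are assigned to
lattice sites by weighted sampling without replacement with weight
(1 − patchiness) + patchiness · [site in own domain]; patchiness defaults
to 0.9. Individual beads splay laterally by 0.25 nm (σ) around the lipid
site. The sterol's weight field is the complement of the co-localization
target's domain, planting the sterol–nanoparticle anti-correlation.

**Transverse structure.** The midplane height h(x, y) is a sum of
`undulation_modes` cosine modes (lowest integer wavevectors, random
phases, amplitude `undulation_amplitude` each, default 0.3 nm × 3 modes).
Phosphates sit exactly at h ± (t/2) where the local thickness t is the
planted plane separation (2 × 2.0 nm) plus an optional Gaussian bump;
tail beads interpolate toward the midplane. With zero amplitude the
bilayer is exactly flat, giving exact references for the thickness map,
leaflet assignment and undulation RMS.

**Nanoparticles.** Lateral positions follow the mixture
(1 − s) · uniform + s · uniform-over-target-domain, so s = 0 is uniform
and s = 1 fully domain-confined, monotonically in between. A fraction
`cluster_fraction` (default 0.5) is placed in contact clusters (default
size 8, Gaussian σ 0.3 nm around cluster centers drawn from the same
law); z sits 1 nm below the local midplane (the inner-leaflet side), with
0.2 nm noise. Ground truth records leaflet labels, cluster memberships,
domain masks, undulation modes and the thickness field.

**What the generator does not emulate:** no physical force field or
dynamics, no area-per-lipid/order-parameter physics, frames are
statistically independent re-jitters rather than correlated dynamics, no
water/ion beads, and domain geometry is a GRF mosaic rather than the
outcome of lipid phase behavior. Passing the recovery tests shows the
estimators are correct and sensitive under realistic geometry and noise;
it does not by itself validate conclusions about any particular real
membrane.

## Leaflet assignment, maps and spectra

Phosphate (PO4) beads are split into leaflet populations against their
global mean z; per 2 nm lateral cell, each population's mean height is
smoothed (3 × 3, periodic) and the local midplane is the average of the
two — leaflet-aware, so a flat bilayer yields the exact midplane whatever
the per-cell counts. Lipids (by phosphate bead, or mean bead position for
sterols) are labeled by the side of the local midplane; cells without
phosphates in the smoothing footprint fall back to the global midplane
with a warning. On 1 nm undulations (half the leaflet offset) recovery
is ≥ 99.5%.

Thickness maps subtract inner from outer mean phosphate z per cell
(default 1 nm cells — the estimator and resolution are package choices,
as no standard exists), masking cells lacking either leaflet. Density
profiles re-center each frame on the mean phosphate z and count beads in
fixed-width bins covering all data, so the integral equals the selected
bead count exactly; units are bead counts (number density available).
Enrichment maps divide time-averaged per-cell counts by the lateral mean
(mean ≡ 1 by construction). Undulation spectra are 2|FFT(h)|/N per
integer wavevector of the cell-mean midplane field; cell-averaging
attenuates a 40 nm wavelength mode on 2 nm cells by < 1%, within the 5%
recovery tolerance.

## Clustering

Particles are linked when their minimum-image distance is ≤ the cutoff;
clusters are connected components (single linkage). The implementation
uses a periodic k-d tree with union-find on the contact pairs; tests
compare it against an independent brute-force all-pairs minimum-image
oracle on 1000 random instances, including clusters straddling the
periodic boundary. The 1.0 nm default cutoff approximates bead-center
contact for a ~0.7 nm CG fullerene and is recorded in all outputs; an
aggregate of two or more counts as a cluster in summaries (the dimer
convention is a documented choice). Cutoffs ≥ half the smallest box
length are rejected (minimum-image ambiguity).

## WHAM and bootstrap

Standard self-consistent WHAM on histograms (default 0.05 nm bins — half
the 0.1 nm window spacing): iterate the P(z)/f_i equations in log space
until the maximum relative change in f_i is < 1e-7 (up to 1e5 iterations;
non-convergence raises with the residual). Zero-count bins are masked;
adjacent windows sharing no counts trigger a warning. G(z) = −kT ln P(z)
is shifted so its mean over a reference region is zero; the default
reference is the outermost 0.5 nm of coverage on the high-z side, i.e.
bulk water in membrane-normal applications. The harmonic restraint
constant is interpreted in kJ mol⁻¹ nm⁻², the standard unit for
coarse-grained umbrella pulling.

Errors use an ordinary within-window bootstrap (≥ 20 replicates; a block
variant with settable block length exists for autocorrelated samples):
resample each window with replacement, re-solve WHAM warm-started from
the converged f_i on the shared binning, and report the per-bin standard
deviation. The estimator reduces exactly to bias-corrected Boltzmann
inversion for a single window, and is invariant under additive constants
in the window potentials up to the reference shift.

The umbrella-sampling data generator draws from
exp(−[U(z) + ½k(z−c)²]/kT) by Metropolis (Gaussian proposal of twice the
bias width, 10% burn-in, 10× thinning), vectorized across windows, for
callable or tabulated potentials; non-finite potentials on the support
are rejected.

**Validation conditions.** The analytic recovery study uses
U(z) = ½ · 50 · z² kJ/mol, 46 windows spaced 0.1 nm, k = 1000
kJ mol⁻¹ nm⁻², 10⁴ samples per window, 298 K. The windows are placed
symmetrically about z = 0 (−2.25 … 2.25 nm) so the checked range
|z| ≤ 2 nm is fully covered; the additive constant is aligned by the mean
difference over that range before measuring the maximum error (< 1
kJ/mol observed ≈ 0.2). Free-energy wells of real nanoparticle–bilayer
systems (tens of kJ/mol) are far larger than this resolution, but
reproducing any specific published minimum would require the original
multi-microsecond membrane simulations, which is out of scope.

## Validation problem sizes

Chosen once as the package's study conditions:

| study | conditions |
|---|---|
| co-localization recovery | 40 × 40 nm, 4 equal tails × 1300 lipids, 629 NPs (10% loading), s = 0.9, 20 seeds |
| co-localization null | 20 × 20 nm, 4 equal tails × 280 lipids, 100 NPs, s = 0, 200 seeds |
| geometry recovery | full default system, flat and 1 nm single-mode variants |
| cluster oracle | 1000 instances of ≤ 50 particles in a 4 nm box |
| WHAM recovery | as above, with 40 bootstrap replicates |

The recovery study uses the 10% nanoparticle loading because the planted
signal scales with the reference occupancy: at 10% loading the mean MSE
margin of the target over the runner-up (~0.06) is an order of magnitude
above the seed-to-seed occupancy noise, making first-rank recovery a
sharp test rather than a coin flip.

## Known limitations

* MSE rankings on heterogeneous compositions confound abundance with
  co-localization (inherent to the statistic; use abundance-controlled
  compositions or the enrichment-map correlations to isolate location).
* No significance test between MSE ranks is provided.
* Leaflet assignment assumes a bilayer topology; vesiculated or ruptured
  membranes violate its assumptions.
* The bootstrap treats samples within a window as exchangeable; for
  correlated time series use the block variant with a block length of
  the order of the correlation time.
* Only orthorhombic boxes and GRO/PDB inputs are supported; binary
  trajectory formats can be added behind the same Trajectory contract.
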