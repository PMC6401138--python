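# Methods

This note records the physical model, the numerical choices and the known
limitations of `nanodpk`, in the spirit of a methods appendix.

## The rescaled-DPK model

The absorbed dose around an electron-emitting nanoparticle is estimated in
three stages.

1. **Secondary-electron spectrum.** Photons from a line source (the bundled
   Yb-169 spectrum, or any user-supplied line list) ionise gold. The
   builtin generator samples a line proportionally to its yield, then an
   atomic shell among those with binding energy B below the line energy
   E_γ, weighted by fixed relative probabilities; the photoelectron carries
   E_γ − B and each vacancy emits optional fixed-energy Auger lines. The
   histogram (0.1-keV bins by default; 1 keV is appropriate for MV spectra)
   is normalised to electrons per incident photon, so it is invariant
   under uniform rescaling of the photon yields.

2. **Homogeneous kernel.** The DPK k(r) is the dose per source electron in
   1-nm concentric shells around an isotropic point source in water,
   obtained by dividing binned energy deposits by shell mass. Kernels are
   normalised per *source electron*; multiplying by the spectrum's
   electrons-per-photon total recovers a per-incident-photon scale. This
   is kept as an explicit external factor to avoid double counting.

3. **EPA rescaling.** For each source-point/tally-point pair the in-gold
   path DTI is computed exactly (parametric quadratic for the sphere and
   the rod wall, linear cap-plane solutions for the rod ends, first exit
   over the full boundary; Bresenham pixel counting on 2D grids) and the
   kernel is evaluated at MPL = GPL + (α − 1)·DTI.

### Rescaling factors

* `unity` — α = 1, geometry-only.
* `tsp` — spectrum-weighted ratio of **linear** total stopping powers,
  gold over water.
* `lrr` — spectrum-weighted ratio of **linear** CSDA ranges, water over
  gold.
* `pdr` — density ratio 19.3.

The stopping-power literature tabulates *mass* quantities; whether the
spectrum-weighted factors should use mass or linear values is ambiguous on
its face. We use linear (per-length) quantities throughout: the EPA
rescales *path lengths*, and the density-ratio factor — a pure
path-length contrast — is consistent with linear scaling. Spectrum sums
weight each bin by (bin weight × bin-centre energy); bin centres, not
edges, represent E_i.

## Material tables

Gold and water tables are computed at import time from the Berger–Seltzer
(Møller) collision stopping-power formula with mean excitation energies
I = 790 eV (gold) and 75 eV (water), Z/A = 0.40108 and 0.55509, plus a
radiative correction S_rad ≈ S_col·Z·E[MeV]/800; the mass CSDA range is
the cumulative integral of 1/S on a fine log grid. The density-effect
correction is omitted (negligible below ~1 MeV). A unit test pins the
water values at 100 keV to the standard tabulated references (4.115
MeV·cm²/g, 1.431e-2 g/cm²) within 3%. The Bethe formula degrades below a
few keV — severely so for gold — hence the default grid starts at 1 keV
and interpolation refuses to extrapolate. Interpolation is log-log, the
standard choice for stopping-power data. Users can substitute measured
(e.g. ESTAR) tables via the CSV reader.

Default secondary-electron parameters for gold: shells K/L1/L2/L3/M/N at
80.725/14.353/13.734/11.919/2.743/0.759 keV with fixed relative weights
0.80/0.06/0.04/0.05/0.04/0.01, and simplified Auger lines at 55 keV
(yield 0.04 per vacancy — gold's K fluorescence yield is high), 8 keV
(0.7) and 2 keV (1.0). These are coarse, single-number stand-ins for
energy-dependent subshell cross-sections and cascade physics; they were
fixed once from standard atomic data. With them the Yb-169 factors come
out at TSP ≈ 7.6 and LRR ≈ 9.3, near (but not equal to) the 8.2/9.6
obtained with a full photon-transport secondary spectrum, which is not
reproducible from a line list alone.

## Profile estimators

`profile_sphere` draws the SP uniformly in the sphere, picks a distance
bin uniformly (stratified, so distant bins are not starved), places the TP
isotropically at radius R0 + d with d uniform in the bin, and records the
per-bin mean of k(MPL). The mean-kernel estimator reproduces the
homogeneous kernel exactly in the point-source limit and matches
volume-averaged shell scoring for smooth kernels; TP placement uniform in
distance rather than in volume differs negligibly over 1-nm bins.

`profile_rod` classifies the rod exterior into the long-axis double cone
(tan ω = r/h beyond the caps) and the complementary short-axis region
(tan θ = h/r beyond the wall); boundary points, a measure-zero set,
belong to neither and are never sampled. TPs are drawn uniformly by
volume directly in the scoring solid of the selected bin — the
frustum pair (long axis, |z| ∈ [h+d, h+d+t], pdf ∝ z²) or the
frustum-bounded hollow cylinder (short axis, lateral radius pdf ∝ s²) —
by inverse-CDF sampling, which lands in the requested region by
construction (no rejection loop). Distances are measured from the cap
plane (long) or the lateral wall (short). Note the scoring solids are
*not* thin spherical shells: a frustum bin at nominal distance d contains
points at centre distances up to (h+d)·sec ω, so rod and sphere profiles
of a comparable particle agree only approximately even at α = 1.

DTI for rods uses the exact first exit over the full boundary (caps and
wall) rather than assuming the exit surface from the tally point's
region: an SP–TP segment can leave through a cap even when the TP lies in
the short-axis region.

## 2D cluster maps

Segmented micrographs become gold/water grids by global mean-RGB
thresholding (gold where mean RGB < 0.4 by default; 50-nm pixels). Each
gold pixel is an isotropic point source at its centre; the dose in each
water pixel sums k(MPL) over sources, with DTI = (number of *strictly
intermediate* gold pixels on the Bresenham line) × pixel size. Endpoint
pixels are excluded from the count — the source pixel's own half-chord is
not part of the traversed gold. Gold pixels receive no dose. With α = 1
the double loop collapses to a vectorised distance computation. The
`synth_cluster` generator (random gold discs on water) is a synthetic
stand-in for real TEM segmentations: it mimics disc-like endosomal
aggregates and exercises every code path, but carries none of the
morphology of a real micrograph, so tests passing on it say nothing about
segmentation quality on real images.

## Transport oracle

The validation transport is straight-line CSDA: electrons travel on
straight isotropic tracks, lose energy at the local linear total stopping
power, and dump the remainder on the spot once below the cutoff (default
0.25 keV). There is no multiple scattering, bremsstrahlung escape or
secondary production — it is *not* a condensed-history Monte Carlo and
never stands in for one; it exists so that EPA accuracy can be asserted
against ground truth with *matched* physics. Steps are limited to
max_step and to 2% energy loss; each electron's step comb gets a random
phase jitter so monoenergetic point-source histograms are smooth. The
gold chord of a sphere-source track is found analytically, so material
assignment is exact at the boundary. Deposits are the floating-point
differences of successive energies, making total energy conservation
exact (Sterbenz subtraction); the sphere-source profile carries an
emitted/inside/outside energy ledger in its metadata.

## Validation problem sizes and toy conditions

The cross-validations run at desk scale, chosen to make the Monte-Carlo
error a small fraction of the asserted tolerances: 1e5 transport
electrons and 1e6 rescaler pairs for profiles, 1e3 random pairs × 1e5
segment samples for the DTI oracle, 1e4 electrons for conservation. The
matched-physics EPA check uses proportional constant-stopping toy tables
(water 0.005 keV/nm; gold scaled so α = 1.3) and a narrow 8-keV line.
Proportional tables make the water-equivalent path mapping exact in the
CSDA limit, isolating the one approximation inherent to the method: the
kernel lookup at MPL rescales the geometric inverse-square factor along
with the range. That residual grows with α·DTI/GPL — with α = 1.3 it
yields MAPE ≈ 1/6/9% for R0 = 5/50/100 nm over the first micron, and
with a gold-like α ≈ 9 it dominates the near-field, which is consistent
with the 10–20% discrepancies such rescaling methods show against full
Monte Carlo at keV energies. This inverse-square mismatch is the main
known limitation of the method (not of its implementation here).

## Numerical conventions

* Energies in keV, lengths in nm, dose in keV/g per source electron
  internally; Gy conversion (1.602176634e-13 Gy per keV/g) only in the
  CLI layer.
* Kernel evaluation: linear interpolation between shell centres; constant
  below the first centre; zero beyond the last centre (finite range).
* No extrapolation outside material-table grids — out-of-grid energies
  raise.
* Degenerate inputs raise `ValueError` (empty spectra, α < 1, dti > gpl,
  non-uniform bins, all-zero reference series, …).
* All stochastic entry points take an integer seed and are bit-reproducible
  for a fixed seed; outputs record seeds in their metadata headers.
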