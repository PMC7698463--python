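# Methods

## Model

`voxfluor` simulates the migration of excitation and fluorescence-emission
photons through a voxelized breast-tissue model to ask a clinical question:
does a fluorescence-labeled cancer of a given size and depth produce a
surface signal above the sensitivity floor of a fluorescence image sensor
(10 nW/cm²)?  Three spectral windows are compared — visible (fluorescein,
488/520 nm), near-infrared (indocyanine green, 780/820 nm) and
shortwave-infrared (PbS quantum dots, 970/1100 nm) — on identical geometry
and seeds.

The medium is a 3-D grid of isotropic voxels (0.033 cm in the reference
anatomy), each carrying one of five labels: ambient air, skin, fat, duct,
cancer.  Each interior label maps to (μa, μs, g, n) per wavelength through
a TSV-backed table.  Photon transport is the standard weighted-photon
random walk of multi-layer tissue Monte Carlo, extended to heterogeneous
voxel grids:

* **Free flight.** A dimensionless pathlength s̄ = −ln ξ is drawn once per
  flight and consumed voxel-by-voxel as μt·d (d = geometric distance in the
  voxel), so free-path statistics stay correct across tissue boundaries;
  the sampler is re-entered only after an interaction.
* **Interaction.** At the interaction site a fraction μa/μt of the weight
  is deposited into the voxel's absorbed-weight grid, then the direction is
  re-sampled from the Henyey–Greenstein phase function (cos θ has mean g;
  g = 0 falls back to isotropic) with uniform azimuth, using the standard
  local-frame rotation with the |μz| ≈ 1 special case.
* **Boundaries.** Voxel faces where n changes (air 1.0 / skin 1.37 / duct
  1.42 / fat·cancer 1.45) apply unpolarized Fresnel reflectance with
  Snell refraction (total internal reflection ⇒ R = 1); matched-n faces
  are transparent.  Transmission into an air voxel is an escape, scored on
  the (x, y) anterior projection; leaving the grid entirely is an escape
  that is not surface-scored (this distinguishes diffuse reflectance from
  transmission in slab geometries).  A photon that escapes into air is not
  re-entered: the breast surface is treated as convex for this purpose.
* **Launch.** The default source is a uniform collimated disk (radius
  1 cm, 50 mW/cm²) centred over the nipple apex at normal incidence; a
  pencil beam is available for validation.  The specular Fresnel
  reflection at the entry face is deducted deterministically from the unit
  initial weight and booked as escaped.  Beam rays that miss the tissue
  contour escape with full weight.
* **Termination.** Below a weight threshold (default 1e−4) Russian
  roulette keeps the photon with probability 1/m (default m = 10) at
  m-fold weight.  A per-photon event cap (default 1e7) guards against
  pathological loops; capped weight is booked separately and counted.

**Weight accounting.** Every run keeps an exact ledger.  Because roulette
*adds* (m−1)·W to each survivor, the identity that holds per run to
≤ 1e−9 relative (enforced in tests) is

    launched + roulette_gain = absorbed + escaped + roulette_killed,

which reduces to `launched = absorbed + escaped + killed` in expectation.

**Fluence.** The collision estimator: Φ[v] = A[v]·P / (N·μa[v]·V_voxel),
where A is deposited weight, P = irradiance × beam aperture area, N the
photon count, V_voxel the voxel volume.  Voxels of a zero-μa tissue would
make this undefined; the engine rejects such volumes explicitly (no tissue
in the shipped table has μa = 0, and a track-length fallback was left
unimplemented for that reason).

## Fluorescence coupling

The probe (concentration assumed uniform in the cancer) couples to the
excitation field through the fluence only: its εC is *not* added to the
cancer μa during excitation transport, and emitted photons are not
re-absorbed by the probe nor do they re-trigger fluorescence
(single-generation model).  Emission photons launch at uniformly random
positions in the cancer voxel union with isotropic directions.  Initial
weights follow one of two modes:

* **with gradient** — w ∝ QY·εC·Φ_ex(local voxel); total launched power is
  normalized to QY·εC·Σ_v Φ_ex[v]·V_voxel exactly (the finite ensemble is
  rescaled by the ratio of the analytic total to the sampled total — a
  ratio adjustment whose bias is O(1/N) and which makes the power
  accounting an exact identity);
* **without gradient** — every photon inherits Φ_ex at the cancer's centre
  voxel (the legacy uniform-excitation approximation).  The two modes
  coincide exactly when Φ_ex is uniform over the cancer.

Emission transport runs at the band's emission wavelength.  Weights are
physically in watts; the kernel runs on weights normalized to unit mean so
the roulette threshold acts relative to a typical photon, and all scores
are rescaled afterwards.

## Detection

Escaping emission weight is binned on the anterior (x, y) projection at
one voxel pitch; irradiance = binned power / bin area.  The detectability
statistic is the peak bin, compared strictly against 10 nW/cm² (a signal of
exactly 10 nW/cm² is not detectable).  An aperture-integrated total power
is also available (`SurfaceMap.total_power`).  Size/depth/band sweeps
reuse one phantom and one seed per geometry across bands (common random
numbers) so band comparisons are not confounded by geometry noise.

## Synthetic anatomy

The reference anatomy is a cryosection-derived thoracic volume
(500 × 250 × 220 voxels at 0.033 cm) that cannot be redistributed, so the
package generates structural stand-ins: a semi-ellipsoid breast cap
(default half-axes 2.0 × 1.2 × 1.2 cm) on an elliptic-cylinder chest block,
a 2-voxel skin shell derived per slice by the same border rule the
segmenter uses, and a duct tree grown as a depth-biased persistence random
walk with binary branching, rasterized as capsules of 0.05 cm radius
(8 primary ducts, 3 branching levels, branch lengths 0.4–0.9 cm — chosen
to give a duct fraction of a few percent of tissue voxels, within the
1–15 % generator contract).  The default grid (140 × 80 × 112) is a
reduced stand-in deep enough for 3 cm embeddings; the full-size grid is a
parameter away.  The generator is seed-deterministic.

What the phantom does *not* emulate: anatomically validated duct
morphology/statistics, heterogeneity within tissue classes, chest-wall
anatomy, or the real breast contour.  Passing trend tests on the phantom
therefore show that the *method* ranks bands, sizes and depths correctly
under realistic optical contrasts — not that absolute signal levels match
any particular anatomy.

Real slice stacks are supported through the segmentation path: 8-bit
grayscale values > 180 → fat, 80–120 → duct, a 2-pixel border against the
outside region → skin, all other interior values → fat (fat is the bulk
matrix and only three tissue classes are defined).  RGB input is converted
by ITU-R 601 luma.  Erosion for the skin border treats the image frame as
tissue so that tissue running off the crop edge does not grow a spurious
border.

## Numerical choices

* Anisotropy g is not part of the published tissue table; all tissues
  default to g = 0.9 (typical soft tissue, consistent with the large μs
  values) and the TSV column can be overridden.
* Voxel membership is centre-in-sphere with half-open extents
  [i·h, (i+1)·h); crossing positions are snapped to the exact face
  coordinate to avoid floating-point drift.
* RNG: NumPy PCG64 for launch sampling; the compiled kernel uses its own
  seeded generator derived from the run seed.  Runs are bitwise
  reproducible single-threaded for a fixed seed.
* Degenerate inputs: μs = 0 deposits the full weight at the first
  interaction (pure absorber); zero-weight photons terminate without
  roulette; empty cancer voxel sets and unplaceable spheres raise.

## Validation

The test suite checks closed-form limits (Beer–Lambert transmission,
Fresnel normal-incidence reflectance 0.02437 at n = 1.37, E[cos θ] = g for
Henyey–Greenstein), exact ledger closure, grid-refinement invariance, and
agreement of the voxel engine's diffuse reflectance with an independent
single-medium Monte Carlo written separately in the test suite (3σ at 1e5
photons).  Trend checks on the synthetic phantom use 1e5 excitation +
1e5 emission photons — sizes chosen so results are stable while the suite
stays quick — and reproduce: SWIR > NIR > VIS peak signal for a 1 cm
cancer at 1 cm depth; monotone decay with depth and growth with diameter;
an emission centroid above the cancer centre in gradient mode under top
illumination; and zero VIS signal from a 1 mm cancer at 3 cm depth.

## Known limitations

* Single fluorescence generation; no photobleaching, no spectral
  bandshapes, no multi-fluorophore mixtures.
* No time-resolved transport or polarization.
* Escape into internal air pockets (non-convex surfaces) terminates the
  photon rather than re-entering tissue across the pocket.
* The collision fluence estimator requires μa > 0 in every tissue present.
* Absolute detectability depths/sizes depend on the anatomy; with the
  synthetic phantom they are indicative, not clinical predictions.
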