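# Methods

`celldosim` estimates the energy deposited in the organelles of a single
spherical cell by the decays of radioactive gold nanoparticles (¹⁹⁸AuNP)
residing in that cell. This note documents the model, its parameters, the
numerical choices, and what the simplifications do and do not allow one to
conclude.

## Cell world

The cell is a ball of radius 6000 nm centred at the origin. The outermost
10 nm shell `[5990, 6000]` nm is the plasma membrane; the nucleus (radius
3300 nm) sits at the origin; 90 mitochondria (radius 463 nm each) are
placed uniformly at random in the cytosol by rejection sampling. These
dimensions describe a CHO (Chinese hamster ovary) cell, the standard
radiobiology model line; reported mitochondria counts for CHO span roughly
60–200, and 90 is the adopted value. All aqueous compartments have unit
density; their elemental compositions (H/C/N/O/S/P mass fractions) are
stored on the `Material` objects and written to exports, but the transport
uses liquid-water stopping parameters for all of them — the compositions
differ from water by less than 1% in electron density, far below the
transport model error.

Interpreting the tabulated "cytosol r = 6000 nm" as the *outer* cell radius
(with the membrane as the outermost shell) keeps the total radius at
6000 nm and makes the whole-cell mass reproduce the published 32–35 Gy dose
conversion; the alternative reading (membrane outside a 6000 nm cytosol)
does not.

Nanoparticles are spheres of radius 3–5 nm and density 19.32 g/cm³. A
placement is specified by count `n_np`, radius `r_np` and a targeted
fraction `x`: `round(n_np·x)` particles are placed in exact contact with
the target organelle surface (centre distance `R_target + r_np`, direction
uniform on the sphere; for mitochondria targets the host is drawn uniformly
per particle), the remainder uniformly in the cytosol. Tangency does not
count as overlap — surface attachment requires it — and every other pair
contact (organelle–organelle, particle–organelle, particle–particle) is
forbidden and resolved by resampling, up to `max_attempts` (default 10⁴)
rounds. Because everything is a sphere, overlap and containment checks are
closed-form distance comparisons, and ray tracing through the world reduces
to quadratic ray–sphere intersections; a k-d tree over particle centres
keeps point classification and boundary search fast for 10⁴–10⁵ particles.

Boundary convention: points within 10⁻⁹ nm of a surface belong to the inner
(more specific) region, with precedence nanoparticle > mitochondrion >
nucleus > membrane > cytosol > outside.

## Source

¹⁹⁸Au (half-life 2.7 d, isotope mass 198 u) decays β⁻ to stable ¹⁹⁸Hg with
endpoint energies 961 keV (99%) and 285 keV (1%) and gamma lines at 412 keV
(96%), 676 keV and 1088 keV. The two weak lines are only bounded ("<1%") in
the branch table the constants follow; they default to 0.01 each and are
configurable. The specific activity ln2·N_A/(T·M) evaluates to
9.04·10¹⁵ Bq/g.

Each simulated decay carries exactly one beta and each gamma line
independently with its probability; directions are isotropic. Beta energies
follow the allowed shape `p·W·(Q−E)²` multiplied by the relativistic
point-Coulomb Fermi function (daughter Z = 80, nuclear radius 1.2·A^⅓ fm),
sampled by rejection. The Coulomb factor matters here: without it the
961 keV branch would average ~389 keV instead of the tabulated ~315 keV,
and every absolute deposit would be ~20% low. A bare-shape mode
(`coulomb=False`) and a monoenergetic endpoint mode are available for
debugging and for isolating spectrum effects.

Decay positions: *discrete-geometric* mode draws a host nanoparticle
(volume-weighted; uniform when all radii are equal) and a uniform point
inside it; *continuous* mode — gold represented as a homogeneous mass
fraction in the cytosol medium — draws the position uniformly over the
cytosol. The whole-cell gold mass percentage `m_Au` is defined against the
full 6000 nm sphere at unit density; this is the only convention that
reproduces all the published percentages (e.g. 10⁴ × 5 nm ↔ 1.1·10⁻² %).

## Transport

The transport is a deliberately simplified condensed-history surrogate
aimed at organelle-scale (µm) scoring:

* **Stopping power.** Relativistic Bethe electron collision stopping power
  from each material's electron density and mean excitation energy
  (water-equivalent media I = 78 eV, gold I = 790 eV), no density or shell
  corrections; below 10 keV a power law matched in value and log-slope at
  10 keV. Against standard tabulations this is accurate to a few percent
  over 1 keV–2 MeV. CSDA ranges are tabulated by quadrature on a log grid
  (800 points, 0.1–2000 keV) and inverted for per-step energy loss, so each
  step's deposit is the exact range-table integral rather than S·Δx.
* **Stepping.** Step length = min(5% of the remaining CSDA range, 1000 nm,
  distance to the next region boundary), so every step lies in one region
  and is credited to it. Halving the step parameters changes the cell
  deposit by <0.5% (converged).
* **Multiple scattering.** After each step the direction is deflected by
  two Gaussian projected angles of Highland width. The logarithmic Highland
  term is evaluated at the electron's remaining CSDA range, not the
  micro-step: the formula is calibrated for the full traversed thickness,
  and applying the bracket per step would underestimate the accumulated
  variance by tens of percent.
* **Termination.** Tracks end at the energy cutoff (default 1 keV; the
  residual, whose range is tens of nm, is deposited locally). The cell is
  embedded in unbounded water: electrons crossing the cell boundary keep
  being transported with coarser (20% of range) steps, their deposits
  counting as escaped energy, until their remaining range cannot bridge the
  straight-line gap back to the cell surface. Setting
  `surrounding_medium=False` terminates at the boundary instead (vacuum
  outside); the difference is ~1% of the cell deposit. Deposits plus
  escaped energy equal the emitted energy exactly, per track.
* **Photons.** Either escape outright or undergo at most one interaction:
  exponential free path with the water attenuation coefficient
  (three-point embedded table at the line energies, log-interpolated),
  local deposit E·μ_en/μ. Over a 6 µm cell the interaction probability is
  ~10⁻⁴–10⁻⁵, so gammas contribute negligibly; the term is kept for
  completeness.

Not modelled: delta-ray production, bremsstrahlung, Auger cascades, atomic
de-excitation, internal conversion, track structure, and the gold
backscatter physics responsible for the few-percent continuous-vs-discrete
difference reported for full condensed-history simulations. Consequently
absolute eV/decay values are reproduced only approximately (the continuous
whole-cell deposit comes out ~14% below the reference 1810 eV/decay, at
the edge of the intended ±15% surrogate envelope), while *ratios* between
conditions — the quantities of scientific interest here — are much less
sensitive to the missing physics.

## Scoring and statistics

Per-batch tallies record eV per region role plus per-object breakdowns for
mitochondria and nanoparticles, and escaped energy. Reporting follows the
common tabulation: "cell" = membrane + cytosol + nucleus + mitochondria +
nanoparticles; the cytosol is reported both including the nanoparticle
deposit (table convention) and excluding it (figure convention);
mitochondria and nanoparticles are sums over objects. Dose in Gy uses the
whole 6 µm sphere mass at unit density (the ≤0.04% admixed gold mass is
neglected).

Runs are repeated over `n_batches` batches (production default 10 × 10⁵
decays, as in the reference protocol); means and sample standard deviations
(n−1) are taken across batches. Batch b of every condition uses child b of
`SeedSequence(base_seed)`, derived statelessly, with separate sub-streams
for geometry construction and decay sampling. Sharing batch seeds across
the conditions of a sweep gives common random numbers: the decay-spectrum
noise, which dominates the per-batch variance, cancels out of enhancement
ratios and linearity fits. Expectations are unaffected.

The relative enhancement is E_rel(x) = 100%·E(x)/E(0), with E(0) the
all-particles-random baseline. Because decays are independent, E(x) =
x·E(1) + (1−x)·E(0) exactly in expectation; the simulated sweep is checked
against this line, and ordinary least squares gives slope, intercept and
R² (R² defined as 1 when the total sum of squares vanishes; constant x is
an error).

## Problem sizes

The test suite and the acceptance script scale the protocol down to desk
size: the targeting sweep runs 8 batches × 4000 decays per grid point in
the tests (6000 in the acceptance script) and the continuous checks
10 × 4000. At these sizes
the Monte-Carlo standard errors are ≈1% on E_rel, ≈12 eV on the absolute
continuous deposit, and ≈0.003 on R² — each several times smaller than the
tolerance it is compared against. The flatness check across gold mass
percentages is paired (shared seeds), so it resolves the <2% bound with
only 3000 decays per condition.

## What the tests do and do not show

The synthetic experiments exercise exactly the study conditions (geometry,
nuclide data, placements, decay counts scaled down); they validate the
geometric sampling machinery against closed-form volume ratios and
brute-force containment, transport against its own conservation laws,
convergence, and straight-line closed forms, and the end-to-end pipeline
against the published scalar anchors (mass percentages, specific activity,
dose conversion, beta ranges, E_rel and its linearity). They do not
establish nanometre-scale accuracy around individual nanoparticles, the
per-organelle absolute deposits at the precision of a full condensed-
history code, or anything about biological response; and a real cell is not
a sphere with monodisperse spherical organelles.
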