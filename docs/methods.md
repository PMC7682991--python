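# Methods

This note documents the models, conventions, defaults and limitations of
`abeta_ims`.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Masses, m/z and isotope patterns (`chem`)

A peptide's elemental composition is the sum of its residue formulas plus
one water; an n-mer (non-covalent assembly of n chains) is n times the
monomer composition.  m/z arithmetic uses

    m/z(n, z) = (n·M + z·m_H⁺) / z,       m_H⁺ = 1.00728 Da,

with M either the average mass (IUPAC 2021 standard atomic weights,
conventional values; bundled in `elements.py`) or the monoisotopic mass.
"Nominal m/z" is the floor of the computed value, matching integer peak
labels.  For the canonical Aβ42 sequence (C₂₀₃H₃₁₁N₅₅O₆₀S) the average
mass is ≈ 4514.1 Da and the monoisotopic mass ≈ 4511.27 Da; species with
equal n/z are exactly m/z-degenerate.

Isotopologue envelopes are computed by element-wise convolution of the
isotope abundance polynomials (exponentiation by squaring, truncated on an
internal grid sized from the distribution's mean and variance).
**Convention:** isotopologues are aggregated by nominal mass shift and
reported on the exact neutron-spaced grid mono + k·1.0033548 Da.  True
abundance-weighted fine-structure centroids deviate from this grid by a few
×10⁻⁴ Da (the ¹⁵N/²H/¹⁷O channels are lighter than the ¹³C channel); at
TWIMS resolving powers that deviation is far below peak widths, and the
grid convention makes the charge-reading rule (spacing = 1.0034/z Th)
exact.  Truncation keeps the most abundant peaks to cumulative 0.9999
(optionally capped at `n_peaks`), then renormalizes the surviving
contiguous range to sum 1.

## Synthetic data (`synth`)

The generators emulate the *statistical structure* the analysis assumes,
not instrument physics (no traveling-wave dynamics, ESI charging, or LILBID
plume modeling).  All generators are bit-deterministic under their seed,
which is recorded in output metadata.

* **Driftscope frames.** Each conformer contributes a separable 2D peak:
  exact isotopologue envelope along m/z (Gaussians at resolving power
  m/FWHM, default 20,000) × a Gaussian arrival-time peak.  Both factors are
  grid-sum-normalized, so the noiseless drift-marginal reproduces the sum
  of isotope envelopes identically — the invariant the detection tests
  rely on.  Noise: multiplicative Gaussian (fractional sigma) plus an
  additive positive baseline, clipped at zero.  Default conformer
  centroids for the 5+ dimer mirror the observed compact pair: MB 8 ms,
  DB 11 ms, unfolding product ~13 ms.
* **CIU/CID series.** Two-state logistic transitions vs lab-frame energy
  E = z·V_trap: the unfolded share rises as cap·logistic((E−E50_CIU)/w),
  total survival falls as logistic(−(E−E50_CID)/w).  Logistic (not erf)
  shape: only 50% points are meaningful anchors, widths default 10 eV.
  Noise acts on the three channel intensities (folded/unfolded/
  dissociated), which are then renormalized — fractions therefore stay on
  the simplex, as real relative intensities do.  The default instrument
  ramp is 5–50 V in 5 V steps.
* **Aggregation time courses.** A deterministic mass-action monomer-
  addition chain: O₁+O₁→O₂ at a nucleation-limited rate (elongation rate
  2×10⁻³ conc⁻¹min⁻¹, nucleation factor 0.05, pool 50 µM-equivalent),
  Oₙ+O₁→Oₙ₊₁ thereafter, integrated with LSODA (rtol 1e-9, atol 1e-12);
  total mass Σ n·Iₙ is conserved to the integrator tolerance.  The
  dimerization flux is split between an MB and a DB channel (weight 0.5);
  an inhibitor suppresses the DB channel and caps the reachable order
  (default cap 6).  These defaults reproduce the qualitative endpoint
  pattern of the experiment (free runs populate the dodecamer within
  200 min; inhibited runs stall at the hexamer).  This chain is synthetic
  scaffolding for testing the statistics — it is *not* a mechanistic claim
  about Aβ42, whose real kinetics involve nucleation, fragmentation and
  secondary processes the chain omits.  Four replicates per timepoint by
  default, matching the four-spectrum averaging protocol.
* **Toy fibrils.** Rigid S-shaped dummy monomers (24 carbon atoms on two
  arcs) stacked at 4.8 Å per layer; `DB` adds a C2-rotated partner
  protofilament 24 Å away.  Valid PDB via gemmi; chain→layer maps are
  emitted alongside.

Passing tests on these fixtures demonstrates the *analysis logic* —
charge/order disambiguation, calibration algebra, model selection,
midpoint recovery — under controlled noise.  They do not demonstrate
robustness to real-data pathologies: chemical noise, peak tailing,
unresolved conformer families, detector saturation, LILBID charge-state
overlap.

## Feature detection and assignment (`assign`)

m/z clusters are contiguous above-threshold runs of the drift-summed
spectrum (threshold: median + min_snr·1.4826·MAD, min_snr default 3),
merged across gaps < 1.2 Th so resolved isotopologues stay in one cluster,
padded ±1.5 Th so envelope tails aren't clipped.  Per cluster, drift peaks
are found with scipy's local-maximum detection (min separation default
0.5 ms); each drift peak's m/z profile is extracted from its own drift
window, so m/z-degenerate species keep separate isotope profiles.  Drift
centroids are refined by parabolic interpolation.

Isotopologue spacing is estimated from the autocorrelation of the m/z
profile, scored at the candidate lags 1.0034/z (z = 1..z_max) and refined
parabolically; fewer than three resolved isotope peaks → "unresolved".
The spacing uncertainty is a curvature-based heuristic bounded by half a
grid step.  **Charge before order:** z = round(1.0034/spacing), then n is
the integer minimizing |m/z_obs − m/z(n, z)| within `mz_tolerance`
(default 0.1 Th).  Ties at the same z resolve to the smaller n with a
warning record.  Unresolved features carry the full ambiguous (n, z)
candidate set — degeneracy is reported, never silently collapsed.

Conformer grouping orders each ion's features by drift: features within
`drift_excess` (default 1.5×) of the most compact drift are "structured"
and labeled MB then DB; beyond it, extended-MB / extended-DB.  MB-more-
compact is an interpretive convention (the lower-CCS family is the less
ordered single-base form).  A structured-MB-plus-extended pattern with no
DB is flagged `db-missing` — the inhibited/mutant signature.

## CCS calibration (`calibrate`)

The TWIMS power-law protocol: t′ = t_D − c·√(m/z)/1000 (EDC delay
coefficient c default 1.41, configurable, logged), Ω′ = Ω/(z·√(1/m_ion +
1/m_gas)), OLS of ln Ω′ on ln t′, application by inverting the reduction.
Drift gas N₂ (28.0134 Da).  Literature calibrant CCS values are
user-supplied inputs, never bundled as truth; `synthetic_calibrants`
builds law-exact tables (optionally noisy) for round-trip validation.
Fits with R² < 0.98 are refused unless explicitly overridden.
Uncertainty: first-order propagation of drift-centroid sigma plus the
log-log fit covariance.

## Growth models (`growth`)

Isotropic growth Ω(n) = Ω_ref·(n/n_ref)^(2/3) (volume-to-area scaling;
exponent fixed, not fitted) anchored at the dimer (n_ref = 2,
configurable); linear growth by weighted least squares (weights 1/σ²).
Charge-state averaging: one Ω per (n, family) as the mean over charge
states with their standard deviation as σ.

**Crossover detection.** n\* is the largest order whose whole prefix stays
within `tolerance_sigma` *effective* standard deviations of the anchored
isotropic curve, where the effective sigma propagates the anchor's own
uncertainty (σ_eff² = σ_m² + ((m/n_ref)^(2/3)·σ_ref)²); all orders above
n\* must fit the linear model better, else "no crossover".  The default
tolerance is 2.5: with the anchor term included, a 2.0 cutoff would break
the prefix on ~5% of in-regime points from noise alone, making the
detector unreliable at realistic noise.  The canonical two-regime fixture
(`two_regime_ccs_law`: dimer 700 Å², isotropic to the tetramer, then
400 Å²/monomer linear, continuous at n = 4) departs from the isotropic
curve by many σ at n = 5 — an unambiguous regime change, as a clear
experimental dataset shows; with 2% noise the detector recovers n\* = 4 in
≈98% of seeds.

**MB/DB comparison.** Both series are fit over their common order range;
Δslope and Δintercept carry normal-approximation CIs from the fit
covariances.  The two-base signature is: slope CI contains 0 while the
intercept CI excludes 0.

## CIU/CID analysis (`ciu`)

Lab-frame energy is E = z·V_trap (single-collision convention).  This
choice is deliberate and documented: it maps the 5–50 V ramp at z = 5 onto
25–250 eV, placing the dimer's 50% unfolding at 85 eV = 17 V; multi-
collision or center-of-mass corrections exist but are not applied.

CIU fits the unfolded share of the *surviving* population
(extended/surviving — the per-energy fingerprint normalization; without
it, dissociation masquerades as refolding and the fitted amplitude is
meaningless).  Energies where survival < 5% are excluded.  The model is a
capped logistic; E50 is the midpoint of the transition's own amplitude,
and the energy at which the *absolute* 50% level is crossed is reported
alongside — it is `None` for cap-limited transitions (cap < 0.5), the
behavior of a ligand-stabilized dimer that dissociates after unfolding at
most ~15%.  A curve whose unfolding channel never exceeds 2% is flagged
"absent" (the DB dimer dissociates without prior unfolding); an all-zero
survival signal is an error.  CID fits total survival as a falling
logistic.  E50 uncertainties come from a seeded nonparametric bootstrap
over energy points (200 resamples by default).

The energy-gap analysis fits two constant gaps with one breakpoint to the
first differences of E50 vs order, by exhaustive search over interior
splits (series are short); an input whose best split does not improve on a
single constant gap is flagged degenerate.

Free-vs-bound comparison classes: "CID-stabilized" (bound dissociation
midpoint higher by more than the 5 eV threshold), "CIU-suppressed
(cap-limited)" (bound transition cap-limited while free is not),
"unchanged" otherwise.

## Kinetics statistics (`kinetics`)

Replicate spectra are averaged in fixed bins (default 10 min; 200 min of
acquisition → 20 bins); binning is idempotent on aligned bins; empty bins
drop with a warning.  Spectra normalize to total intensity.  The
monomer-over-oligomer statistic is

    M/O = I₁ / Σₙ n·Iₙ .

The denominator sum includes n = 1 by default: the printed form of the
ratio leaves the sum unscoped, and including the monomer makes M/O the
monomer's share of total peptide mass, bounded by 1 and equal to 1 iff
only monomer is present.  The n ≥ 2 alternative is exposed via
`include_monomer=False`.  Maximum order present uses a relative threshold
(default 0.01 of total intensity).  Condition comparisons bootstrap over
replicates (200 resamples, seeded); single-replicate tables flag their CIs
unavailable.  Oligomer order per peak is assumed pre-assigned
(mass-resolved); anion charge deconvolution is out of scope.

## Structure-based CCS (`structure`)

Fibril structures are read via gemmi (heteroatoms excluded by default).
Cropping: MB takes n consecutive layers of one protofilament; DB takes
consecutive paired layers (odd n drops one partner, flagged).  The crops
are used as-is — gas-phase relaxation (MD) and per-charge-state
protonation ensembles are not reimplemented; externally relaxed
coordinates can be read back in.

Theoretical CCS uses the projection approximation: the orientation-
averaged area of the union of disks of radius r_vdW + r_gas (Bondi radii;
gas radius default 1.5 Å for an N₂-like gas), estimated by Monte Carlo —
quaternion-uniform orientations (default 300) × hit-or-miss area sampling
in the projected bounding box (default 5000 rays).  The reported standard
error is the orientation-to-orientation spread over √N.  PA was chosen
because it is exactly verifiable (a single atom projects to π(r+r_gas)²)
and suffices for slope/intercept comparisons; it systematically
underestimates CCS relative to trajectory methods and ignores long-range
ion–gas interactions.

One PA-specific caveat the toy fixtures expose: for two *coplanar*
protofilaments the projections overlap near the inter-protofilament axis,
so the DB per-monomer slope comes out 10–20% below twice-the-MB
expectation even at generous separations.  The tests assert slope
agreement at that level and the clearly larger DB intercept; the
synthetic CCS-series fixtures (exact lines plus noise) are used where an
exact equal-slope construction is needed.

## Replica workflow and problem sizes

`pipeline.run_replica` chains assignment → calibration → growth → CIU/CID
→ kinetics → structure CCS on seeded fixtures and writes `report.json`
plus CSV tables (features, CCS series, E50 table, fingerprint matrix, M/O
curves); identical seeds give byte-identical reports.  Default sizes are
chosen for desk-scale reproducibility — two narrow driftscope windows
(~10 Th at 0.008–0.01 Th steps), eight oligomer orders × two charge
states for growth, six CIU orders on the 10-point ramp, 80-point kinetics
time courses with 4 replicates, and 120 orientations × 2000 rays per PA
evaluation — and complete in a few seconds on one CPU.

## Known limitations

* No vendor raw-file ingestion; frames arrive as delimited text.
* No Bayesian deconvolution of unresolved charge-state mixtures; an
  unresolved feature reports its candidate set and stops there.
* The isotope model has no fine structure or adducts other than protons;
  no post-translational modifications.
* The kinetics chain fits no rate constants to real data and omits
  secondary nucleation/fragmentation.
* PA-only theoretical CCS; no trajectory-method or EHSS cross-sections,
  no MD relaxation, no secondary-structure analysis.
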