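# Methods

This note records the models implemented in `hgthermo`, their
assumptions, the defaults that matter, and what the synthetic-data
scenarios do and do not establish.

## Thermodynamic model

A binding event at temperature T is described by (ΔG, ΔH, −TΔS, K_a),
linked by ΔG = ΔH + (−TΔS) and K_a = exp(−ΔG/RT) with
R = 1.987204×10⁻³ kcal/(mol·K). `BindingThermo` enforces both
identities at construction to 10⁻⁹ kcal/mol, so inconsistent records
cannot propagate. Energies are stored in kcal/mol and heat capacities
reported in cal/(mol·K), the mixed convention of the calorimetry
literature (slopes are multiplied by 1000 at the reporting boundary,
nowhere else).

ΔC_p,b is defined as the slope of a **linear** ΔH(T) model fitted by
ordinary least squares; a temperature-independent ΔC_p is an explicit
modelling assumption, justified for near-rigid hosts and guests whose
conformational distributions barely shift over a 50 K window.
Quadratic-in-T enthalpy models and van't Hoff estimation of ΔH from
K_a(T) are deliberately out of scope. Fits are unweighted unless
per-point standard deviations are supplied, in which case
inverse-variance weights are used. When the response has zero
variance (constant ΔH), r² is defined as 1: the zero-slope line fits
exactly. Extrapolation integrates dH/dT = C_p and dS/dT = C_p/T
around the reference state, so ΔG(T) follows Gibbs–Helmholtz rather
than a naive linear extension.

Compensation is quantified as the OLS slope of TΔS on ΔH across
complexes at fixed T. Agreement between calculated and experimental
vectors is reported as RMSE, mean signed error, and r² (squared
Pearson correlation of the scatter — the convention under which a
systematic offset degrades RMSE but not r²); 95% confidence intervals
come from paired case-resampling bootstrap (default 10,000 replicates,
percentile intervals, explicit seed).

## ITC model

The cell is treated with the standard perfusion (overfill) convention:
an injection of volume dV displaces an equal volume, diluting cell
contents by (1 − dV/V0) while the incoming titrant mixes instantly.
Bound concentration comes from the exact quadratic root of 1:1 mass
action with the stoichiometry n scaling the cell-species
concentration; the incremental heat of injection i is
dH·V0·(b_i − b_{i−1}(1 − dV_i/V0)) + q_dil. Dilution heat is a
constant per-injection offset fitted alongside (K_a, ΔH, n) rather
than a separate blank titration. The first injection is discarded
from the residuals by default (syringe-tip diffusion), though its
volume still enters the concentration bookkeeping. Fitting is
Levenberg–Marquardt on (ln K_a, ΔH, n, q_dil), with the log
parameterization keeping K_a positive; initial values come from the
isotherm shape (plateau → ΔH, inflection molar ratio → n). A c-value
(n·K_a·[cell]) outside [1, 1000] triggers a warning, and below 0.1 the
fitted K_a is flagged unreliable — standard Wiseman conditioning.

Peak integration subtracts a baseline interpolated linearly between
quiescent segments (the tail of each inter-injection gap, median
power); if a segment has no samples the global median is used with a
warning. Integration is trapezoidal over a fixed window after each
injection; overlapping windows are an error, not a silent merge.

## Computational calorimetry

The binding enthalpy is the difference of mean potential energies
between end states. The pressure–volume term is omitted entirely (for
a liquid at 1 atm it is negligible against kcal/mol enthalpies).
Water-count imbalances between ensembles are balanced by adding
N_excess times the mean per-water energy of a neat-water ensemble
("per-water bulk correction", assigned to the W–W channel); a strict
mode demands balanced counts instead. The exact bookkeeping used by
any particular simulation campaign is rarely published; the bulk
correction is this package's declared choice and is exercised by the
generators, which deliberately unbalance the counts.

Because the force field is pairwise additive, two exact partitions
hold and are asserted to 10⁻⁹: ΔH = ΔH_H–G + ΔH_desolv (solute-only
terms, including intra-solute reorganization, versus every
water-involving term) and ΔH = ΔH_LJ + ΔH_elec + ΔH_valence. A
force-field term absent from *all* ensembles is reported absent
(`None`), never silently zero. Uncertainties use block averaging
(default block 1% of the series, minimum 10 blocks; remainder frames
dropped), which stays calibrated under autocorrelation shorter than
the block.

Per-channel ΔC_p values are OLS slopes of each channel's ΔH(T); OLS
linearity makes channel slopes sum exactly to the total slope, which
is also asserted.

## Hydrogen bonds

A bond requires donor–acceptor (heavy atom) distance **strictly**
below 3.0 Å and D–H–A angle **strictly** above 150°; boundary values
are not bonds (documented tie-break). Chemistry comes from an
annotation sidecar, not perception: donors are O/N with attached H,
acceptors O/N; water is 2 donors + 1 acceptor, carbonyl O acceptor
only, hydroxyl O both. Intra-molecular pairs are excluded by default
(the four reported categories are all intermolecular); callers with
topology can supply a bond-separation matrix to re-admit intra-solute
pairs ≥3 covalent bonds apart. Bifurcated bonds are all counted if
each passes the cuts. Detection uses a KD-tree over acceptors with a
strict re-check at the cutoff (tree queries are inclusive); minimum
image is applied when an orthorhombic box is present. A brute-force
O(N²) detector with identical cuts serves as the test oracle.

Change-on-binding tables mirror the four-category layout: Δ per
category is bound − (free host + free guest), with waters missing from
the bound ensemble credited at the bulk per-water W–W rate. Cavity
waters are counted inside a cylinder about the host axis (default
radius 4 Å, half-height = half the portal separation — a declared
geometric convention, as such boundaries always are).

## GIST maps

Each water is assigned wholly to the voxel containing its oxygen (0.5
Å default spacing; no kernel smoothing — the most conservative
discretization), carrying its solute–water energy and its half-share
of water–water pair energies (the standard GIST split). Waters
outside the grid pool into a far-field bucket so voxel sums plus
far-field equal ensemble totals exactly — asserted to 10⁻⁹.
Normalization divides occupancy by frames × voxel volume × ρ₀
(ρ₀ = 0.0334 Å⁻³) and re-references E_ww by the bulk per-water value.

The heat-capacity map is an **enthalpic finite difference**: per
voxel, (ΔE_solv(T₂) − ΔE_solv(T₁))/(T₂ − T₁) over bound-minus-free
difference maps, by default across the extreme temperatures (278/328
K). Orientational/translational entropy estimators are out of scope;
this is consistent with treating the solvent term as
enthalpy-dominated, which the calorimetry decomposition supports.
Region integrals sum voxel values whose centers fall inside the
region; cavity + portal + remainder = total by construction. The
portal region defaults to two slabs 3 Å thick beyond each portal
plane, radius = cavity radius + 2 Å. Maps export as OpenDX text
(writer implemented here; the format is trivial and output-only).

## Binding geometry

The host axis is the unit vector between portal-ring centroids
(default) or the least-variance direction of the ring-atom coordinate
covariance (the ring normal). The guest axis is tail→head over atom
selections — hydroxyl O relative to the cage centroid for mono-ols,
O→O for diols. The tilt is arccos|u_h·u_g| folded into [0°, 90°] by
default (axis signs are arbitrary); the unfolded angle feeds flip
detection. Flips use hysteresis at 60°/120°: the guest must cross
well beyond the midpoint to register, so fluctuations of the ~10°
scale observed for these complexes can never chatter. Dwell times are
reported between consecutive flips.

## Synthetic scenarios: what they emulate, and what they do not

`ScenarioSpec` defaults define the reference study conditions used by
the test suite and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| temperatures | 278…328 K, 10 K steps | the measured range |
| K_a(298) | 10⁷ M⁻¹ | mid-range CBn affinity (c = 500 in the cell) |
| ΔH(298) | −12 kcal/mol | typical of the measured complexes |
| ΔC_p | −90 cal/(mol·K) | mid-range of the −144…−55 measured span |
| n | 1.0 | all systems are 1:1 |
| ITC noise | 0.5% of the largest heat | good modern instrument |
| cell/syringe | 200 µL, 50 µM / 500 µM, 25×2 µL | standard small-cell titration |
| compensation fraction | 0.70 | −TΔS(T) cancels 70% of ΔH(T) changes |
| ΔH_H–G | −19 kcal/mol, T-flat | rigid-solute picture |
| cavity waters | 6 | matches the adamantanol-scale expulsion count |

The energy-ensemble generator builds stationary Gaussian (optionally
AR(1)) component series whose mean arithmetic reproduces the target
decomposition exactly, with the entire temperature dependence placed
in the complex's water–water channel — the rigid-solute limit. The
toy complex realizes *exact* hydrogen-bond target counts by explicit
construction (bulk waters are mutually separated beyond the cutoff so
no accidental bonds arise), and the GIST generator puts the
temperature-dependent per-water energy on the cavity waters with slope
chosen so that expelling them reproduces the desolvation ΔC_p — which
is what makes the cross-module consistency check (GIST integral =
calorimetry desolvation channel) a non-trivial closed loop rather than
a tautology: the two routes consume different data (voxelized
per-water energies vs whole-ensemble component series with independent
noise).

What passing these tests shows: the estimators are unbiased and
internally consistent on data whose generating process satisfies the
model assumptions exactly. What they do not show: robustness to real
force-field energetics, baseline artifacts in real thermograms,
flexible solutes (where ΔH_H–G acquires temperature dependence), or
finite-size/cutoff corrections in real simulation campaigns — all of
which require real data.

Problem sizes were chosen for precision at interactive cost: 2000
frames per energy ensemble, 40 frames per GIST accumulation on a 24³
grid, 100 titration replicates for error medians.

## Numerical choices and degenerate inputs

Strict inequalities at both hydrogen-bond cutoffs; zero-variance
regressors raise rather than return NaN; the binding quadratic guards
its discriminant (negative values are impossible for valid inputs and
indicate corrupted concentrations); empty voxels contribute g = 0 and
zero energy; degenerate axis frames are excluded from tilt series and
reported, not silently dropped. All random draws flow through
`numpy.random.default_rng(seed)`; identical (spec, seed) pairs give
identical outputs.

## Interface choices

The package is consumed from Python: the module functions plus the
`examples/` scripts are the interface, and no shell entry point is
shipped — the analyses operate on in-memory arrays and DataFrames, and
a CLI wrapper would add a serialization layer without adding
capability. Tabular inputs are plain CSV with a header row (energy
components as `<group_pair>:<ff_term>` columns); maps export to
OpenDX; everything else is JSON.

## Known limitations

Only 1:1 binding (no competitive or multi-site isotherms); no Origin
file parsing; no MD engine or force-field evaluation (energies arrive
precomputed); the hydrogen-bond affinity regression on the printed
(rounded) tables gives −5.0 kcal/mol per bond and r² = 0.60 (0.84
excluding the CB7 adamantanol outlier) — slightly different from
values derivable from unrounded per-system data, as rounding at one
decimal place propagates visibly through a six-point regression.
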