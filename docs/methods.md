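# Methods

This note records the models implemented in `forcespec`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical decisions a maintainer should know about. Units are fixed
package-wide: lengths in nm, forces in pN, time in s, rates in 1/s,
energies in pN·nm.

## Polymer elasticity

### QM-FRC for polypeptide

Unfolded protein is modelled as a freely rotating chain: bonds of length
*b* = 0.11 nm connected at a fixed angle *γ* = 41°, the standard
parametrization for polypeptide backbones. The chain enters through its
effective persistence length

    p = b · cos(γ/2) / |ln cos γ|  ≈ 0.366 nm,

and the fractional extension is evaluated in the two stretching regimes
relevant to the analysis:

    x/L = 1 − (4 F p / kBT)^(−1/2)    for F b/kBT <  p/b   (WLC-like)
    x/L = 1 − kBT / (2 F b)           for F b/kBT ≥  p/b   (discrete chain)

The branches are continuous at the boundary (≈124 pN for the default
parameters), where both equal 1 − b/(2p). The discrete-chain correction is
kBT/(2Fb) rather than the freely jointed kBT/(Fb) because the bond-angle
constraint leaves only one effective transverse fluctuation per bond. The
model is not meaningful below F = kBT/(4p) ≈ 2.8 pN (the first branch
crosses zero); forces at or below that limit raise a domain error, and
forces below a configurable validity floor (default 10 pN) are computed
but flagged with a `LowForceWarning`. The entropic low-force regime is
deliberately not modelled: every consumer of the ratio works above the
transform threshold.

Backbone elasticity at high force is included as a force-dependent contour
length, L(F) = L0 · (1 + c1·F + c2·F²). The default coefficients
(c1 = 3×10⁻⁵ pN⁻¹, c2 = 3×10⁻⁸ pN⁻²) give ≈0.5 % elongation at 150 pN and
≈3 % at 600 pN, the order indicated by ab initio calculations of peptide
backbone stretching. The exact published coefficient set was not available
when this package was written, so the values are a documented placeholder
with the correct magnitude and curvature; they are configurable, and
disabling the correction (`qm_correction=None`) reproduces the uncorrected
FRC identically. Because the simulator and the transform share the same
polymer model, none of the recovery results depend on the particular
coefficient values.

The contour-length transform inverts the extension model per sample:
L0 = x / (stretch_factor(F) · x/L(F)). Samples at or below the force
threshold are rejected (returned as NaN, counted, never raised), since the
noise-dominated low-force region carries no barrier-position information.

### WLC for PEG linkers

The 5 kDa PEG linkers on either side of the complex are worm-like chains
via the Marko–Siggia interpolation formula with persistence length
0.38 nm and 32 nm contour per linker (64 nm total by default). PEG's
force-induced conformational transition (helical–planar lengthening above
a few hundred pN) is ignored — a known fidelity limit of the synthetic
data, not of the analysis. Protein stretches always use the QM-FRC; the
WLC is never fitted.

### Increment bookkeeping

A domain of n residues with folded N–C length d contributes
ΔLc = n·0.365 − d nm of contour when it unfolds. The default template
table reproduces the hallmark increments of the Xyn-XMod-Doc : Coh-CBM
assay — Xyn ≈ 89 nm, CBM ≈ 56 nm, XMod ≈ 34 nm — from nominal residue
counts; the exact construct bookkeeping (exact residue counts and folded
lengths) is a placeholder at the printed precision of those increments,
and the XMod entry in particular is a plausible value for a ~100-residue
β-sandwich rather than a published number. All entries are configurable.

## Rupture kinetics

Bell kinetics k(F) = k_off·exp(F·Δx/kBT) throughout, evaluated in log
space so extreme forces cannot overflow silently. At constant loading rate
r the rupture-force density, survival function and most probable force
have the usual closed forms; the sampler inverts the analytic survival
function (exact, no rejection step). kBT defaults to 4.114 pN·nm
(T ≈ 298 K; the temperature of the experiment is not stated more
precisely, and kBT is configurable).

The dynamic-force-spectrum fit is linear least squares in (ln r, F*)
space: slope m = kBT/Δx, intercept c with
k_off = (Δx/kBT)·exp(−c/m). Standard errors come from the linear-fit
covariance by the delta method. Per-point weighting by event counts is
available but off by default (the original analysis does not state any
weighting). Loading-rate histograms are fitted in log space by default
(configurable): realized loading rates are approximately log-normally
distributed across a dataset.

**k_off is an order-of-magnitude quantity.** Because it enters the
closed form through a logarithm, a modest error in Δx or a few-pN bias in
the modal forces moves k_off by integer factors. Synthetic recovery
studies in the test suite recover Δx to a few per cent and k_off within a
factor of ~2–5 at 500 events per speed; consumers should treat recovered
off-rates accordingly.

Gaussian modal fits use Freedman–Diaconis binning by default (bin widths
are not stated in the source analysis) and a bounded least-squares
Gaussian; degenerate spread and non-convergence raise with diagnostics.

## The KMC pulling simulator

The mechanical circuit is a Hookean cantilever (default 50 pN/nm, a
typical value for the soft levers used in such experiments; not a
published number) in series with the PEG linkers and the polyprotein. At
piezo separation z = v·t the force solves

    z = F/k_c + x_peg(F) + L_unfolded · x/L(F) · stretch(F),

evaluated by interpolating a precomputed monotone z(F) grid (0–2500 pN,
sub-pN spacing); folded domains are treated as rigid (their folded lengths
are constant offsets absorbed into the baseline). Event times for every
Bell channel (each folded domain, plus complex rupture) are drawn by
inverting the cumulative hazard accumulated along the discrete force
schedule — exact for rates piecewise-constant over one internal step
(default 10 µs), so no per-step event probability needs to be bounded.
Output is decimated to the sampling rate (default 25 kHz) with the exact
event samples always retained, so logged event forces equal the curve
forces at the event indices. Gaussian force noise (default 5 pN, typical
AFM force noise) is added to the reported force only; the ground-truth
log keeps noise-free forces and instantaneous loading rates computed from
the compliance of the circuit, because the effective loading rate at a
given pulling speed depends on the full compliance chain rather than
being proportional to speed.

The default construct mirrors pulling configuration I: three xylanase
sub-domains (30 + 30 + 29 nm — the three-peaked fingerprint), CBM
(56 nm), XMod (34 nm), and the final Doc:Coh rupture. Fingerprint-domain
Bell parameters are not published; the defaults (Xyn Δx = 0.45 nm,
k_off = 10⁻³ s⁻¹; CBM Δx = 0.40 nm, k_off = 5×10⁻⁴ s⁻¹) place the
unfolding forces where the experiment reports them (~100–150 pN).

**Bond-history branching is explicit, not emergent.** The published Bell
parameters for XMod unfolding and for intact rupture do not reproduce the
observed ~35–40 % XMod-first fraction under naive rate competition (the
XMod unfolding force at these loading rates sits ~100 pN below the intact
rupture force, which would make XMod-first dominate). A trace therefore
draws its pathway up front with `shield_branch_probability` (default
0.375): on the shielded path the complex cannot rupture until XMod has
unfolded, after which the shielded kinetics govern; on the intact path
XMod stays folded. The emergent-competition mode is available behind the
`emergent_competition` flag for sensitivity studies. Refolding is disabled
within a trace (events are rare at these speeds); the configuration-II
behaviour in which the xylanase fingerprint is lost after the first few
traces of a series is a dataset-level flag (`xyn_single_use`).

An optional fraction of "junk" traces (short random tethers, weak random
events, no fingerprint) emulates the nonspecific-adhesion majority of a
real AFM data set and exercises the screening stage; these are labelled
synthetic nonspecific adhesion in code and ground truth.

### What the synthetic data do not emulate

No thermal cantilever dynamics or 1/f noise, no hydrodynamic drag, no
surface-adhesion artifacts near contact, no multiple tethers, no drift,
no PEG conformational transition, no refolding during a trace. Passing
recovery tests therefore demonstrate that the *reduction chain* is
unbiased on data obeying its generative assumptions — they do not certify
robustness to every instrumental artifact of real curves. The screening
thresholds that a human would apply by eye are codified as explicit,
configurable thresholds instead.

## Curve reduction decisions

- **Event detection** localizes the sharp force *drop* (single-step fall
  plus a sustained median drop over the following samples) rather than the
  noisy local maximum; with 5 pN noise this pins the event sample exactly
  in simulation (≥98 % within 2 samples). A trace that ends above the
  force floor is treated as truncated at its final rupture. Defaults:
  min_drop 30 pN, min_force 50 pN (events below ~50 pN sit in the
  PEG/noise region), min_separation 5 nm.
- **Loading rate** is the slope of a line fit to force vs time over the
  final 30 % of the force rise to the peak. The valley search runs on a
  lightly smoothed trace and requires ≥20 pN of accumulated rise before it
  may stop, so noise cannot truncate the window. Median relative error vs
  ground truth is <10 % at the defaults.
- **Linker correction.** Transforming the *total* extension of the
  composite chain (WLC linkers + FRC protein) with the FRC alone shifts
  each state's apparent position by a force-dependent linker term; states
  probed over different force ranges (the CBM state ends at ~150 pN, the
  final state at ~630 pN) acquire offsets differing by ~3 nm, biasing
  peak-to-peak increments. The pipeline therefore subtracts the modelled
  WLC linker extension at the sample force before the FRC transform
  (`correct_linkers`, default on; the uncorrected mode is available).
  This is exact for synthetic data, where linker parameters are known;
  for real data with polydisperse linkers the cross-correlation alignment
  below absorbs the per-curve offsets but not the intra-curve force
  dependence.
- **Per-curve barrier positions** for classification come from the median
  apparent contour length of each inter-event segment (robust, works on
  single curves); the per-curve *histograms* (1 nm bins) feed the master
  histogram, assembled by iterative integer-bin cross-correlation
  alignment (±10 nm search) against the running master — the procedure
  used for experimental barrier-position histograms, where absolute
  offsets vary curve to curve.
- **Fingerprint matching** assigns each template increment to a disjoint
  subset of up to three measured increments (sum within ±8 nm tolerance;
  the source analysis quotes only approximate increments). The assignment
  is optimized globally — maximize matched templates, then minimize total
  error — so the three-step xylanase matches its 89 nm total even when
  CBM unfolds between the sub-steps, and an exact multi-part sum cannot
  steal increments another template needs. A curve is *specific* when Xyn
  and CBM both match; the final rupture is *shielded* exactly when the
  XMod increment also matched earlier in the same trace.

## Problem sizes

The recovery studies shipped with the package use: 5 loading rates ×
500 analytic samples for the dynamic-force-spectrum fit; 200 simulated
curves at 1.6 µm/s for fingerprint recovery; 2000 single-bond traces for
the simulator-vs-closed-form distribution check; and 500 mixed-speed
curves (5 speeds, 0.2–6.4 µm/s) for the end-to-end per-history recovery.
These sizes give statistical resolution comfortably inside the tolerances
asserted in the tests while keeping the whole suite fast. The
experimental spectrum itself (2,122 traces from many cantilevers) is not
reproducible from public data — no raw AFM curves are deposited — which
is why the end-to-end synthetic study is the validation instrument here.

## Known limitations

- The QM-correction coefficients and the exact fingerprint residue
  bookkeeping are documented placeholders (correct magnitudes, not
  transcribed published values); both are configurable.
- The simulator's explicit pathway branching reproduces the observed
  branch fraction by construction, so the branch fraction itself is an
  input, not a prediction.
- Recovered off-rates are order-of-magnitude estimates by the nature of
  the Bell-Evans intercept.
- No instrument-vendor file parsers; TSV/HDF5 are the supported inputs.
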