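# forcespec

Analysis toolkit for AFM single-molecule force spectroscopy (SMFS) of
mechanically ultrastable receptor–ligand complexes, built around the
XMod-Doc:Coh cellulosome-adhesion system: a cohesin:dockerin pair that
withstands 600–750 pN, with an X-module that mechanically shields the
binding interface. The package provides the full reduction chain for
constant-speed pulling experiments — polymer-elasticity contour-length
transformation, unfolding-fingerprint classification, bond-history
stratification and Bell-Evans dynamic-force-spectrum fitting — together
with a kinetic Monte Carlo (KMC) simulator of the pulling experiment that
generates realistic force–extension curves with ground-truth event logs.

## The models

**Polymer elasticity.** Unfolded polypeptide is described by a freely
rotating chain with quantum-mechanical backbone-stretch corrections
(QM-FRC): bonds of length *b* = 0.11 nm joined at a fixed angle
*γ* = 41°, giving the fractional extension

```
x/L = 1 − (4 F p / kBT)^(−1/2)      for F b/kBT <  p/b
x/L = 1 − kBT / (2 F b)             for F b/kBT ≥  p/b
```

with effective persistence length `p = b·cos(γ/2)/|ln cos γ|` and a
force-dependent contour length `L(F) = L0 (1 + c1 F + c2 F²)` for the
elastic backbone stretch. The model has no free fit parameters, which is
what makes the contour-length transform `L0 = x / (x/L · L/L0)` of every
(force, extension) sample well defined. PEG linkers are worm-like chains
(Marko–Siggia interpolation, persistence 0.38 nm). Unfolding a domain of
*n* residues adds ΔLc = *n*·0.365 nm − (folded length) of contour; the
xylanase (~89 nm) and CBM (~56 nm) increments are the fingerprints used to
screen for genuine single-molecule traces.

**Rupture kinetics.** Bond dissociation under force follows Bell kinetics,
`k(F) = k_off · exp(F Δx / kBT)`; at constant loading rate *r* the most
probable rupture force is

```
F* = (kBT/Δx) · ln( r Δx / (k_off kBT) )
```

so a straight-line fit of F* against ln r (the dynamic force spectrum)
yields the distance to the transition state Δx from the slope and the
intrinsic off-rate k_off from the intercept. Final ruptures are stratified
by bond history: *intact* (XMod folded, Δx = 0.13 nm, k_off = 7.3×10⁻⁷ s⁻¹)
versus *shielded* (rupture immediately after XMod unfolding, Δx = 0.19 nm,
k_off = 4.7×10⁻⁴ s⁻¹ — a ~300 pN rupture instead of ~630 pN).

**Simulator.** The KMC engine pulls a cantilever–PEG–polyprotein circuit at
constant speed, solving the series force balance at every step and drawing
unfolding/rupture times by inverting the cumulative hazard of each Bell
channel. It reproduces the three-peaked Xyn fingerprint, CBM unfolding,
the ~35–40 % XMod-first pathway, and final ruptures whose distribution
matches the closed-form Bell-Evans density.

## Worked example

```
$ forcespec simulate --n 200 --seed 42 --out curves.h5
wrote 200 curves to curves.h5
$ forcespec analyze --curves curves.h5 --out run
200 curves, 199 specific; fits: none
$ forcespec report --run run/report.json
config 61cecaaad0200501 seed 0
curves: 200 total / 200 with events / 199 specific (intact 129, shielded 70)
fingerprint increments: CBM=56.0 nm, XMod=34.0 nm, Xyn=89.0 nm
```

199 of 200 simulated curves pass the fingerprint screen; 70 (35 %) show
XMod unfolding before the final rupture and are tagged *shielded*. The
master barrier-position histogram recovers the programmed Xyn, CBM and
XMod contour-length increments exactly. A single pulling speed gives only
one point of the dynamic force spectrum (hence "fits: none"); running the
same pipeline on 500 curves spread over five speeds (0.2–6.4 µm/s) and
fitting each history class prints

```
intact: delta_x = 0.132 nm, k_off = 4.94e-07 1/s
shielded: delta_x = 0.185 nm, k_off = 6.36e-04 1/s
```

recovering the programmed kinetics (0.13 nm / 7.3×10⁻⁷ s⁻¹ and
0.19 nm / 4.7×10⁻⁴ s⁻¹; the off-rate is exponentially sensitive to the
intercept and is an order-of-magnitude quantity). The same chain is
available from Python via `forcespec.simulate_dataset` and
`forcespec.run_pipeline`.

## Layout

- `forcespec.polymer_models` — QM-FRC / WLC elasticity, contour-length
  transform, increment bookkeeping
- `forcespec.rupture_kinetics` — Bell-Evans rates, rupture-force
  distributions, samplers, Gaussian modal fits, DFS fitting
- `forcespec.synthetic_data` — KMC pulling simulator and dataset generator
- `forcespec.curve_processing` — event detection, loading rates,
  histograms, fingerprint classification, bond-history tagging
- `forcespec.pipeline` / `forcespec.io` / `forcespec.cli` — configuration,
  formats (TSV / HDF5 / CSV / JSON / TOML) and the `forcespec` CLI

See `docs/methods.md` for the modelling choices, defaults and limitations.
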