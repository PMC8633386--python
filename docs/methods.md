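# Methods

This note documents the models behind `metamel`, the parameters that
matter, what the synthetic stages do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Spectral container and reference data

All spectra live on a fixed 380–780 nm grid with 1 nm spacing (401
samples); integrals use the rectangle rule at Δλ = 1 nm (a trapezoid rule
differs by < 0.2 % on smooth LED spectra and serves as the independent test
oracle, never as the implementation).  Bundled reference tables
(`metamel.tables`):

- **CIE 1931 2° colour-matching functions** from the standard 5 nm abridged
  tabulation, cubic-spline resampled to 1 nm.  Internal anchors: the three
  columns integrate equally to ~0.1 %, V(555) = 1, the equal-energy
  spectrum maps to (x, y) = (1/3, 1/3).
- **Standard illuminant D65** from the 10 nm tabulation, linearly resampled;
  its chromaticity computes to (0.3127, 0.3291), CCT 6504 K, Duv +0.0032.
- **Melanopic sensitivity s_mel.** No official 1 nm tabulation is bundled;
  the curve is *constructed from its defining physiology*: the Govardovskii
  (2000) A1 pigment template at λ_max = 480 nm, converted to energy units,
  multiplied by an adult ocular-media transmittance model
  (optical density `d(λ) = d₄₀₀ · exp(−s · (λ − 400 nm))`).  The two lens
  parameters (d₄₀₀ = 0.742, s = 0.0253 /nm) are calibrated once against two
  standard-defined anchors — the 490 nm peak of the melanopic curve and the
  melanopic D65 efficacy constant 1.3262 mW/lm — and frozen.
- **Planckian radiators** from Planck's law with c₂ = 1.4388·10⁻² m·K.

**Melanopic EDI** is computed in its defining ratio form: the illuminance of
D65 with the same melanopic irradiance as the test spectrum.  The
conversion constant is therefore *derived* from the bundled tables at
import (it evaluates to 1.3262·10⁻³ W·m⁻²·lx⁻¹, matching the standard's
printed value) and DER(D65) = 1 holds exactly by construction.  Melanopic
values for strongly non-daylight spectra inherit the accuracy of the
constructed s_mel; the package's comparative quantities (tuning ranges,
contrasts, orderings) are insensitive to small shape error because every
spectrum is weighted by the same curve.

**CCT/Duv** uses Ohno-style nearest-point search on a dense Planck table
(0.2 mired steps, 1000–25000 K) in the CIE 1960 uv diagram with parabolic
refinement; Duv is signed positive above the locus.  Round-trip accuracy:
|ΔCCT|/CCT < 0.1 %, |ΔDuv| < 2·10⁻⁵.  Points with |Duv| > 0.05 raise an
out-of-range error.  Duv arithmetic (offsets, distances) is always done in
1960 uv (v = ⅔·v′), while targets and maps are expressed in u'v' and xy.

## Synthetic luminaires

The three presets reproduce the channel rosters of a commercial tunable
multi-channel LED luminaire
(6-channel: 475/504/521/662 nm narrowband + 4655 K and 2740 K phosphor
whites; 8-channel: 450/465/504/521/638/662 nm + whites; 11-channel:
419/450/457/504/521/597/638/662 nm + lime phosphor + whites).  Measured
primaries of the real device are not published, so channels are modelled:

- narrowband LEDs as Gaussians, default FWHM 20 nm (typical chromatic-LED
  linewidth; per-channel configurable);
- phosphor whites as a 450 nm pump plus one broad phosphor Gaussian whose
  centre/width/ratio are solved (deterministic least squares) to land on
  the Planckian locus at the nominal CCT within |ΔCCT| ≤ 50 K and
  |Duv| ≤ 0.005;
- the lime phosphor as a 550 nm / FWHM 100 nm Gaussian.

Channel spectra are normalised to unit radiometric power, and dimming is
exactly linear in the per-channel weights (the real device's duty-cycle
nonlinearity is deliberately not modelled).  Consequences: absolute
tuning-range numbers and their exact argmax chromaticities are *not*
expected to reproduce any measured-primary study; orderings, trends and
gate behaviour are the meaningful outputs.  This is also why passing tests
on these synthetic primaries shows the machinery is correct under the
stated conditions, not that a particular physical luminaire achieves a
particular Δγ.

## Target grid

17 CCT levels from 2700 K to 7443 K, each with 33 Duv offsets
{0, ±0.003, …, ±0.048} — 561 targets.  The CCT ladder is uniform in u'v'
arc length along the locus (the published ladder is not tabulated;
`spacing="mired"` gives uniform reciprocal-temperature spacing instead).
Duv offsets are applied perpendicular to the locus in 1960 uv, so
recomputing (CCT, Duv) from any target reproduces it within 10⁻⁴.
Out-of-gamut targets simply yield empty metamer sets.

## Metamer harvesting

The published study used a proprietary heuristic optimiser; `metamel`
substitutes a self-contained differential-evolution harvest (any
harvest-capable search satisfies the contract):

- variables: per-channel weights in [0, 1]ⁿ; population 60; rand/1/bin
  with F dithered in (0.4, 0.9), CR = 0.9; up to 500 generations per
  repetition (budget-configurable); candidates exceeding a channel-count
  limit have their smallest weights zeroed;
- objective: Euclidean u'v' distance to the target plus a hinge penalty
  (weight 10⁻³ per lx) for illuminance outside 220 ± 2 lx;
- **harvest, not optimum**: every population member that visits the
  feasible region (per-axis Δu', Δv' ≤ 0.001 *and* illuminance inside the
  window) is archived, capped per repetition;
- repetitions cycle through three modes: plain exploration, melanopic-EDI
  maximisation and minimisation.  In the extremum modes the chromaticity
  term is flattened inside half the tolerance and a small melanopic term
  (10⁻⁶ per lx) is added, scaled so candidates stay inside the tolerance
  box.  Without these modes the archive clusters around wherever the search
  first converged and systematically under-estimates the melanopic extent
  of the metamer manifold, increasingly so for higher channel counts;
- seeds: per-repetition generators derive from `SeedSequence([seed, rep])`;
  the pipeline derives per-target seeds from
  `SeedSequence([master_seed, target_index])`, so every target is
  independently reproducible.

Archived weight vectors are deduplicated by snapping to a 10⁻³ grid in
weight space (the published work never defines spectrum distinctness; two
solutions closer than ~0.1 % duty cycle are one metamer for our purposes).
When a member cap applies, the archive is thinned *evenly* across its
length so every repetition and search phase contributes.  Survivors are
re-checked against the tolerance, linearly rescaled to exactly 250 lx
(chromaticity and DER are scale-invariant, so pre- vs post-rescale
tolerance checking is immaterial), and stored with their full metric
record.

## Colour fidelity

Scoring follows the TM-30 architecture: CCT-matched reference illuminant
(Planckian below 4000 K, daylight above 5000 K, luminance-proportional
blend between), evaluation samples rendered under test and reference,
colour differences in CAM02-UCS (CIECAM02 with average surround,
L_A = 100 cd·m⁻², Y_b = 20, standard degree-of-adaptation formula; the
implementation reproduces the two published CIECAM02 worked examples), a
general index `R_f = 10·ln(exp((100 − 6.73·ΔĒ)/10) + 1)` and 16 local
hue-bin indices with R_f,h1 the 0–22.5° (red) bin.  Two deliberate
departures, both load-bearing for interpretation:

1. **Synthetic evaluation samples.**  The standard's 99 reflectances are
   not redistributable, so a deterministic synthetic panel of 99 smooth
   band-pass/band-stop/edge/two-band/near-neutral reflectances stands in
   (`evaluation_samples`, labelled synthetic).  The panel covers all 16 hue
   bins at every relevant CCT (tested 2700–7443 K).  Absolute R_f values
   therefore differ from commercial TM-30 implementations; the scale
   anchors (reference scores 100, D65 scores ~100 against the daylight
   reference) and the threshold semantics (85/90 gates, nesting,
   monotonicity) are preserved, and those are what the pipeline consumes.
2. **2° observer throughout**, consistent with the rest of the package.

The daylight-phase reference is likewise built without the official
S₀/S₁/S₂ components: a smooth continuum (Planckian, blended toward bundled
D65 as the CCT approaches D65's in reciprocal temperature) plus three broad
Gaussian correctors solved linearly so the chromaticity lands exactly on
the CIE daylight locus.  Corrections stay ≲ 10 % of the continuum peak.

A CRI-style diagnostic `ra` (mean CAM02-UCS colour difference over an
8-sample subset, 100 − 4.6·ΔĒ) is reported for orientation only and never
used as a gate; it is not the CIE 13.3 procedure.

## Reductions and the atlas

Per target: melanopic-EDI extremes by exhaustive scan (first occurrence on
ties), Δγ, ΔE = E_v·Δγ, and Michelson contrast.  Per CCT level: γ̂_min,
γ̂_max (extremes across the Duv ladder — the non-metameric optima) and Δγ̃
(largest same-chromaticity range), each with its arg-max Duv.  The atlas
linearly interpolates Δγ and C_M over CIE xy on a regular raster masked to
the convex hull of summarised targets (no extrapolation; gaps where
optimisation failed stay gaps), and records brute-force global maxima with
ties broken by lowest (cct_level, duv_level).  DER/contrast are reported to
two decimals, lux to one.

## Reduced study conditions

The full 561-target × 3-luminaire study is expensive; the shipped
acceptance test runs the same pipeline on a reduced grid chosen as the
package's standard verification size: 5 CCT levels × 7 Duv offsets
(|Duv| ≤ 0.009), all three luminaires, population 60, 250 generations,
12 repetitions per target, archives capped at 4000 visits/repetition and
1200 distinct metamers/target (the full-scale study behind the method
averaged ~300–400 metamers per target with 6–8 repetitions; the extra
repetitions here stabilise the gated extremes on the much smaller grid).
Under these conditions the qualitative findings hold with margin across
master seeds: the per-CCT tuning range Δγ̃ increases with CCT (Spearman
ρ = 1.0 at the default seed), the P3-gated global Δγ_max orders 6ch ≤ 8ch
and 6ch ≤ 11ch, stricter gates shrink every per-target range, and every
harvested metamer satisfies the tolerance and exact-250 lx invariants.

## Known limitations

- Gaussian/phosphor channel models, linear dimming, no thermal droop or
  driver quantisation; a measured-SPD loader exists (`spectra_from_csv`)
  but ships untested against real device data.
- s_mel is a calibrated physiological construction, not the official
  tabulation; melanopic absolute values carry that model error (the D65
  anchor and all ratios/orderings do not).
- Fidelity scores are TM-30-*style*, not certifiable TM-30 values (see
  above); CRI `ra` is indicative only.
- Only the melanopic channel is implemented; other alpha-opic channels
  would slot into the same integral machinery but are untested.
- The stochastic harvest estimates the tuning range from below: deeper
  harvests can only widen per-target ranges.
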