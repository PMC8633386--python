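# metamel

Metameric multi-channel LED spectra and their melanopic tuning range.

Light drives the circadian system through melanopsin-containing,
intrinsically photosensitive retinal ganglion cells (ipRGCs), largely
independently of the visual channel.  Spectra that match in chromaticity and
illuminance — *metamers* — can therefore differ substantially in melanopic
drive: a luminaire can hold its visual appearance fixed while silently
tuning its circadian stimulus.  `metamel` is a research tool for mapping how
large that tuning range is, and where in colour space it is largest, for
tunable multi-channel LED luminaires.  It is aimed at lighting researchers
and engineers designing integrative (visual + circadian) lighting.

## What it computes

For a spectrum X(λ) on the 380–780 nm, 1 nm grid:

- photopic illuminance `E_v = 683 · Σ V(λ) X(λ) Δλ` (lx),
- melanopic equivalent daylight illuminance (CIE S 026)
  `E_mel^D65 = (1 / 1.3262·10⁻³) · Σ s_mel(λ) X(λ) Δλ` (lx),
- melanopic daylight efficacy ratio `γ_mel^D65 = E_mel^D65 / E_v`
  (= 1 for D65 by definition),
- CIE 1931 xy / CIE 1976 u'v' chromaticity, and CCT / Duv by Ohno-style
  search against a dense Planckian-locus table.

The pipeline emulates three luminaires (6, 8 and 11 LED channels: Gaussian
narrowband primaries plus phosphor-white and lime models), builds a grid of
561 chromaticity targets along the Planckian locus (17 CCT levels from
2700 K to 7443 K × Duv offsets 0, ±0.003, …, ±0.048), and for each target
harvests metamers with a differential-evolution search: weights in [0, 1]
per channel, chromaticity within Δu', Δv' ≤ 0.001 of the target (Δu'v' ≤
1.41·10⁻³), illuminance optimised at 220 ± 2 lx and then rescaled exactly
to 250 lx.  Each metamer set is gated by TM-30-style colour-fidelity
criteria (priority level 3: R_f ≥ 85 & R_f,h1 ≥ 85; level 2: 90/90) and
reduced to its tuning metrics

```
Δγ_mel = |γ_max − γ_min|,   ΔE_mel = E_v · Δγ_mel,
C_M = (E_mel,max − E_mel,min) / (E_mel,max + E_mel,min)
```

which are interpolated into CIExy maps ("atlases") with their global
maxima.  See `docs/methods.md` for the models, assumptions and deliberate
departures from the letter of the TM-30 standard (synthetic evaluation
samples, 2° observer throughout).

## Worked example

```python
from metamel import (build_luminaire, build_grid, optimize_target,
                     filter_metamers, score_metamer_set,
                     apply_fidelity_criterion, summarize_target)

lum = build_luminaire("11ch")
targets = build_grid(n_cct=5, duv_max=0.009, duv_step=0.003)
target = min((t for t in targets if t.duv_level == 0),
             key=lambda t: abs(t.cct - 5500))

run = optimize_target(lum, target, seed=1, repetitions=8)
ms = score_metamer_set(filter_metamers(run, max_members=400))
gated = apply_fidelity_criterion(ms, "p3")
s = summarize_target(gated)
```

prints, with the values from this exact seed:

```
target: CCT 5411 K, Duv +0.000, u'v' = (0.2076, 0.4788)
harvest: 32000 feasible visits, 400 distinct metamers, 17 pass Rf>=85 & Rf,h1>=85
melanopic EDI at 250 lx: 192.4 .. 224.1 lx (delta 31.7 lx)
melanopic DER: 0.770 .. 0.896 (delta_gamma 0.127), Michelson contrast C_M = 0.08
```

Read: at this fixed white point and a fixed 250 lx on the desk, swapping
between the two extreme metamers changes the melanopic stimulus by ~32 lx
melanopic EDI (13 % of the illuminance) without any visible change, while
keeping colour fidelity at the R_f ≥ 85 level.  Ungated, the same target
tunes over a much wider range — colour rendition is the binding constraint.

The same pipeline is scriptable from the shell:

```sh
metamel grid --n-cct 17 --out grid.csv
metamel optimize --luminaire 11ch --seed 1 --reps 8 --out runs/
metamel analyze --runs runs/ --fidelity p3
metamel report --atlas runs/atlas_11ch_p3
```

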