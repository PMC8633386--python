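"""Bundled standard reference tables on the common 380–780 nm, 1 nm grid.

Everything downstream (tristimulus integration, photometry, melanopic
quantities, the Planckian locus) is computed from the arrays defined here, so
the provenance of each table is recorded in :data:`TABLE_VERSIONS` and the
arrays are exposed read-only.

Tables
------
* CIE 1931 2° colour-matching functions, abridged 5 nm tabulation,
  spline-resampled to 1 nm.  The photopic luminous efficiency function V(λ)
  is the ȳ column, with V(555 nm) = 1 by definition.
* CIE standard illuminant D65, relative spectral power, 10 nm tabulation
  linearly resampled to 1 nm (normalised to 100 at 560 nm).
* Melanopic spectral sensitivity s_mel(λ), peak-normalised at 490 nm.  No
  official 1 nm tabulation ships with this package; the curve is constructed
  from its defining physiology instead: the Govardovskii (2000) A1 visual
  pigment template at λ_max = 480 nm, expressed in energy units, filtered by
  a smooth ocular-media (lens) transmittance model for the adult standard
  observer.  The two lens parameters are calibrated once against two
  standard-defined anchors — the 490 nm peak of the melanopic curve and the
  melanopic D65 luminous efficacy constant 1.3262 mW/lm — and frozen below.
* Planckian radiator spectra from Planck's law with c2 = 1.4388·10⁻² m·K.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

#: Common wavelength grid, nm.  Shared and immutable.
WAVELENGTHS = np.arange(380.0, 781.0, 1.0)
WAVELENGTHS.setflags(write=False)

#: Number of samples in the common grid.
N_WAVELENGTHS = 401

#: Maximum luminous efficacy of radiation, lm/W.
LUMINOUS_EFFICACY_MAX = 683.002

TABLE_VERSIONS = {
    "cmf": "CIE 1931 2-deg colour-matching functions, 5 nm abridged, "
           "cubic-spline resampled to 1 nm",
    "v_lambda": "CIE photopic V(lambda) = y-bar of the 1931 2-deg observer",
    "d65": "CIE standard illuminant D65, 10 nm tabulation, linearly "
           "resampled to 1 nm",
    "s_mel": "melanopic sensitivity constructed from the Govardovskii A1 "
             "template (lambda_max 480 nm, energy units) with a calibrated "
             "ocular-media transmittance model; peak 1 at 490 nm",
    "planck": "Planck's law, c2 = 1.4388e-2 m K",
}

_WL5 = np.arange(380.0, 781.0, 5.0)

# CIE 1931 2-deg colour-matching functions x-bar, y-bar, z-bar at 5 nm.
_CMF_5NM = np.array([
    [0.001368, 0.000039, 0.006450],
    [0.002236, 0.000064, 0.010550],
    [0.004243, 0.000120, 0.020050],
    [0.007650, 0.000217, 0.036210],
    [0.014310, 0.000396, 0.067850],
    [0.023190, 0.000640, 0.110200],
    [0.043510, 0.001210, 0.207400],
    [0.077630, 0.002180, 0.371300],
    [0.134380, 0.004000, 0.645600],
    [0.214770, 0.007300, 1.039050],
    [0.283900, 0.011600, 1.385600],
    [0.328500, 0.016840, 1.622960],
    [0.348280, 0.023000, 1.747060],
    [0.348060, 0.029800, 1.782600],
    [0.336200, 0.038000, 1.772110],
    [0.318700, 0.048000, 1.744100],
    [0.290800, 0.060000, 1.669200],
    [0.251100, 0.073900, 1.528100],
    [0.195360, 0.090980, 1.287640],
    [0.142100, 0.112600, 1.041900],
    [0.095640, 0.139020, 0.812950],
    [0.057950, 0.169300, 0.616200],
    [0.032010, 0.208020, 0.465180],
    [0.014700, 0.258600, 0.353300],
    [0.004900, 0.323000, 0.272000],
    [0.002400, 0.407300, 0.212300],
    [0.009300, 0.503000, 0.158200],
    [0.029100, 0.608200, 0.111700],
    [0.063270, 0.710000, 0.078250],
    [0.109600, 0.793200, 0.057250],
    [0.165500, 0.862000, 0.042160],
    [0.225750, 0.914850, 0.029840],
    [0.290400, 0.954000, 0.020300],
    [0.359700, 0.980300, 0.013400],
    [0.433450, 0.994950, 0.008750],
    [0.512050, 1.000000, 0.005750],
    [0.594500, 0.995000, 0.003900],
    [0.678400, 0.978600, 0.002750],
    [0.762100, 0.952000, 0.002100],
    [0.842500, 0.915400, 0.001800],
    [0.916300, 0.870000, 0.001650],
    [0.978600, 0.816300, 0.001400],
    [1.026300, 0.757000, 0.001100],
    [1.056700, 0.694900, 0.001000],
    [1.062200, 0.631000, 0.000800],
    [1.045600, 0.566800, 0.000600],
    [1.002600, 0.503000, 0.000340],
    [0.938400, 0.441200, 0.000240],
    [0.854450, 0.381000, 0.000190],
    [0.751400, 0.321000, 0.000100],
    [0.642400, 0.265000, 0.000050],
    [0.541900, 0.217000, 0.000030],
    [0.447900, 0.175000, 0.000020],
    [0.360800, 0.138200, 0.000010],
    [0.283500, 0.107000, 0.000000],
    [0.218700, 0.081600, 0.000000],
    [0.164900, 0.061000, 0.000000],
    [0.121200, 0.044580, 0.000000],
    [0.087400, 0.032000, 0.000000],
    [0.063600, 0.023200, 0.000000],
    [0.046770, 0.017000, 0.000000],
    [0.032900, 0.011920, 0.000000],
    [0.022700, 0.008210, 0.000000],
    [0.015840, 0.005723, 0.000000],
    [0.011359, 0.004102, 0.000000],
    [0.008111, 0.002929, 0.000000],
    [0.005790, 0.002091, 0.000000],
    [0.004109, 0.001484, 0.000000],
    [0.002899, 0.001047, 0.000000],
    [0.002049, 0.000740, 0.000000],
    [0.001440, 0.000520, 0.000000],
    [0.001000, 0.000361, 0.000000],
    [0.000690, 0.000249, 0.000000],
    [0.000476, 0.000172, 0.000000],
    [0.000332, 0.000120, 0.000000],
    [0.000235, 0.000085, 0.000000],
    [0.000166, 0.000060, 0.000000],
    [0.000117, 0.000042, 0.000000],
    [0.000083, 0.000030, 0.000000],
    [0.000059, 0.000021, 0.000000],
    [0.000042, 0.000015, 0.000000],
])

_WL10 = np.arange(380.0, 781.0, 10.0)

# CIE standard illuminant D65, relative SPD at 10 nm (100 at 560 nm).
_D65_10NM = np.array([
    49.98, 54.65, 82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81,
    114.86, 115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05,
    100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29, 83.70, 80.03,
    80.21, 82.28, 78.28, 69.72, 71.61, 74.35, 61.60, 69.89, 75.09, 63.59,
    46.42, 66.81, 63.38,
])

# Ocular-media model parameters: optical density d(λ) = D400 * exp(-S*(λ-400)),
# calibrated against the 490 nm melanopic peak and the 1.3262 mW/lm anchor.
_LENS_D400 = 0.7419028
_LENS_SLOPE = 0.0253486

# Govardovskii A1 alpha-band template constants.
_GOV_A, _GOV_B, _GOV_C, _GOV_D = 69.7, 28.0, -14.9, 0.674
_GOV_b, _GOV_c = 0.922, 1.104

#: Second radiation constant for Planck's law, m·K (CIE value).
PLANCK_C2 = 1.4388e-2


def _resample_cmf() -> np.ndarray:
    out = np.column_stack([
        CubicSpline(_WL5, _CMF_5NM[:, k])(WAVELENGTHS) for k in range(3)
    ])
    return np.clip(out, 0.0, None)


def _pigment_template(wavelengths: np.ndarray, lam_max: float) -> np.ndarray:
    """Govardovskii et al. (2000) A1 pigment absorbance (quantal units)."""
    x = lam_max / wavelengths
    a = 0.8795 + 0.0459 * np.exp(-((lam_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_GOV_A * (a - x))
        + np.exp(_GOV_B * (_GOV_b - x))
        + np.exp(_GOV_C * (_GOV_c - x))
        + _GOV_D
    )
    lam_beta = 189.0 + 0.315 * lam_max
    width_beta = -40.5 + 0.195 * lam_max
    beta = 0.26 * np.exp(-(((wavelengths - lam_beta) / width_beta) ** 2))
    return alpha + beta


def _melanopic_sensitivity() -> np.ndarray:
    density = _LENS_D400 * np.exp(-_LENS_SLOPE * (WAVELENGTHS - 400.0))
    transmittance = 10.0 ** (-density)
    # energy-based sensitivity: quantal template times wavelength
    s = _pigment_template(WAVELENGTHS, 480.0) * WAVELENGTHS * transmittance
    return s / s.max()


#: CIE 1931 2° colour-matching functions on the 1 nm grid, shape (401, 3).
CMF_2DEG = _resample_cmf()
CMF_2DEG.setflags(write=False)

#: Photopic luminous efficiency V(λ); V(555 nm) = 1.
V_LAMBDA = CMF_2DEG[:, 1].copy()
V_LAMBDA.setflags(write=False)

#: Relative SPD of standard illuminant D65 on the 1 nm grid.
D65_SPD = np.interp(WAVELENGTHS, _WL10, _D65_10NM)
D65_SPD.setflags(write=False)

#: Melanopic spectral sensitivity, peak-normalised.
S_MEL = _melanopic_sensitivity()
S_MEL.setflags(write=False)


def planck_spd(cct: float) -> np.ndarray:
    """Relative SPD of a Planckian (blackbody) radiator at ``cct`` kelvin.

    Normalised to a maximum of 1 on the grid; only the relative shape is
    meaningful for colorimetry.
    """
    if not np.isfinite(cct) or cct <= 0:
        raise ValueError(f"blackbody temperature must be positive, got {cct}")
    lam = WAVELENGTHS * 1e-9
    spd = lam ** -5.0 / np.expm1(PLANCK_C2 / (lam * cct))
    return spd / spd.max()


def daylight_locus_xy(cct: float) -> tuple[float, float]:
    """CIE daylight-locus chromaticity (x_D, y_D) for 4000 K ≤ cct ≤ 25000 K."""
    if not 4000.0 <= cct <= 25000.0:
        raise ValueError(f"daylight locus defined for 4000-25000 K, got {cct}")
    t = 1e3 / cct
    if cct <= 7000.0:
        x = 0.244063 + 0.09911 * t + 2.9678 * t ** 2 - 4.6070 * t ** 3
    else:
        x = 0.237040 + 0.24748 * t + 1.9018 * t ** 2 - 2.0064 * t ** 3
    y = -3.000 * x ** 2 + 2.870 * x - 0.275
    return float(x), float(y)
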