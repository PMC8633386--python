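"""Spectra and the scalar quantities attached to them.

The central container is :class:`Spectrum`, a spectral irradiance
distribution on the fixed 380–780 nm / 1 nm grid.  All photometric,
melanopic and chromaticity quantities are integrals against the bundled
reference tables (:mod:`metamel.tables`), evaluated with the rectangle rule
at Δλ = 1 nm.

Melanopic quantities follow CIE S 026: the melanopic equivalent daylight
illuminance (melanopic EDI) of a spectrum is the illuminance of standard
daylight D65 that produces the same melanopic irradiance, and the melanopic
daylight efficacy ratio (melanopic DER) is melanopic EDI divided by
illuminance.  The EDI is computed in its defining D65-anchored ratio form,
so DER(D65) = 1 holds exactly for the bundled tables; the resulting
conversion constant :data:`MELANOPIC_EFFICACY_D65` evaluates to the
standard's 1.3262 mW/lm.

CCT and Duv use Ohno's method: nearest point on a dense Planckian-locus
table in the CIE 1960 uv diagram with parabolic refinement, Duv signed
positive above the locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .tables import (
    CMF_2DEG,
    D65_SPD,
    LUMINOUS_EFFICACY_MAX,
    N_WAVELENGTHS,
    S_MEL,
    TABLE_VERSIONS,
    V_LAMBDA,
    WAVELENGTHS,
    planck_spd,
)

__all__ = [
    "Spectrum",
    "Chromaticity",
    "SpectrumMetrics",
    "GridError",
    "DegenerateSpectrumError",
    "CCTRangeError",
    "MELANOPIC_EFFICACY_D65",
    "illuminance",
    "melanopic_irradiance",
    "melanopic_edi",
    "melanopic_der",
    "tristimulus",
    "chromaticity",
    "xy_from_uv_prime",
    "uv_prime_from_xy",
    "cct_duv",
    "locus_uv",
    "locus_point",
    "rescale_to_illuminance",
    "spectrum_metrics",
    "spectra_to_csv",
    "spectra_from_csv",
    "metrics_to_json",
]


class GridError(ValueError):
    """Raised when spectral data does not live on the shared 401-point grid."""


class DegenerateSpectrumError(ValueError):
    """Raised when an operation is undefined for an (all but) zero spectrum."""


class CCTRangeError(ValueError):
    """Raised when a chromaticity is too far from the Planckian locus."""


@dataclass(frozen=True)
class Spectrum:
    """Spectral irradiance on the fixed 380–780 nm, 1 nm grid.

    Parameters
    ----------
    values
        Spectral irradiance in W·m⁻²·nm⁻¹, non-negative, length 401.
    name
        Optional label carried through I/O.
    """

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_WAVELENGTHS,):
            raise GridError(
                f"expected {N_WAVELENGTHS} samples on the 380-780 nm 1 nm "
                f"grid, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("spectral values must be finite")
        if np.any(values < 0):
            raise ValueError("spectral irradiance must be non-negative")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def wavelengths(self) -> np.ndarray:
        """The shared wavelength grid in nm (read-only)."""
        return WAVELENGTHS

    def scaled(self, factor: float) -> "Spectrum":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return Spectrum(self.values * factor, name=self.name)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        return Spectrum(self.values + other.values)

    def __mul__(self, factor: float) -> "Spectrum":
        return self.scaled(float(factor))

    __rmul__ = __mul__


class Chromaticity(NamedTuple):
    """A chromaticity in both CIE 1931 xy and CIE 1976 u'v' coordinates."""

    x: float
    y: float
    u_prime: float
    v_prime: float


@dataclass(frozen=True)
class SpectrumMetrics:
    """Every scalar metric attached to one spectrum."""

    e_v: float
    e_mel: float
    gamma_mel: float
    x: float
    y: float
    u_prime: float
    v_prime: float
    cct: float
    duv: float

    def as_dict(self) -> dict:
        return {
            "E_v_lx": self.e_v,
            "E_mel_D65_lx": self.e_mel,
            "gamma_mel_D65": self.gamma_mel,
            "x": self.x,
            "y": self.y,
            "u_prime": self.u_prime,
            "v_prime": self.v_prime,
            "cct_K": self.cct,
            "duv": self.duv,
        }


#: Bundled D65 as a :class:`Spectrum` (relative scale).
D65 = Spectrum(D65_SPD, name="D65")

#: Melanopic irradiance of D65 per lx of D65 illuminance, W·m⁻²·lx⁻¹.
#: CIE S 026 tabulates this conversion constant as 1.3262 mW/lm.
MELANOPIC_EFFICACY_D65 = float(
    (S_MEL * D65_SPD).sum()
    / (LUMINOUS_EFFICACY_MAX * (V_LAMBDA * D65_SPD).sum())
)


def _values(spd: Spectrum | np.ndarray) -> np.ndarray:
    if isinstance(spd, Spectrum):
        return spd.values
    arr = np.asarray(spd, dtype=float)
    if arr.shape != (N_WAVELENGTHS,):
        raise GridError(f"expected shape ({N_WAVELENGTHS},), got {arr.shape}")
    return arr


def illuminance(spd: Spectrum | np.ndarray) -> float:
    """Photopic illuminance in lx: 683.002 lm/W × Σ V(λ)·X(λ)·Δλ."""
    return float(LUMINOUS_EFFICACY_MAX * (V_LAMBDA * _values(spd)).sum())


def melanopic_irradiance(spd: Spectrum | np.ndarray) -> float:
    """Melanopic-weighted irradiance Σ s_mel(λ)·X(λ)·Δλ, W·m⁻²."""
    return float((S_MEL * _values(spd)).sum())


def melanopic_edi(spd: Spectrum | np.ndarray) -> float:
    """Melanopic equivalent daylight (D65) illuminance in lx.

    Illuminance of D65 producing the same melanopic irradiance as ``spd``;
    equivalently the melanopic irradiance divided by
    :data:`MELANOPIC_EFFICACY_D65` (≈ 1.3262·10⁻³ W·m⁻²·lx⁻¹).
    """
    return melanopic_irradiance(spd) / MELANOPIC_EFFICACY_D65


def melanopic_der(spd: Spectrum | np.ndarray) -> float:
    """Melanopic daylight efficacy ratio γ = melanopic EDI / illuminance.

    Dimensionless and invariant under positive scaling of the spectrum;
    equals 1 for D65.
    """
    e_v = illuminance(spd)
    if e_v <= 0:
        raise DegenerateSpectrumError(
            "melanopic DER undefined for zero illuminance"
        )
    return melanopic_edi(spd) / e_v


def tristimulus(spd: Spectrum | np.ndarray) -> np.ndarray:
    """CIE 1931 2° tristimulus values (X, Y, Z), rectangle rule at 1 nm."""
    return CMF_2DEG.T @ _values(spd)


def _chromaticity_from_xyz(xyz: np.ndarray) -> Chromaticity:
    total = float(xyz.sum())
    if total <= 0:
        raise DegenerateSpectrumError("zero tristimulus: chromaticity undefined")
    x, y = float(xyz[0] / total), float(xyz[1] / total)
    denom = float(xyz[0] + 15.0 * xyz[1] + 3.0 * xyz[2])
    u_prime = float(4.0 * xyz[0] / denom)
    v_prime = float(9.0 * xyz[1] / denom)
    return Chromaticity(x, y, u_prime, v_prime)


def chromaticity(spd: Spectrum | np.ndarray) -> Chromaticity:
    """CIE 1931 xy and CIE 1976 u'v' chromaticity of a spectrum."""
    return _chromaticity_from_xyz(tristimulus(spd))


def uv_prime_from_xy(x: float, y: float) -> tuple[float, float]:
    denom = -2.0 * x + 12.0 * y + 3.0
    return 4.0 * x / denom, 9.0 * y / denom


def xy_from_uv_prime(u_prime: float, v_prime: float) -> tuple[float, float]:
    denom = 6.0 * u_prime - 16.0 * v_prime + 12.0
    return 9.0 * u_prime / denom, 4.0 * v_prime / denom


def _chromaticity_from_uv_prime(u_prime: float, v_prime: float) -> Chromaticity:
    x, y = xy_from_uv_prime(u_prime, v_prime)
    return Chromaticity(float(x), float(y), float(u_prime), float(v_prime))


# ---------------------------------------------------------------------------
# Planckian locus and Ohno CCT/Duv
# ---------------------------------------------------------------------------

# Dense locus table, uniform in reciprocal temperature (0.2 mired steps over
# 1000 K .. 25000 K), in the CIE 1960 uv diagram (u = u', v = 2/3 v').
_LOCUS_MIRED = np.arange(40.0, 1000.0001, 0.2)


def _build_locus() -> tuple[np.ndarray, np.ndarray]:
    ccts = 1e6 / _LOCUS_MIRED
    uv = np.empty((ccts.size, 2))
    lam = WAVELENGTHS * 1e-9
    lam5 = lam ** -5.0
    c2_over_lam = 1.4388e-2 / lam
    for i, cct in enumerate(ccts):
        spd = lam5 / np.expm1(c2_over_lam / cct)
        xyz = CMF_2DEG.T @ spd
        denom = xyz[0] + 15.0 * xyz[1] + 3.0 * xyz[2]
        uv[i] = 4.0 * xyz[0] / denom, 6.0 * xyz[1] / denom
    return ccts, uv


_LOCUS_CCT, _LOCUS_UV = _build_locus()


def locus_uv(cct: float) -> tuple[float, float]:
    """CIE 1960 (u, v) of the Planckian radiator at ``cct`` (from the SPD)."""
    xyz = tristimulus(planck_spd(cct))
    denom = float(xyz[0] + 15.0 * xyz[1] + 3.0 * xyz[2])
    return float(4.0 * xyz[0] / denom), float(6.0 * xyz[1] / denom)


def locus_point(cct: float) -> Chromaticity:
    """Chromaticity of the Planckian radiator at ``cct`` kelvin."""
    if not 1000.0 <= cct <= 20000.0:
        raise CCTRangeError(f"cct {cct} outside supported 1000-20000 K")
    xyz = tristimulus(planck_spd(cct))
    return _chromaticity_from_xyz(xyz)


def _locus_tangent(index: int) -> np.ndarray:
    lo = max(index - 1, 0)
    hi = min(index + 1, _LOCUS_UV.shape[0] - 1)
    tangent = _LOCUS_UV[hi] - _LOCUS_UV[lo]
    return tangent / np.hypot(*tangent)


def _locus_normal(index: int) -> np.ndarray:
    """Unit normal to the locus pointing to the above-Planck (positive) side."""
    tx, ty = _locus_tangent(index)
    normal = np.array([-ty, tx])
    if normal[1] < 0:  # above the locus is the +v side
        normal = -normal
    return normal


def cct_duv(u_prime: float, v_prime: float) -> tuple[float, float]:
    """Correlated colour temperature and signed Duv of a chromaticity.

    Ohno-style search: nearest point on the dense Planckian table in the
    CIE 1960 uv diagram, refined by parabolic interpolation of the distance
    over the bracketing table entries.  Duv is the distance in uv, signed
    positive above the locus.

    Raises
    ------
    CCTRangeError
        If |Duv| exceeds 0.05 (CCT not meaningfully defined).
    """
    point = np.array([u_prime, 2.0 / 3.0 * v_prime])
    dist = np.hypot(*(point - _LOCUS_UV).T)
    i = int(np.argmin(dist))
    if 0 < i < dist.size - 1:
        d0, d1, d2 = dist[i - 1], dist[i], dist[i + 1]
        m0, m1, m2 = _LOCUS_MIRED[i - 1], _LOCUS_MIRED[i], _LOCUS_MIRED[i + 1]
        denom = d0 - 2.0 * d1 + d2
        shift = 0.5 * (d0 - d2) / denom if abs(denom) > 1e-300 else 0.0
        shift = float(np.clip(shift, -1.0, 1.0))
        mired = m1 + shift * (m2 - m1)
        # parabolic minimum distance
        dmin = d1 - 0.25 * (d0 - d2) * shift
    else:
        mired = _LOCUS_MIRED[i]
        dmin = dist[i]
    cct = 1e6 / mired
    sign = float(np.sign(np.dot(point - _LOCUS_UV[i], _locus_normal(i))))
    duv = sign * float(dmin)
    if abs(duv) > 0.05:
        raise CCTRangeError(
            f"chromaticity is {duv:+.4f} from the Planckian locus; "
            "CCT is not defined beyond |Duv| = 0.05"
        )
    return float(cct), duv


def rescale_to_illuminance(
    spd: Spectrum, target: float = 250.0
) -> Spectrum:
    """Linearly rescale a spectrum to the target photopic illuminance.

    Chromaticity and melanopic DER are invariant under this operation.
    """
    if target <= 0:
        raise ValueError(f"target illuminance must be positive, got {target}")
    e_v = illuminance(spd)
    if e_v <= 0:
        raise DegenerateSpectrumError(
            "cannot rescale a zero-illuminance spectrum"
        )
    return Spectrum(spd.values * (target / e_v), name=spd.name)


def spectrum_metrics(spd: Spectrum | np.ndarray) -> SpectrumMetrics:
    """Compute the full metric record for one spectrum."""
    e_v = illuminance(spd)
    e_mel = melanopic_edi(spd)
    chrom = chromaticity(spd)
    cct, duv = cct_duv(chrom.u_prime, chrom.v_prime)
    if e_v <= 0:
        raise DegenerateSpectrumError("metrics undefined for zero illuminance")
    return SpectrumMetrics(
        e_v=e_v,
        e_mel=e_mel,
        gamma_mel=e_mel / e_v,
        x=chrom.x,
        y=chrom.y,
        u_prime=chrom.u_prime,
        v_prime=chrom.v_prime,
        cct=cct,
        duv=duv,
    )


# ---------------------------------------------------------------------------
# I/O: wide CSV with a wavelength_nm column, JSON sidecars for metrics
# ---------------------------------------------------------------------------

def spectra_to_csv(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    """Write spectra as a wide CSV (first column ``wavelength_nm``)."""
    data = {"wavelength_nm": WAVELENGTHS.astype(int)}
    for i, spd in enumerate(spectra):
        data[spd.name or f"spectrum_{i}"] = spd.values
    pd.DataFrame(data).to_csv(path, index=False)


def spectra_from_csv(path: str | Path) -> list[Spectrum]:
    """Read spectra from the wide CSV format written by :func:`spectra_to_csv`."""
    frame = pd.read_csv(path)
    if "wavelength_nm" not in frame.columns:
        raise GridError("missing wavelength_nm column")
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    if wl.shape != (N_WAVELENGTHS,) or not np.allclose(wl, WAVELENGTHS):
        raise GridError("CSV wavelengths do not match the 380-780/1 nm grid")
    return [
        Spectrum(frame[col].to_numpy(dtype=float), name=str(col))
        for col in frame.columns
        if col != "wavelength_nm"
    ]


def metrics_to_json(
    path: str | Path, records: Iterable[SpectrumMetrics], **metadata
) -> None:
    """Write metric records plus table-version metadata as JSON."""
    payload = {
        "table_versions": TABLE_VERSIONS,
        "metrics": [rec.as_dict() for rec in records],
    }
    payload.update(metadata)
    Path(path).write_text(json.dumps(payload, indent=1))
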