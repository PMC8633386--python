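"""Synthetic multi-channel LED luminaires and additive mixing.

Three presets emulate the channel rosters of a commercial tunable
multi-channel LED luminaire:

* ``6ch``  — narrowband 475/504/521/662 nm + phosphor whites 4655 K, 2740 K
* ``8ch``  — narrowband 450/465/504/521/638/662 nm + the two whites
* ``11ch`` — narrowband 419/450/457/504/521/597/638/662 nm + a lime
  phosphor channel + the two whites

Measured primaries of the real device are not published, so channels are
modelled: narrowband LEDs as Gaussian lineshapes (default FWHM 20 nm),
phosphor whites as a blue-pump Gaussian plus a broad phosphor Gaussian whose
centre/width/ratio are solved numerically to land on the Planckian locus at
the nominal CCT, and the lime phosphor as a broad Gaussian (550 nm,
FWHM 100 nm).  Channel spectra are normalised to unit radiometric power and
dimming is exactly linear in the per-channel weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from . import colorimetry as cm
from .colorimetry import Chromaticity, Spectrum
from .grid import ChromaticityTarget
from .tables import N_WAVELENGTHS, WAVELENGTHS

__all__ = [
    "LEDChannel",
    "LuminaireConfig",
    "gaussian_primary",
    "phosphor_white",
    "lime_phosphor",
    "build_luminaire",
    "mix",
    "random_feasible_target",
    "PRESETS",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ModelFitError(RuntimeError):
    """Raised when the phosphor-white solver fails to reach its target."""


@dataclass(frozen=True)
class LEDChannel:
    """One LED primary at full drive.

    ``peak_nm`` holds the nominal narrowband peak, or the nominal CCT in
    kelvin for phosphor white channels.  The SPD is normalised to unit
    radiometric power (Σ values · Δλ = 1 W·m⁻²).
    """

    name: str
    kind: str  # narrowband | phosphor_white | phosphor_lime
    peak_nm: float
    spd: Spectrum

    def __post_init__(self) -> None:
        if self.kind not in ("narrowband", "phosphor_white", "phosphor_lime"):
            raise ValueError(f"unknown channel kind {self.kind!r}")


@dataclass(frozen=True)
class LuminaireConfig:
    """An ordered set of LED channels mixed additively."""

    name: str
    channels: tuple[LEDChannel, ...]
    max_active: int = 0  # 0 means "all channels may be active"

    def __post_init__(self) -> None:
        if self.max_active == 0:
            object.__setattr__(self, "max_active", len(self.channels))
        if not 1 <= self.max_active <= len(self.channels):
            raise ValueError("max_active must be within 1..n_channels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_matrix(self) -> np.ndarray:
        """(n_channels, 401) stack of channel SPDs."""
        return np.stack([ch.spd.values for ch in self.channels])

    def describe(self) -> list[dict]:
        return [
            {"name": ch.name, "kind": ch.kind, "peak_nm": ch.peak_nm}
            for ch in self.channels
        ]

    def to_yaml(self, path: str | Path) -> None:
        payload = {"name": self.name, "channels": self.describe(),
                   "max_active": self.max_active}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _unit_power(values: np.ndarray) -> np.ndarray:
    total = values.sum()  # Δλ = 1 nm
    if total <= 0:
        raise ValueError("channel spectrum has no power")
    return values / total


def gaussian_primary(
    peak_nm: float, fwhm_nm: float = 20.0, name: str | None = None
) -> LEDChannel:
    """Narrowband LED modelled as a Gaussian lineshape on the grid."""
    if not 380.0 < peak_nm < 780.0:
        raise ValueError(f"peak {peak_nm} nm outside the 380-780 nm grid")
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    values = np.exp(-0.5 * ((WAVELENGTHS - peak_nm) / sigma) ** 2)
    return LEDChannel(
        name=name or f"led_{peak_nm:.0f}nm",
        kind="narrowband",
        peak_nm=float(peak_nm),
        spd=Spectrum(_unit_power(values)),
    )


def _white_model(params: np.ndarray) -> np.ndarray:
    centre, width, ratio = params
    pump = np.exp(-0.5 * ((WAVELENGTHS - 450.0) / (20.0 * _FWHM_TO_SIGMA)) ** 2)
    phosphor = np.exp(
        -0.5 * ((WAVELENGTHS - centre) / (width * _FWHM_TO_SIGMA)) ** 2
    )
    return pump / pump.sum() + ratio * phosphor / phosphor.sum()


def phosphor_white(target_cct: float, name: str | None = None) -> LEDChannel:
    """Phosphor-converted white LED hitting the locus at ``target_cct``.

    A 450 nm blue pump plus one broad phosphor Gaussian; centre, width and
    pump-to-phosphor ratio are solved so the channel chromaticity lands on
    the Planckian locus at the nominal CCT (|ΔCCT| ≤ 50 K, |Duv| ≤ 0.005).
    """
    if not 2000.0 <= target_cct <= 8000.0:
        raise ValueError(f"white CCT {target_cct} outside 2000-8000 K")
    target = cm.locus_point(target_cct)
    target_uv = np.array([target.u_prime, 2.0 / 3.0 * target.v_prime])

    def residuals(params: np.ndarray) -> np.ndarray:
        chrom = cm.chromaticity(_white_model(params))
        uv = np.array([chrom.u_prime, 2.0 / 3.0 * chrom.v_prime])
        # third residual mildly regularises the underdetermined width
        return np.array([
            1e3 * (uv[0] - target_uv[0]),
            1e3 * (uv[1] - target_uv[1]),
            1e-2 * (params[1] - 115.0) / 115.0,
        ])

    x0 = np.array([640.0 - 0.02 * (target_cct - 2700.0), 115.0, 4.0])
    sol = least_squares(
        residuals, x0,
        bounds=([500.0, 60.0, 0.05], [700.0, 180.0, 50.0]),
    )
    values = _unit_power(_white_model(sol.x))
    chrom = cm.chromaticity(values)
    cct, duv = cm.cct_duv(chrom.u_prime, chrom.v_prime)
    if abs(cct - target_cct) > 50.0 or abs(duv) > 0.005:
        raise ModelFitError(
            f"white solver missed {target_cct} K: got {cct:.0f} K, "
            f"Duv {duv:+.4f}"
        )
    return LEDChannel(
        name=name or f"white_{target_cct:.0f}K",
        kind="phosphor_white",
        peak_nm=float(target_cct),
        spd=Spectrum(values),
    )


def lime_phosphor(name: str = "lime") -> LEDChannel:
    """Phosphor-converted lime channel: broad Gaussian, 550 nm / FWHM 100 nm."""
    sigma = 100.0 * _FWHM_TO_SIGMA
    values = np.exp(-0.5 * ((WAVELENGTHS - 550.0) / sigma) ** 2)
    return LEDChannel(
        name=name,
        kind="phosphor_lime",
        peak_nm=550.0,
        spd=Spectrum(_unit_power(values)),
    )


_NARROWBAND_PEAKS = {
    "6ch": (475, 504, 521, 662),
    "8ch": (450, 465, 504, 521, 638, 662),
    "11ch": (419, 450, 457, 504, 521, 597, 638, 662),
}

PRESETS = tuple(_NARROWBAND_PEAKS)

_WHITE_CACHE: dict[float, LEDChannel] = {}


def _shared_white(cct: float) -> LEDChannel:
    # the two whites are shared objects across presets
    if cct not in _WHITE_CACHE:
        _WHITE_CACHE[cct] = phosphor_white(cct)
    return _WHITE_CACHE[cct]


def build_luminaire(
    preset: str | int,
    fwhm_nm: float = 20.0,
    max_active: int = 0,
) -> LuminaireConfig:
    """Build one of the 6-, 8- or 11-channel presets."""
    key = f"{preset}ch" if isinstance(preset, int) else str(preset)
    if key not in _NARROWBAND_PEAKS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    channels = [
        gaussian_primary(float(peak), fwhm_nm)
        for peak in _NARROWBAND_PEAKS[key]
    ]
    if key == "11ch":
        channels.append(lime_phosphor())
    channels.append(_shared_white(4655.0))
    channels.append(_shared_white(2740.0))
    return LuminaireConfig(
        name=key, channels=tuple(channels), max_active=max_active
    )


def mix(config: LuminaireConfig, weights: Sequence[float]) -> Spectrum:
    """Additive mixture of channel SPDs with per-channel weights in [0, 1]."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (config.n_channels,):
        raise ValueError(
            f"expected {config.n_channels} weights, got shape {w.shape}"
        )
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("channel weights must lie in [0, 1]")
    return Spectrum(w @ config.channel_matrix())


def random_feasible_target(
    config: LuminaireConfig,
    rng_seed: int | np.random.Generator,
    illuminance_lx: float = 220.0,
    max_tries: int = 200,
) -> tuple[ChromaticityTarget, np.ndarray]:
    """Draw a chromaticity target that is achievable by construction.

    Random white-heavy channel weights are rescaled to the working
    illuminance; the mixture's chromaticity becomes the target and the
    generating weights are returned alongside it.  Deterministic in the
    seed.  Draws landing outside the CCT-definable region (|Duv| > 0.05)
    are rejected and redrawn.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    is_white = np.array(
        [ch.kind == "phosphor_white" for ch in config.channels]
    )
    for _ in range(max_tries):
        w = np.where(
            is_white,
            rng.uniform(0.3, 1.0, config.n_channels),
            rng.uniform(0.0, 0.35, config.n_channels),
        )
        spd = Spectrum(w @ config.channel_matrix())
        e_v = cm.illuminance(spd)
        if e_v <= 0:
            continue
        w = w * (illuminance_lx / e_v)
        if np.any(w > 1.0):
            continue
        chrom = cm.chromaticity(mix(config, w))
        try:
            target = ChromaticityTarget.from_chromaticity(chrom)
        except cm.CCTRangeError:
            continue
        return target, w
    raise RuntimeError("could not draw a feasible target; check the config")
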