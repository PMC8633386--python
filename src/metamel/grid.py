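"""Chromaticity-coordinate optimisation targets along the Planckian locus.

The default grid is 17 CCT levels from 2700 K to 7443 K, spaced uniformly in
u'v' arc length along the locus, each carrying 33 signed Duv offsets
{0, ±0.003, …, ±0.048} — 561 targets in total.  Duv offsets are taken
perpendicular to the locus in the CIE 1960 uv diagram (the space in which
Duv is defined), and every target records its chromaticity in both u'v' and
xy.  A ``spacing="mired"`` option places the CCT levels uniformly in
reciprocal temperature instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorimetry as cm
from .colorimetry import CCTRangeError, Chromaticity

__all__ = [
    "ChromaticityTarget",
    "planck_point",
    "duv_offset",
    "build_grid",
    "grid_to_csv",
    "grid_from_csv",
]


@dataclass(frozen=True)
class ChromaticityTarget:
    """One optimisation objective: a chromaticity at (cct, duv)."""

    cct: float
    duv: float
    u_prime: float
    v_prime: float
    x: float
    y: float
    cct_level: int = -1
    duv_level: int = 0

    @property
    def index(self) -> tuple[int, int]:
        return (self.cct_level, self.duv_level)

    @classmethod
    def from_chromaticity(
        cls,
        chrom: Chromaticity,
        cct_level: int = -1,
        duv_level: int = 0,
    ) -> "ChromaticityTarget":
        cct, duv = cm.cct_duv(chrom.u_prime, chrom.v_prime)
        return cls(
            cct=cct,
            duv=duv,
            u_prime=chrom.u_prime,
            v_prime=chrom.v_prime,
            x=chrom.x,
            y=chrom.y,
            cct_level=cct_level,
            duv_level=duv_level,
        )


def planck_point(cct: float) -> Chromaticity:
    """Chromaticity of the blackbody radiator at ``cct`` (1000–20000 K)."""
    return cm.locus_point(cct)


def _nearest_locus_index(u: float, v: float) -> int:
    d = np.hypot(cm._LOCUS_UV[:, 0] - u, cm._LOCUS_UV[:, 1] - v)
    return int(np.argmin(d))


def duv_offset(base: Chromaticity, duv: float) -> Chromaticity:
    """Displace a chromaticity perpendicular to the Planckian locus.

    The offset is applied in the CIE 1960 uv diagram along the local locus
    normal, by the signed distance ``duv`` (positive above the locus), and
    converted back to u'v' / xy.  ``cct_duv`` of the result recovers the
    base CCT and ``duv`` within tolerance.
    """
    if abs(duv) > 0.05:
        raise ValueError(f"|duv| must be <= 0.05, got {duv}")
    u, v = base.u_prime, 2.0 / 3.0 * base.v_prime
    i = _nearest_locus_index(u, v)
    normal = cm._locus_normal(i)
    u_new = u + duv * normal[0]
    v_new = v + duv * normal[1]
    return cm._chromaticity_from_uv_prime(u_new, 1.5 * v_new)


def _cct_levels(
    n_cct: int, cct_min: float, cct_max: float, spacing: str
) -> np.ndarray:
    if cct_min > cct_max:
        raise ValueError("cct_min must not exceed cct_max")
    if n_cct == 1 or cct_min == cct_max:
        return np.linspace(cct_min, cct_max, n_cct)
    if spacing == "mired":
        return 1e6 / np.linspace(1e6 / cct_min, 1e6 / cct_max, n_cct)
    if spacing != "arc":
        raise ValueError(f"unknown spacing {spacing!r}")
    # uniform in u'v' arc position along the locus between the endpoints
    mask = (cm._LOCUS_CCT >= cct_min) & (cm._LOCUS_CCT <= cct_max)
    ccts = cm._LOCUS_CCT[mask][::-1]  # ascending CCT
    uv = cm._LOCUS_UV[mask][::-1]
    du = np.diff(uv[:, 0])
    dv = 1.5 * np.diff(uv[:, 1])  # arc length measured in u'v'
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(du, dv))])
    positions = np.linspace(0.0, arc[-1], n_cct)
    levels = np.interp(positions, arc, ccts)
    levels[0], levels[-1] = cct_min, cct_max
    return levels


def build_grid(
    n_cct: int = 17,
    cct_min: float = 2700.0,
    cct_max: float = 7443.0,
    duv_max: float = 0.048,
    duv_step: float = 0.003,
    spacing: str = "arc",
) -> list[ChromaticityTarget]:
    """Construct the target grid: ``n_cct`` CCT levels × the Duv ladder.

    Defaults give 17 × 33 = 561 targets covering 2700–7443 K with Duv
    offsets {0, ±0.003, …, ±0.048}.
    """
    if n_cct < 1 or duv_max < 0 or duv_step <= 0:
        raise ValueError("grid parameters must be positive")
    n_steps = round(duv_max / duv_step)
    if abs(n_steps * duv_step - duv_max) > 1e-12:
        raise ValueError(
            f"duv_max {duv_max} is not an integer multiple of {duv_step}"
        )
    duv_levels = np.arange(-n_steps, n_steps + 1)
    targets: list[ChromaticityTarget] = []
    for level, cct in enumerate(_cct_levels(n_cct, cct_min, cct_max, spacing)):
        base = planck_point(float(cct))
        for duv_level in duv_levels:
            duv = float(duv_level * duv_step)
            chrom = duv_offset(base, duv) if duv_level else base
            targets.append(
                ChromaticityTarget(
                    cct=float(cct),
                    duv=duv,
                    u_prime=chrom.u_prime,
                    v_prime=chrom.v_prime,
                    x=chrom.x,
                    y=chrom.y,
                    cct_level=level,
                    duv_level=int(duv_level),
                )
            )
    return targets


_GRID_COLUMNS = [
    "cct_K", "duv", "u_prime", "v_prime", "x", "y", "cct_level", "duv_level",
]


def grid_to_csv(path: str | Path, targets: list[ChromaticityTarget]) -> None:
    rows = [
        (t.cct, t.duv, t.u_prime, t.v_prime, t.x, t.y, t.cct_level, t.duv_level)
        for t in targets
    ]
    pd.DataFrame(rows, columns=_GRID_COLUMNS).to_csv(path, index=False)


def grid_from_csv(path: str | Path) -> list[ChromaticityTarget]:
    frame = pd.read_csv(path)
    missing = set(_GRID_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
    return [
        ChromaticityTarget(
            cct=float(r.cct_K),
            duv=float(r.duv),
            u_prime=float(r.u_prime),
            v_prime=float(r.v_prime),
            x=float(r.x),
            y=float(r.y),
            cct_level=int(r.cct_level),
            duv_level=int(r.duv_level),
        )
        for r in frame.itertuples()
    ]
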