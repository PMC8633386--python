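"""Reduction of metamer sets into melanopic tuning-range metrics.

Per chromaticity target the melanopic EDI extremes of the metamer set give
the tuning range ΔE_mel = |E_mel,max − E_mel,min| (equivalently
Δγ = |γ_max − γ_min|, with ΔE = E_v·Δγ at the fixed output illuminance) and
the melanopic Michelson contrast
C_M = (E_mel,max − E_mel,min)/(E_mel,max + E_mel,min).  Per CCT, extremes
are also taken across the Duv ladder: γ̂_min/γ̂_max (the best reachable
non-metameric DERs at that CCT) and Δγ̃ (the largest same-chromaticity
tuning range), each with its arg-max Duv.  The atlas interpolates the
per-target fields over CIE xy and records the global maxima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from .grid import ChromaticityTarget
from .optimizer import MetamerSet

__all__ = [
    "TargetSummary",
    "CCTSummary",
    "Atlas",
    "michelson_contrast",
    "delta_e_at_lux",
    "summarize_target",
    "summarize_cct",
    "build_atlas",
    "summaries_to_csv",
    "summaries_from_csv",
    "cct_summaries_to_csv",
]


def michelson_contrast(e_min: float, e_max: float) -> float:
    """Michelson contrast (E_max − E_min)/(E_max + E_min) of an EDI pair."""
    if e_min < 0 or e_max < e_min:
        raise ValueError("require 0 <= e_min <= e_max")
    if e_max == 0:
        raise ValueError("contrast undefined when both extremes are zero")
    return (e_max - e_min) / (e_max + e_min)


def delta_e_at_lux(delta_gamma: float, e_v: float) -> float:
    """Melanopic EDI tuning range ΔE = E_v · Δγ at illuminance ``e_v``."""
    if delta_gamma < 0 or e_v < 0:
        raise ValueError("inputs must be non-negative")
    return delta_gamma * e_v


@dataclass(frozen=True)
class TargetSummary:
    """Melanopic tuning metrics of one chromaticity target."""

    target: ChromaticityTarget
    n_metamers: int
    e_mel_min: float
    e_mel_max: float
    delta_e_mel: float
    gamma_min: float
    gamma_max: float
    delta_gamma: float
    c_m: float


@dataclass(frozen=True)
class CCTSummary:
    """Per-CCT extremes across the Duv ladder."""

    cct: float
    cct_level: int
    n_targets: int
    gamma_hat_min: float
    gamma_hat_max: float
    delta_gamma_tilde: float
    duv_at_gamma_min: float
    duv_at_gamma_max: float
    duv_at_delta_gamma: float


def summarize_target(ms: MetamerSet) -> TargetSummary | None:
    """Scan a metamer set for its melanopic extremes.

    Returns ``None`` (the no-summary sentinel) for an empty set.  Ties are
    broken by first occurrence.
    """
    if ms.n == 0:
        return None
    edi = ms.melanopic_edis()
    e_min, e_max = float(edi.min()), float(edi.max())
    e_v = ms.output_illuminance
    return TargetSummary(
        target=ms.target,
        n_metamers=ms.n,
        e_mel_min=e_min,
        e_mel_max=e_max,
        delta_e_mel=abs(e_max - e_min),
        gamma_min=e_min / e_v,
        gamma_max=e_max / e_v,
        delta_gamma=abs(e_max - e_min) / e_v,
        c_m=michelson_contrast(e_min, e_max),
    )


def summarize_cct(summaries: list[TargetSummary]) -> CCTSummary | None:
    """Aggregate the summaries of one CCT level across its Duv offsets.

    γ̂_min/γ̂_max are the extreme DERs reachable at the CCT when Duv is a
    free parameter; Δγ̃ is the largest *same-chromaticity* tuning range,
    each recorded with the Duv at which it occurs (first occurrence on
    ties).
    """
    summaries = [s for s in summaries if s is not None]
    if not summaries:
        return None
    levels = {s.target.cct_level for s in summaries}
    if len(levels) != 1:
        raise ValueError("summaries must share one cct_level")
    g_min = min(summaries, key=lambda s: s.gamma_min)
    g_max = max(summaries, key=lambda s: s.gamma_max)
    dg = max(summaries, key=lambda s: s.delta_gamma)
    return CCTSummary(
        cct=summaries[0].target.cct,
        cct_level=summaries[0].target.cct_level,
        n_targets=len(summaries),
        gamma_hat_min=g_min.gamma_min,
        gamma_hat_max=g_max.gamma_max,
        delta_gamma_tilde=dg.delta_gamma,
        duv_at_gamma_min=g_min.target.duv,
        duv_at_gamma_max=g_max.target.duv,
        duv_at_delta_gamma=dg.target.duv,
    )


@dataclass(frozen=True)
class Atlas:
    """Interpolated tuning-range maps over CIE xy for one luminaire/criterion.

    ``delta_gamma_field`` and ``c_m_field`` are rasters over the regular
    (x_grid, y_grid) mesh, NaN outside the convex hull of the summarised
    targets (no extrapolation).  Global maxima are brute-force maxima over
    the raw per-target values; on ties the lowest (cct_level, duv_level)
    index wins.
    """

    luminaire: str
    criterion: str
    summaries: tuple[TargetSummary, ...]
    cct_summaries: tuple[CCTSummary, ...]
    x_grid: np.ndarray
    y_grid: np.ndarray
    delta_gamma_field: np.ndarray
    c_m_field: np.ndarray
    max_delta_gamma: TargetSummary
    max_c_m: TargetSummary
    metadata: dict = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summaries_to_csv(outdir / "target_summaries.csv", self.summaries)
        cct_summaries_to_csv(outdir / "cct_summaries.csv", self.cct_summaries)
        np.savetxt(outdir / "delta_gamma_field.csv",
                   self.delta_gamma_field, delimiter=",")
        np.savetxt(outdir / "c_m_field.csv", self.c_m_field, delimiter=",")
        payload = {
            "luminaire": self.luminaire,
            "criterion": self.criterion,
            "max_delta_gamma": {
                "value": self.max_delta_gamma.delta_gamma,
                "cct_K": self.max_delta_gamma.target.cct,
                "duv": self.max_delta_gamma.target.duv,
                "x": self.max_delta_gamma.target.x,
                "y": self.max_delta_gamma.target.y,
            },
            "max_c_m": {
                "value": self.max_c_m.c_m,
                "cct_K": self.max_c_m.target.cct,
                "duv": self.max_c_m.target.duv,
                "x": self.max_c_m.target.x,
                "y": self.max_c_m.target.y,
            },
            "x_range": [float(self.x_grid.min()), float(self.x_grid.max())],
            "y_range": [float(self.y_grid.min()), float(self.y_grid.max())],
        }
        payload.update(self.metadata)
        (outdir / "atlas.json").write_text(json.dumps(payload, indent=1))

    def plot(self, path: str | Path, which: str = "delta_gamma") -> None:
        """Optional heatmap export (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fld = (self.delta_gamma_field if which == "delta_gamma"
               else self.c_m_field)
        best = (self.max_delta_gamma if which == "delta_gamma"
                else self.max_c_m)
        fig, ax = plt.subplots(figsize=(5, 4))
        pm = ax.pcolormesh(self.x_grid, self.y_grid, fld, shading="auto")
        ax.plot(best.target.x, best.target.y, "ro", ms=6)
        ax.set_xlabel("CIE x")
        ax.set_ylabel("CIE y")
        ax.set_title(f"{which} — {self.luminaire}, {self.criterion}")
        fig.colorbar(pm, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _tie_key(s: TargetSummary) -> tuple:
    return (s.target.cct_level, s.target.duv_level)


def build_atlas(
    summaries: list[TargetSummary | None],
    luminaire: str = "",
    criterion: str = "",
    resolution: int = 120,
    metadata: dict | None = None,
    strict: bool = True,
) -> Atlas:
    """Interpolate per-target fields over CIE xy and locate global maxima.

    With ``strict=False`` a degenerate layout (fewer than 3 summarised
    targets, or collinear ones) yields NaN rasters instead of an error; the
    summaries and brute-force maxima are still populated.
    """
    kept = sorted((s for s in summaries if s is not None), key=_tie_key)
    if not kept:
        raise ValueError("no summarised targets at all; atlas undefined")
    pts = np.array([(s.target.x, s.target.y) for s in kept])
    degenerate = (
        len(kept) < 3
        or np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-12) < 2
    )
    if degenerate and strict:
        if len(kept) < 3:
            raise ValueError("need at least 3 summarised targets for an atlas")
        raise ValueError("targets are collinear; atlas undefined")
    xg = np.linspace(pts[:, 0].min(), pts[:, 0].max(), resolution)
    yg = np.linspace(pts[:, 1].min(), pts[:, 1].max(), resolution)
    mesh = np.meshgrid(xg, yg)
    if degenerate:
        dg_field = np.full((resolution, resolution), np.nan)
        cm_field = np.full((resolution, resolution), np.nan)
    else:
        dg = np.array([s.delta_gamma for s in kept])
        c_m = np.array([s.c_m for s in kept])
        dg_field = griddata(pts, dg, tuple(mesh), method="linear")
        cm_field = griddata(pts, c_m, tuple(mesh), method="linear")
    max_dg = max(kept, key=lambda s: (s.delta_gamma, ))
    max_cm = max(kept, key=lambda s: (s.c_m, ))
    # first occurrence in (cct_level, duv_level) order wins on exact ties
    max_dg = next(s for s in kept if s.delta_gamma == max_dg.delta_gamma)
    max_cm = next(s for s in kept if s.c_m == max_cm.c_m)
    grouped: dict[int, list[TargetSummary]] = {}
    for s in kept:
        grouped.setdefault(s.target.cct_level, []).append(s)
    cct_summaries = tuple(
        cs for level in sorted(grouped)
        if (cs := summarize_cct(grouped[level])) is not None
    )
    return Atlas(
        luminaire=luminaire,
        criterion=criterion,
        summaries=tuple(kept),
        cct_summaries=cct_summaries,
        x_grid=xg,
        y_grid=yg,
        delta_gamma_field=dg_field,
        c_m_field=cm_field,
        max_delta_gamma=max_dg,
        max_c_m=max_cm,
        metadata=metadata or {},
    )


_SUMMARY_COLUMNS = [
    "cct_K", "duv", "u_prime", "v_prime", "x", "y", "cct_level", "duv_level",
    "n_metamers", "e_mel_min_lx", "e_mel_max_lx", "delta_e_mel_lx",
    "gamma_min", "gamma_max", "delta_gamma", "c_m",
]


def summaries_to_csv(
    path: str | Path, summaries: tuple[TargetSummary, ...]
) -> None:
    rows = [
        (
            s.target.cct, s.target.duv, s.target.u_prime, s.target.v_prime,
            s.target.x, s.target.y, s.target.cct_level, s.target.duv_level,
            s.n_metamers, s.e_mel_min, s.e_mel_max, s.delta_e_mel,
            s.gamma_min, s.gamma_max, s.delta_gamma, s.c_m,
        )
        for s in summaries
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLUMNS).to_csv(path, index=False)


def summaries_from_csv(path: str | Path) -> list[TargetSummary]:
    frame = pd.read_csv(path)
    out = []
    for r in frame.itertuples():
        target = ChromaticityTarget(
            cct=float(r.cct_K), duv=float(r.duv),
            u_prime=float(r.u_prime), v_prime=float(r.v_prime),
            x=float(r.x), y=float(r.y),
            cct_level=int(r.cct_level), duv_level=int(r.duv_level),
        )
        out.append(TargetSummary(
            target=target, n_metamers=int(r.n_metamers),
            e_mel_min=float(r.e_mel_min_lx), e_mel_max=float(r.e_mel_max_lx),
            delta_e_mel=float(r.delta_e_mel_lx),
            gamma_min=float(r.gamma_min), gamma_max=float(r.gamma_max),
            delta_gamma=float(r.delta_gamma), c_m=float(r.c_m),
        ))
    return out


def cct_summaries_to_csv(
    path: str | Path, summaries: tuple[CCTSummary, ...]
) -> None:
    rows = [
        (
            s.cct, s.cct_level, s.n_targets, s.gamma_hat_min, s.gamma_hat_max,
            s.delta_gamma_tilde, s.duv_at_gamma_min, s.duv_at_gamma_max,
            s.duv_at_delta_gamma,
        )
        for s in summaries
    ]
    pd.DataFrame(rows, columns=[
        "cct_K", "cct_level", "n_targets", "gamma_hat_min", "gamma_hat_max",
        "delta_gamma_tilde", "duv_at_gamma_min", "duv_at_gamma_max",
        "duv_at_delta_gamma",
    ]).to_csv(path, index=False)
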