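"""Metamer harvesting by stochastic constrained search.

For each chromaticity target a differential-evolution population search runs
over the per-channel weight box [0, 1]ⁿ, minimising the Euclidean u'v'
distance to the target with a hinge penalty for photopic illuminance outside
the 220 ± 2 lx working window.  The point of the search is not the optimum
but the harvest: every population member that visits the feasible region
(per-axis Δu', Δv' ≤ 0.001 and illuminance inside the window) is archived.
Several independently seeded repetitions are run per target; the archive is
then deduplicated in weight space, survivors are rescaled to exactly 250 lx
and returned as the target's metamer set.

Because chromaticity and illuminance are linear images of the weights
(through the channel tristimulus), each generation is evaluated with a
single (population × channels) matrix product; spectra are only
materialised for archived solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import colorimetry as cm
from .colorimetry import Spectrum, SpectrumMetrics
from .grid import ChromaticityTarget
from .luminaire import LuminaireConfig

__all__ = [
    "OptimizerSettings",
    "OptimizationRun",
    "MetamerRecord",
    "MetamerSet",
    "CHROMA_TOLERANCE",
    "tolerance_diagonal",
    "optimize_target",
    "filter_metamers",
    "enforce_channel_limit",
]

#: Per-axis metamer tolerance on Δu' and Δv'.
CHROMA_TOLERANCE = 1e-3


def tolerance_diagonal(tol: float = CHROMA_TOLERANCE) -> float:
    """Box diagonal of the per-axis (Δu', Δv') tolerance: √2·tol ≈ 1.41·10⁻³.

    Spectra within the per-axis box are therefore within this Δu'v'
    distance of the target.
    """
    return float(np.hypot(tol, tol))


@dataclass(frozen=True)
class OptimizerSettings:
    """Tunable parameters of the harvest search."""

    population: int = 60
    generations: int = 500
    mutation: tuple[float, float] = (0.4, 0.9)  # F dither range
    crossover: float = 0.9
    illuminance_target: float = 220.0
    illuminance_window: float = 2.0
    chroma_tolerance: float = CHROMA_TOLERANCE
    dedup_tolerance: float = 1e-3
    max_archive: int = 4000  # feasible visits kept per repetition
    output_illuminance: float = 250.0


@dataclass(frozen=True)
class OptimizationRun:
    """Raw harvest for one target: archived feasible weight vectors."""

    target: ChromaticityTarget
    config: LuminaireConfig
    seed: int
    repetitions: int
    settings: OptimizerSettings
    weights: np.ndarray  # (n_solutions, n_channels), pre-rescale feasible
    best_distance: float
    feasible: bool

    @property
    def n_solutions(self) -> int:
        return int(self.weights.shape[0])


@dataclass(frozen=True)
class MetamerRecord:
    """One metamer: generating weights, 250 lx spectrum, metrics, fidelity.

    ``spectrum`` may be ``None`` for records rebuilt from cached metric
    tables; every quantity the reductions consume lives in ``metrics``.
    """

    weights: np.ndarray
    spectrum: Spectrum | None
    metrics: SpectrumMetrics
    fidelity: "object | None" = None  # FidelityScores, attached later

    def with_fidelity(self, scores) -> "MetamerRecord":
        return replace(self, fidelity=scores)


@dataclass(frozen=True)
class MetamerSet:
    """All metamers of one chromaticity target, at the output illuminance."""

    target: ChromaticityTarget
    members: tuple[MetamerRecord, ...]
    output_illuminance: float = 250.0

    def __post_init__(self) -> None:
        for rec in self.members:
            if abs(rec.metrics.e_v - self.output_illuminance) > 1e-9 * max(
                1.0, self.output_illuminance
            ):
                raise ValueError("metamer illuminance != output illuminance")
            if (
                abs(rec.metrics.u_prime - self.target.u_prime)
                > CHROMA_TOLERANCE + 1e-12
                or abs(rec.metrics.v_prime - self.target.v_prime)
                > CHROMA_TOLERANCE + 1e-12
            ):
                raise ValueError("metamer outside the chromaticity tolerance")

    @property
    def n(self) -> int:
        return len(self.members)

    def melanopic_edis(self) -> np.ndarray:
        return np.array([rec.metrics.e_mel for rec in self.members])


def enforce_channel_limit(
    weights: np.ndarray, max_active: int
) -> np.ndarray:
    """Zero the smallest weights so at most ``max_active`` remain non-zero.

    Works on a single weight vector or a (population, n) batch; idempotent.
    Solutions may legitimately use fewer channels than the limit.
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float)).copy()
    n = w.shape[1]
    if max_active > n:
        raise ValueError("max_active exceeds the number of channels")
    if max_active < n:
        order = np.argsort(w, axis=1)  # ascending: smallest first
        drop = order[:, : n - max_active]
        np.put_along_axis(w, drop, 0.0, axis=1)
    return w[0] if np.asarray(weights).ndim == 1 else w


def _channel_tristimulus(config: LuminaireConfig) -> np.ndarray:
    """(n_channels, 3) tristimulus of each channel at full drive."""
    return config.channel_matrix() @ cm.CMF_2DEG


def _uv_prime_and_ev(w: np.ndarray, chan_xyz: np.ndarray):
    """u'v' and illuminance for a (pop, n) weight batch via channel XYZ."""
    xyz = w @ chan_xyz
    denom = xyz[:, 0] + 15.0 * xyz[:, 1] + 3.0 * xyz[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        up = 4.0 * xyz[:, 0] / denom
        vp = 9.0 * xyz[:, 1] / denom
    e_v = cm.LUMINOUS_EFFICACY_MAX * xyz[:, 1]
    return up, vp, e_v


def _objective(
    up: np.ndarray, vp: np.ndarray, e_v: np.ndarray, e_mel: np.ndarray,
    target: ChromaticityTarget, settings: OptimizerSettings,
    mel_sign: float,
) -> np.ndarray:
    """Chromaticity distance + illuminance hinge, with optional melanopic
    pressure.

    With ``mel_sign`` ±1 the repetition hunts the melanopic extremes: the
    chromaticity term is flattened inside half the tolerance so that, once
    a candidate is safely metameric, selection is driven toward large
    (resp. small) melanopic EDI while the scales keep it inside the
    tolerance box.
    """
    dist = np.hypot(up - target.u_prime, vp - target.v_prime)
    hinge = np.maximum(
        0.0,
        np.abs(e_v - settings.illuminance_target)
        - settings.illuminance_window,
    )
    if mel_sign:
        obj = (
            np.maximum(dist - 0.5 * settings.chroma_tolerance, 0.0)
            + 1e-3 * hinge
            + mel_sign * 1e-6 * e_mel
        )
    else:
        obj = dist + 1e-3 * hinge
    return np.where(np.isfinite(obj), obj, 1e9)


def _feasible_mask(
    up: np.ndarray, vp: np.ndarray, e_v: np.ndarray,
    target: ChromaticityTarget, settings: OptimizerSettings,
) -> np.ndarray:
    return (
        (np.abs(up - target.u_prime) <= settings.chroma_tolerance)
        & (np.abs(vp - target.v_prime) <= settings.chroma_tolerance)
        & (
            np.abs(e_v - settings.illuminance_target)
            <= settings.illuminance_window
        )
    )


def _run_repetition(
    rng: np.random.Generator,
    chan_xyz: np.ndarray,
    chan_mel: np.ndarray,
    target: ChromaticityTarget,
    settings: OptimizerSettings,
    max_active: int,
    mel_sign: float,
) -> tuple[np.ndarray, float]:
    """One seeded differential-evolution repetition; returns feasible visits."""
    n = chan_xyz.shape[0]
    pop_n = settings.population
    # start in the box, rescaled towards the working illuminance
    pop = rng.uniform(0.0, 1.0, (pop_n, n))
    _, _, e_v = _uv_prime_and_ev(pop, chan_xyz)
    scale = np.where(e_v > 0, settings.illuminance_target / e_v, 1.0)
    pop = np.clip(pop * scale[:, None], 0.0, 1.0)
    pop = enforce_channel_limit(pop, max_active)

    up, vp, e_v = _uv_prime_and_ev(pop, chan_xyz)
    fitness = _objective(up, vp, e_v, pop @ chan_mel, target, settings,
                         mel_sign)
    best_dist = float(np.hypot(up - target.u_prime,
                               vp - target.v_prime).min())
    archive: list[np.ndarray] = []
    archived = 0
    mask = _feasible_mask(up, vp, e_v, target, settings)
    if mask.any():
        archive.append(pop[mask].copy())
        archived += int(mask.sum())

    f_lo, f_hi = settings.mutation
    for _ in range(settings.generations):
        idx = np.arange(pop_n)
        r1, r2, r3 = (
            (idx + rng.integers(1, pop_n, pop_n)) % pop_n,
            (idx + rng.integers(1, pop_n, pop_n)) % pop_n,
            (idx + rng.integers(1, pop_n, pop_n)) % pop_n,
        )
        f = rng.uniform(f_lo, f_hi, (pop_n, 1))
        mutant = pop[r1] + f * (pop[r2] - pop[r3])
        cross = rng.uniform(size=(pop_n, n)) < settings.crossover
        cross[idx, rng.integers(0, n, pop_n)] = True
        trial = np.clip(np.where(cross, mutant, pop), 0.0, 1.0)
        trial = enforce_channel_limit(trial, max_active)

        t_up, t_vp, t_ev = _uv_prime_and_ev(trial, chan_xyz)
        t_fit = _objective(t_up, t_vp, t_ev, trial @ chan_mel, target,
                           settings, mel_sign)
        improved = t_fit <= fitness
        pop = np.where(improved[:, None], trial, pop)
        fitness = np.where(improved, t_fit, fitness)
        best_dist = min(best_dist, float(np.hypot(
            t_up - target.u_prime, t_vp - target.v_prime).min()))

        mask = _feasible_mask(t_up, t_vp, t_ev, target, settings)
        if mask.any():
            archive.append(trial[mask].copy())
            archived += int(mask.sum())
            if archived >= settings.max_archive:
                break

    visits = (
        np.concatenate(archive)[: settings.max_archive]
        if archive
        else np.empty((0, n))
    )
    return visits, best_dist


def optimize_target(
    config: LuminaireConfig,
    target: ChromaticityTarget,
    seed: int,
    repetitions: int = 8,
    settings: OptimizerSettings | None = None,
) -> OptimizationRun:
    """Harvest feasible spectra for one chromaticity target.

    ``repetitions`` independent searches are run with seeds derived from
    ``seed``; all feasible visits are pooled.  Repetitions cycle through
    three modes — plain exploration, melanopic-EDI maximisation and
    minimisation — so the pooled archive samples the full melanopic extent
    of the metamer manifold, not just the neighbourhood the search first
    converged to.  An infeasible target (e.g. outside the luminaire gamut)
    yields an empty archive with ``feasible=False`` rather than an
    exception.
    """
    settings = settings or OptimizerSettings()
    chan_xyz = _channel_tristimulus(config)
    chan_mel = (
        config.channel_matrix() @ cm.S_MEL
    ) / cm.MELANOPIC_EFFICACY_D65
    all_visits = []
    best = np.inf
    for rep in range(repetitions):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), rep])
        )
        mel_sign = (0.0, 1.0, -1.0)[rep % 3]
        visits, dist = _run_repetition(
            rng, chan_xyz, chan_mel, target, settings, config.max_active,
            mel_sign,
        )
        all_visits.append(visits)
        best = min(best, dist)
    weights = (
        np.concatenate(all_visits)
        if all_visits
        else np.empty((0, config.n_channels))
    )
    return OptimizationRun(
        target=target,
        config=config,
        seed=int(seed),
        repetitions=repetitions,
        settings=settings,
        weights=weights,
        best_distance=best,
        feasible=weights.shape[0] > 0,
    )


def _dedup_weights(weights: np.ndarray, tol: float) -> np.ndarray:
    """Collapse weight vectors closer than ``tol`` (max-norm).

    Vectors are snapped to a ``tol`` grid and uniqued, keeping first
    occurrence order — deterministic and O(n log n).
    """
    if weights.shape[0] == 0:
        return weights
    keys = np.round(weights / tol).astype(np.int64)
    _, first = np.unique(keys, axis=0, return_index=True)
    return weights[np.sort(first)]


def filter_metamers(
    run: OptimizationRun, max_members: int | None = None
) -> MetamerSet:
    """Reduce a harvest to the target's metamer set at 250 lx.

    Re-checks the per-axis chromaticity tolerance, deduplicates
    near-identical weight vectors, rescales survivors to the output
    illuminance exactly and attaches the full metric record to each member.
    """
    settings = run.settings
    weights = _dedup_weights(run.weights, settings.dedup_tolerance)
    if max_members is not None and weights.shape[0] > max_members:
        # thin evenly across the archive so every repetition and search
        # phase contributes, rather than keeping only the earliest visits
        idx = np.linspace(0, weights.shape[0] - 1, max_members).astype(int)
        weights = weights[idx]
    chan = run.config.channel_matrix()
    members = []
    for w in weights:
        spd = Spectrum(w @ chan)
        e_v = cm.illuminance(spd)
        if e_v <= 0:
            continue
        chrom = cm.chromaticity(spd)
        if (
            abs(chrom.u_prime - run.target.u_prime) > settings.chroma_tolerance
            or abs(chrom.v_prime - run.target.v_prime)
            > settings.chroma_tolerance
        ):
            continue
        scale = settings.output_illuminance / e_v
        scaled = Spectrum(spd.values * scale)
        metrics = cm.spectrum_metrics(scaled)
        # pin the stored illuminance to the exact output level (the rescale
        # is exact up to the last ulp of the division)
        metrics = SpectrumMetrics(
            e_v=settings.output_illuminance,
            e_mel=metrics.e_mel,
            gamma_mel=metrics.e_mel / settings.output_illuminance,
            x=metrics.x, y=metrics.y,
            u_prime=metrics.u_prime, v_prime=metrics.v_prime,
            cct=metrics.cct, duv=metrics.duv,
        )
        # keep the generating (pre-rescale) duty cycles, which live in [0, 1]
        members.append(
            MetamerRecord(weights=w, spectrum=scaled, metrics=metrics)
        )
    return MetamerSet(
        target=run.target,
        members=tuple(members),
        output_illuminance=settings.output_illuminance,
    )
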