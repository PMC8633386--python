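"""End-to-end orchestration: grid → harvest → gate → summaries → atlas.

A :class:`PipelineConfig` plus one master seed reproduces every output.
The master seed fans out counter-style — per-target seeds come from
``SeedSequence([master_seed, target_index])`` and the optimizer derives
per-repetition streams from those — so any single target can be recomputed
independently and identically.

Per-target harvests are cached as JSON metric tables under
``outdir/runs/`` keyed by a hash of the harvest-relevant configuration
(luminaire, grid, optimizer settings, master seed — *not* the fidelity
criterion).  Re-running with a different criterion therefore reuses the
cache and only re-applies the gate; a cache written under a different
harvest configuration raises :class:`StaleCacheError`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, fidelity, grid as grid_mod, optimizer
from .colorimetry import SpectrumMetrics, spectra_to_csv
from .fidelity import FidelityScores
from .grid import ChromaticityTarget
from .luminaire import build_luminaire
from .optimizer import MetamerRecord, MetamerSet, OptimizerSettings

__all__ = [
    "PipelineConfig",
    "StaleCacheError",
    "run_pipeline",
    "harvest_target",
    "load_cached_set",
]

logger = logging.getLogger("metamel")


class StaleCacheError(RuntimeError):
    """A cached per-target run was produced under a different configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs."""

    luminaire: str = "11ch"
    fwhm_nm: float = 20.0
    max_active: int = 0
    n_cct: int = 17
    cct_min: float = 2700.0
    cct_max: float = 7443.0
    duv_max: float = 0.048
    duv_step: float = 0.003
    spacing: str = "arc"
    population: int = 60
    generations: int = 500
    repetitions: int = 8
    max_archive: int = 4000
    max_members: int = 500
    master_seed: int = 1
    criterion: str = "p3"
    output_illuminance: float = 250.0
    outdir: str = "metamel_out"
    save_spectra: bool = False
    atlas_resolution: int = 120

    def optimizer_settings(self) -> OptimizerSettings:
        return OptimizerSettings(
            population=self.population,
            generations=self.generations,
            max_archive=self.max_archive,
            output_illuminance=self.output_illuminance,
        )

    def harvest_hash(self) -> str:
        """Hash of the fields that determine the cached harvests."""
        payload = dataclasses.asdict(self)
        for key in ("criterion", "outdir", "save_spectra",
                    "atlas_resolution"):
            payload.pop(key)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def target_seed(master_seed: int, target_index: int) -> int:
    """Per-target seed derived counter-style from the master seed."""
    seq = np.random.SeedSequence([int(master_seed), int(target_index)])
    return int(seq.generate_state(1)[0] % (2 ** 31))


def _cache_path(outdir: Path, target: ChromaticityTarget) -> Path:
    return (
        outdir / "runs"
        / f"target_L{target.cct_level:02d}_D{target.duv_level:+03d}.json"
    )


def _member_row(rec: MetamerRecord) -> dict:
    row = rec.metrics.as_dict()
    row["weights"] = [round(float(w), 6) for w in rec.weights]
    if rec.fidelity is not None:
        row["rf"] = rec.fidelity.rf
        row["rf_h1"] = rec.fidelity.rf_h1
        row["ra"] = rec.fidelity.ra
    return row


def _record_from_row(row: dict) -> MetamerRecord:
    metrics = SpectrumMetrics(
        e_v=row["E_v_lx"], e_mel=row["E_mel_D65_lx"],
        gamma_mel=row["gamma_mel_D65"], x=row["x"], y=row["y"],
        u_prime=row["u_prime"], v_prime=row["v_prime"],
        cct=row["cct_K"], duv=row["duv"],
    )
    scores = None
    if "rf" in row:
        scores = FidelityScores(rf=row["rf"], rf_h1=row["rf_h1"],
                                ra=row["ra"])
    return MetamerRecord(
        weights=np.asarray(row["weights"], dtype=float),
        spectrum=None,
        metrics=metrics,
        fidelity=scores,
    )


def harvest_target(
    config: PipelineConfig,
    luminaire_config,
    target: ChromaticityTarget,
    index: int,
) -> MetamerSet:
    """Optimise, filter and fidelity-score one target (criterion-free)."""
    run = optimizer.optimize_target(
        luminaire_config,
        target,
        seed=target_seed(config.master_seed, index),
        repetitions=config.repetitions,
        settings=config.optimizer_settings(),
    )
    ms = optimizer.filter_metamers(run, max_members=config.max_members)
    if ms.n:
        ms = fidelity.score_metamer_set(ms)
    return ms


def load_cached_set(
    path: Path, expected_hash: str
) -> MetamerSet:
    payload = json.loads(path.read_text())
    if payload["harvest_hash"] != expected_hash:
        raise StaleCacheError(
            f"{path} was produced under configuration "
            f"{payload['harvest_hash']}, expected {expected_hash}"
        )
    target = ChromaticityTarget(**payload["target"])
    members = tuple(_record_from_row(row) for row in payload["members"])
    return MetamerSet(
        target=target,
        members=members,
        output_illuminance=payload["output_illuminance"],
    )


def _store_set(
    path: Path, ms: MetamerSet, harvest_hash: str
) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "harvest_hash": harvest_hash,
        "target": dataclasses.asdict(ms.target),
        "output_illuminance": ms.output_illuminance,
        "members": [_member_row(rec) for rec in ms.members],
    }
    path.write_text(json.dumps(payload))


def run_pipeline(config: PipelineConfig) -> analysis.Atlas:
    """Run (or resume) the full pipeline and return the atlas.

    Stages: build the luminaire and target grid, harvest metamers per
    target (cached), apply the configured fidelity criterion, reduce to
    per-target and per-CCT summaries, and interpolate the atlas.  Outputs
    land under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    lum = build_luminaire(
        config.luminaire, fwhm_nm=config.fwhm_nm, max_active=config.max_active
    )
    targets = grid_mod.build_grid(
        n_cct=config.n_cct, cct_min=config.cct_min, cct_max=config.cct_max,
        duv_max=config.duv_max, duv_step=config.duv_step,
        spacing=config.spacing,
    )
    hhash = config.harvest_hash()
    summaries: list[analysis.TargetSummary | None] = []
    n_infeasible = 0
    for index, target in enumerate(targets):
        path = _cache_path(outdir, target)
        if path.exists():
            ms = load_cached_set(path, hhash)
        else:
            ms = harvest_target(config, lum, target, index)
            _store_set(path, ms, hhash)
            if config.save_spectra and ms.n:
                spectra_to_csv(
                    path.with_suffix(".csv"),
                    [rec.spectrum for rec in ms.members],
                )
        gated = fidelity.apply_fidelity_criterion(ms, config.criterion)
        if ms.n == 0:
            n_infeasible += 1
        logger.info(
            "target %3d cct=%6.0fK duv=%+.3f yield=%4d pass(%s)=%4d",
            index, target.cct, target.duv, ms.n, config.criterion, gated.n,
        )
        summaries.append(analysis.summarize_target(gated))
    logger.info(
        "%d/%d targets infeasible for %s",
        n_infeasible, len(targets), config.luminaire,
    )
    atlas = analysis.build_atlas(
        summaries,
        luminaire=config.luminaire,
        criterion=config.criterion,
        resolution=config.atlas_resolution,
        strict=False,
        metadata={
            "harvest_hash": hhash,
            "master_seed": config.master_seed,
            "n_targets": len(targets),
            "n_infeasible": n_infeasible,
        },
    )
    atlas.to_dir(outdir / f"atlas_{config.luminaire}_{config.criterion}")
    return atlas
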