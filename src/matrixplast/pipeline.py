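"""End-to-end pipeline orchestration.

A single :class:`RunConfig` (loadable from YAML/JSON) selects stages and
parameters; :func:`run_pipeline` executes them in dependency order on
synthetic inputs and writes every table under a run directory, with a
manifest (config hash, package version, per-stage outputs, collected
warnings) at its root.  One top-level seed fans out to per-stage child seeds
through ``numpy.random.SeedSequence(seed).spawn``, so any stage can be re-run
independently yet reproducibly.

Stages: ``materials`` (creep-recovery + decomposition + yield bounding and
indentation cycles), ``displacement`` (bead pair -> PIV -> averaged map ->
stress), ``motility`` (tracks -> classification -> probability / speeds),
``morphology`` (shape masks -> circularity), ``transport`` (partition
coefficients + optics).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .cells import circularity, classify_motile, max_speed, motility_probability
from .displacement import (average_displacement_map, max_matrix_displacement,
                           piv_displacement_field)
from .rheology import (decompose_creep_recovery, estimate_yield_stress,
                       indentation_plasticity)
from .stress import hooke_stress, principal_stress, strain_field
from .rheology import ElasticParams
from .synth.beads import FieldSpec, generate_bead_image_pair
from .synth.indentation import simulate_indentation_cycles
from .synth.shapes import generate_shape_mask
from .synth.tracks import TrackSimParams, generate_tracks, tracks_to_table
from .synth.viscoplastic import ViscoplasticParams, simulate_creep_recovery
from .transport import (OpticalSpec, PartitionMeasurement,
                        interpenetration_histogram, partition_coefficient,
                        rayleigh_resolution)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "child_seed"]

ALL_STAGES = ("materials", "displacement", "motility", "morphology", "transport")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study conditions."""

    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    # materials
    creep_stresses: tuple[float, ...] = (10.0, 50.0, 100.0, 150.0)
    load_duration: float = 3600.0
    recovery_duration: float = 6400.0
    rheo_dt: float = 2.0
    rheo_noise_sd: float = 0.0
    plasticity_tolerance: float = 1.0
    indentation_retained_fraction: float = 0.3
    # displacement / stress
    pixel_size: float = 0.5
    piv_window: int = 64
    piv_overlap: float = 0.5
    field_amplitude: float = 1.0
    field_decay_length: float = 15.0
    cell_radius: float = 14.0
    elastic_E: float = 2000.0
    elastic_v: float = 0.49
    cutoff_radius: float = 20.0
    bin_size: float = 10.0
    # motility
    track_params: dict = field(default_factory=dict)
    motility_threshold: float = 14.0
    # transport
    tracer_diameter_nm: float = 40.0
    wavelength_nm: float = 560.0
    numerical_aperture: float = 1.4
    # inputs that must exist if given
    input_paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.piv_overlap < 1):
            raise ValueError("piv_overlap must be in (0, 1)")
        for name, p in self.input_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input path {name!r} not found: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        for key in ("stages", "creep_stresses"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    outputs: dict
    warnings: list
    started: str
    finished: str = ""

    def write(self, path: str | Path) -> Path:
        return mio.save_json(asdict(self), path)


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: SeedSequence(seed) spawned in the
    fixed stage order, keeping values below 2**31."""
    idx = ALL_STAGES.index(stage)
    ss = np.random.SeedSequence(seed).spawn(len(ALL_STAGES))[idx]
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _stage_materials(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    params = ViscoplasticParams.ipn_like(30.0)  # high-plasticity-like preset
    series = []
    rows = []
    for i, stress in enumerate(cfg.creep_stresses):
        trace = simulate_creep_recovery(
            params, stress, cfg.load_duration, cfg.recovery_duration,
            dt=cfg.rheo_dt, noise_sd=cfg.rheo_noise_sd, seed=seed + i)
        mio.save_trace(trace, outdir / f"creep_{int(stress)}Pa.csv")
        res = decompose_creep_recovery(trace)
        series.append((stress, res))
        rows.append({"stress_Pa": stress,
                     "strain_total": res.strain_total_end_load,
                     "strain_elastic": res.strain_elastic,
                     "strain_viscoelastic": res.strain_viscoelastic,
                     "strain_permanent": res.strain_permanent,
                     "degree_of_plasticity_pct": res.degree_of_plasticity})
    bound = estimate_yield_stress(series, cfg.plasticity_tolerance)
    first, second = simulate_indentation_cycles(cfg.indentation_retained_fraction)
    indent = indentation_plasticity(first, second)
    table = outdir / "plasticity_decomposition.csv"
    mio.save_table(pd.DataFrame(rows), table)
    summary = outdir / "materials_summary.json"
    mio.save_json({
        "yield_bound_Pa": bound.value, "yield_relation": bound.relation,
        "indentation_retained_depth_mm": indent.retained_depth,
        "indentation_peak_force_ratio": indent.peak_force_ratio}, summary)
    return {"decomposition": str(table), "summary": str(summary)}


def _stage_displacement(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    half = 256 * cfg.pixel_size / 2
    spec = FieldSpec(kind="contractile_dipole", amplitude=cfg.field_amplitude,
                     center=(half, half), decay_length=cfg.field_decay_length)
    pair = generate_bead_image_pair(spec, image_size=256,
                                    pixel_size=cfg.pixel_size, seed=seed,
                                    window=cfg.piv_window,
                                    overlap=cfg.piv_overlap,
                                    exclusion_radius=cfg.cell_radius)
    mio.save_stack(np.stack([pair.reference, pair.deformed]).astype(np.float32),
                   outdir / "bead_pair.tif")
    fld = piv_displacement_field(pair, window=cfg.piv_window,
                                 overlap=cfg.piv_overlap)
    mio.save_field(fld, outdir / "displacement_field.csv")
    max_disp = max_matrix_displacement(fld, (half, half), cfg.cutoff_radius)
    amap = average_displacement_map([(fld, (half, half), (1.0, 0.0))],
                                    cfg.cutoff_radius, cfg.bin_size)
    mio.save_json({"bin_edges_um": amap.bin_edges, "mean_u_um": amap.mean_u,
                   "mean_v_um": amap.mean_v, "n_cells": amap.n_cells},
                  outdir / "averaged_map.json")
    strains = strain_field(fld)
    stresses = hooke_stress(strains, ElasticParams(cfg.elastic_E, cfg.elastic_v))
    pmax, upper = principal_stress(stresses)
    df = pd.DataFrame({
        "x_um": fld.grid_x.ravel(), "y_um": fld.grid_y.ravel(),
        "sigma11_Pa": stresses.sigma11.ravel(),
        "sigma22_Pa": stresses.sigma22.ravel(),
        "sigma12_Pa": stresses.sigma12.ravel(),
        "sigma33_Pa": stresses.sigma33.ravel(),
        "principal_max_Pa": pmax.ravel(),
        "valid": stresses.valid_mask.ravel().astype(int)})
    table = outdir / "stress_field.csv"
    mio.save_table(df, table)
    mio.save_json({"max_matrix_displacement_um": max_disp,
                   "upper_bound_stress_Pa": upper},
                  outdir / "displacement_summary.json")
    return {"stress_field": str(table),
            "summary": str(outdir / "displacement_summary.json")}


def _stage_motility(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    tp = TrackSimParams(**{"seed": seed, **cfg.track_params})
    tracks = generate_tracks(tp)
    mio.save_table(tracks_to_table(tracks), outdir / "tracks.csv",
                   schema="tracks")
    prob, ci = motility_probability(tracks, cfg.motility_threshold)
    speeds = [max_speed(tr) for tr in tracks
              if classify_motile(tr, cfg.motility_threshold)[0]]
    summary = outdir / "motility_summary.json"
    mio.save_json({"motile_probability": prob, "wilson_ci_95": list(ci),
                   "n_tracks": len(tracks),
                   "max_speed_um_per_h": speeds}, summary)
    return {"tracks": str(outdir / "tracks.csv"), "summary": str(summary)}


def _stage_morphology(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    rows = []
    for kind, aspect in (("disk", 1.0), ("ellipse", 2.0), ("rectangle", 1.0),
                         ("star", 1.0)):
        mask, truth = generate_shape_mask(kind, size_px=100, aspect=aspect)
        rows.append({"kind": kind, "aspect": aspect,
                     "circularity": circularity(mask),
                     "circularity_analytic": truth.circularity})
    table = outdir / "circularity.csv"
    mio.save_table(pd.DataFrame(rows), table)
    return {"circularity": str(table)}


def _stage_transport(cfg: RunConfig, outdir: Path, seed: int) -> dict:
    trapped = PartitionMeasurement(n_encapsulated=1e10, volume_gel=0.1,
                                   volume_supernatant=1.0,
                                   concentration_supernatant=1e7)
    free = PartitionMeasurement(n_encapsulated=1.1e10, volume_gel=0.1,
                                volume_supernatant=1.0,
                                concentration_supernatant=1e10)
    rng = np.random.default_rng(seed)
    phantom = 100.0 + rng.normal(0, 5.0, (64, 64))
    hist = interpenetration_histogram([phantom])
    summary = outdir / "transport_summary.json"
    mio.save_json({
        "partition_coefficient_trapped": partition_coefficient(trapped),
        "partition_coefficient_free": partition_coefficient(free),
        "rayleigh_resolution_nm": rayleigh_resolution(
            OpticalSpec(cfg.wavelength_nm, cfg.numerical_aperture)),
        "interpenetration_cv": hist["cv"],
        "interpenetration_n_modes": hist["n_modes"]}, summary)
    return {"summary": str(summary)}


_STAGE_FUNCS = {"materials": _stage_materials,
                "displacement": _stage_displacement,
                "motility": _stage_motility,
                "morphology": _stage_morphology,
                "transport": _stage_transport}


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Execute the configured stages in order and write a manifest.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained and listed in the manifest written next to
    them.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(),
                           version=__version__, outputs={}, warnings=[],
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        seed = child_seed(config.seed, stage)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                manifest.outputs[stage] = _STAGE_FUNCS[stage](config,
                                                              stage_dir, seed)
            except Exception as exc:
                manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
                manifest.write(outdir / "manifest.json")
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.warnings.extend(f"{stage}: {w.message}" for w in caught)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
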