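"""End-to-end orchestration: simulate -> normalize -> melt fit -> bands -> SAS.

A single :class:`RunConfig` (loadable from YAML) drives every stage; the
run writes a versioned JSON report with a provenance block (config hash,
seed, package versions) so that any run can be reproduced exactly.
Stage failures are recorded by stage name; stages that do not depend on
the failed one still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy
import yaml

from . import __version__
from .bands import DEFAULT_BAND_CENTERS, track_band_series
from .melting import (
    SequentialModelParams,
    global_fit_sequential,
    select_significant_species,
    svd_decompose,
)
from .sas import (
    BoxModel,
    MixtureModel,
    fit_sas_model,
    guinier_fit,
    ift_pr,
    kratky_transform,
    porod_volume,
)
from .spectra_io import (
    MeltingMatrix,
    Probe,
    SASCurve,
    read_melting_matrix,
    read_sas_curve,
    write_melting_matrix,
    write_sas_curve,
)
from .synthetic import (
    TEL22_CD_PARAMS,
    TEL22_UVRR_PARAMS,
    SyntheticSpec,
    cd_temperatures,
    default_cd_species,
    default_uvrr_species,
    generate_melting_matrix,
    generate_sas_curve,
    uvrr_temperatures,
)

log = logging.getLogger("gqmelt")

REPORT_SCHEMA_VERSION = 1

#: default V-autocorrelation cutoffs per probe
DEFAULT_CUTOFFS = {Probe.CD: 0.8, Probe.UVRR: 0.7}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``stages`` selects among simulate / melt_fit / bands / sas.  When a
    matrix or curve path is absent, the simulate stage must provide the
    synthetic stand-in.
    """

    outdir: str = "gqmelt_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "melt_fit"])
    # melting analysis
    probe: str = "cd"
    steps: int = 3
    cutoff: float | None = None  # None -> probe default (0.8 CD, 0.7 UVRR)
    matrix_path: str | None = None
    noise_sd: float = 0.02  # synthetic noise, relative to max |spectrum|
    # band tracking (UVRR)
    band_centers: list[float] = field(default_factory=lambda: list(DEFAULT_BAND_CENTERS))
    # SAS analysis
    sas_path: str | None = None
    sas_side_a: float = 15.0
    sas_height_c: float = 27.0
    sas_dimer_fraction: float = 0.0
    sas_noise_frac: float = 0.01
    sas_fix: list[str] = field(default_factory=lambda: ["gap", "background"])
    dmax: float = 40.0

    def __post_init__(self) -> None:
        if self.cutoff is not None and not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be in (0, 1)")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        known = {"simulate", "melt_fit", "bands", "sas"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; known: {sorted(known)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def effective_cutoff(self) -> float:
        return self.cutoff if self.cutoff is not None else DEFAULT_CUTOFFS[Probe(self.probe)]

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _simulate_matrix(cfg: RunConfig) -> MeltingMatrix:
    probe = Probe(cfg.probe)
    if probe is Probe.CD:
        species, temps, params = default_cd_species(), cd_temperatures(), TEL22_CD_PARAMS
    else:
        species, temps, params = (
            default_uvrr_species(),
            uvrr_temperatures(),
            TEL22_UVRR_PARAMS,
        )
    peak = max(float(np.max(np.abs(s.amplitude))) for s in species)
    spec = SyntheticSpec(
        model=params,
        species_spectra=species,
        temperatures=temps,
        noise_sd=cfg.noise_sd * peak,
        seed=cfg.seed,
        probe=probe,
    )
    return generate_melting_matrix(spec)


def _simulate_curve(cfg: RunConfig) -> SASCurve:
    model = MixtureModel(
        monomer=BoxModel(cfg.sas_side_a, None, cfg.sas_height_c),
        dimer_fraction=cfg.sas_dimer_fraction,
    )
    return generate_sas_curve(model, noise_frac=cfg.sas_noise_frac, seed=cfg.seed + 1)


def _write_table(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, header="\t".join(header), delimiter="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "config": asdict(config),
            "config_hash": config.hash(),
            "seed": config.seed,
            "versions": {
                "gqmelt": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
        },
        "stages": {},
        "errors": {},
    }

    matrix: MeltingMatrix | None = None
    curve: SASCurve | None = None

    if "simulate" in config.stages:
        try:
            matrix = _simulate_matrix(config)
            write_melting_matrix(matrix, out / "synthetic_matrix.tsv")
            curve = _simulate_curve(config)
            write_sas_curve(curve, out / "synthetic_sas.dat")
            report["stages"]["simulate"] = {
                "matrix_shape": list(matrix.shape),
                "sas_points": len(curve),
                "files": ["synthetic_matrix.tsv", "synthetic_sas.dat"],
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.exception("simulate stage failed")
            report["errors"]["simulate"] = str(exc)
            matrix = curve = None

    if config.matrix_path:
        matrix = read_melting_matrix(config.matrix_path, probe=config.probe)
    if config.sas_path:
        curve = read_sas_curve(config.sas_path)

    if "melt_fit" in config.stages:
        try:
            if matrix is None:
                raise RuntimeError("no melting matrix: give matrix_path or run simulate")
            svd = svd_decompose(matrix)
            cutoff = config.effective_cutoff()
            rank, var = select_significant_species(svd, cutoff)
            fit = global_fit_sequential(svd, rank=rank, steps=rank - 1)
            _write_table(
                out / "populations.tsv",
                ["T_C"] + [f"f_{k}" for k in range(fit.populations.shape[1])],
                [fit.temperatures] + list(fit.populations.T),
            )
            _write_table(
                out / "species_spectra.tsv",
                ["axis"] + [f"species_{k}" for k in range(fit.species_spectra.shape[1])],
                [fit.axis] + list(fit.species_spectra.T),
            )
            report["stages"]["melt_fit"] = {
                "cutoff": cutoff,
                "rank": rank,
                "variance_explained_percent": var,
                "steps": rank - 1,
                "dH_kcal_mol": list(fit.params.dH),
                "dH_err": list(fit.params.dH_err or []),
                "Tm_C": list(fit.params.Tm),
                "Tm_err": list(fit.params.Tm_err or []),
                "chi2_reduced": fit.chi2_reduced,
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("melt_fit stage failed")
            report["errors"]["melt_fit"] = str(exc)

    if "bands" in config.stages:
        try:
            if matrix is None:
                raise RuntimeError("no melting matrix: give matrix_path or run simulate")
            if matrix.probe is not Probe.UVRR:
                raise RuntimeError("band tracking needs a UVRR matrix")
            series = track_band_series(matrix, band_centers=config.band_centers)
            _write_table(
                out / "band_series.tsv",
                ["T_C"]
                + [f"center_{c:.0f}" for c in config.band_centers]
                + [f"height_{c:.0f}" for c in config.band_centers],
                [series.temperatures] + list(series.centers.T) + list(series.intensities.T),
            )
            report["stages"]["bands"] = {
                "n_bands": len(config.band_centers),
                "failed_columns": list(series.failed),
                "final_centers": [float(c) for c in series.centers[-1]],
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("bands stage failed")
            report["errors"]["bands"] = str(exc)

    if "sas" in config.stages:
        try:
            if curve is None:
                raise RuntimeError("no SAS curve: give sas_path or run simulate")
            i0, rg, qwin, info = guinier_fit(curve)
            porod = porod_volume(curve, guinier=(i0, rg))
            model0 = MixtureModel(
                monomer=BoxModel(config.sas_side_a, None, config.sas_height_c),
                dimer_fraction=0.3,
                scale=i0 / (1.0 + 2.0 * 0.3),
            )
            fit = fit_sas_model(curve, model0, fix=set(config.sas_fix))
            pr = ift_pr(curve, Dmax=config.dmax)
            kratky = kratky_transform(curve)
            _write_table(out / "kratky.tsv", ["q", "q2I"], [kratky[:, 0], kratky[:, 1]])
            _write_table(out / "pofr.tsv", ["r_A", "p"], [pr.r, pr.p])
            report["stages"]["sas"] = {
                "guinier": {"I0": i0, "Rg_A": rg, "q_window": list(qwin), **info},
                "porod_volume_A3": porod["volume"],
                "mixture_fit": {
                    "side_a_A": fit.model.monomer.side_a,
                    "height_c_A": fit.model.monomer.height_c,
                    "dimer_fraction": fit.model.dimer_fraction,
                    "chi2_reduced": fit.chi2_reduced,
                    "errors": fit.errors,
                },
                "pr": {
                    "Dmax_A": pr.Dmax,
                    "Rg_A": pr.Rg,
                    "I0": pr.I0,
                    "alpha": pr.alpha,
                    "chi2_reduced": pr.chi2_reduced,
                    "dmax_warning": pr.dmax_warning,
                },
            }
        except Exception as exc:  # noqa: BLE001
            log.exception("sas stage failed")
            report["errors"]["sas"] = str(exc)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
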