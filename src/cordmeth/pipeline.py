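"""End-to-end orchestration: simulate/load -> QC -> clocks -> deconvolution
-> epigenetic scores -> group inference, with serialized intermediates.

A run is a pure function of (config, seed): the same configuration produces
byte-identical result tables.  Each stage logs its input/output dimensions
and every number in the report is traceable to a written table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import pathlib

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .clocks import ClockModel, compute_acceleration, predict_dnam_age, read_clock_csv
from .deconv import CellReference, estimate_composition, read_reference_csv
from .qc import filter_probes, quantile_normalize
from .scores import compute_weights, read_es_csv, score_samples, z_transform
from .stats import GLMSpec, fit_invgauss_glm, run_group_comparisons, spearman_rho
from .synthetic import (
    ES_PANEL_SIZES,
    DEFAULT_CELL_TYPES,
    SimulationConfig,
    default_es_models,
    make_cell_reference,
    make_toy_clock,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_GLM_COVARIATES = [
    "apgar",
    "birth_weight_g",
    "maternal_infectious_disease",
    "maternal_ethnicity_white",
    "maternal_age",
    "CD4T",
    "CD8T",
    "Neutrophils",
    "nRBC",
    "es_gestational_smoking",
    "group_pce",
]


@dataclasses.dataclass
class RunConfig:
    """Inputs, analysis toggles and output location for one pipeline run.

    Either ``simulation`` or the explicit input paths must be present.
    """

    output_dir: str = "results/run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    # explicit inputs (used when simulation is None)
    beta_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    detection_p_path: str | None = None
    clock_csvs: list[str] = dataclasses.field(default_factory=list)
    reference_csv: str | None = None
    es_csv: str | None = None
    # analysis toggles
    weight_mode: str = "absolute"
    detection_fail_when: str = "ge"
    detection_p_threshold: float = 0.05
    missing_policy: str = "impute"
    glm_covariates: list[str] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_GLM_COVARIATES)
    )
    glm_response_shift: float = 10.0

    def validate(self) -> None:
        if self.simulation is None:
            required = {
                "beta_path": self.beta_path,
                "sample_sheet_path": self.sample_sheet_path,
                "annotation_path": self.annotation_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(
                    "config needs either a simulation block or input paths; "
                    f"missing {missing}"
                )
            for label, path in (
                ("beta", self.beta_path),
                ("sample sheet", self.sample_sheet_path),
                ("annotation", self.annotation_path),
                ("detection p", self.detection_p_path),
                ("reference", self.reference_csv),
                ("ES", self.es_csv),
                *((f"clock {p}", p) for p in self.clock_csvs),
            ):
                if path is not None and not pathlib.Path(path).exists():
                    raise FileNotFoundError(f"{label} file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        sim = payload.pop("simulation", None)
        config = cls(**payload)
        if sim is not None:
            config.simulation = SimulationConfig(**sim)
        return config

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        if self.simulation is not None:
            payload["simulation"] = dataclasses.asdict(self.simulation)
        return yaml.safe_dump(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _simulate_inputs(config: RunConfig, outdir: pathlib.Path):
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    clock = make_toy_clock(sim.n_clock_probes, seed=sim.seed)
    reference = make_cell_reference(
        sim.n_cell_types,
        sim.n_background_probes,
        seed=sim.seed,
        cell_types=DEFAULT_CELL_TYPES if sim.n_cell_types == len(DEFAULT_CELL_TYPES) else None,
    )
    es_models = default_es_models(seed=sim.seed)
    beta, cohort, detp, annot, truth = simulate_cohort(sim, clock, reference, es_models)
    cio.write_matrix_tsv(beta, outdir / "beta.tsv")
    cio.write_sample_sheet(cohort, outdir / "sample_sheet.csv")
    cio.write_annotation(annot, outdir / "annotation.csv")
    cio.write_matrix_tsv(detp, outdir / "detection_p.tsv")
    cio.write_ground_truth(truth, outdir / "ground_truth.json")
    return beta, cohort, detp, annot, [clock], reference, es_models


def _load_inputs(config: RunConfig):
    beta = cio.read_matrix_tsv(config.beta_path)
    cohort = cio.read_sample_sheet(config.sample_sheet_path)
    annot = cio.read_annotation(config.annotation_path)
    detp = (
        cio.read_matrix_tsv(config.detection_p_path)
        if config.detection_p_path
        else None
    )
    clocks = [read_clock_csv(p) for p in config.clock_csvs]
    reference = read_reference_csv(config.reference_csv) if config.reference_csv else None
    es_models = read_es_csv(config.es_csv) if config.es_csv else {}
    return beta, cohort, detp, annot, clocks, reference, es_models


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage in order and write all outputs.

    Returns the run report (also written to ``report.json``).
    """
    config.validate()
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cordmeth")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "version": __version__,
        }
    }
    try:
        if config.simulation is not None:
            beta, cohort, detp, annot, clocks, reference, es_models = _simulate_inputs(
                config, outdir
            )
        else:
            beta, cohort, detp, annot, clocks, reference, es_models = _load_inputs(config)
        logger.info("inputs: %d probes x %d samples", *beta.shape)

        # --- QC ---------------------------------------------------------
        try:
            filtered, filter_report = filter_probes(
                beta,
                annot,
                detp,
                p_threshold=config.detection_p_threshold,
                fail_when=config.detection_fail_when,
            )
        except Exception as err:
            raise RuntimeError(f"stage qc/filter_probes failed: {err}") from err
        (outdir / "filter_report.json").write_text(filter_report.to_json())
        report["filter_report"] = dataclasses.asdict(filter_report)
        logger.info("filtering: %d -> %d probes", filter_report.n_input,
                    filter_report.n_retained)

        try:
            normalized = quantile_normalize(filtered)
        except Exception as err:
            raise RuntimeError(f"stage qc/quantile_normalize failed: {err}") from err

        results = cohort.copy()
        comparisons_vars: dict[str, str] = {}

        # --- clocks -------------------------------------------------------
        report["clocks"] = {}
        for clock in clocks:
            try:
                dnam, coverage = predict_dnam_age(
                    normalized, clock, missing_policy=config.missing_policy
                )
                accel = compute_acceleration(dnam, results["ga_weeks"])
            except Exception as err:
                raise RuntimeError(f"stage clocks/{clock.name} failed: {err}") from err
            results[f"dnam_ga_{clock.name}"] = dnam
            results[f"accel_{clock.name}"] = accel
            comparisons_vars[f"dnam_ga_{clock.name}"] = "continuous"
            comparisons_vars[f"accel_{clock.name}"] = "continuous"
            report["clocks"][clock.name] = {
                "coverage": dataclasses.asdict(coverage),
                "ga_spearman": dataclasses.asdict(
                    spearman_rho(results["ga_weeks"], dnam)
                ),
            }
            logger.info("clock %s: %d/%d probes", clock.name,
                        coverage.n_present, coverage.n_clock_probes)

        # --- deconvolution ------------------------------------------------
        if reference is not None:
            try:
                composition = estimate_composition(normalized, reference)
            except Exception as err:
                raise RuntimeError(f"stage cell_deconv failed: {err}") from err
            for cell in reference.cell_types:
                results[cell] = composition[cell]
                comparisons_vars[cell] = "continuous"
            results["deconv_residual_norm"] = composition["residual_norm"]

        # --- epigenetic scores ---------------------------------------------
        es_coverage = {}
        for phenotype, model in es_models.items():
            try:
                compute_weights(model, mode=config.weight_mode)
                raw = score_samples(normalized, model, missing_policy="drop")
                z = z_transform(raw)
            except Exception as err:
                raise RuntimeError(f"stage epigenetic_scores/{phenotype} failed: {err}") from err
            results[f"es_{phenotype}"] = z
            comparisons_vars[f"es_{phenotype}"] = "continuous"
            es_coverage[phenotype] = int(model.probes.index.isin(normalized.index).sum())
        report["es_coverage"] = es_coverage

        # --- group comparisons ---------------------------------------------
        for var, kind in (
            ("ga_weeks", "continuous"),
            ("apgar", "continuous"),
            ("birth_weight_g", "continuous"),
            ("maternal_age", "continuous"),
            ("sex_male", "categorical"),
            ("maternal_infectious_disease", "categorical"),
            ("maternal_ethnicity_white", "categorical"),
            ("tobacco_use", "categorical"),
            ("bdnf_ng_ml", "continuous"),
        ):
            if var in results.columns:
                comparisons_vars.setdefault(var, kind)
        try:
            comparisons = run_group_comparisons(results, comparisons_vars)
        except Exception as err:
            raise RuntimeError(f"stage stats/group_comparisons failed: {err}") from err
        comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
        report["group_comparisons"] = comparisons.to_dict(orient="records")

        # --- BDNF correlations ----------------------------------------------
        if "bdnf_ng_ml" in results.columns:
            report["bdnf_correlations"] = {}
            for clock in clocks:
                res = spearman_rho(results[f"accel_{clock.name}"], results["bdnf_ng_ml"])
                report["bdnf_correlations"][clock.name] = dataclasses.asdict(res)

        # --- GLMs -------------------------------------------------------------
        report["glm"] = {}
        for clock in clocks:
            covs = [c for c in config.glm_covariates if c in results.columns]
            dropped = sorted(set(config.glm_covariates) - set(covs))
            if dropped:
                logger.warning("GLM %s: dropping absent covariates %s", clock.name, dropped)
            spec = GLMSpec(
                response=f"accel_{clock.name}",
                covariates=covs,
                response_shift=config.glm_response_shift,
            )
            try:
                fit = fit_invgauss_glm(results, results[f"accel_{clock.name}"], spec)
            except Exception as err:
                raise RuntimeError(f"stage stats/glm {clock.name} failed: {err}") from err
            table = pd.DataFrame(
                {
                    "covariate": fit.coefficients.index,
                    "beta": fit.coefficients.to_numpy(),
                    "se": fit.standard_errors.to_numpy(),
                    "wald": fit.wald.to_numpy(),
                    "p_value": fit.wald_p.to_numpy(),
                }
            )
            table.to_csv(outdir / f"glm_{clock.name}.csv", index=False)
            report["glm"][clock.name] = {
                "coefficients": fit.coefficients.to_dict(),
                "wald": fit.wald.to_dict(),
                "wald_p": fit.wald_p.to_dict(),
                "dispersion": fit.dispersion,
                "deviance": fit.deviance,
                "null_deviance": fit.null_deviance,
                "omnibus_chi2": fit.omnibus_chi2,
                "omnibus_p": fit.omnibus_p,
                "converged": fit.converged,
            }

        results.rename_axis("sample_id").to_csv(outdir / "cohort_results.csv")
        cio.write_json(report, outdir / "report.json")
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
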