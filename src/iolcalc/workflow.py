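"""End-to-end study orchestration: simulate or load a cohort, split it,
optimize lens constants on the training set, train the adapted calculator,
and evaluate all methods on the held-out validation eyes.

All randomness flows from one master seed through named substreams (cohort
generation, patient split, CV folds), so a rerun with the same config and
seed reproduces every output file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import adaptation, optimize, simulate, stats
from .formulas import HaigisConstants, SRKTConstants, haigis_refraction_array, srkt_refraction_array
from .records import Cohort, filter_eligible, read_biometry_table, split_train_validation

logger = logging.getLogger("iolcalc")

__all__ = ["StudyConfig", "StudyConfigError", "StageError", "run_study", "STAGES"]

STAGES = ("config", "cohort", "split", "optimize", "train", "evaluate", "report")

EVAL_COVARIATES = ("axial_length", "acd", "mean_keratometry", "wtw")
BANDS = (("within_025", 0.25), ("within_050", 0.50), ("within_100", 1.00))


class StudyConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class StudyConfig:
    """Validated configuration of a full study run."""

    seed: int = 0
    out_dir: str = "study_out"
    input_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    n_validation_patients: int = 400
    strict_split: bool = False
    min_cdva: float = 0.8
    srkt_a_constant: float | str = "optimize"
    haigis_constants: tuple[float, float, float] | str = "optimize"
    c_values: tuple[float, ...] = adaptation.HyperparameterGrid().c_values
    gamma_values: tuple[float, ...] = adaptation.HyperparameterGrid().gamma_values
    epsilon: float = 0.1
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.input_csv is not None and self.synthetic:
            raise StudyConfigError("give either input_csv or a synthetic spec, not both")
        if self.n_validation_patients < 1:
            raise StudyConfigError("n_validation_patients must be positive")
        if self.cv_folds < 2:
            raise StudyConfigError("cv_folds must be at least 2")
        if self.srkt_a_constant != "optimize" and not isinstance(self.srkt_a_constant, (int, float)):
            raise StudyConfigError("srkt_a_constant must be 'optimize' or a number")
        if self.haigis_constants != "optimize" and len(self.haigis_constants) != 3:
            raise StudyConfigError("haigis_constants must be 'optimize' or an (a0, a1, a2) triple")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StudyConfigError(f"unknown config key(s): {sorted(unknown)}")
        raw = dict(raw)
        for key in ("c_values", "gamma_values", "haigis_constants"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _substream_seeds(master: int, n: int = 3) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _build_cohort(config: StudyConfig, cohort_seed: int) -> Cohort:
    if config.input_csv:
        return read_biometry_table(config.input_csv)
    kwargs = dict(config.synthetic)
    bias = kwargs.pop("bias", None)
    truth_model = kwargs.pop("truth_model", "srkt")
    if truth_model == "srkt":
        truth_constants = SRKTConstants(float(kwargs.pop("truth_a_constant", 119.0)))
    else:
        a0, a1, a2 = kwargs.pop("truth_haigis", (-2.1245, 0.2032, 0.2866))
        truth_constants = HaigisConstants(a0, a1, a2)
    spec = simulate.CohortSpec(
        truth_model=truth_model,
        truth_constants=truth_constants,
        bias_spec=bias,
        seed=cohort_seed,
        **kwargs,
    )
    return simulate.generate_cohort(spec)


def _test_result_dict(res: stats.TestResult) -> dict:
    doc: dict = {"statistic": res.statistic, "p_value": res.p_value, "method": res.method}
    if res.pairwise is not None:
        doc["pairwise"] = [
            {
                "pair": list(p.pair),
                "statistic": p.statistic,
                "p_raw": p.p_raw,
                "p_adjusted": p.p_adjusted,
                "note": p.note,
            }
            for p in res.pairwise
        ]
    if res.residuals is not None:
        doc["adjusted_residuals"] = res.residuals.tolist()
        doc["flagged"] = res.flagged.tolist()
    return doc


def _plain_table(summaries: dict[str, stats.ErrorSummary]) -> str:
    methods = list(summaries)
    rows = [
        ("Mean (SD), D", lambda s: f"{s.mean_pe:.2f} ({s.sd_pe:.2f})"),
        ("MedAE, D", lambda s: f"{s.medae:.2f}"),
        ("Within +/-0.25 D", lambda s: f"{s.pct_within_025:.1f}%"),
        ("Within +/-0.50 D", lambda s: f"{s.pct_within_050:.1f}%"),
        ("Within +/-1.00 D", lambda s: f"{s.pct_within_100:.1f}%"),
        ("Greater than +0.50 D", lambda s: f"{s.pct_over_plus_050:.1f}%"),
    ]
    width = 22
    lines = [
        f"Prediction-error summary (N = {summaries[methods[0]].n} validation eyes)",
        "Metric".ljust(width) + "".join(m.ljust(12) for m in methods),
    ]
    for name, fmt in rows:
        lines.append(name.ljust(width) + "".join(fmt(summaries[m]).ljust(12) for m in methods))
    return "\n".join(lines) + "\n"


def run_study(config: StudyConfig, json_float_fmt: bool = True) -> dict:
    """Run the full pipeline and write the report set to ``config.out_dir``.

    Returns a dict with the in-memory results (constants, model, summaries,
    test results, regressions) for library callers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_seed, split_seed, fold_seed = _substream_seeds(config.seed)

    def _stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise StageError(name, exc) from exc

    cohort = _stage("cohort", lambda: filter_eligible(_build_cohort(config, cohort_seed), config.min_cdva))
    train, valid = _stage(
        "split",
        lambda: split_train_validation(
            cohort, config.n_validation_patients, split_seed, strict=config.strict_split
        ),
    )
    logger.info("cohort: %d eyes -> train %d / validation %d", len(cohort), len(train), len(valid))

    def _optimize():
        if config.srkt_a_constant == "optimize":
            srkt_report = optimize.optimize_a_constant(train)
        else:
            srkt_report = optimize.OptimizationReport(
                SRKTConstants(float(config.srkt_a_constant)), len(train), 0, float("nan"), 0
            )
        if config.haigis_constants == "optimize":
            haigis_report = optimize.optimize_haigis_constants(train)
        else:
            haigis_report = optimize.OptimizationReport(
                HaigisConstants(*map(float, config.haigis_constants)),
                len(train), 0, float("nan"), 0,
            )
        return srkt_report, haigis_report

    srkt_report, haigis_report = _stage("optimize", _optimize)
    a_const = srkt_report.constants
    h_const = haigis_report.constants

    model = _stage(
        "train",
        lambda: adaptation.train_adapted_calculator(
            train,
            a_const,
            adaptation.HyperparameterGrid(config.c_values, config.gamma_values, config.epsilon),
            cv_folds=config.cv_folds,
            seed=fold_seed,
        ),
    )

    def _evaluate():
        L = valid.column("axial_length")
        K = valid.column("mean_keratometry")
        acd = valid.column("acd")
        P = valid.column("iol_power")
        mrse = valid.column("postop_mrse")
        preds = {
            "srkt": srkt_refraction_array(L, K, a_const.a_constant, P),
            "haigis": haigis_refraction_array(L, K, acd, h_const, P),
            "adapted": np.array(
                [adaptation.adapted_predict_refraction(model, r, r.iol_power) for r in valid]
            ),
        }
        pe = {m: optimize.prediction_error(mrse, p) for m, p in preds.items()}
        summaries = {m: stats.summarize_errors(v) for m, v in pe.items()}
        tests = {
            "mean_errors": stats.compare_mean_errors(pe),
            "absolute_errors": stats.compare_absolute_errors(
                {m: np.abs(v) for m, v in pe.items()}
            ),
        }
        def _band_test(counts):
            # a band with no eyes on one side (e.g. noise-free cohorts) makes
            # the chi-squared degenerate; report why instead of aborting
            try:
                return stats.compare_band_proportions(counts)
            except ValueError as exc:
                logger.warning("band comparison skipped: %s", exc)
                return {"skipped": str(exc), "counts": counts}

        band_tests = {}
        for band_name, bound in BANDS:
            counts = [
                [int(np.sum(np.abs(pe[m]) <= bound)), int(np.sum(np.abs(pe[m]) > bound))]
                for m in pe
            ]
            band_tests[band_name] = _band_test(counts)
        counts = [[int(np.sum(pe[m] > 0.5)), int(np.sum(pe[m] <= 0.5))] for m in pe]
        band_tests["over_plus_050"] = _band_test(counts)
        regressions = {
            method: {
                cov: stats.regress_error_on_covariate(pe[method], valid.column(cov))
                for cov in EVAL_COVARIATES
            }
            for method in ("srkt", "adapted")
        }
        return preds, pe, summaries, tests, band_tests, regressions

    preds, pe, summaries, tests, band_tests, regressions = _stage("evaluate", _evaluate)

    def _report():
        (out / "constants_srkt.json").write_text(
            optimize.report_to_json(srkt_report, train.label, config.seed), encoding="utf-8"
        )
        (out / "constants_haigis.json").write_text(
            optimize.report_to_json(haigis_report, train.label, config.seed), encoding="utf-8"
        )
        adaptation.save_model(model, out / "adapted_model.json")

        table = valid.to_dataframe()[["patient_id", "eye_side", "iol_power_d", "postop_mrse_d"]]
        for m in preds:
            table[f"pred_{m}_d"] = preds[m]
            table[f"pe_{m}_d"] = pe[m]
        table.to_csv(out / "predictions.csv", index=False)

        for m, s in summaries.items():
            (out / f"summary_{m}.json").write_text(
                json.dumps(dataclasses.asdict(s), indent=2), encoding="utf-8"
            )
        for name, res in tests.items():
            (out / f"test_{name}.json").write_text(
                json.dumps(_test_result_dict(res), indent=2), encoding="utf-8"
            )
        (out / "test_band_proportions.json").write_text(
            json.dumps(
                {
                    k: (_test_result_dict(v) if isinstance(v, stats.TestResult) else v)
                    for k, v in band_tests.items()
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        (out / "regressions.json").write_text(
            json.dumps(
                {
                    method: {cov: dataclasses.asdict(r) for cov, r in covs.items()}
                    for method, covs in regressions.items()
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        (out / "report.txt").write_text(_plain_table(summaries), encoding="utf-8")
        (out / "study.json").write_text(
            json.dumps(
                {
                    "format": "iolcalc-study-v1",
                    "seed": config.seed,
                    "substreams": {"cohort": cohort_seed, "split": split_seed, "folds": fold_seed},
                    "n_total": len(cohort),
                    "n_train": len(train),
                    "n_validation": len(valid),
                },
                indent=2,
            ),
            encoding="utf-8",
        )

    _stage("report", _report)
    return {
        "train": train,
        "validation": valid,
        "srkt_report": srkt_report,
        "haigis_report": haigis_report,
        "model": model,
        "predictions": preds,
        "prediction_errors": pe,
        "summaries": summaries,
        "tests": tests,
        "band_tests": band_tests,
        "regressions": regressions,
    }
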