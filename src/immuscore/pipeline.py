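"""End-to-end orchestration: score -> stratify -> survival -> evaluate
-> expression -> drugs, with input validation and a consolidated,
reproducible run report.

A run is driven by a :class:`PipelineConfig` (typically loaded from
YAML). All outputs land under a config-hashed, timestamp-free directory
so that re-running an identical configuration reproduces byte-identical
files. Every source of randomness (bootstrap, CV folds) flows from the
config-declared seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drugs import compare_drug_groups, zscore_normalize
from .evaluation import (
    confusion_accuracy,
    decision_curve,
    harrell_c,
    idi_nri,
    time_dependent_auc,
)
from .expression import (
    filter_de,
    lasso_cox,
    log_transform,
    moderated_t_test,
    risk_score_and_split,
)
from .phenotype import (
    StratificationRule,
    build_matrix,
    compare_markers,
    compute_immuscore,
    stratify,
)
from .survival import cox_fit, km_estimate, logrank_test

logger = logging.getLogger("immuscore.pipeline")

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "validate_inputs"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.message = message


@dataclass
class PipelineConfig:
    markers_path: str = ""
    survival_path: str = ""
    drugs_path: str = ""
    expression_path: str = ""
    out_dir: str = "results"
    rule_mode: str = "cohort_median"  # or "fixed_cutoff"
    rule_cutoff: float = 1.2
    horizon_months: float = 36.0
    dca_horizons: tuple = (12.0, 36.0, 60.0)
    n_bootstrap: int = 200
    lasso_folds: int = 10
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "score": True,
            "survival": True,
            "evaluate": True,
            "expression": True,
            "drugs": True,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown configuration key {key!r}")
            if key == "stages":
                cfg.stages.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def semantic_dict(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")  # output location is not semantically meaningful
        d["dca_horizons"] = list(map(float, d["dca_horizons"]))
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema and cross-reference checks; returns a report, never raises.

    The report has ``errors`` (fatal) and ``warnings`` lists of strings.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    tables: dict[str, pd.DataFrame] = {}

    def load(name, path, **kw):
        if not path:
            return None
        if not Path(path).exists():
            errors.append(f"{name}: file not found: {path}")
            return None
        try:
            tables[name] = pd.read_csv(path, sep="\t", **kw)
            return tables[name]
        except Exception as exc:
            errors.append(f"{name}: unreadable ({exc})")
            return None

    markers = load("markers", config.markers_path)
    survival = load("survival", config.survival_path, index_col="patient_id")
    drugs_df = load("drugs", config.drugs_path, index_col="patient_id")
    expr = load("expression", config.expression_path, index_col="gene_id")

    if markers is not None:
        need = {"patient_id", "antibody", "category"}
        missing = need - set(markers.columns)
        if missing:
            errors.append(f"markers: missing columns {sorted(missing)}")
        else:
            from .phenotype import encode_intensity

            for i, cat in markers["category"].items():
                try:
                    encode_intensity(cat)
                except ValueError:
                    errors.append(
                        f"markers: row {i}: unknown category {cat!r}"
                    )
                    break
    if survival is not None:
        for col in ("time_months", "event"):
            if col not in survival.columns:
                errors.append(f"survival: missing column {col!r}")
        if "time_months" in survival.columns:
            bad = survival.index[
                ~(survival["time_months"].astype(float) > 0)
            ]
            for pid in bad[:5]:
                errors.append(
                    f"survival: non-positive time for patient {pid!r}"
                )
        if "event" in survival.columns and not set(
            survival["event"].dropna().unique()
        ) <= {0, 1}:
            errors.append("survival: event column must be 0/1")
        if "response" not in survival.columns:
            warnings_.append("survival: no response column (CR/RR stages limited)")
    if markers is not None and survival is not None and "patient_id" in markers:
        only_markers = set(markers["patient_id"]) - set(survival.index)
        if only_markers:
            warnings_.append(
                f"{len(only_markers)} patients in markers absent from survival"
            )
    for name, df in (("drugs", drugs_df), ("expression", expr)):
        if df is not None and survival is not None:
            ids = set(df.index) if name == "drugs" else set(df.columns)
            extra = ids - set(survival.index)
            if extra:
                warnings_.append(
                    f"{len(extra)} patients in {name} absent from survival"
                )
    if expr is not None and (expr.to_numpy(dtype=float) < 0).any():
        errors.append("expression: negative TPM values")

    return {"errors": errors, "warnings": warnings_, "n_tables": len(tables)}


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _breslow_event_prob(data, covariates, horizon, duration_col, event_col):
    """Per-subject event probability by ``horizon`` from a Cox fit with
    a Breslow baseline hazard."""
    fit = cox_fit(data, covariates, duration_col=duration_col, event_col=event_col)
    X = data[covariates].to_numpy(dtype=float)
    eta = X @ fit.coef
    time = data[duration_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=int)
    w = np.exp(eta)
    event_times = np.unique(time[event == 1])
    h0 = 0.0
    for t in event_times[event_times <= horizon]:
        d = int(((time == t) & (event == 1)).sum())
        h0 += d / w[time >= t].sum()
    risk = 1.0 - np.exp(-h0 * w)
    return np.clip(risk, 0.0, 1.0), fit


def _frame_to_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a consolidated report.

    Returns the report dict (also written to ``report.json`` inside the
    config-hashed output directory). Any stage error aborts with a
    :class:`StageError`; outputs of earlier stages are preserved.
    """
    if not any(config.stages.values()):
        raise StageError("setup", "no stage enabled")
    out = Path(config.out_dir) / f"run_{config.config_hash()}"
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.semantic_dict(),
        "stages": {},
        "outputs": {},
    }

    def require(path, stage):
        if not path or not Path(path).exists():
            raise StageError(stage, f"input file missing: {path!r}")

    # shared inputs
    require(config.survival_path, "setup")
    survival = pd.read_csv(
        config.survival_path, sep="\t", index_col="patient_id"
    )

    groups = None  # High/Low per patient

    # --- score ------------------------------------------------------------
    if config.stages.get("score"):
        stage = "score"
        try:
            require(config.markers_path, stage)
            calls = pd.read_csv(config.markers_path, sep="\t")
            matrix = build_matrix(calls)
            scores = compute_immuscore(matrix)
            rule = StratificationRule(
                mode=config.rule_mode, cutoff=config.rule_cutoff
            )
            strata = stratify(scores, rule)
            groups = strata["group"]
            _frame_to_tsv(
                strata[["immuscore", "group"]], out / "immuscore.tsv"
            )
            report["outputs"]["immuscore"] = "immuscore.tsv"
            stage_stats = {
                "n_scored": int(strata["immuscore"].notna().sum()),
                "threshold": float(strata["threshold"].iloc[0]),
                "n_high": int((groups == "High").sum()),
                "n_low": int((groups == "Low").sum()),
            }
            if "response" in survival.columns:
                tests = compare_markers(
                    matrix, survival["response"].reindex(matrix.index)
                )
                _frame_to_tsv(tests, out / "marker_tests.tsv")
                report["outputs"]["marker_tests"] = "marker_tests.tsv"
                stage_stats["n_markers_significant"] = int(
                    (tests["p_adj"] < 0.05).sum()
                )
            report["stages"][stage] = stage_stats
            logger.info("score: %s", stage_stats)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # assemble the survival analysis frame with the score group
    frame = survival.copy()
    if groups is not None:
        frame["score_group"] = groups.reindex(frame.index)
        frame["high_score"] = (frame["score_group"] == "High").astype(float)

    # --- survival ---------------------------------------------------------
    if config.stages.get("survival"):
        stage = "survival"
        try:
            if groups is None:
                raise StageError(stage, "survival stage needs the score stage")
            sub = frame.dropna(subset=["score_group", "time_months", "event"])
            lr = logrank_test(
                sub["time_months"], sub["event"], sub["score_group"]
            )
            fit = cox_fit(sub, ["high_score"])
            km_rows = []
            for label, grp in sub.groupby("score_group"):
                km = km_estimate(grp["time_months"], grp["event"])
                for i in range(km.times.size):
                    km_rows.append(
                        {
                            "group": label,
                            "time_months": km.times[i],
                            "n_risk": int(km.n_risk[i]),
                            "n_events": int(km.n_events[i]),
                            "survival": km.survival[i],
                        }
                    )
            _frame_to_tsv(
                pd.DataFrame(km_rows), out / "km_curves.tsv", index=False
            )
            _write_json(
                {
                    "statistic": lr.statistic,
                    "df": lr.df,
                    "p_value": lr.p_value,
                    "groups": [str(g) for g in lr.groups],
                    "observed": lr.observed,
                    "expected": lr.expected,
                },
                out / "logrank.json",
            )
            _frame_to_tsv(fit.summary(), out / "fits.tsv")
            report["outputs"].update(
                {
                    "km_curves": "km_curves.tsv",
                    "logrank": "logrank.json",
                    "fits": "fits.tsv",
                }
            )
            report["stages"][stage] = {
                "logrank_p": lr.p_value,
                "hr_high_vs_low": float(fit.hr[0]),
                "hr_ci": [float(fit.ci_low[0]), float(fit.ci_high[0])],
                "cox_p": float(fit.p[0]),
            }
            logger.info("survival: %s", report["stages"][stage])
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # --- evaluate ---------------------------------------------------------
    if config.stages.get("evaluate"):
        stage = "evaluate"
        try:
            if groups is None:
                raise StageError(stage, "evaluate stage needs the score stage")
            sub = frame.dropna(
                subset=["score_group", "time_months", "event", "immuscore"]
                if "immuscore" in frame
                else ["score_group", "time_months", "event"]
            )
            scores = (
                pd.read_csv(out / "immuscore.tsv", sep="\t", index_col=0)[
                    "immuscore"
                ]
                .reindex(sub.index)
                .astype(float)
            )
            sub = sub.loc[scores.notna()]
            scores = scores.loc[sub.index]
            risk = -scores  # higher score is protective
            horizon = float(config.horizon_months)
            cres = harrell_c(sub["time_months"], sub["event"], risk)
            ares = time_dependent_auc(
                sub["time_months"], sub["event"], risk, horizon
            )
            sub = sub.assign(neg_score=risk)
            risk_new, _ = _breslow_event_prob(
                sub, ["neg_score", "age"] if "age" in sub else ["neg_score"],
                horizon, "time_months", "event",
            )
            if "age" in sub:
                risk_old, _ = _breslow_event_prob(
                    sub, ["age"], horizon, "time_months", "event"
                )
            else:
                risk_old = np.full(len(sub), risk_new.mean())
            known = (sub["event"] == 1) & (sub["time_months"] <= horizon)
            at_risk = sub["time_months"] > horizon
            evaluable = known | at_risk
            reclass = idi_nri(
                risk_old[evaluable],
                risk_new[evaluable],
                known[evaluable].astype(int),
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
            )
            dca_frames = []
            for h in config.dca_horizons:
                dc = decision_curve(
                    risk_new, sub["time_months"], sub["event"], float(h)
                )
                dc.insert(0, "horizon", float(h))
                dca_frames.append(dc)
            _frame_to_tsv(
                pd.concat(dca_frames, ignore_index=True),
                out / "decision_curve.tsv",
                index=False,
            )
            stats_ = {
                "c_index": cres.c_index,
                "auc": ares.auc,
                "auc_horizon_months": horizon,
                "idi": reclass.idi,
                "nri": reclass.nri,
            }
            if "response" in sub.columns:
                conf = confusion_accuracy(
                    sub["score_group"], sub["response"]
                )
                stats_["accuracy_pct"] = conf.accuracy_pct
                stats_["confusion"] = {
                    f"{g}_{r}": int(conf.counts.loc[g, r])
                    for g in conf.counts.index
                    for r in conf.counts.columns
                }
            _write_json(stats_, out / "evaluation.json")
            report["outputs"].update(
                {
                    "evaluation": "evaluation.json",
                    "decision_curve": "decision_curve.tsv",
                }
            )
            report["stages"][stage] = stats_
            logger.info("evaluate: %s", stats_)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # --- expression -------------------------------------------------------
    if config.stages.get("expression"):
        stage = "expression"
        try:
            require(config.expression_path, stage)
            tpm = pd.read_csv(
                config.expression_path, sep="\t", index_col="gene_id"
            )
            if "response" not in survival.columns:
                raise StageError(stage, "expression stage needs response labels")
            common = [c for c in tpm.columns if c in survival.index]
            tpm = tpm[common]
            logex = log_transform(tpm)
            de = moderated_t_test(
                logex, survival["response"].reindex(logex.columns)
            )
            degs = filter_de(de)
            _frame_to_tsv(de, out / "de_results.tsv")
            stage_stats = {"n_genes": int(len(de)), "n_de_genes": len(degs)}
            surv_lasso = survival.loc[common]
            lasso_genes = degs if len(degs) >= 2 else list(
                de.sort_values("p").index[:50]
            )
            n_events = int(surv_lasso["event"].sum())
            folds = min(config.lasso_folds, max(n_events, 2))
            path_, model = lasso_cox(
                logex.loc[lasso_genes],
                surv_lasso,
                n_folds=folds,
                seed=config.seed,
            )
            lasso_tab = pd.DataFrame(
                {
                    "lambda": path_.alphas,
                    "cv_deviance_mean": path_.cv_mean,
                    "cv_deviance_se": path_.cv_se,
                    "n_nonzero": (path_.coefs.to_numpy() != 0).sum(axis=0),
                }
            )
            _frame_to_tsv(lasso_tab, out / "lasso_path.tsv", index=False)
            split = risk_score_and_split(model, logex)
            _frame_to_tsv(split, out / "risk_scores.tsv")
            stage_stats.update(
                {
                    "lambda_min": path_.lambda_min,
                    "signature_genes": model.genes,
                    "risk_split_degenerate": split.attrs["degenerate"],
                }
            )
            if not split.attrs["degenerate"]:
                joined = surv_lasso.join(split)
                lr = logrank_test(
                    joined["time_months"], joined["event"], joined["risk_group"]
                )
                stage_stats["risk_group_logrank_p"] = lr.p_value
            report["outputs"].update(
                {
                    "de_results": "de_results.tsv",
                    "lasso_path": "lasso_path.tsv",
                    "risk_scores": "risk_scores.tsv",
                }
            )
            report["stages"][stage] = stage_stats
            logger.info("expression: %s", stage_stats)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    # --- drugs ------------------------------------------------------------
    if config.stages.get("drugs"):
        stage = "drugs"
        try:
            require(config.drugs_path, stage)
            if groups is None:
                raise StageError(stage, "drugs stage needs the score stage")
            raw = pd.read_csv(
                config.drugs_path, sep="\t", index_col="patient_id"
            )
            z = zscore_normalize(raw)
            table = compare_drug_groups(z, groups.reindex(z.index))
            _frame_to_tsv(table, out / "drug_comparisons.tsv")
            report["outputs"]["drug_comparisons"] = "drug_comparisons.tsv"
            report["stages"][stage] = {
                "n_compounds": int(len(table)),
                "n_significant": int((table["p_adj"] < 0.05).sum()),
                "n_low_less_sensitive": int(
                    (
                        (table["p_adj"] < 0.05)
                        & (table["more_sensitive"] == "High")
                    ).sum()
                ),
            }
            logger.info("drugs: %s", report["stages"][stage])
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc

    _write_json(report, out / "report.json")
    return report
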