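"""Seeded synthetic cohorts with the statistical structure the analysis
assumes, so every downstream stage is testable without external data.

The generator emulates the layered structure of a public AML resource
(marker-intensity calls, right-censored survival, ex vivo drug response,
bulk TPM expression) for an ASXL1-mutated-like cohort:

* five-level categorical marker intensities for CD11b, CD123 and
  HLA-DR, with the lower categories enriched in relapsed/refractory
  (R/R) patients;
* exponential survival whose hazard is multiplied by a configurable
  High-vs-Low hazard ratio for patients whose *realized* ImmuScore is at
  or above the cohort median (so the generator's truth matches what the
  pipeline estimates), with independent exponential censoring and an
  administrative cutoff;
* per-compound standard-normal drug responses with a mean Z shift added
  to Low-score patients (higher Z = less sensitive);
* a log-normal TPM matrix in which a small number of prognostic genes
  carry a log2-scale mean shift between response groups.

One root seed drives deterministic per-table sub-streams, so adding a
table never shifts the others and regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import (
    CORE_MARKERS,
    StratificationRule,
    build_matrix,
    compute_immuscore,
    stratify,
)

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_cohort",
           "write_cohort", "read_cohort"]

#: Intensity categories from lowest to highest.
CATEGORIES = ("negative", "dim", "partdim", "part", "bright")

_DEFAULT_PROBS = {
    "CR": [0.15, 0.15, 0.10, 0.40, 0.20],
    "RR": [0.40, 0.25, 0.15, 0.15, 0.05],
}

# fixed per-table sub-stream keys
_STREAMS = {"response": 1, "markers": 2, "survival": 3, "drugs": 4,
            "expression": 5, "covariates": 6}


def _default_marker_probs() -> dict:
    return {
        marker: {grp: list(p) for grp, p in _DEFAULT_PROBS.items()}
        for marker in CORE_MARKERS
    }


@dataclass
class SimulationConfig:
    """Free parameters of the cohort generator.

    The survival default ``hr_high_vs_low=0.38`` matches the reported
    High-vs-Low hazard ratio of the score; ``drug_shift`` is the mean
    Z-score increase of Low-score patients (reduced sensitivity);
    prognostic genes emulate response-associated transcripts such as
    MAP3K15 via a +/- ``prognostic_log2fc`` group mean shift on the
    log2 scale.
    """

    seed: int = 0
    n_patients: int = 200
    frac_rr: float = 0.4
    marker_category_probs: dict = field(default_factory=_default_marker_probs)
    hr_high_vs_low: float = 0.38
    baseline_hazard: float = 1.0 / 24.0  # per month; Low-group rate
    censor_rate: float = 0.01  # independent exponential censoring
    admin_cutoff: float = 60.0  # months
    n_drugs: int = 20
    drug_shift: float = 0.8
    n_genes: int = 200
    n_prognostic_genes: int = 2
    prognostic_log2fc: float = 2.0
    expression_dispersion: float = 1.0
    missingness: float = 0.0  # optional per-call marker missingness

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("config error: n_patients must be >= 2")
        if not 0.0 < self.frac_rr < 1.0:
            raise ValueError("config error: frac_rr must lie in (0, 1)")
        if self.hr_high_vs_low <= 0:
            raise ValueError("config error: hr_high_vs_low must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("config error: baseline_hazard must be > 0")
        if self.censor_rate <= 0:
            raise ValueError("config error: censor_rate must be > 0")
        if self.admin_cutoff <= 0:
            raise ValueError("config error: admin_cutoff must be > 0")
        if self.expression_dispersion <= 0:
            raise ValueError("config error: expression_dispersion must be > 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("config error: missingness must lie in [0, 1)")
        if self.n_prognostic_genes > self.n_genes:
            raise ValueError(
                "config error: n_prognostic_genes exceeds n_genes"
            )
        for marker, per_group in self.marker_category_probs.items():
            for grp, probs in per_group.items():
                p = np.asarray(probs, dtype=float)
                if p.size != len(CATEGORIES):
                    raise ValueError(
                        f"config error: marker_category_probs[{marker}][{grp}] "
                        f"needs {len(CATEGORIES)} entries"
                    )
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"config error: marker_category_probs[{marker}][{grp}] "
                        "must be a probability vector summing to 1"
                    )

    def rng(self, table: str) -> np.random.Generator:
        """Deterministic per-table sub-stream of the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[table]])
        )


@dataclass
class SyntheticCohort:
    """The four analysis tables plus the generating truth."""

    marker_calls: pd.DataFrame  # long: patient_id, antibody, category
    survival: pd.DataFrame  # indexed by patient_id
    drug_matrix: pd.DataFrame  # patient x compound
    expression: pd.DataFrame  # gene x patient TPM
    truth: dict

    @property
    def patients(self) -> list:
        return list(self.survival.index)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort from the configured generative model."""
    config.validate()
    n = config.n_patients
    patients = [f"P{i:04d}" for i in range(1, n + 1)]

    response = np.where(
        config.rng("response").random(n) < config.frac_rr, "RR", "CR"
    )

    # --- marker calls -----------------------------------------------------
    rng_m = config.rng("markers")
    rows = []
    for marker in CORE_MARKERS:
        per_group = config.marker_category_probs[marker]
        for i, pid in enumerate(patients):
            if config.missingness and rng_m.random() < config.missingness:
                continue
            probs = np.asarray(per_group[response[i]], dtype=float)
            cat = CATEGORIES[rng_m.choice(len(CATEGORIES), p=probs)]
            rows.append((pid, marker, cat))
    marker_calls = pd.DataFrame(
        rows, columns=["patient_id", "antibody", "category"]
    )

    # realized score group (median rule) drives the hazard
    matrix = build_matrix(marker_calls)
    scores = compute_immuscore(matrix)
    strata = stratify(scores, StratificationRule(mode="cohort_median"))
    group = strata["group"].reindex(patients)
    is_high = (group == "High").to_numpy()

    # --- survival ---------------------------------------------------------
    rng_s = config.rng("survival")
    rate = np.where(
        is_high,
        config.baseline_hazard * config.hr_high_vs_low,
        config.baseline_hazard,
    )
    t_event = rng_s.exponential(1.0 / rate)
    t_cens = rng_s.exponential(1.0 / config.censor_rate, size=n)
    t_cens = np.minimum(t_cens, config.admin_cutoff)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive

    rng_c = config.rng("covariates")
    age = np.round(rng_c.normal(58.0, 12.0, size=n)).clip(18, 90)
    survival = pd.DataFrame(
        {
            "time_months": time,
            "event": event,
            "response": response,
            "age": age.astype(int),
        },
        index=pd.Index(patients, name="patient_id"),
    )

    # --- drugs ------------------------------------------------------------
    rng_d = config.rng("drugs")
    compounds = [f"drug_{j:02d}" for j in range(1, config.n_drugs + 1)]
    Z = rng_d.standard_normal((n, config.n_drugs))
    Z[~is_high] += config.drug_shift  # Low-score patients less sensitive
    drug_matrix = pd.DataFrame(
        Z, index=pd.Index(patients, name="patient_id"), columns=compounds
    )

    # --- expression -------------------------------------------------------
    rng_e = config.rng("expression")
    genes = [f"gene_{g:04d}" for g in range(1, config.n_genes + 1)]
    base = rng_e.uniform(1.0, 8.0, size=config.n_genes)  # log2 mean
    log2 = rng_e.normal(
        base[:, None], config.expression_dispersion, size=(config.n_genes, n)
    )
    prognostic = genes[: config.n_prognostic_genes]
    rr = response == "RR"
    for k in range(config.n_prognostic_genes):
        # alternate direction; the first gene is up in R/R (MAP3K15-like)
        sign = 1.0 if k % 2 == 0 else -1.0
        log2[k, rr] += sign * config.prognostic_log2fc
    tpm = np.maximum(2.0 ** np.clip(log2, 0.0, None) - 1.0, 0.0)
    expression = pd.DataFrame(
        tpm, index=pd.Index(genes, name="gene_id"),
        columns=pd.Index(patients, name="patient_id"),
    )

    truth = {
        "config": asdict(config),
        "true_group": dict(zip(patients, group.fillna("Low"))),
        "true_log_hr": float(np.log(config.hr_high_vs_low)),
        "prognostic_genes": prognostic,
        "score_threshold": float(strata["threshold"].iloc[0]),
    }
    return SyntheticCohort(marker_calls, survival, drug_matrix, expression, truth)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the four TSV tables plus truth.json; round-trips losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": directory / "markers.tsv",
        "survival": directory / "survival.tsv",
        "drugs": directory / "drugs.tsv",
        "expression": directory / "expression.tsv",
        "truth": directory / "truth.json",
    }
    cohort.marker_calls.to_csv(paths["markers"], sep="\t", index=False)
    cohort.survival.to_csv(paths["survival"], sep="\t")
    cohort.drug_matrix.to_csv(paths["drugs"], sep="\t")
    cohort.expression.to_csv(paths["expression"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    marker_calls = pd.read_csv(directory / "markers.tsv", sep="\t")
    survival = pd.read_csv(
        directory / "survival.tsv", sep="\t", index_col="patient_id"
    )
    drug_matrix = pd.read_csv(
        directory / "drugs.tsv", sep="\t", index_col="patient_id"
    )
    expression = pd.read_csv(
        directory / "expression.tsv", sep="\t", index_col="gene_id"
    )
    expression.columns.name = "patient_id"
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticCohort(marker_calls, survival, drug_matrix, expression, truth)
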