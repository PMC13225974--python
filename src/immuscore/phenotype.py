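"""Semi-quantitative encoding of flow-cytometry marker intensity and the
three-marker ImmuScore.

Diagnostic AML flow reports record each surface antigen as a categorical
intensity call. The encoder maps those calls onto a fixed numeric scale

    bright -> 1.0      (strong positive)
    part   -> 0.5      (general positive pattern)
    dim    -> 0.2      (weak)
    partdim-> 0.2      (partial-dim)
    negative -> 0.0

and the ImmuScore of a patient is the sum of the encoded intensities of
CD11b, CD123 and HLA-DR, hence a value in [0, 3]. Patients are
dichotomized at the cohort median (score >= median -> "High") or at a
fixed cutoff (the discovery analysis used 1.2); High-score patients
carry the favourable phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "INTENSITY_SCORES",
    "DEFAULT_FIXED_CUTOFF",
    "CORE_MARKERS",
    "StratificationRule",
    "encode_intensity",
    "build_matrix",
    "compute_immuscore",
    "stratify",
    "compare_markers",
]

#: Numeric score per normalized intensity category.
INTENSITY_SCORES: dict[str, float] = {
    "bright": 1.0,
    "part": 0.5,
    "positive": 0.5,  # synonym for the general positive pattern
    "pos": 0.5,
    "dim": 0.2,
    "partdim": 0.2,
    "negative": 0.0,
    "neg": 0.0,
}

#: Fixed ImmuScore cutoff used by the discovery cohort analysis.
DEFAULT_FIXED_CUTOFF: float = 1.2

#: The three routinely reported markers entering the ImmuScore.
CORE_MARKERS: tuple[str, str, str] = ("CD11b", "CD123", "HLA-DR")


def _normalize_label(label: str) -> str:
    """Lower-case and strip whitespace/punctuation from a category call."""
    return "".join(ch for ch in str(label).lower() if ch.isalnum())


def _normalize_marker(name: str) -> str:
    """Canonicalize an antibody name ("HLA-DR" == "hladr" == "HLA DR")."""
    return "".join(ch for ch in str(name).upper() if ch.isalnum())


def encode_intensity(category: str) -> float:
    """Encode one categorical intensity call as its numeric score.

    Raises
    ------
    ValueError
        If the label does not normalize to a known category.
    """
    key = _normalize_label(category)
    if key not in INTENSITY_SCORES:
        accepted = sorted(set(INTENSITY_SCORES))
        raise ValueError(
            f"unknown intensity category {category!r}; accepted labels "
            f"(case/whitespace-insensitive): {accepted}"
        )
    return INTENSITY_SCORES[key]


def build_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long marker-call table into a patient x antibody score matrix.

    Parameters
    ----------
    calls : DataFrame with columns ``patient_id``, ``antibody``, ``category``.

    Returns
    -------
    DataFrame indexed by patient_id with one column per antibody; cells
    hold encoded scores in {0, 0.2, 0.5, 1.0}, NaN where a (patient,
    antibody) pair was not observed.

    Duplicated (patient, antibody) rows with identical categories are
    de-duplicated with a warning; conflicting duplicates are an error.
    """
    required = {"patient_id", "antibody", "category"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"marker-call table lacks columns: {sorted(missing)}")

    df = calls.loc[:, ["patient_id", "antibody", "category"]].copy()
    df["score"] = df["category"].map(encode_intensity)

    dup = df.duplicated(subset=["patient_id", "antibody"], keep=False)
    if dup.any():
        per_cell = df[dup].groupby(["patient_id", "antibody"])["score"].nunique()
        conflicts = per_cell[per_cell > 1]
        if len(conflicts):
            cell = conflicts.index[0]
            raise ValueError(
                f"conflicting duplicate marker call for patient "
                f"{cell[0]!r}, antibody {cell[1]!r}"
            )
        warnings.warn(
            f"{int(dup.sum())} duplicate marker-call rows with identical "
            "categories were de-duplicated",
            stacklevel=2,
        )
        df = df.drop_duplicates(subset=["patient_id", "antibody"])

    matrix = df.pivot(index="patient_id", columns="antibody", values="score")
    matrix.columns.name = None
    return matrix


def _locate_core_markers(matrix: pd.DataFrame) -> dict[str, str | None]:
    """Map canonical core-marker names to actual matrix columns."""
    by_norm = {_normalize_marker(c): c for c in matrix.columns}
    return {m: by_norm.get(_normalize_marker(m)) for m in CORE_MARKERS}


def compute_immuscore(
    matrix: pd.DataFrame, missing_as_negative: bool = False
) -> pd.DataFrame:
    """Sum the CD11b + CD123 + HLA-DR scores per patient.

    Patients missing any of the three markers get no score (NaN) and the
    per-marker presence flags record the gap, unless
    ``missing_as_negative`` imputes absent calls as 0 (sensitivity-
    analysis mode).

    Returns
    -------
    DataFrame indexed by patient_id with columns ``immuscore`` and
    ``has_<marker>`` flags.
    """
    located = _locate_core_markers(matrix)
    if all(col is None for col in located.values()):
        raise ValueError(
            f"none of the core markers {CORE_MARKERS} present in the matrix "
            f"(columns: {list(matrix.columns)})"
        )

    out = pd.DataFrame(index=matrix.index)
    parts = []
    for marker, col in located.items():
        values = (
            matrix[col]
            if col is not None
            else pd.Series(np.nan, index=matrix.index)
        )
        out[f"has_{_normalize_marker(marker)}"] = values.notna()
        parts.append(values)
    stacked = pd.concat(parts, axis=1)
    if missing_as_negative:
        stacked = stacked.fillna(0.0)
    out.insert(0, "immuscore", stacked.sum(axis=1, min_count=3))
    return out


@dataclass(frozen=True)
class StratificationRule:
    """How ImmuScores are dichotomized into High/Low groups.

    mode "cohort_median" thresholds at the median of the available
    scores; "fixed_cutoff" thresholds at ``cutoff``. With
    ``inclusive_high`` (the default, matching the stated median rule) a
    score equal to the threshold is High.
    """

    mode: str = "cohort_median"
    cutoff: float = DEFAULT_FIXED_CUTOFF
    inclusive_high: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("cohort_median", "fixed_cutoff"):
            raise ValueError(f"unknown stratification mode {self.mode!r}")
        if self.mode == "fixed_cutoff" and not 0.0 <= self.cutoff <= 3.0:
            raise ValueError("fixed cutoff must lie in [0, 3]")


def stratify(
    scores: pd.Series | pd.DataFrame,
    rule: StratificationRule | None = None,
) -> pd.DataFrame:
    """Assign High/Low groups from ImmuScores.

    Parameters
    ----------
    scores : Series of scores indexed by patient, or the output frame of
        :func:`compute_immuscore` (its ``immuscore`` column is used).
    rule : stratification rule; defaults to the cohort-median rule.

    Returns
    -------
    DataFrame with columns ``immuscore``, ``group`` ("High"/"Low",
    NaN-scored patients unassigned) and ``threshold`` (the realized
    threshold, identical for every row).
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["immuscore"]
    rule = rule or StratificationRule()
    available = scores.dropna()
    if available.empty:
        raise ValueError("no scored patients to stratify")
    threshold = (
        float(np.median(available))
        if rule.mode == "cohort_median"
        else float(rule.cutoff)
    )
    if rule.inclusive_high:
        high = scores >= threshold
    else:
        high = scores > threshold
    group = pd.Series(
        np.where(scores.isna(), None, np.where(high, "High", "Low")),
        index=scores.index,
        dtype=object,
    )
    return pd.DataFrame(
        {"immuscore": scores, "group": group, "threshold": threshold}
    )


def compare_markers(
    matrix: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str] = ("CR", "RR"),
) -> pd.DataFrame:
    """Per-antibody Wilcoxon rank-sum comparison between response groups.

    Uses the asymptotic two-sided test (tie + continuity corrected) and
    BH adjustment across antibodies. Antibodies with fewer than two
    observed values in either group are skipped with a warning.

    Parameters
    ----------
    matrix : encoded patient x antibody matrix.
    labels : per-patient response label, aligned on the matrix index.
    groups : the two label values to contrast (first vs second).

    Returns
    -------
    DataFrame indexed by antibody with group medians, the W statistic,
    raw and BH-adjusted p-values.
    """
    labels = labels.reindex(matrix.index)
    rows = []
    skipped = []
    for antibody in matrix.columns:
        a = matrix.loc[labels == groups[0], antibody].dropna()
        b = matrix.loc[labels == groups[1], antibody].dropna()
        if len(a) < 2 or len(b) < 2:
            skipped.append(antibody)
            continue
        w, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "antibody": antibody,
                f"median_{groups[0]}": float(np.median(a)),
                f"median_{groups[1]}": float(np.median(b)),
                "n_" + groups[0]: len(a),
                "n_" + groups[1]: len(b),
                "W": w,
                "p": p,
            }
        )
    if skipped:
        warnings.warn(
            f"antibodies skipped for insufficient group sizes: {skipped}",
            stacklevel=2,
        )
    if not rows:
        raise ValueError(
            f"no antibody has >=2 observations in both groups {groups}"
        )
    table = pd.DataFrame(rows).set_index("antibody")
    table["p_adj"] = bh_adjust(table["p"])
    return table
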