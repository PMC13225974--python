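"""Ex vivo drug-sensitivity normalization and group contrasts.

Raw per-compound response measurements (treated as opaque reals; the
assay may report AUC or IC50) are standardized within each compound to
Z-scores, with the convention that a *higher Z means reduced
sensitivity* (more resistant). Group contrasts are per-compound
Wilcoxon rank-sum tests with BH adjustment across compounds and star
annotations at the 0.05/0.01/0.001/0.0001 levels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import bh_adjust, significance_stars, wilcoxon_rank_sum

__all__ = ["zscore_normalize", "compare_drug_groups"]


def zscore_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardize each compound column to mean 0, sample SD 1.

    Missing values are ignored per compound (pairwise deletion, never
    imputed). Compounds with fewer than two observations or zero
    variance are dropped with a warning.
    """
    dropped = []
    cols = {}
    for compound in raw.columns:
        x = raw[compound].astype(float)
        obs = x.dropna()
        if len(obs) < 2 or float(obs.std(ddof=1)) == 0.0:
            dropped.append(compound)
            continue
        cols[compound] = (x - obs.mean()) / obs.std(ddof=1)
    if dropped:
        warnings.warn(
            f"compounds dropped (constant or <2 observations): {dropped}",
            stacklevel=2,
        )
    if not cols:
        raise ValueError("no compound column could be standardized")
    return pd.DataFrame(cols, index=raw.index)


def compare_drug_groups(
    z: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str] = ("High", "Low"),
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-compound Wilcoxon rank-sum contrast of two patient groups.

    Parameters
    ----------
    z : patient x compound Z-score matrix.
    groups : per-patient group label aligned on the index.
    contrast : the two group labels to compare (first vs second).
    adjust : "bh" (default) or "none".

    Returns
    -------
    DataFrame indexed by compound with group medians, W, raw p,
    adjusted p, a direction flag naming the *more sensitive* (lower
    median Z) group, and significance stars on the adjusted p.
    Compounds with an entirely missing group are skipped with a warning.
    """
    if adjust not in ("bh", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    groups = groups.reindex(z.index)
    rows = []
    skipped = []
    for compound in z.columns:
        a = z.loc[(groups == contrast[0]).to_numpy(), compound].dropna()
        b = z.loc[(groups == contrast[1]).to_numpy(), compound].dropna()
        if a.empty or b.empty:
            skipped.append(compound)
            continue
        w, p = wilcoxon_rank_sum(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if med_a == med_b:
            direction = "none"
        else:
            # lower Z = more sensitive
            direction = contrast[0] if med_a < med_b else contrast[1]
        rows.append(
            {
                "compound": compound,
                f"median_{contrast[0]}": med_a,
                f"median_{contrast[1]}": med_b,
                "W": w,
                "p": p,
                "more_sensitive": direction,
            }
        )
    if skipped:
        warnings.warn(
            f"compounds skipped (one group entirely missing): {skipped}",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no compound had observations in both groups")
    table = pd.DataFrame(rows).set_index("compound")
    table["p_adj"] = bh_adjust(table["p"]) if adjust == "bh" else table["p"]
    table["stars"] = [significance_stars(p) for p in table["p_adj"]]
    return table
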