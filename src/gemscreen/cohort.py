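"""Survival stratification and cohort-level statistics.

Patients with vital status "dead" are split into survival tertiles on days
lived after diagnosis: the low group falls strictly below the 1/3 quantile,
the high group strictly above the 2/3 quantile, and the middle tertile is
discarded.  Differential-expression results between the groups are consumed
as a gene score table (log2 fold change + p-value); a built-in two-group
Welch test on log expression is provided as a stand-in for runs on synthetic
data, and is never used when an external DE table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "stratify_survival",
    "GeneScoreTable",
    "split_de",
    "simple_de",
    "dependency_validation",
    "StratificationError",
]

# Contrast direction of a DE table.  "high_vs_low" is the convention in which
# log2fc < 0 means the gene is HIGHER in the low-survival group.
HIGH_VS_LOW = "high_vs_low"
LOW_VS_HIGH = "low_vs_high"


class StratificationError(ValueError):
    pass


def stratify_survival(
    clinical: pd.DataFrame,
    low_q: float = 1 / 3,
    high_q: float = 2 / 3,
) -> Tuple[List[str], List[str], Tuple[float, float]]:
    """Split dead patients into low/high survival tertile groups.

    ``clinical`` needs columns ``sample_id``, ``vital_status``, ``days``.
    Quantiles use linear interpolation (the common type-7 rule); membership
    is strict: low = days < low cut, high = days > high cut.
    Returns (low ids, high ids, (low cut, high cut)).
    """
    required = {"sample_id", "vital_status", "days"}
    missing = required - set(clinical.columns)
    if missing:
        raise StratificationError(f"clinical table missing columns {sorted(missing)}")
    dead = clinical[clinical["vital_status"].str.lower() == "dead"]
    if len(dead) < 3:
        raise StratificationError(
            f"need >= 3 samples with vital status 'dead', got {len(dead)}"
        )
    days = dead["days"].astype(float).to_numpy()
    lo_cut = float(np.quantile(days, low_q, method="linear"))
    hi_cut = float(np.quantile(days, high_q, method="linear"))
    if lo_cut >= hi_cut:
        raise StratificationError(
            f"degenerate survival distribution: cut points coincide ({lo_cut:g})"
        )
    low = dead.loc[days < lo_cut, "sample_id"].tolist()
    high = dead.loc[days > hi_cut, "sample_id"].tolist()
    return low, high, (lo_cut, hi_cut)


@dataclass
class GeneScoreTable:
    """Per-gene DE result: log2 fold change and p-value, plus its contrast.

    ``orientation`` must be declared ('high_vs_low' or 'low_vs_high') so the
    up/down split cannot silently flip sign.
    """

    table: pd.DataFrame  # columns: gene, log2fc, p
    orientation: str

    def __post_init__(self):
        need = {"gene", "log2fc", "p"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"gene score table missing columns {sorted(missing)}")
        if self.orientation not in (HIGH_VS_LOW, LOW_VS_HIGH):
            raise ValueError(
                f"orientation must be declared as {HIGH_VS_LOW!r} or {LOW_VS_HIGH!r}"
            )
        if self.table["gene"].duplicated().any():
            raise ValueError("duplicate gene rows in score table")
        p = self.table["p"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")


def split_de(table: GeneScoreTable, alpha: float = 0.05) -> Tuple[Set[str], Set[str]]:
    """Split significant genes into (up_in_low, down_in_low) sets.

    Under the high-vs-low contrast, genes with log2fc < 0 are upregulated in
    the low-survival group; log2fc = 0 rows are assigned to neither set.
    """
    df = table.table
    sig = df["p"] < alpha
    fc = df["log2fc"]
    if table.orientation == HIGH_VS_LOW:
        up_in_low = set(df.loc[sig & (fc < 0), "gene"])
        down_in_low = set(df.loc[sig & (fc > 0), "gene"])
    else:
        up_in_low = set(df.loc[sig & (fc > 0), "gene"])
        down_in_low = set(df.loc[sig & (fc < 0), "gene"])
    return up_in_low, down_in_low


def simple_de(
    expr: pd.DataFrame,
    low_group: Sequence[str],
    high_group: Sequence[str],
    already_log: bool = True,
) -> GeneScoreTable:
    """Two-group Welch t-test per gene on (log) expression.

    A stand-in DE test for synthetic runs (the study's negative-binomial DE
    model is consumed as an external input on real data).  log2fc is
    mean(high) - mean(low), i.e. the high-vs-low contrast; genes with zero
    variance in both groups get p = 1.
    """
    low = [s for s in low_group if s in expr.columns]
    high = [s for s in high_group if s in expr.columns]
    if not low or not high:
        raise ValueError("both groups must contain samples present in the matrix")
    X = expr if already_log else np.log2(expr + 1)
    xl = X[low].to_numpy(float)
    xh = X[high].to_numpy(float)
    log2fc = xh.mean(axis=1) - xl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xh, xl, axis=1, equal_var=False)
    # zero variance in both groups: Welch statistic undefined -> p = 1
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = pd.DataFrame({"gene": expr.index, "log2fc": log2fc, "p": p})
    return GeneScoreTable(out.reset_index(drop=True), orientation=HIGH_VS_LOW)


def dependency_validation(
    matrix: pd.DataFrame, targets: Iterable[str]
) -> Tuple[pd.DataFrame, List[str]]:
    """Validate targets against a gene x cell-line dependency-score matrix.

    Essential genes score around -1, non-essential around 0.  For each target
    we report its median score across cell lines and a two-sided one-sample
    t-test of its per-cell-line scores against the mean of all genes' median
    scores.  Returns (result frame, skipped targets).
    """
    if not np.isfinite(matrix.to_numpy(float)).all():
        raise ValueError("dependency matrix contains non-finite values")
    medians = matrix.median(axis=1)
    reference = float(medians.mean())
    rows = []
    skipped: List[str] = []
    for gene in sorted(set(targets)):
        if gene not in matrix.index:
            skipped.append(gene)
            continue
        scores = matrix.loc[gene].to_numpy(float)
        med = float(np.median(scores))
        if np.allclose(scores, scores[0]) and np.isclose(scores[0], reference):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(scores, reference)
        rows.append({"gene": gene, "median": med, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows, columns=["gene", "median", "t", "p"]), skipped
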