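"""Differential statistics for label-free shotgun metaproteomics.

The pipeline follows common practice for peak-area proteomics of replicated
culture conditions: protein peak areas are normalised per sample to percent
of the sample total, each condition is compared to a fixed reference
condition by a per-protein two-sided t-test (Welch by default) on replicate
percentages together with a log2 fold change of condition means, and
proteins are called over-/under-expressed when p < alpha and |log2FC|
exceeds a threshold (strict inequalities; defaults alpha = 0.05,
threshold = 0.5). Calls are then aggregated over functional categories and
taxa. No multiple-testing correction is applied by default; an optional
Benjamini–Hochberg adjustment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinAbundanceTable",
    "DifferentialExpression",
    "DifferentialExpressionResults",
    "normalize_to_percent",
    "log2_foldchange",
    "differential_test",
    "classify",
    "aggregate",
]

ALPHA = 0.05
LOG2FC_THRESHOLD = 0.5
UNCLASSIFIED = "unclassified"


@dataclass
class ProteinAbundanceTable:
    """Proteins x samples peak areas with condition and annotation metadata.

    Parameters
    ----------
    areas : DataFrame
        Rows = protein identifiers, columns = sample identifiers, values =
        non-negative peak areas (or percentages after normalisation).
    conditions : Series
        Condition label per sample (index = sample identifiers).
    taxa, categories : Series, optional
        Per-protein taxon and functional-category annotations.
    """

    areas: pd.DataFrame
    conditions: pd.Series
    taxa: pd.Series | None = None
    categories: pd.Series | None = None
    is_percent: bool = False

    def __post_init__(self) -> None:
        if not set(self.areas.columns) <= set(self.conditions.index):
            missing = set(self.areas.columns) - set(self.conditions.index)
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be >= 0")
        totals = self.areas.sum(axis=0)
        zero = totals[totals <= 0]
        if len(zero):
            raise ValueError(
                f"sample(s) with zero total area: {list(zero.index)}"
            )

    def replicate_columns(self, condition) -> list[str]:
        cond = self.conditions.loc[list(self.areas.columns)]
        return list(cond.index[cond == condition])

    def condition_labels(self) -> list:
        seen: list = []
        for s in self.areas.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen


def normalize_to_percent(table: ProteinAbundanceTable) -> ProteinAbundanceTable:
    """Express every sample column as percent of its total peak area.

    Each column of the returned table sums to exactly 100; within-column
    ratios are preserved (the transform is scale-invariant per sample).
    """
    totals = table.areas.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"cannot normalize sample(s) with zero total: {list(zero.index)}")
    pct = table.areas.div(totals, axis=1) * 100.0
    return ProteinAbundanceTable(
        areas=pct,
        conditions=table.conditions,
        taxa=table.taxa,
        categories=table.categories,
        is_percent=True,
    )


def log2_foldchange(mean_test: float, mean_ref: float, pseudocount: float = 0.0) -> float:
    """log2((mean_test + pc) / (mean_ref + pc)); antisymmetric in test/ref."""
    if mean_test < 0 or mean_ref < 0 or pseudocount < 0:
        raise ValueError("means and pseudocount must be >= 0")
    num = mean_test + pseudocount
    den = mean_ref + pseudocount
    if num == 0 and den == 0:
        return float("nan")  # undefined: protein absent everywhere
    if den == 0:
        return float("inf")
    if num == 0:
        return float("-inf")
    return float(np.log2(num / den))


def differential_test(
    test_replicates, ref_replicates, equal_var: bool = False
) -> float:
    """Two-sided t-test p-value between two replicate groups.

    Welch's unequal-variance test by default. When both groups have zero
    variance and equal means the difference is exactly zero and p = 1 by
    convention (logged); zero variance with unequal means gives p = 0.
    """
    a = np.asarray(test_replicates, dtype=float)
    b = np.asarray(ref_replicates, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("at least 2 replicates per group required")
    scale = max(abs(a).max(), abs(b).max(), 1e-300)
    if a.std(ddof=1) <= 1e-12 * scale and b.std(ddof=1) <= 1e-12 * scale:
        # degenerate replicate groups: no within-group variation
        if abs(a.mean() - b.mean()) <= 1e-12 * scale:
            logger.debug("zero variance in both groups with equal means: p=1")
            return 1.0
        return 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)


def classify(
    log2fc: float, p: float, alpha: float = ALPHA, delta: float = LOG2FC_THRESHOLD
) -> str:
    """Call a protein up, down, or ns (strict inequalities at the boundaries)."""
    if np.isnan(log2fc) or np.isnan(p):
        return "ns"
    if p < alpha and log2fc > delta:
        return "up"
    if p < alpha and log2fc < -delta:
        return "down"
    return "ns"


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class DifferentialExpressionResults:
    """Per-protein and aggregated differential-expression results."""

    model: "DifferentialExpression"
    records: pd.DataFrame  # per (protein, condition) vs reference
    pseudocount: float

    def summary(self) -> str:
        lines = [
            "Differential expression vs reference "
            f"condition {self.model.reference!r}",
            f"proteins: {self.records['protein'].nunique()}   "
            f"comparisons: {len(self.records)}   "
            f"pseudocount: {self.pseudocount:.4g} %",
            f"t-test: {'Student' if self.model.equal_var else 'Welch'}; "
            f"alpha={self.model.alpha}, |log2FC|>{self.model.delta}"
            + ("; BH-adjusted" if self.model.bh_correct else ""),
        ]
        for cond, grp in self.records.groupby("condition", sort=False):
            n_up = (grp["status"] == "up").sum()
            n_down = (grp["status"] == "down").sum()
            lines.append(
                f"  {cond} vs {self.model.reference}: "
                f"{n_up} up, {n_down} down, {(grp['status'] == 'ns').sum()} ns"
            )
        return "\n".join(lines)

    def category_summary(self) -> pd.DataFrame:
        return aggregate(self.records, self.model.table.categories, by="category")

    def taxon_summary(self) -> pd.DataFrame:
        return aggregate(self.records, self.model.table.taxa, by="taxon")


class DifferentialExpression:
    """Differential-expression analysis of a protein table vs a reference.

    Parameters
    ----------
    table : ProteinAbundanceTable
        Raw peak areas (normalised internally) or an already-percent table.
    reference : condition label
        Reference condition all others are compared against.
    equal_var : bool
        Student's t-test instead of Welch's.
    pseudocount : float or None
        Percentage added inside the fold-change ratio only; ``None`` uses
        half the smallest nonzero normalised value in the table.
    bh_correct : bool
        Apply Benjamini–Hochberg adjustment per comparison (off by default).
    """

    def __init__(
        self,
        table: ProteinAbundanceTable,
        reference,
        alpha: float = ALPHA,
        delta: float = LOG2FC_THRESHOLD,
        equal_var: bool = False,
        pseudocount: float | None = None,
        bh_correct: bool = False,
    ) -> None:
        if reference not in set(table.conditions.loc[list(table.areas.columns)]):
            raise ValueError(f"reference condition {reference!r} has no samples")
        self.table = table if table.is_percent else normalize_to_percent(table)
        self.reference = reference
        self.alpha = alpha
        self.delta = delta
        self.equal_var = equal_var
        self.pseudocount = pseudocount
        self.bh_correct = bh_correct

    def fit(self) -> DifferentialExpressionResults:
        tbl = self.table
        ref_cols = tbl.replicate_columns(self.reference)
        if len(ref_cols) < 2:
            raise ValueError("reference condition needs >= 2 replicates")
        pc = self.pseudocount
        if pc is None:
            vals = tbl.areas.to_numpy()
            nonzero = vals[vals > 0]
            pc = float(nonzero.min() / 2.0) if len(nonzero) else 0.0
            logger.info("pseudocount defaulted to %.4g %% (half min nonzero)", pc)

        ref = tbl.areas[ref_cols].to_numpy()
        rows = []
        for cond in tbl.condition_labels():
            if cond == self.reference:
                continue
            cols = tbl.replicate_columns(cond)
            if len(cols) < 2:
                logger.warning("condition %r skipped: <2 replicates", cond)
                continue
            test = tbl.areas[cols].to_numpy()
            mean_ref = ref.mean(axis=1)
            mean_test = test.mean(axis=1)
            pvals = np.array(
                [
                    differential_test(test[i], ref[i], equal_var=self.equal_var)
                    for i in range(test.shape[0])
                ]
            )
            if self.bh_correct:
                pvals = _bh_adjust(pvals)
            for i, prot in enumerate(tbl.areas.index):
                fc = log2_foldchange(mean_test[i], mean_ref[i], pc)
                rows.append(
                    {
                        "protein": prot,
                        "condition": cond,
                        "mean_ref": mean_ref[i],
                        "mean_test": mean_test[i],
                        "log2_foldchange": fc,
                        "p_value": pvals[i],
                        "status": classify(fc, pvals[i], self.alpha, self.delta),
                    }
                )
        records = pd.DataFrame(
            rows,
            columns=[
                "protein",
                "condition",
                "mean_ref",
                "mean_test",
                "log2_foldchange",
                "p_value",
                "status",
            ],
        )
        return DifferentialExpressionResults(
            model=self, records=records, pseudocount=pc
        )


def aggregate(
    records: pd.DataFrame,
    annotations: pd.Series | None,
    by: str = "category",
) -> pd.DataFrame:
    """Summarise per-protein calls over an annotation grouping.

    Returns, per (group, condition): mean of test/reference percentages,
    mean +/- sd of log2 fold changes over member proteins, and up/down/ns
    counts. Proteins without an annotation fall into ``"unclassified"``.
    """
    rec = records.copy()
    if annotations is None:
        rec[by] = UNCLASSIFIED
    else:
        rec[by] = rec["protein"].map(annotations).fillna(UNCLASSIFIED)
    finite = rec["log2_foldchange"].replace([np.inf, -np.inf], np.nan)
    rec["_fc"] = finite
    out = []
    for (grp, cond), sub in rec.groupby([by, "condition"], sort=False):
        out.append(
            {
                by: grp,
                "condition": cond,
                "n_proteins": len(sub),
                "mean_percent_ref": sub["mean_ref"].mean(),
                "mean_percent_test": sub["mean_test"].mean(),
                "log2fc_mean": sub["_fc"].mean(),
                "log2fc_sd": sub["_fc"].std(ddof=1),
                "n_up": int((sub["status"] == "up").sum()),
                "n_down": int((sub["status"] == "down").sum()),
                "n_ns": int((sub["status"] == "ns").sum()),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            by,
            "condition",
            "n_proteins",
            "mean_percent_ref",
            "mean_percent_test",
            "log2fc_mean",
            "log2fc_sd",
            "n_up",
            "n_down",
            "n_ns",
        ],
    )
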