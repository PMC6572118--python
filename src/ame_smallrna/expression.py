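"""Relative quantification of qRT-PCR Ct tables by the 2^-ddCt method.

Per replicate, dCt = Ct(gene) - Ct(reference gene); per condition,
ddCt = mean dCt(condition) - mean dCt(control) and the fold change is
2^-ddCt. Significance is a two-sided Welch t-test of the replicate dCt values
of the condition against the control. A gene is called up-regulated when
fold >= 2 with p < 0.05, down-regulated when fold <= 0.5 with p < 0.05,
otherwise not significant. No multiple-testing correction is applied by
default (per-gene tests); Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

FOLD_THRESHOLD = 2.0
ALPHA = 0.05


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    fold_change: float
    log2_fold: float
    replicate_sd: float
    p_value: float  # NaN when untestable (<2 replicates)
    call: str = "ns"  # 'up' | 'down' | 'ns'


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct TSV with columns gene, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _delta_ct(df: pd.DataFrame, gene: str, reference_gene: str) -> pd.DataFrame:
    """Per (condition, replicate) dCt = Ct(gene) - Ct(reference)."""
    g = df[df.gene == gene][["condition", "replicate", "ct"]]
    r = df[df.gene == reference_gene][["condition", "replicate", "ct"]]
    if r.empty:
        raise ValueError(f"reference gene '{reference_gene}' absent from Ct table")
    if g.empty:
        raise ValueError(f"gene '{gene}' absent from Ct table")
    merged = g.merge(r, on=["condition", "replicate"], suffixes=("_gene", "_ref"))
    merged["dct"] = merged["ct_gene"] - merged["ct_ref"]
    return merged[["condition", "replicate", "dct"]]


def delta_delta_ct(
    ct_table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    control_condition: str,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
) -> list[RelativeExpression]:
    """2^-ddCt fold change of ``gene`` in every non-control condition."""
    dct = _delta_ct(ct_table, gene, reference_gene)
    ctrl = dct[dct.condition == control_condition]["dct"].to_numpy()
    if ctrl.size == 0:
        raise ValueError(f"control condition '{control_condition}' absent for {gene}")
    out: list[RelativeExpression] = []
    for cond in dct["condition"].unique():
        if cond == control_condition:
            continue
        vals = dct[dct.condition == cond]["dct"].to_numpy()
        ddct = vals.mean() - ctrl.mean()
        # per-replicate folds relative to the control mean carry the spread
        rep_folds = 2.0 ** -(vals - ctrl.mean())
        fold = 2.0**-ddct
        if vals.size >= 2 and ctrl.size >= 2:
            p = float(stats.ttest_ind(vals, ctrl, equal_var=False).pvalue)
        else:
            p = float("nan")
        rel = RelativeExpression(
            gene=gene,
            condition=cond,
            fold_change=float(fold),
            log2_fold=float(-ddct),
            replicate_sd=float(rep_folds.std(ddof=1)) if vals.size >= 2 else float("nan"),
            p_value=p,
        )
        rel.call = call_responsive(rel, fold_threshold=fold_threshold, alpha=alpha)
        out.append(rel)
    return out


def call_responsive(
    rel: RelativeExpression,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
) -> str:
    """'up' iff fold >= threshold and p < alpha; 'down' iff fold <= 1/threshold
    and p < alpha; otherwise 'ns'."""
    if math.isnan(rel.p_value) or rel.p_value >= alpha:
        return "ns"
    if rel.fold_change >= fold_threshold:
        return "up"
    if rel.fold_change <= 1.0 / fold_threshold:
        return "down"
    return "ns"


def tissue_dominance(
    ct_table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    tissue_a: str = "leaf",
    tissue_b: str = "root",
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
) -> str:
    """Dominant tissue when its normalized expression is >= fold_threshold x
    the other's with p < alpha; else 'none'."""
    dct = _delta_ct(ct_table, gene, reference_gene)
    a = dct[dct.condition == tissue_a]["dct"].to_numpy()
    b = dct[dct.condition == tissue_b]["dct"].to_numpy()
    if a.size < 2 or b.size < 2:
        return "none"
    fold_a_over_b = 2.0 ** -(a.mean() - b.mean())
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if p < alpha and fold_a_over_b >= fold_threshold:
        return tissue_a
    if p < alpha and fold_a_over_b <= 1.0 / fold_threshold:
        return tissue_b
    return "none"


def responsiveness_summary(
    calls: dict[str, list[RelativeExpression]],
    classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene responsiveness (up/down at >= 1 condition; 'up' wins when a
    gene moves both ways) tabulated per class.

    ``classes`` maps gene -> class label (e.g. conserved/non_conserved);
    unlabeled genes fall in class 'all'.
    """
    rows = []
    for gene, rels in calls.items():
        directions = {r.call for r in rels} - {"ns"}
        if "up" in directions:
            verdict = "up"
        elif "down" in directions:
            verdict = "down"
        else:
            verdict = "ns"
        cls = (classes or {}).get(gene, "all")
        rows.append({"gene": gene, "class": cls, "call": verdict})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["class", "up", "down", "ns", "responsive"])
    summary = (
        df.pivot_table(index="class", columns="call", aggfunc="size", fill_value=0)
        .reindex(columns=["up", "down", "ns"], fill_value=0)
        .reset_index()
    )
    summary.columns.name = None
    summary["responsive"] = summary["up"] + summary["down"]
    return summary


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (optional; defaults off in the calling pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = n - rank_from_last
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj.tolist()


def expression_report(
    ct_table: pd.DataFrame,
    genes: list[str],
    reference_gene: str,
    control_condition: str,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    rows = []
    for gene in genes:
        for rel in delta_delta_ct(
            ct_table, gene, reference_gene, control_condition,
            fold_threshold=fold_threshold, alpha=alpha,
        ):
            rows.append(
                {
                    "gene": rel.gene,
                    "condition": rel.condition,
                    "fold_change": rel.fold_change,
                    "log2_fold": rel.log2_fold,
                    "replicate_sd": rel.replicate_sd,
                    "p_value": rel.p_value,
                    "call": rel.call,
                }
            )
    return pd.DataFrame(rows)
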