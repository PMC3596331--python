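"""qPCR expression analysis: ΔCt fold changes and t-test based calls.

Relative expression follows the ΔCt convention at 100% amplification
efficiency: ΔCt = Ct(target) - Ct(reference) per replicate (mean of the
reference genes when several are declared, emulating Actin2/18S
normalisation), relative expression = 2^(-ΔCt), and the fold change
between two conditions is 2 raised to the difference of their mean ΔCt.
Significance is a classic two-sample two-sided Student t-test on the
replicate ΔCt values (no Welch correction, no multiple-testing
adjustment by default; Benjamini-Hochberg is available as an opt-in
column).

Call rules: a treatment moves a gene "up"/"down" when the fold change
passes 1.2-fold with P < 0.05; a tissue is "preferential" for a gene only
when its expression beats EVERY other tissue by more than 2-fold with
P < 0.05 — a for-all rule that at most one tissue can satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct")

FOLD_TREATMENT = 1.2
FOLD_PREFERENTIAL = 2.0
ALPHA = 0.05


@dataclass(frozen=True)
class CtTable:
    """Replicate-level Ct measurements plus the declared reference genes."""

    data: pd.DataFrame
    reference_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        ct = self.data["ct"]
        if not ((ct > 0) & (ct < 45)).all():
            raise ValueError("Ct values must lie in (0, 45) cycles")
        counts = self.data.groupby(["gene", "condition"]).size()
        if counts.nunique() != 1:
            raise ValueError("every gene x condition must have the same replicate count")
        conditions = set(self.data["condition"])
        for ref in self.reference_genes:
            ref_conditions = set(self.data.loc[self.data["gene"] == ref, "condition"])
            if ref_conditions != conditions:
                raise ValueError(f"reference gene {ref!r} missing in some conditions")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(
            g for g in self.data["gene"].unique() if g not in self.reference_genes
        )

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.data["condition"].unique())


@dataclass(frozen=True)
class ExpressionCall:
    """Fold change and P-value for one gene in one comparison."""

    gene: str
    condition: str
    fold_change: float
    p_value: float
    call: str  # preferential | up | down | unchanged

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def read_ct_table(path: str | Path, reference_genes: Sequence[str]) -> CtTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return CtTable(data=df, reference_genes=tuple(reference_genes))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Per-replicate ΔCt and relative expression 2^(-ΔCt).

    The reference Ct is the mean over the declared reference genes within
    the same condition and replicate.
    """
    df = table.data
    ref = (
        df[df["gene"].isin(table.reference_genes)]
        .groupby(["condition", "replicate"])["ct"]
        .mean()
        .rename("ref_ct")
    )
    out = df[~df["gene"].isin(table.reference_genes)].join(
        ref, on=["condition", "replicate"], how="left"
    )
    if out["ref_ct"].isna().any():
        raise ValueError("missing reference Ct in some condition/replicate")
    out = out.assign(delta_ct=out["ct"] - out["ref_ct"])
    out = out.assign(rel_expr=2.0 ** (-out["delta_ct"]))
    return out[["gene", "condition", "replicate", "delta_ct", "rel_expr"]]


def _student_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided two-sample Student t p-value with a zero-variance guard.

    When both samples are (numerically) constant the t statistic is
    undefined; the limit value is reported instead: p = 0 for unequal
    means, 1 for equal means.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    pooled_var = np.var(a, ddof=1) + np.var(b, ddof=1)
    if pooled_var <= np.finfo(float).eps:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _pair_stats(dct: pd.DataFrame, gene: str, test: str, control: str) -> tuple[float, float]:
    sub = dct[dct["gene"] == gene]
    a = sub.loc[sub["condition"] == test, "delta_ct"].to_numpy()
    b = sub.loc[sub["condition"] == control, "delta_ct"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"gene {gene!r}: condition missing ({test!r} vs {control!r})")
    fc = 2.0 ** (b.mean() - a.mean())  # higher expression in test -> lower ΔCt
    return fc, _student_t(a, b)


def fold_change(
    table: CtTable,
    condition_test: str,
    condition_control: str,
    fold_threshold: float = FOLD_TREATMENT,
    alpha: float = ALPHA,
    adjust: bool = False,
) -> list[ExpressionCall]:
    """Treatment-vs-control calls for every non-reference gene.

    call = "up" if FC > ``fold_threshold`` and p < alpha, "down" if
    FC < 1/``fold_threshold`` and p < alpha, else "unchanged".  With
    ``adjust=True`` the alpha decision is applied to Benjamini-Hochberg
    adjusted p-values (reported p-values stay raw).
    """
    dct = delta_ct(table)
    raw: list[tuple[str, float, float]] = []
    for gene in table.genes:
        fc, p = _pair_stats(dct, gene, condition_test, condition_control)
        raw.append((gene, fc, p))
    pvals = np.array([p for _, _, p in raw])
    decision_p = _benjamini_hochberg(pvals) if adjust else pvals
    calls = []
    for (gene, fc, p), dp in zip(raw, decision_p):
        if fc > fold_threshold and dp < alpha:
            verdict = "up"
        elif fc < 1.0 / fold_threshold and dp < alpha:
            verdict = "down"
        else:
            verdict = "unchanged"
        calls.append(
            ExpressionCall(
                gene=gene, condition=condition_test, fold_change=fc, p_value=p, call=verdict
            )
        )
    return calls


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, pvals[idx] * m / rank_from_top)
        adjusted[idx] = running
    return adjusted


def preferential_call(
    table: CtTable,
    gene: str,
    fold_threshold: float = FOLD_PREFERENTIAL,
    alpha: float = ALPHA,
) -> tuple[str | None, pd.DataFrame]:
    """Tissue in which the gene is preferentially expressed, if any.

    Tissue t wins only if, against EVERY other tissue, the fold change
    exceeds ``fold_threshold`` with p < alpha; the >2-fold for-all rule
    makes the winner unique when one exists.  Returns the winning tissue
    (or None) plus the full pairwise FC/p table.
    """
    conditions = table.conditions
    if len(conditions) < 2:
        raise ValueError("preferential calls need at least two tissues")
    dct = delta_ct(table)
    rows = []
    winner = None
    for tissue in conditions:
        all_pass = True
        for other in conditions:
            if other == tissue:
                continue
            fc, p = _pair_stats(dct, gene, tissue, other)
            passed = fc > fold_threshold and p < alpha
            all_pass &= passed
            rows.append(
                {"tissue": tissue, "vs": other, "fold_change": fc, "p_value": p, "pass": passed}
            )
        if all_pass:
            winner = tissue
    return winner, pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "condition": c.condition,
                "fold_change": c.fold_change,
                "p_value": c.p_value,
                "call": c.call,
            }
            for c in calls
        ]
    )
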