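"""Expression contrasts between selected-promoter and background gene sets.

Consumes precomputed differential-expression tables (gene, tissue, stage,
log2 fold change, adjusted p) and asks two questions of each tissue: is
the proportion of differentially expressed genes higher among genes with
selected promoters (Fisher's exact test on the 2x2 table), and are the
fold changes of their DE genes larger (Welch's unequal-variance t test on
|log2FC|, up- and down-regulated strata separately, Holm-Bonferroni
adjusted across the whole contrast family)?
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_de_table",
    "deg_proportion_test",
    "fold_change_contrast",
    "ExpressionContrast",
    "ExpressionContrastResult",
]

REQUIRED_COLS = ("gene", "tissue", "log2fc", "padj")


def read_de_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    return df


def _subset(de: pd.DataFrame, gene_ids, tissue: str) -> tuple[pd.DataFrame, int]:
    ids = set(gene_ids)
    sub = de[(de["tissue"] == tissue) & de["gene"].isin(ids)]
    return sub, len(ids - set(sub["gene"]))


def deg_proportion_test(
    de: pd.DataFrame,
    selected_ids,
    background_ids,
    tissue: str,
    alpha: float = 0.05,
) -> dict:
    """Fisher's exact test on DE proportions (selected vs background).

    Returns proportions, the odds ratio, the two-sided hypergeometric p,
    and the count of requested genes absent from the table.
    """
    selected_ids = list(selected_ids)
    background_ids = list(background_ids)
    if not selected_ids or not background_ids:
        raise ValueError("both gene sets must be non-empty")
    if set(selected_ids) & set(background_ids):
        raise ValueError("gene sets must be disjoint")
    sel, miss_s = _subset(de, selected_ids, tissue)
    bg, miss_b = _subset(de, background_ids, tissue)
    if len(sel) == 0 or len(bg) == 0:
        raise ValueError(f"no genes of a set found in tissue {tissue!r}")
    a = int((sel["padj"] < alpha).sum())
    b = len(sel) - a
    c = int((bg["padj"] < alpha).sum())
    d = len(bg) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "tissue": tissue,
        "n_selected": len(sel),
        "n_background": len(bg),
        "n_missing": miss_s + miss_b,
        "prop_selected": a / len(sel),
        "prop_background": c / len(bg),
        "odds_ratio": float(odds),
        "p_value": float(p),
    }


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (statsmodels-backed)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def fold_change_contrast(
    de: pd.DataFrame,
    selected_ids,
    background_ids,
    tissues,
    alpha: float = 0.05,
    min_genes: int = 2,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per (tissue, direction) Welch test on |log2FC| of DE genes.

    Strata with fewer than ``min_genes`` DE genes in either set are
    flagged and excluded from the Holm family; all remaining strata from
    one invocation form a single adjustment family.
    """
    rows = []
    for tissue in tissues:
        sel, _ = _subset(de, selected_ids, tissue)
        bg, _ = _subset(de, background_ids, tissue)
        sel = sel[sel["padj"] < alpha]
        bg = bg[bg["padj"] < alpha]
        for direction, keep in (("up", lambda x: x > 0), ("down", lambda x: x < 0)):
            s_vals = sel.loc[keep(sel["log2fc"]), "log2fc"].abs().to_numpy()
            b_vals = bg.loc[keep(bg["log2fc"]), "log2fc"].abs().to_numpy()
            row = {
                "tissue": tissue,
                "direction": direction,
                "n_selected": len(s_vals),
                "n_background": len(b_vals),
                "mean_abs_lfc_selected": float(np.mean(s_vals)) if len(s_vals) else np.nan,
                "mean_abs_lfc_background": float(np.mean(b_vals)) if len(b_vals) else np.nan,
            }
            if len(s_vals) >= min_genes and len(b_vals) >= min_genes:
                t, p = stats.ttest_ind(s_vals, b_vals, equal_var=equal_var)
                row["p_value"] = float(p)
                row["excluded"] = False
            else:
                row["p_value"] = np.nan
                row["excluded"] = True
            rows.append(row)
    out = pd.DataFrame(rows)
    ok = ~out["excluded"]
    out["p_holm"] = np.nan
    out.loc[ok, "p_holm"] = holm_adjust(out.loc[ok, "p_value"].to_numpy())
    return out


@dataclass
class ExpressionContrast:
    """Selected-vs-background expression contrast, statsmodels-style."""

    de: pd.DataFrame
    selected_ids: list
    background_ids: list
    tissues: tuple = None
    alpha: float = 0.05
    equal_var: bool = False  # True -> Student's pooled test

    def __post_init__(self):
        if self.tissues is None:
            self.tissues = tuple(pd.unique(self.de["tissue"]))

    def fit(self) -> "ExpressionContrastResult":
        props = pd.DataFrame(
            [
                deg_proportion_test(self.de, self.selected_ids, self.background_ids, t, self.alpha)
                for t in self.tissues
            ]
        )
        folds = fold_change_contrast(
            self.de, self.selected_ids, self.background_ids, self.tissues,
            self.alpha, equal_var=self.equal_var,
        )
        return ExpressionContrastResult(self, props, folds)


@dataclass
class ExpressionContrastResult:
    model: ExpressionContrast
    proportion_tests: pd.DataFrame
    fold_change_tests: pd.DataFrame = field(default=None)

    def summary(self) -> str:
        lines = [
            "Expression contrast: selected promoters vs background",
            "=" * 53,
            f"selected genes: {len(self.model.selected_ids)}; background: {len(self.model.background_ids)}",
            "",
            "DE-proportion (Fisher exact):",
        ]
        for r in self.proportion_tests.itertuples(index=False):
            lines.append(
                f"  {r.tissue:<8} {100*r.prop_selected:5.1f}% vs {100*r.prop_background:5.1f}%  "
                f"OR={r.odds_ratio:6.2f}  P={r.p_value:.3g}"
            )
        lines.append("")
        lines.append("|log2FC| of DE genes (Welch, Holm-adjusted):")
        for r in self.fold_change_tests.itertuples(index=False):
            if r.excluded:
                lines.append(f"  {r.tissue:<8} {r.direction:<4} (too few DE genes)")
            else:
                lines.append(
                    f"  {r.tissue:<8} {r.direction:<4} {r.mean_abs_lfc_selected:5.2f} vs "
                    f"{r.mean_abs_lfc_background:5.2f}  P_holm={r.p_holm:.3g}"
                )
        return "\n".join(lines)
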