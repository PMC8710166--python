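"""Differential-expression threshold screening and qPCR quantification.

Operates on a normalized gene × sample expression matrix with a two-group
(control vs exposed) design.  The screening arithmetic is deliberately
simple and transparent:

* per-gene log2 fold change of group means (with a pseudocount),
* a two-sided Welch unequal-variance t-test per gene, computed on
  log2(value + 1) by default — this is a self-contained substitute for
  count-model differential testing (DESeq-style negative-binomial fits
  are out of scope here), and externally computed p-values can be screened
  instead,
* Benjamini–Hochberg FDR adjustment,
* threshold screening: a gene is *up* if log2FC >= +1 (inclusive) and
  significant, *down* if log2FC <= −1; the significance cut is strict
  (p < alpha), on raw p by default or on BH-adjusted p in FDR mode,
* 2^−ΔΔCt relative quantification for qRT-PCR validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

CONTROL = "control"
EXPOSED = "exposed"


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of non-negative normalized expression values.

    Parameters
    ----------
    values : DataFrame indexed by unique gene ids, columns are sample ids.
    groups : mapping/Series sample id -> group label ("control"/"exposed").
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    def group_columns(self, group: str) -> pd.DataFrame:
        cols = self.groups.index[self.groups == group]
        if len(cols) == 0:
            raise ValidationError(f"no samples labelled {group!r}")
        return self.values[cols]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the DEG screen.

    ``use_adjusted=False`` (default) screens on raw p < alpha; True screens
    on BH-adjusted p (FDR mode).  The fold-change cut is inclusive on both
    sides (|log2FC| >= min_abs_log2fc).
    """

    min_abs_log2fc: float = 1.0
    alpha: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValidationError("min_abs_log2fc must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha!r}")


@dataclass(frozen=True)
class DdctInput:
    """Cycle-threshold quadruple for one target gene and one reference gene."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_treated",
            "ct_ref_treated",
            "ct_target_control",
            "ct_ref_control",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")


def log2_fold_change(
    mat: ExpressionMatrix,
    gene: str | None = None,
    pseudocount: float = 1.0,
) -> "float | pd.Series":
    """log2((mean_exposed + c) / (mean_control + c)) per gene.

    Returns a scalar for a single ``gene``, otherwise a Series over all
    genes.  The pseudocount ``c`` (default 1) guards all-zero genes.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    exposed = mat.group_columns(EXPOSED).mean(axis=1)
    control = mat.group_columns(CONTROL).mean(axis=1)
    lfc = np.log2((exposed + pseudocount) / (control + pseudocount))
    lfc.name = "log2fc"
    if gene is None:
        return lfc
    if gene not in lfc.index:
        raise ValidationError(f"gene {gene!r} not in matrix")
    return float(lfc.loc[gene])


def welch_t_pvalues(mat: ExpressionMatrix, log_transform: bool = True) -> pd.Series:
    """Two-sided Welch t-test p per gene, exposed vs control.

    With ``log_transform`` (default) the test is run on log2(value + 1),
    which keeps the t-statistic well calibrated on log-normal-like
    expression values.  Genes with zero variance in both groups and equal
    means get p = 1.
    """
    exposed = mat.group_columns(EXPOSED)
    control = mat.group_columns(CONTROL)
    if exposed.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError("welch_t_pvalues needs at least 2 samples per group")
    a = exposed.to_numpy(dtype=float)
    b = control.to_numpy(dtype=float)
    if log_transform:
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: nan from 0/0 -> no evidence against the null
    degenerate = np.isnan(p) & np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate] = 1.0
    return pd.Series(p, index=mat.gene_ids, name="p")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_k = min_{j >= k} (m * p_(j) / j) on the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must all lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of a DEG screen: gene lists and Table-8-shaped counts."""

    table: pd.DataFrame  # gene_id, log2fc, p, padj, direction
    up: tuple[str, ...]
    down: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {"total": len(self.up) + len(self.down),
                "up": len(self.up), "down": len(self.down)}


def screen_degs(
    results: pd.DataFrame,
    criteria: ScreenCriteria | None = None,
) -> ScreenResult:
    """Apply the |log2FC| >= 1, p < 0.05 screen to per-gene results.

    Parameters
    ----------
    results : DataFrame with columns ``gene_id`` (or the index), ``log2fc``
        and ``p``; a ``padj`` column is computed by BH if absent.  Accepts
        externally computed statistics (e.g. a count-model test) as-is.
    """
    if criteria is None:
        criteria = ScreenCriteria()
    df = results.copy()
    if "gene_id" not in df.columns:
        df = df.reset_index(names="gene_id")
    for col in ("log2fc", "p"):
        if col not in df.columns:
            raise ValidationError(f"results missing required column {col!r}")
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise ValidationError(f"non-finite values in column {col!r}")
    if "padj" not in df.columns:
        df["padj"] = bh_fdr(df["p"].to_numpy())
    pcol = "padj" if criteria.use_adjusted else "p"
    sig = df[pcol].to_numpy(dtype=float) < criteria.alpha
    lfc = df["log2fc"].to_numpy(dtype=float)
    up_mask = sig & (lfc >= criteria.min_abs_log2fc)
    down_mask = sig & (lfc <= -criteria.min_abs_log2fc)
    direction = np.where(up_mask, "up", np.where(down_mask, "down", "none"))
    df["direction"] = direction
    return ScreenResult(
        table=df,
        up=tuple(df.loc[up_mask, "gene_id"]),
        down=tuple(df.loc[down_mask, "gene_id"]),
    )


def differential_expression(
    mat: ExpressionMatrix,
    criteria: ScreenCriteria | None = None,
    pseudocount: float = 1.0,
    log_transform: bool = True,
) -> ScreenResult:
    """Full screen on a matrix: fold change + Welch test + BH + thresholds."""
    lfc = log2_fold_change(mat, pseudocount=pseudocount)
    p = welch_t_pvalues(mat, log_transform=log_transform)
    results = pd.DataFrame({"log2fc": lfc, "p": p})
    return screen_degs(results, criteria)


def ddct_relative_expression(d: DdctInput) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference) within each condition; the fold
    change of treated vs control is 2 to the negative ΔΔCt.
    """
    dct_treated = d.ct_target_treated - d.ct_ref_treated
    dct_control = d.ct_target_control - d.ct_ref_control
    return float(2.0 ** -(dct_treated - dct_control))
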