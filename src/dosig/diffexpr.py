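"""Per-gene tumor-vs-normal differential expression.

Each gene is tested with either a two-sample z-test or a Mann-Whitney U
test. The parametric branch is taken only when an Anderson-Darling test
accepts normality (p > 0.05) in *both* classes and both classes have at
least 8 samples; any failure routes the gene to the rank test. Raw
p-values are Benjamini-Hochberg adjusted across all tested genes, and a
gene is called differentially expressed when adjusted p < ``p_cut`` and
|log2FC| >= ``fc_cut``. The retained list is ranked by adjusted p
(ties: larger |log2FC|, then gene id) and truncated to the user input
size ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset, LINEAR, NORMAL, TUMOR

MANN_WHITNEY = "mann_whitney"
Z_TEST = "z_test"

#: default pseudo-count added to linear-scale group means before the log2 ratio
DEFAULT_EPSILON = 0.25


class NormalityTestUnavailable(ValueError):
    """Anderson-Darling cannot run (n < 8 or zero variance); caller must
    fall back to the nonparametric branch."""


def anderson_darling(values) -> tuple[float, float]:
    """Anderson-Darling normality test with estimated mean/SD.

    Returns the small-sample-corrected statistic A* = A2*(1 + 0.75/n +
    2.25/n^2) and its p-value from the D'Agostino-Stephens piecewise
    exponential approximation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise NormalityTestUnavailable(f"need n >= 8, got {x.size}")
    if np.std(x, ddof=1) == 0:
        raise NormalityTestUnavailable("zero variance")
    a2, p = normal_ad(x)
    n = x.size
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    return float(a2_star), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U reported for group ``a``).

    Exact null distribution when n_a + n_b <= 16 and there are no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 16 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def two_sample_z(a, b) -> tuple[float, float]:
    """Unpooled two-sample z-test with plug-in sample variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    se2 = np.var(a, ddof=1) / a.size + np.var(b, ddof=1) / b.size
    if se2 <= 0:
        raise ValueError("zero pooled variance")
    z = (a.mean() - b.mean()) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def log2_fold_change(a, b, scale: str = LINEAR, epsilon: float = DEFAULT_EPSILON) -> float:
    """log2 ratio of tumor to normal means (difference of means on log2 scale)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if scale == LINEAR:
        return float(np.log2((a.mean() + epsilon) / (b.mean() + epsilon)))
    return float(a.mean() - b.mean())


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGTable:
    """Retained differentially expressed genes plus the thresholds applied.

    ``records`` has columns gene_id, test_used, statistic, p_raw, p_adj,
    log2fc, direction, sorted by the ranking used for the top-n cut.
    ``all_results`` keeps the untruncated per-gene table for diagnostics.
    """

    records: pd.DataFrame
    p_cut: float
    fc_cut: float
    n: int | None
    all_results: pd.DataFrame = field(repr=False, default=None)

    @property
    def genes(self) -> list[str]:
        return list(self.records["gene_id"])

    def is_empty(self) -> bool:
        return len(self.records) == 0

    def to_tsv(self, path) -> None:
        self.records.to_csv(Path(path), sep="\t", index=False)


_COLUMNS = ["gene_id", "test_used", "statistic", "p_raw", "p_adj", "log2fc", "direction"]


def run_differential_expression(
    ds: ExpressionDataset,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
    n: int | None = None,
    epsilon: float = DEFAULT_EPSILON,
    normality_alpha: float = 0.05,
) -> DEGTable:
    """Test every gene, adjust, threshold and truncate to the input size."""
    tumor = ds.tumor_samples
    normal = ds.normal_samples
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError(
            f"need >= 3 samples per class, got {len(tumor)} tumor / {len(normal)} normal"
        )
    tmat = ds.values[tumor].to_numpy(float)
    nmat = ds.values[normal].to_numpy(float)
    big_enough = len(tumor) >= 8 and len(normal) >= 8

    rows = []
    for gi, gene in enumerate(ds.gene_ids):
        a, b = tmat[gi], nmat[gi]
        use_z = False
        if big_enough:
            try:
                use_z = (
                    anderson_darling(a)[1] > normality_alpha
                    and anderson_darling(b)[1] > normality_alpha
                )
            except NormalityTestUnavailable:
                use_z = False
        if use_z:
            stat, p = two_sample_z(a, b)
            test = Z_TEST
        else:
            stat, p = mann_whitney_u(a, b)
            test = MANN_WHITNEY
        fc = log2_fold_change(a, b, scale=ds.scale, epsilon=epsilon)
        rows.append((gene, test, stat, p, fc))

    table = pd.DataFrame(rows, columns=["gene_id", "test_used", "statistic", "p_raw", "log2fc"])
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    table = table[_COLUMNS]

    kept = table[(table["p_adj"] < p_cut) & (table["log2fc"].abs() >= fc_cut)].copy()
    kept["_absfc"] = kept["log2fc"].abs()
    kept = kept.sort_values(
        ["p_adj", "_absfc", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absfc")
    if n is not None:
        kept = kept.head(int(n))
    kept = kept.reset_index(drop=True)
    return DEGTable(records=kept, p_cut=p_cut, fc_cut=fc_cut, n=n, all_results=table)
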