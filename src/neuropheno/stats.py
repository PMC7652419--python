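"""Group statistics: t tests, normality screening, two-stage FDR, ΔΔCt.

The inferential toolkit used across the pipeline: two-tailed unpaired t
tests (pooled-variance by default, Welch–Satterthwaite on request), a
one-sample Kolmogorov–Smirnov normality screen against a normal with the
sample's own mean and SD, the adaptive two-stage linear step-up
false-discovery procedure of Benjamini, Krieger and Yekutieli (BKY) at
q = 5%, and ΔΔCt relative quantification of qPCR panels normalised to a
housekeeping gene (GAPDH) and a reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "t_test",
    "ks_normality",
    "fdr_bky",
    "ddct_fold_change",
    "delta_ct",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """Two-sample comparison summary (mean ± SEM per group, t, df, p)."""

    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    statistic: float
    df: float
    pvalue: float
    kind: str  # "pooled" | "welch"

    def summary(self) -> str:
        (la, lb), (na, nb) = self.labels, self.n
        return (
            f"{la} (n={na}): {self.means[0]:.4g} ± {self.sems[0]:.3g}  vs  "
            f"{lb} (n={nb}): {self.means[1]:.4g} ± {self.sems[1]:.3g}; "
            f"t({self.df:.4g}) = {self.statistic:.4g}, p = {self.pvalue:.4g} "
            f"[{self.kind}]"
        )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def t_test(
    a: np.ndarray,
    b: np.ndarray,
    welch: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-tailed unpaired t test (pooled variance, or Welch when flagged).

    When both groups are constant with equal means the statistic is taken
    as 0 with p = 1 by convention (logged), rather than propagating a 0/0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    kind = "welch" if welch else "pooled"
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        logger.info("zero variance in both groups with equal means: t=0, p=1")
        t_stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        labels=labels,
        n=(a.size, b.size),
        means=(float(np.mean(a)), float(np.mean(b))),
        sems=(_sem(a), _sem(b)),
        statistic=t_stat,
        df=df,
        pvalue=p,
        kind=kind,
    )


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample K-S test against N(mean, SD) with estimated parameters.

    Mirrors the historical normality-screen usage; estimating the
    parameters from the same sample makes the test anti-conservative
    (a Lilliefors-type correction is deliberately not substituted), which
    is logged rather than silently corrected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("normality screen needs n >= 5")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    logger.debug(
        "K-S normality screen with estimated parameters is anti-conservative"
    )
    res = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(res.statistic), float(res.pvalue)


def _bh_mask(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up discovery mask at level alpha."""
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= thresh)[0]
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask


def fdr_bky(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Two-stage linear step-up FDR control (BKY) at level ``q``.

    Stage 1 runs Benjamini–Hochberg at q′ = q/(1+q) to estimate the number
    of true nulls m₀ = m − r₁; stage 2 re-runs BH at q′·m/m₀.  Edge cases:
    no stage-1 discoveries → none overall; all discovered at stage 1 → all.
    Returns a boolean discovery mask aligned with the input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q1 = q / (1.0 + q)
    stage1 = _bh_mask(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(p.size, dtype=bool)
    if r1 == p.size:
        return np.ones(p.size, dtype=bool)
    m0 = p.size - r1
    return _bh_mask(p, q1 * p.size / m0)


def delta_ct(
    ct: pd.DataFrame,
    housekeeping: str = "Gapdh",
    gene_col: str = "gene",
    ct_col: str = "ct",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Per-subject ΔCt = Ct_gene − Ct_housekeeping for every target gene."""
    if housekeeping not in set(ct[gene_col]):
        raise ValueError(f"housekeeping gene {housekeeping!r} missing from table")
    hk = (
        ct[ct[gene_col] == housekeeping]
        .set_index(subject_col)[ct_col]
        .rename("ct_hk")
    )
    targets = ct[ct[gene_col] != housekeeping].copy()
    missing = set(targets[subject_col]) - set(hk.index)
    if missing:
        raise ValueError(f"subjects missing housekeeping Ct: {sorted(missing)}")
    targets = targets.join(hk, on=subject_col)
    targets["dct"] = targets[ct_col] - targets["ct_hk"]
    return targets


def ddct_fold_change(
    ct: pd.DataFrame,
    reference_group: str,
    housekeeping: str = "Gapdh",
    group_col: str = "group",
    gene_col: str = "gene",
    ct_col: str = "ct",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """ΔΔCt fold changes per gene, treated relative to the reference group.

    ΔCt is aggregated within groups by the arithmetic mean (equivalently
    the geometric mean of relative quantities 2^−ΔCt);
    ΔΔCt = mean ΔCt(treated) − mean ΔCt(reference);
    fold change = 2^(−ΔΔCt).  Per-subject ΔCt values are returned by
    :func:`delta_ct` for downstream t tests.
    """
    groups = list(pd.unique(ct[group_col]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    others = [g for g in groups if g != reference_group]
    if len(others) != 1:
        raise ValueError("exactly two groups are required")
    treated = others[0]
    d = delta_ct(ct, housekeeping, gene_col, ct_col, subject_col)
    rows = []
    for gene, grp in d.groupby(gene_col, sort=True):
        ref = grp[grp[group_col] == reference_group]["dct"]
        trt = grp[grp[group_col] == treated]["dct"]
        if ref.empty or trt.empty:
            raise ValueError(f"gene {gene!r} lacks data in one group")
        ddct = float(trt.mean() - ref.mean())
        rows.append(
            {
                "gene": gene,
                "ddct": ddct,
                "fold_change": float(2.0 ** (-ddct)),
                "n_ref": int(ref.size),
                "n_treated": int(trt.size),
            }
        )
    return pd.DataFrame(rows)
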