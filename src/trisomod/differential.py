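"""Karyotype-specific gene module tests.

Given the latent activity matrix ``B`` (modules x samples) and per-sample
karyotype labels, each module's activities are compared between T21 and D21
samples with a two-sided Wilcoxon rank-sum test (exact distribution for small
tie-free groups, normal approximation with continuity and tie correction
otherwise), followed by Benjamini-Hochberg correction. Modules passing the
FDR gate are flagged as T21-specific gene modules (SGMs); the strongest ones
additionally pass an absolute effect-size threshold on the difference of group
means of the standardized activities.

The activity matrix is standardized and signed, so a fold change is
ill-defined; the effect size reported here is mean(T21) - mean(D21) in
standardized activity units and the conventional 0.25 threshold is applied to
its absolute value. Output metadata records this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .errors import DegenerateDataError, InvalidInputError

EFFECT_CONVENTION = "difference of group means of standardized activities (T21 - D21)"


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values, returned in the input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise InvalidInputError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p for x vs y: exact when both groups <= 25 and tie-free."""
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def test_differential_activity(B: pd.DataFrame, karyotype: pd.Series) -> pd.DataFrame:
    """Per-module Wilcoxon comparison of T21 vs D21 activities.

    Returns a table indexed by module with columns statistic, pvalue, fdr,
    effect (mean T21 - mean D21), direction.
    """
    karyotype = pd.Series(karyotype).reindex(B.columns)
    if karyotype.isna().any():
        raise InvalidInputError("karyotype labels missing for some samples of B")
    t21 = B.columns[karyotype == "T21"]
    d21 = B.columns[karyotype == "D21"]
    if len(t21) < 2 or len(d21) < 2:
        raise InvalidInputError("each karyotype group needs at least 2 samples")
    stats, pvals, effects = [], [], []
    for lv in B.index:
        x = B.loc[lv, t21].to_numpy(dtype=float)
        y = B.loc[lv, d21].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            stat, p = float(len(x) * len(y)) / 2.0, 1.0
        else:
            stat, p = _wilcoxon(x, y)
        stats.append(stat)
        pvals.append(p)
        effects.append(float(x.mean() - y.mean()))
    table = pd.DataFrame({
        "statistic": stats,
        "pvalue": pvals,
        "fdr": benjamini_hochberg(pvals),
        "effect": effects,
    }, index=pd.Index(B.index, name="lv"))
    table["direction"] = np.where(table["effect"] > 0, "up", "down")
    table.attrs["effect_convention"] = EFFECT_CONVENTION
    return table


def select_sgm(table: pd.DataFrame, fdr_threshold: float = 0.05,
               effect_threshold: float = 0.25) -> pd.DataFrame:
    """Flag SGMs (fdr < threshold) and top SGMs (additionally |effect| > threshold)."""
    out = table.copy()
    out["is_sgm"] = out["fdr"] < fdr_threshold
    out["is_top_sgm"] = out["is_sgm"] & (out["effect"].abs() > effect_threshold)
    out.attrs.update(table.attrs)
    out.attrs["fdr_threshold"] = fdr_threshold
    out.attrs["effect_threshold"] = effect_threshold
    return out


def summarize_sgm(table: pd.DataFrame) -> dict:
    """Counts of SGMs by direction and of top SGMs."""
    sgm = table[table["is_sgm"]]
    return {
        "n_modules": int(len(table)),
        "n_sgm": int(len(sgm)),
        "n_up": int((sgm["direction"] == "up").sum()),
        "n_down": int((sgm["direction"] == "down").sum()),
        "n_top_sgm": int(table["is_top_sgm"].sum()),
    }


@dataclass
class FisherResult:
    """A 2x2 exact test result."""

    table: np.ndarray
    odds_ratio: float
    pvalue: float
    sidedness: str


def chr21_representation_test(Z: pd.DataFrame, sgm_flags: pd.Series,
                              gene_chromosomes: pd.Series,
                              membership_frac: float = 0.05) -> FisherResult:
    """Fisher exact test of chromosome-21 gene representation, SGM vs non-SGM modules.

    A gene belongs to a module group when it falls in the top
    ``membership_frac`` by absolute loading of any module in that group.
    Genes qualifying for both groups are counted once, in the SGM group, so
    the 2x2 table is disjoint.
    """
    from .annotate import top_genes  # local import avoids a module cycle

    sgm_flags = pd.Series(sgm_flags).reindex(Z.columns)
    if sgm_flags.isna().any():
        raise InvalidInputError("sgm_flags must cover every module of Z")
    chroms = pd.Series(gene_chromosomes).reindex(Z.index)
    if chroms.isna().any():
        raise InvalidInputError("chromosome annotation must cover all genes in Z")
    sgm_members: set[str] = set()
    other_members: set[str] = set()
    for lv in Z.columns:
        top = top_genes(Z, lv, membership_frac)
        if bool(sgm_flags[lv]):
            sgm_members |= top
        else:
            other_members |= top
    other_members -= sgm_members
    if not sgm_members or not other_members:
        raise DegenerateDataError("one of the module gene groups is empty")
    is21 = chroms.astype(str) == "21"
    a = int(is21[list(sgm_members)].sum())
    b = int(is21[list(other_members)].sum())
    counts = np.array([[a, b],
                       [len(sgm_members) - a, len(other_members) - b]], dtype=int)
    odds, p = fisher_exact(counts, alternative="two-sided")
    return FisherResult(table=counts, odds_ratio=float(odds), pvalue=float(p),
                        sidedness="two-sided")
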