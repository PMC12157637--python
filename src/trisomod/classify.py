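"""Module-based comorbidity classification among T21 samples.

Each module's per-sample activity is treated as a univariate score for
separating comorbidity cases from controls, quantified by ROC AUC
(Mann-Whitney normalization, ties 0.5) and by a class-balanced mean average
precision (mAPS): the average precision recomputed over repeated subsamples of
the negative class matched in size to the positives, then averaged. A module
"passes" for a comorbidity when both AUC and mAPS exceed their thresholds
(default 0.65 each); a minimum case count is exposed as configuration.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.metrics import average_precision_score, roc_auc_score

from .differential import FisherResult
from .errors import DegenerateDataError, InvalidInputError, UndefinedMetricError

logger = logging.getLogger(__name__)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    lab = np.asarray(labels)
    if not np.isin(lab, (0, 1)).all():
        raise InvalidInputError("labels must be binary 0/1")
    return lab.astype(int)


def roc_auc(scores, labels) -> float:
    """Probability a random case outscores a random control (ties 0.5)."""
    lab = _check_binary(labels)
    if lab.min() == lab.max():
        raise UndefinedMetricError("ROC AUC undefined with a single class")
    return float(roc_auc_score(lab, np.asarray(scores, dtype=float)))


def average_precision(scores, labels) -> float:
    """Step-sum average precision over the score-sorted threshold sequence."""
    lab = _check_binary(labels)
    if lab.sum() == 0:
        raise UndefinedMetricError("average precision undefined without cases")
    return float(average_precision_score(lab, np.asarray(scores, dtype=float)))


def balanced_maps(scores, labels, iterations: int = 50,
                  seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Mean and SD of average precision over negative-class subsamples.

    Each iteration draws n_cases controls without replacement and scores the
    cases plus that subsample; when controls are fewer than cases all controls
    are used every iteration (logged).
    """
    lab = _check_binary(labels)
    sc = np.asarray(scores, dtype=float)
    cases = np.flatnonzero(lab == 1)
    controls = np.flatnonzero(lab == 0)
    if cases.size == 0:
        raise UndefinedMetricError("balanced mAPS undefined without cases")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_draw = cases.size
    if controls.size < n_draw:
        logger.info("fewer controls (%d) than cases (%d); using all controls "
                    "each iteration", controls.size, n_draw)
        n_draw = controls.size
    vals = np.empty(iterations)
    for i in range(iterations):
        sub = rng.choice(controls, size=n_draw, replace=False)
        keep = np.concatenate([cases, sub])
        vals[i] = average_precision(sc[keep], lab[keep])
    return float(vals.mean()), float(vals.std())


def evaluate_modules(B: pd.DataFrame, metadata: pd.DataFrame,
                     comorbidities: list[str] | None = None,
                     modules: list[str] | None = None,
                     auc_threshold: float = 0.65, maps_threshold: float = 0.65,
                     iterations: int = 50, seed: int = 0,
                     min_class_size: int = 5) -> pd.DataFrame:
    """AUC / mAPS of every (module, comorbidity) pair among T21 samples.

    Samples with a missing status are excluded pairwise; pairs with fewer than
    ``min_class_size`` cases or controls are skipped with a log record. Each
    pair gets an independent subsampling stream derived from the master seed,
    so re-running a single pair reproduces its mAPS exactly.
    """
    modules = list(B.index) if modules is None else list(modules)
    if comorbidities is None:
        comorbidities = [c for c in metadata.columns if c != "karyotype"]
    t21 = metadata.index[metadata["karyotype"] == "T21"]
    t21 = [s for s in t21 if s in B.columns]
    rows = []
    for ci, com in enumerate(comorbidities):
        status = metadata.loc[t21, com]
        valid = status.notna()
        labels = status[valid].astype(int)
        n_cases = int((labels == 1).sum())
        n_controls = int((labels == 0).sum())
        for mi, lv in enumerate(modules):
            if n_cases < min_class_size or n_controls < min_class_size:
                logger.info("pair (%s, %s) skipped: %d cases / %d controls",
                            lv, com, n_cases, n_controls)
                continue
            scores = B.loc[lv, labels.index].to_numpy(dtype=float)
            auc = roc_auc(scores, labels.to_numpy())
            aps = average_precision(scores, labels.to_numpy())
            rng = np.random.default_rng(np.random.SeedSequence([seed, mi, ci]))
            maps, maps_sd = balanced_maps(scores, labels.to_numpy(),
                                          iterations=iterations, seed=rng)
            rows.append({"lv": lv, "comorbidity": com, "n_cases": n_cases,
                         "n_controls": n_controls, "auc": auc, "aps": aps,
                         "maps": maps, "maps_sd": maps_sd,
                         "passes": auc > auc_threshold and maps > maps_threshold})
    return pd.DataFrame(rows, columns=["lv", "comorbidity", "n_cases",
                                       "n_controls", "auc", "aps", "maps",
                                       "maps_sd", "passes"])


def quartile_enrichment(scores, labels, quantile_level: float = 0.75) -> FisherResult:
    """One-sided Fisher test of case over-representation above a score quantile.

    Samples are dichotomized at the empirical ``quantile_level`` of the scores
    (>= threshold vs below); the 2x2 table against case status is tested with
    the one-sided ("greater") exact test.
    """
    lab = _check_binary(labels)
    if lab.min() == lab.max():
        raise UndefinedMetricError("quartile enrichment needs both classes")
    sc = np.asarray(scores, dtype=float)
    if np.all(sc == sc[0]):
        raise DegenerateDataError("all scores identical; no quartile split exists")
    threshold = float(np.quantile(sc, quantile_level))
    high = sc >= threshold
    counts = np.array([
        [int((high & (lab == 1)).sum()), int((high & (lab == 0)).sum())],
        [int((~high & (lab == 1)).sum()), int((~high & (lab == 0)).sum())],
    ])
    odds, p = fisher_exact(counts, alternative="greater")
    return FisherResult(table=counts, odds_ratio=float(odds), pvalue=float(p),
                        sidedness="greater")
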