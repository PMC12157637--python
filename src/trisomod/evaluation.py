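"""Truth-aware evaluation of a fitted pipeline run on synthetic data.

Fitted modules carry arbitrary labels, so comparing a run against the planted
truth needs a correspondence between fitted and true modules. Two notions are
used, each where it is the right tool:

* one-to-one matching (assignment problem on absolute loading correlations)
  for *recovery* summaries — how faithfully the planted loading columns were
  reconstructed;
* argmax tagging (each fitted module is tagged with its single best-correlated
  true module) for *false-positive* accounting — a fitted module that splits
  or duplicates a planted module still carries real planted signal, and
  counting it as a false positive would misstate the method's specificity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .factorize import FactorModel, match_modules
from .simulate import SyntheticTruth


def tag_modules(Z_hat: pd.DataFrame, Z_true: pd.DataFrame) -> pd.DataFrame:
    """Tag each fitted module with its best-correlated true module (argmax)."""
    A = Z_hat.to_numpy(dtype=float)
    T = Z_true.reindex(Z_hat.index).to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    T = T - T.mean(axis=0)
    an = np.linalg.norm(A, axis=0)
    tn = np.linalg.norm(T, axis=0)
    an[an == 0] = 1.0
    tn[tn == 0] = 1.0
    corr = np.abs((A / an).T @ (T / tn))
    best = corr.argmax(axis=1)
    return pd.DataFrame({
        "lv": list(Z_hat.columns),
        "best_true": [Z_true.columns[j] for j in best],
        "abs_corr": corr[np.arange(corr.shape[0]), best],
    }).set_index("lv")


def planted_recovery_summary(model: FactorModel, report: dict,
                             truth: SyntheticTruth) -> dict:
    """Compare one pipeline run's flags against the planted truth.

    Returns per-stage counts of recovered planted items and of false
    positives among nulls, plus the mean matched loading correlation.
    """
    tags = tag_modules(model.Z, truth.Z_true)
    tag_of = tags["best_true"].to_dict()
    matched = match_modules(model.Z, truth.Z_true)

    planted_sgm_names = {f"LV{i + 1}" for i in truth.planted_sgm}
    sgm = list(report["stages"]["differential"]["sgm"])
    covered = {tag_of[lv] for lv in sgm}
    sgm_recovered = len(planted_sgm_names & covered)
    sgm_fp = sum(1 for lv in sgm if tag_of[lv] not in planted_sgm_names)

    links = [(lv, trait) for lv, trait in report["stages"]["association"]["links"]]
    planted_pairs = {(trait, f"LV{m + 1}") for trait, m in truth.planted_trait_pairs}
    link_hits = {(trait, tag_of[lv]) for lv, trait in links} & planted_pairs
    link_fp = sum(1 for lv, trait in links
                  if (trait, tag_of[lv]) not in planted_pairs)

    passing = [(lv, com) for lv, com in report["stages"]["classification"]["passing"]]
    planted_coms = {(com, f"LV{m + 1}")
                    for com, m in truth.planted_comorbidity_pairs}
    com_hits = {(com, tag_of[lv]) for lv, com in passing} & planted_coms
    com_fp = sum(1 for lv, com in passing
                 if (com, tag_of[lv]) not in planted_coms)

    return {
        "mean_matched_abs_corr": float(matched["abs_corr"].mean()),
        "n_sgm": len(sgm),
        "planted_sgm": len(planted_sgm_names),
        "planted_sgm_recovered": sgm_recovered,
        "sgm_false_positives": sgm_fp,
        "n_links": len(links),
        "planted_links": len(planted_pairs),
        "planted_links_recovered": len(link_hits),
        "link_false_positives": link_fp,
        "n_passing_pairs": len(passing),
        "planted_comorbidities": len(planted_coms),
        "planted_comorbidities_recovered": len(com_hits),
        "comorbidity_false_positives": com_fp,
    }


def all_planted_recovered(summary: dict) -> bool:
    return (summary["planted_sgm_recovered"] == summary["planted_sgm"]
            and summary["planted_links_recovered"] == summary["planted_links"]
            and summary["planted_comorbidities_recovered"]
            == summary["planted_comorbidities"])


def no_false_positives(summary: dict) -> bool:
    return (summary["sgm_false_positives"] == 0
            and summary["link_false_positives"] == 0
            and summary["comorbidity_false_positives"] == 0)
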