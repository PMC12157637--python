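"""Pathway-guided penalized matrix factorization.

Decomposes a row-normalized expression matrix ``X`` (genes x samples) into
nonnegative gene loadings ``Z`` (genes x k) and latent activities ``B``
(k x samples), while pulling ``Z`` toward a sparse nonnegative combination
``C @ U`` of prior gene-set membership columns:

    minimize  ||X - Z B||_F^2 + lam1 ||Z - C U||_F^2
              + lam2 ||B||_F^2 + lam3 ||U||_1
    subject to  Z >= 0,  U >= 0

solved by block coordinate minimization: ``B`` by ridge least squares in
closed form, ``Z`` by cyclic exact column updates with nonnegativity, ``U`` by
cyclic coordinate soft-thresholding with nonnegativity. Every block step is an
exact minimization over its block, so the objective is non-increasing.

The number of components is estimated by permutation-based parallel analysis;
pathway alignment of a fitted model is scored by rank-sum AUC of held-out
gene-set members, with the hold-out masked from ``C`` before fitting.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import mannwhitneyu

from . import io
from .differential import benjamini_hochberg
from .errors import GeneAlignmentError, InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization

def zscore_rows(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene row (n-1 denominator); constant rows become all-zero.

    Raises :class:`InvalidInputError` when fewer than two samples are present.
    Constant rows are flagged with a log warning.
    """
    if X.shape[1] < 2:
        raise InvalidInputError("z-scoring needs at least 2 samples per gene")
    vals = X.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (vals - mu) / sd_safe
    if const.any():
        out[const] = 0.0
        logger.warning("%d constant gene rows set to zero during normalization",
                       int(const.sum()))
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ---------------------------------------------------------------------------
# component-number estimation (parallel analysis)

def estimate_num_components(Xn: pd.DataFrame | np.ndarray, n_permutations: int = 20,
                            quantile: float = 0.95, seed: int = 0) -> int:
    """Count leading singular values exceeding their permutation-null quantile.

    Each permutation shuffles every gene row independently, destroying
    inter-gene correlation while preserving per-row marginals; the returned k
    is the length of the leading run of observed singular values above the
    rank-matched null quantile.
    """
    if n_permutations < 1:
        raise InvalidConfigError("n_permutations must be >= 1")
    vals = np.asarray(Xn, dtype=float) if not isinstance(Xn, pd.DataFrame) \
        else Xn.to_numpy(dtype=float)
    obs = np.linalg.svd(vals, compute_uv=False)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, obs.size))
    for i in range(n_permutations):
        null[i] = np.linalg.svd(rng.permuted(vals, axis=1), compute_uv=False)
    thresh = np.quantile(null, quantile, axis=0)
    k = 0
    while k < obs.size and obs[k] > thresh[k]:
        k += 1
    return k


# ---------------------------------------------------------------------------
# the factor model

@dataclass
class FactorModel:
    """A fitted pathway-guided decomposition.

    ``Z``/``B`` are the post-hoc standardized matrices (each Z column and each
    B row mean 0, unit variance, constant ones left untouched); ``Z_raw`` /
    ``B_raw`` are the solver's nonnegative-loading solution.
    """

    Z: pd.DataFrame
    B: pd.DataFrame
    U: pd.DataFrame
    Z_raw: pd.DataFrame
    B_raw: pd.DataFrame
    k: int
    penalties: tuple[float, float, float]
    frac: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def save(self, outdir: str | os.PathLike, seed: int | None = None) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        io.write_table(self.Z, os.path.join(outdir, "Z.tsv"), seed=seed,
                       index_label="gene_id")
        io.write_table(self.B, os.path.join(outdir, "B.tsv"), seed=seed,
                       index_label="lv")
        io.write_table(self.U, os.path.join(outdir, "U.tsv"), seed=seed,
                       index_label="gene_set")
        io.write_table(self.Z_raw, os.path.join(outdir, "Z_raw.tsv"), seed=seed,
                       index_label="gene_id")
        io.write_table(self.B_raw, os.path.join(outdir, "B_raw.tsv"), seed=seed,
                       index_label="lv")
        manifest = {
            "k": self.k,
            "penalties": {"lambda1": self.penalties[0], "lambda2": self.penalties[1],
                          "lambda3": self.penalties[2]},
            "frac": self.frac,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "final_objective": self.objective_trace[-1] if self.objective_trace else None,
            "objective_trace": self.objective_trace,
            "notes": ("Z constrained nonnegative before standardization; "
                      "component count from permutation parallel analysis when automatic"),
        }
        io.write_json(manifest, os.path.join(outdir, "manifest.json"))

    @classmethod
    def load(cls, outdir: str | os.PathLike) -> "FactorModel":
        outdir = str(outdir)
        manifest = io.read_json(os.path.join(outdir, "manifest.json"))
        pen = manifest["penalties"]
        return cls(
            Z=io.read_matrix(os.path.join(outdir, "Z.tsv")),
            B=io.read_matrix(os.path.join(outdir, "B.tsv")),
            U=io.read_matrix(os.path.join(outdir, "U.tsv")),
            Z_raw=io.read_matrix(os.path.join(outdir, "Z_raw.tsv")),
            B_raw=io.read_matrix(os.path.join(outdir, "B_raw.tsv")),
            k=manifest["k"],
            penalties=(pen["lambda1"], pen["lambda2"], pen["lambda3"]),
            frac=manifest["frac"],
            objective_trace=list(manifest.get("objective_trace", [])),
            converged=manifest["converged"],
            n_iter=manifest["n_iter"],
        )


def prior_matrix_from_sets(sets: dict[str, list[str]], genes: pd.Index | list[str]) -> pd.DataFrame:
    """Binary gene x gene-set membership matrix over the given gene universe."""
    genes = pd.Index(genes, name="gene_id" if pd.Index(genes).name is None
                     else pd.Index(genes).name)
    C = pd.DataFrame(0, index=genes,
                     columns=pd.Index(list(sets), name="gene_set"), dtype=np.int8)
    for name, members in sets.items():
        present = genes.intersection(members)
        C.loc[present, name] = 1
    return C


def _objective(X, Z, B, C, U, lam1, lam2, lam3) -> float:
    R = X - Z @ B
    P = Z - C @ U
    return float(np.sum(R * R) + lam1 * np.sum(P * P)
                 + lam2 * np.sum(B * B) + lam3 * np.abs(U).sum())


def _solve(X: np.ndarray, C: np.ndarray, k: int, lam1: float, lam2: float,
           lam3: float, max_iter: int, tol: float):
    g, s = X.shape
    p = C.shape[1]
    Usvd, sv, Vt = np.linalg.svd(X, full_matrices=False)
    k_eff = min(k, sv.size)
    Z = Usvd[:, :k_eff].copy()
    sign = np.sign(Z.sum(axis=0))
    sign[sign == 0] = 1.0
    Z *= sign
    B = (sv[:k_eff, None] * Vt[:k_eff]) * sign[:, None]
    if k_eff < k:  # pad degenerate extra components with zeros
        Z = np.hstack([Z, np.zeros((g, k - k_eff))])
        B = np.vstack([B, np.zeros((k - k_eff, s))])
    Z = np.maximum(Z, 0.0)
    U = np.zeros((p, k))
    CtC = C.T @ C
    cdiag = np.diag(CtC).astype(float)
    thr = lam3 / (2.0 * lam1) if lam1 > 0 else np.inf
    eye_k = np.eye(k)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        B_old = B
        # B: ridge least squares, exact
        B = np.linalg.solve(Z.T @ Z + lam2 * eye_k, Z.T @ X)
        # Z: one cyclic sweep of exact nonnegative column updates
        G = B @ B.T
        XBt = X @ B.T
        CU = C @ U
        for j in range(k):
            den = G[j, j] + lam1
            if den <= 0:
                Z[:, j] = 0.0
                continue
            r = XBt[:, j] + lam1 * CU[:, j] - Z @ G[:, j] + Z[:, j] * G[j, j]
            Z[:, j] = np.maximum(0.0, r / den)
        # U: cyclic soft-threshold row updates (columns are independent)
        if np.isfinite(thr):
            CtZ = C.T @ Z
            for _ in range(2):
                for m in range(p):
                    if cdiag[m] <= 0:
                        U[m, :] = 0.0
                        continue
                    r = CtZ[m, :] - CtC[m, :] @ U + cdiag[m] * U[m, :]
                    U[m, :] = np.maximum(0.0, (r - thr) / cdiag[m])
        trace.append(_objective(X, Z, B, C, U, lam1, lam2, lam3))
        denom = max(float(np.linalg.norm(B_old)), 1e-12)
        if float(np.linalg.norm(B - B_old)) / denom < tol:
            converged = True
            break
    return Z, B, U, trace, converged, it


def _standardize(Z: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center and unit-scale Z columns and B rows (constant ones untouched)."""
    Zs = Z.copy()
    mu = Zs.mean(axis=0)
    sd = Zs.std(axis=0, ddof=1)
    ok = sd > 0
    Zs[:, ok] = (Zs[:, ok] - mu[ok]) / sd[ok]
    Bs = B.copy()
    mu = Bs.mean(axis=1)
    sd = Bs.std(axis=1, ddof=1)
    ok = sd > 0
    Bs[ok] = (Bs[ok] - mu[ok, None]) / sd[ok, None]
    return Zs, Bs


def _frac_nonzero_lvs(U: np.ndarray) -> float:
    return float(np.mean((U > 0).any(axis=0)))


def fit(Xn: pd.DataFrame, C: pd.DataFrame, k: int, frac: float = 0.7,
        penalties: tuple[float, float, float] | None = None,
        max_iter: int = 350, tol: float = 5e-3, seed: int = 0,
        tune_refits: int = 6, tune_max_iter: int = 40) -> FactorModel:
    """Fit the pathway-guided factorization.

    When ``penalties`` is omitted, ``lam2`` is set to the (k+1)-th singular
    value of ``Xn`` — the noise floor left out of the model — with
    ``lam1 = lam2 / 2``, and ``lam3`` is tuned by bisection over short refits
    so the fraction of latent variables with at least one nonzero pathway
    coefficient is closest to ``frac``. The scale matters twice over: a
    rank-one component survives the two quadratic penalties only when its
    singular value exceeds sqrt(lam1 * lam2), so penalties at the noise edge
    shrink each retained component by less than the noise itself, and they
    vanish on noise-free input where the reconstruction should be exact.

    ``seed`` is accepted for interface uniformity; the solver itself is
    deterministic (SVD warm start).
    """
    del seed  # deterministic solver
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    if not 0.0 < frac <= 1.0:
        raise InvalidConfigError("frac must lie in (0,1]")
    if k > min(Xn.shape):
        raise InvalidConfigError(f"k={k} exceeds min(genes, samples)={min(Xn.shape)}")
    if not Xn.index.equals(C.index):
        raise GeneAlignmentError("genes of Xn and C must be identical and ordered identically")
    X = Xn.to_numpy(dtype=float)
    Cv = C.to_numpy(dtype=float)

    if penalties is not None:
        lam1, lam2, lam3 = (float(v) for v in penalties)
        if min(lam1, lam2, lam3) < 0:
            raise InvalidConfigError("penalties must be nonnegative")
    else:
        sv = np.linalg.svd(X, compute_uv=False)
        # the noise floor: first singular value NOT retained by the model;
        # floor guards noise-free (rank <= k) inputs
        noise_edge = sv[k] if k < sv.size else 0.0
        lam2 = float(max(noise_edge, 1e-6 * sv[0], 1e-12))
        lam1 = lam2 / 2.0
        lam3 = _tune_lam3(X, Cv, k, lam1, lam2, frac, tune_refits, tune_max_iter, tol)

    Z, B, U, trace, converged, n_iter = _solve(X, Cv, k, lam1, lam2, lam3,
                                               max_iter, tol)
    if not converged:
        logger.warning("factorization stopped at max_iter=%d without meeting tol=%g",
                       max_iter, tol)
    Zs, Bs = _standardize(Z, B)
    modules = pd.Index([f"LV{i + 1}" for i in range(k)], name="lv")
    return FactorModel(
        Z=pd.DataFrame(Zs, index=Xn.index, columns=modules),
        B=pd.DataFrame(Bs, index=modules, columns=Xn.columns),
        U=pd.DataFrame(U, index=C.columns, columns=modules),
        Z_raw=pd.DataFrame(Z, index=Xn.index, columns=modules),
        B_raw=pd.DataFrame(B, index=modules, columns=Xn.columns),
        k=k, penalties=(lam1, lam2, lam3), frac=frac,
        objective_trace=trace, converged=converged, n_iter=n_iter,
    )


def _tune_lam3(X, Cv, k, lam1, lam2, frac, tune_refits, tune_max_iter, tol) -> float:
    """Geometric bisection of lam3 against the target active-LV fraction."""
    # crude upper bound from the warm start's pathway projections
    Usvd, sv, _ = np.linalg.svd(X, full_matrices=False)
    Z0 = np.maximum(Usvd[:, :min(k, sv.size)], 0.0) * sv[None, :min(k, sv.size)]
    hi = 2.0 * lam1 * float(np.abs(Cv.T @ Z0).max()) + 1e-12
    lo = hi * 1e-5
    best = (np.inf, hi)
    evals = 0
    # ensure the bracket actually spans the target
    while evals < 2:
        _, _, U, _, _, _ = _solve(X, Cv, k, lam1, lam2, hi, tune_max_iter, tol)
        f_hi = _frac_nonzero_lvs(U)
        evals += 1
        if abs(f_hi - frac) < best[0]:
            best = (abs(f_hi - frac), hi)
        if f_hi > frac:
            lo, hi = hi, hi * 100.0
        else:
            break
    while evals < tune_refits:
        mid = math.sqrt(lo * hi)
        _, _, U, _, _, _ = _solve(X, Cv, k, lam1, lam2, mid, tune_max_iter, tol)
        f_mid = _frac_nonzero_lvs(U)
        evals += 1
        if abs(f_mid - frac) < best[0]:
            best = (abs(f_mid - frac), mid)
        if f_mid > frac:
            lo = mid
        else:
            hi = mid
    return best[1]


# ---------------------------------------------------------------------------
# prior hold-out and alignment scoring

def mask_prior(C: pd.DataFrame, holdout_frac: float = 0.2,
               seed: int = 0) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Mask a fraction of each gene set's members; returns (masked C, held-out genes).

    Deterministic given the column order of ``C`` and the seed, so alignment
    scoring can reconstruct the identical hold-out after fitting.
    """
    if not 0.0 < holdout_frac < 1.0:
        raise InvalidConfigError("holdout_frac must lie in (0,1)")
    rng = np.random.default_rng(seed)
    Cm = C.copy()
    holdout: dict[str, list[str]] = {}
    for name in C.columns:
        members = list(C.index[C[name] == 1])
        n_hold = int(round(holdout_frac * len(members)))
        if n_hold == 0:
            holdout[name] = []
            continue
        chosen = rng.choice(len(members), size=n_hold, replace=False)
        held = sorted(members[i] for i in chosen)
        Cm.loc[held, name] = 0
        holdout[name] = held
    return Cm, holdout


def pathway_alignment(model: FactorModel, C: pd.DataFrame,
                      holdout_frac: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Score each (LV, gene set) pair with nonzero pathway coefficient.

    AUC is the Mann-Whitney statistic of the LV's raw loadings for held-out
    member genes versus all non-member genes (ties 0.5), with the one-sided
    normal-approximation p-value; FDR is BH across all scored pairs. The model
    must have been fitted with the same (C, holdout_frac, seed) masking.
    """
    _, holdout = mask_prior(C, holdout_frac, seed)
    Zr = model.Z_raw
    rows = []
    for j, lv in enumerate(model.U.columns):
        active = model.U.index[model.U[lv] > 0]
        for name in active:
            held = [g for g in holdout.get(name, []) if g in Zr.index]
            if len(held) < 2:
                logger.info("alignment pair (%s, %s) skipped: <2 held-out members",
                            lv, name)
                continue
            members_all = set(C.index[C[name] == 1]) | set(holdout.get(name, []))
            non_members = Zr.index.difference(members_all)
            pos = Zr.loc[held, lv].to_numpy()
            neg = Zr.loc[non_members, lv].to_numpy()
            res = mannwhitneyu(pos, neg, alternative="greater", method="asymptotic")
            auc = float(res.statistic) / (len(pos) * len(neg))
            rows.append({"lv": lv, "gene_set": name, "auc": auc,
                         "pvalue": float(res.pvalue)})
    table = pd.DataFrame(rows, columns=["lv", "gene_set", "auc", "pvalue"])
    if len(table):
        table["fdr"] = benjamini_hochberg(table["pvalue"].to_numpy())
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table


def match_modules(Z_hat: pd.DataFrame, Z_true: pd.DataFrame) -> pd.DataFrame:
    """One-to-one matching of recovered to planted modules by |loading correlation|.

    Solves the assignment problem maximizing total absolute Pearson
    correlation between loading columns; returns rows (lv, true_module,
    abs_corr) for the min(k_hat, k_true) matched pairs.
    """
    A = Z_hat.to_numpy(dtype=float)
    T = Z_true.reindex(Z_hat.index).to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    T = T - T.mean(axis=0)
    an = np.linalg.norm(A, axis=0)
    tn = np.linalg.norm(T, axis=0)
    an[an == 0] = 1.0
    tn[tn == 0] = 1.0
    corr = np.abs((A / an).T @ (T / tn))
    ri, ci = linear_sum_assignment(-corr)
    return pd.DataFrame({
        "lv": [Z_hat.columns[i] for i in ri],
        "true_module": [Z_true.columns[j] for j in ci],
        "abs_corr": corr[ri, ci],
    })
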