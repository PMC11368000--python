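"""Structure-activity analysis: descriptor screening and prediction.

Relates chemicals x descriptors matrices (substructure counts or
physicochemical properties) to bioactivity PODs:

* a variation filter keeps only descriptors where at least two chemicals
  differ from the modal value (near-constant features have no power);
* Spearman rank correlations between every descriptor and every
  bioactivity variable, with Benjamini-Hochberg q-values and a q < 0.1
  significance call;
* leave-one-out (or k-fold) cross-validated ridge regression with a common
  penalty chosen by inner leave-one-out on each training fold, summarized
  as the Pearson correlation between out-of-fold predictions and observed
  values;
* a permutation test (phenotype labels shuffled across chemicals) giving
  an empirical p-value per bioactivity variable, with Holm and BH-FDR
  adjustment across variables.

PODs enter as log10(uM); censored or inactive entries are imputed at
300 uM (3x the maximum tested concentration, the activity-call bound) —
configurable to exclusion. A lower POD means higher potency, so a
"negative correlation" marks descriptors whose presence increases effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CENSORED_POD_UM = 300.0
# wide enough that the inner CV can shrink a pure-noise phenotype to a
# near-constant predictor
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2.0, 5.0, 30))


def variation_filter(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep descriptors where >= 2 chemicals differ from the modal value."""
    if len(matrix) < 3:
        raise ValueError("need at least 3 chemicals")
    keep = []
    for col in matrix.columns:
        vals = matrix[col]
        counts = vals.value_counts(dropna=False)
        n_differ = len(vals) - int(counts.iloc[0])
        if n_differ >= 2:
            keep.append(col)
    return matrix[keep]


def spearman_screen(
    descriptors: pd.DataFrame,
    bioactivity: pd.DataFrame,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Spearman rho, two-sided p and BH q for every descriptor x variable.

    Ranks use average tie handling; p-values come from the t approximation
    (matching scipy's spearmanr). The BH correction runs across all tested
    pairs; zero-variance vectors are excluded and counted.
    """
    chems = descriptors.index.intersection(bioactivity.index)
    if len(chems) < 5:
        raise ValueError("need at least 5 aligned chemicals")
    X = descriptors.loc[chems]
    Y = bioactivity.loc[chems]
    n = len(chems)

    def rank(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        arr = df.to_numpy(dtype=float)
        ranks = np.apply_along_axis(stats.rankdata, 0, arr)
        ok = arr.std(axis=0) > 0
        return ranks, ok

    rx, okx = rank(X)
    ry, oky = rank(Y)
    rx = (rx - rx.mean(axis=0)) / rx.std(axis=0, ddof=0).clip(min=1e-300)
    ry = (ry - ry.mean(axis=0)) / ry.std(axis=0, ddof=0).clip(min=1e-300)
    rho = rx.T @ ry / n                          # (descriptors, variables)

    rows = []
    for i, d in enumerate(X.columns):
        for j, v in enumerate(Y.columns):
            if not (okx[i] and oky[j]):
                continue
            r = float(np.clip(rho[i, j], -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2 * stats.t.sf(abs(t), n - 2))
            rows.append({"descriptor": d, "variable": v, "spearman_rho": r, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < q_threshold
    n_excluded = (~okx).sum() * len(Y.columns) + okx.sum() * (~oky).sum()
    out.attrs["n_excluded_pairs"] = int(n_excluded)
    return out


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="holm")[1]


# ---------------------------------------------------------------------------
# Common-penalty ridge with nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class _Fold:
    """Precomputed geometry of one outer fold (independent of y)."""

    train: np.ndarray
    test: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    U: np.ndarray        # n_train x r
    s: np.ndarray        # r
    V: np.ndarray        # p x r
    X_test_std: np.ndarray


def _make_folds(X: np.ndarray, n_folds: int | None, seed: int) -> list[_Fold]:
    n = X.shape[0]
    if n_folds is None or n_folds >= n:
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        parts = np.array_split(perm, n_folds)
        splits = [
            (np.setdiff1d(np.arange(n), part), part) for part in parts
        ]
    folds = []
    for train, test in splits:
        Xt = X[train]
        mean = Xt.mean(axis=0)
        std = Xt.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)
        Z = (Xt - mean) / std
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        folds.append(
            _Fold(train, test, mean, std, U, s, Vt.T, (X[test] - mean) / std)
        )
    return folds


def _predict_fold(fold: _Fold, y: np.ndarray, lambda_grid: np.ndarray) -> np.ndarray:
    """Out-of-fold ridge predictions with the penalty chosen by inner
    leave-one-out error on the training fold (closed form via the SVD)."""
    y_tr = y[fold.train]
    y_mean = y_tr.mean()
    yc = y_tr - y_mean
    Uty = fold.U.T @ yc                            # (r,)
    s2 = fold.s**2
    best_lam, best_err = lambda_grid[0], np.inf
    U2 = fold.U**2
    for lam in lambda_grid:
        d = s2 / (s2 + lam)
        yhat = fold.U @ (d * Uty)
        h = U2 @ d                                 # diag of hat matrix
        resid = (yc - yhat) / np.clip(1.0 - h, 1e-10, None)
        err = float(np.mean(resid**2))
        if err < best_err:
            best_err, best_lam = err, lam
    d = fold.s / (s2 + best_lam)
    beta = fold.V @ (d * Uty)
    return fold.X_test_std @ beta + y_mean


def ridge_cv_predict(
    descriptors: pd.DataFrame | np.ndarray,
    y,
    n_folds: int | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    _folds: list[_Fold] | None = None,
) -> dict:
    """Cross-validated common-penalty ridge prediction of one phenotype.

    Returns out-of-fold predictions for every chemical and the Pearson r
    between predictions and observations. ``n_folds=None`` means
    leave-one-out; fold assignment is seeded otherwise. A constant
    phenotype vector yields ``cv_r = nan`` with a flag.
    """
    X = np.asarray(descriptors, dtype=float)
    yv = np.asarray(y, dtype=float)
    if X.shape[0] != yv.size:
        raise ValueError("descriptors and phenotype vector are misaligned")
    grid = np.asarray(lambda_grid, dtype=float)
    folds = _folds if _folds is not None else _make_folds(X, n_folds, seed)
    preds = np.empty_like(yv)
    for fold in folds:
        preds[fold.test] = _predict_fold(fold, yv, grid)
    if np.std(yv) == 0 or np.std(preds) == 0:
        return {"cv_r": float("nan"), "predictions": preds, "degenerate": True}
    r = float(np.corrcoef(preds, yv)[0, 1])
    return {"cv_r": r, "predictions": preds, "degenerate": False}


def permutation_significance(
    descriptors: pd.DataFrame,
    bioactivity: pd.DataFrame,
    n_perm: int = 999,
    n_folds: int | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-calibrated significance of cross-validated predictions.

    For each bioactivity variable, the observed cv_r is compared with the
    null distribution obtained by re-running the full nested-CV procedure
    on label permutations (one shared permutation of chemicals per round):
    empirical_p = (1 + #{r_perm >= r_obs}) / (n_perm + 1). Holm-adjusted
    p-values and BH q-values run across variables.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 limits p-value resolution")
    chems = descriptors.index.intersection(bioactivity.index)
    X = np.asarray(descriptors.loc[chems], dtype=float)
    Y = bioactivity.loc[chems]
    n = len(chems)
    grid = np.asarray(lambda_grid, dtype=float)
    folds = _make_folds(X, n_folds, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    perms = [rng.permutation(n) for _ in range(n_perm)]

    rows = []
    for var in Y.columns:
        yv = Y[var].to_numpy(dtype=float)
        obs = ridge_cv_predict(X, yv, lambda_grid=grid, _folds=folds)
        if obs["degenerate"] or not np.isfinite(obs["cv_r"]):
            rows.append({"variable": var, "cv_prediction_r": float("nan"),
                         "empirical_p": float("nan"), "degenerate": True})
            continue
        r_obs = obs["cv_r"]
        count = 0
        for perm in perms:
            rp = ridge_cv_predict(X, yv[perm], lambda_grid=grid, _folds=folds)["cv_r"]
            if np.isfinite(rp) and rp >= r_obs:
                count += 1
        emp_p = (1 + count) / (n_perm + 1)
        rows.append({"variable": var, "cv_prediction_r": r_obs,
                     "empirical_p": emp_p, "degenerate": False})
    out = pd.DataFrame(rows)
    ok = out["empirical_p"].notna()
    out["p_adj"] = np.nan
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = holm_adjust(out.loc[ok, "empirical_p"])
        out.loc[ok, "q"] = bh_qvalues(out.loc[ok, "empirical_p"])
    return out


# ---------------------------------------------------------------------------
# Bioactivity matrix assembly
# ---------------------------------------------------------------------------


def bioactivity_matrix(
    podsets,
    censored_pod_uM: float = CENSORED_POD_UM,
    censored_policy: str = "impute",
) -> pd.DataFrame:
    """Chemicals x bioactivity-variables matrix of log10 PODs.

    Variables are per-donor PODs for each phenotype plus the across-donor
    minimum per phenotype (n_phenotypes x (n_donors + 1) variables, e.g.
    85 at 5 phenotypes x 16 donors). Censored entries are imputed at
    ``censored_pod_uM`` (3x the top tested concentration) or left missing
    with ``censored_policy='exclude'``.
    """
    if censored_policy not in ("impute", "exclude"):
        raise ValueError("censored_policy must be 'impute' or 'exclude'")
    fill = np.log10(censored_pod_uM)
    rows: dict[str, dict[str, float]] = {}
    for ps in podsets:
        donor_pods = ps.donor_pods()
        vals = {}
        for donor, pod in donor_pods.items():
            vals[f"{ps.phenotype}|{donor}"] = pod
        vals[f"{ps.phenotype}|min"] = float(donor_pods.min())
        for key, pod in vals.items():
            if np.isfinite(pod):
                v = np.log10(pod)
            else:
                v = fill if censored_policy == "impute" else np.nan
            rows.setdefault(ps.chemical_id, {})[key] = v
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    df.index.name = "chemical_id"
    return df
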