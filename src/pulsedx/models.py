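"""Two-group classification and feature mining on the 193-feature matrix.

Three complementary routes:

* **PCA score thresholding** (unsupervised): z-score the features, project
  onto principal components, and classify by the cut on one component's
  scores that minimises training misclassification.
* **Designed-regressand least squares with EFBLS selection** (supervised):
  regress the two-valued target Y (n2 for group-1 rows, −n1 for group-2
  rows, so ΣY = 0 and OLS is canonical-correlation optimal) on a small
  subset of centred features chosen by a greedy forward/backward
  residual-sum-of-squares search capped at 7 regressors.
* **LASSO** (supervised): the L1-penalised least squares
  min ||Y − Zβ||² + λ Σ|β_j|, solved by cyclic coordinate descent with
  soft-thresholding, with λ chosen by K-fold cross-validation under the
  one-standard-error rule.

Group separation is judged by the histogram of predicted indices (threshold
at the regressand mean, 0) and a label-permutation p-value; feature
stability by selection frequencies ("used times") over repeated
train/holdout rounds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConvergenceError, PulseError

K_MAX = 7  # cap on selected regressors (overfitting guard for small cohorts)


# --- standardization --------------------------------------------------------

@dataclasses.dataclass
class Standardizer:
    """Column centering (and optional unit-SD scaling) fitted on training rows."""

    centers: np.ndarray
    scales: np.ndarray
    flagged: np.ndarray  # columns with (near-)zero variance, scale forced to 1

    @classmethod
    def fit(cls, X: np.ndarray, scale: bool = True) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        centers = X.mean(axis=0)
        if scale:
            sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
            flagged = sd <= 1e-12
            scales = np.where(flagged, 1.0, sd)
        else:
            scales = np.ones(X.shape[1])
            flagged = np.zeros(X.shape[1], dtype=bool)
        return cls(centers=centers, scales=scales, flagged=flagged)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.centers) / self.scales


def standardize(X: np.ndarray, scale: bool = True
                ) -> tuple[np.ndarray, Standardizer]:
    """Center (and scale) columns; returns (Z, fitted transform)."""
    st = Standardizer.fit(X, scale=scale)
    return st.transform(X), st


# --- designed regressand ----------------------------------------------------

def design_regressand(n1: int, n2: int) -> np.ndarray:
    """Y = (n2,...,n2, −n1,...,−n1): n1 rows of n2 then n2 rows of −n1 (ΣY = 0)."""
    if n1 < 2 or n2 < 2:
        raise PulseError(f"each group needs at least 2 members (got {n1}, {n2})")
    return np.concatenate([np.full(n1, float(n2)), np.full(n2, -float(n1))])


def regressand_for_labels(labels: np.ndarray, group1: str, group2: str) -> np.ndarray:
    """Row-aligned designed regressand for an arbitrary label ordering."""
    labels = np.asarray(labels)
    m1 = labels == group1
    m2 = labels == group2
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise PulseError(f"each group needs at least 2 members (got {n1}, {n2})")
    if n1 + n2 != len(labels):
        raise PulseError("labels contain rows outside the two groups")
    y = np.where(m1, float(n2), -float(n1))
    return y


# --- EFBLS: greedy forward/backward least-squares selection -----------------

@dataclasses.dataclass
class EfblsResult:
    features: list[int]       # selected column indices, in selection order
    coef: np.ndarray          # LS coefficients on the selected columns
    rss_path: list[float]     # RSS after each accepted forward step
    rss: float


def _ls_rss(Z: np.ndarray, y: np.ndarray, cols: list[int]) -> tuple[np.ndarray, float]:
    A = Z[:, cols]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return coef, float(r @ r)


def efbls_select(Z: np.ndarray, y: np.ndarray, k_max: int = K_MAX,
                 tol: float = 1e-4) -> EfblsResult:
    """Greedy forward selection with a backward pruning pass.

    Forward: at each step add the column giving the largest RSS reduction
    (computed by Gram–Schmidt projection against the current selection, so
    collinear candidates contribute no gain and are skipped automatically).
    Backward: after each addition, drop any earlier column whose removal
    raises RSS by at most ``tol`` × current RSS.  Stops when no addition
    improves RSS by more than the tolerance or ``k_max`` columns are held.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = Z.shape
    if k_max > K_MAX:
        raise PulseError(f"k_max={k_max} exceeds the regressor cap {K_MAX}")
    if n <= k_max + 1:
        raise PulseError(f"need more than k_max+1={k_max + 1} rows, got {n}")

    selected: list[int] = []
    rss_path: list[float] = []
    Q = np.empty((n, 0))
    r = y.copy()
    yty = float(y @ y)
    rss = yty
    steps = 0

    while len(selected) < k_max and steps < 4 * k_max:
        steps += 1
        if rss <= 1e-12 * yty:  # numerically perfect fit
            break
        Zt = Z - Q @ (Q.T @ Z)
        norms2 = np.einsum("ij,ij->j", Zt, Zt)
        proj = Zt.T @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            gains = np.where(norms2 > 1e-10 * n, proj ** 2 / norms2, 0.0)
        gains[selected] = 0.0
        j = int(np.argmax(gains))
        if gains[j] <= tol * rss:
            break
        selected.append(j)
        q = Zt[:, j] / np.sqrt(norms2[j])
        Q = np.column_stack([Q, q])
        r = r - q * (q @ r)
        rss -= float(gains[j])
        rss_path.append(rss)

        # backward pass: try removing earlier features that became redundant
        if len(selected) > 1:
            changed = True
            while changed and len(selected) > 1:
                changed = False
                for f in list(selected[:-1]):
                    cand = [c for c in selected if c != f]
                    _, rss_wo = _ls_rss(Z, y, cand)
                    if rss_wo - rss <= tol * rss:
                        selected = cand
                        rss = rss_wo
                        changed = True
                        break
            # refresh the orthonormal basis after any removal
            coef, rss = _ls_rss(Z, y, selected)
            Qm, _ = np.linalg.qr(Z[:, selected])
            Q = Qm
            r = y - Q @ (Q.T @ y)

    if not selected:
        return EfblsResult(features=[], coef=np.empty(0), rss_path=[], rss=rss)
    coef, rss = _ls_rss(Z, y, selected)
    return EfblsResult(features=selected, coef=coef, rss_path=rss_path, rss=rss)


# --- LASSO: coordinate descent ----------------------------------------------

@dataclasses.dataclass
class LassoModel:
    lam: float
    coef: np.ndarray
    q: int = 1
    cv_lambdas: np.ndarray | None = None
    cv_mse: np.ndarray | None = None
    cv_se: np.ndarray | None = None

    @property
    def nonzero(self) -> np.ndarray:
        return np.flatnonzero(self.coef)


def lasso_lambda_max(Z: np.ndarray, y: np.ndarray) -> float:
    """Smallest λ at which β = 0 solves min ||y − Zβ||² + λΣ|β| (KKT bound)."""
    return 2.0 * float(np.max(np.abs(Z.T @ y))) if Z.shape[1] else 0.0


def _cd_sweep(G: np.ndarray, c: np.ndarray, thr: float, beta: np.ndarray,
              diag: np.ndarray, idx) -> float:
    """One cyclic soft-thresholding pass over ``idx``; returns max |Δβ|."""
    max_change = 0.0
    for j in idx:
        if diag[j] <= 0:
            continue
        rho = c[j] - G[j] @ beta + diag[j] * beta[j]
        newb = np.sign(rho) * max(abs(rho) - thr, 0.0) / diag[j]
        change = abs(newb - beta[j])
        if change > 0:
            beta[j] = newb
            if change > max_change:
                max_change = change
    return max_change


def _cd_solve(G: np.ndarray, c: np.ndarray, lam: float, beta: np.ndarray,
              tol: float, max_sweeps: int) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent on ||y−Zβ||² + λΣ|β| given G=Z'Z, c=Z'y.

    Full passes alternate with cheap passes restricted to the active set
    (the usual speed-up); convergence is max coefficient change < tol over
    a full pass.
    """
    d = len(c)
    thr = lam / 2.0
    diag = np.diag(G).copy()
    all_idx = np.arange(d)
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        change = _cd_sweep(G, c, thr, beta, diag, all_idx)
        if change < tol:
            return beta, sweeps
        active = np.flatnonzero(beta)
        while sweeps < max_sweeps and len(active):
            sweeps += 1
            if _cd_sweep(G, c, thr, beta, diag, active) < tol:
                break
    return beta, -1


def lasso_fit(Z: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8,
              max_sweeps: int = 10000, beta0: np.ndarray | None = None) -> LassoModel:
    """Solve min_β ||y − Zβ||² + λ Σ|β_j| by cyclic coordinate descent.

    Convergence: the maximum coefficient change in a full sweep drops below
    ``tol``.  ``Z`` is expected standardized (centred columns), ``y``
    centred or zero-sum, so no intercept is carried.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise PulseError("λ must be >= 0")
    G = Z.T @ Z
    c = Z.T @ y
    beta = np.zeros(Z.shape[1]) if beta0 is None else beta0.astype(float).copy()
    beta, sweeps = _cd_solve(G, c, lam, beta, tol, max_sweeps)
    if sweeps < 0:
        raise ConvergenceError(f"coordinate descent did not converge at λ={lam}")
    return LassoModel(lam=lam, coef=beta)


def lasso_path(Z: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
               tol: float = 1e-8, max_sweeps: int = 10000) -> np.ndarray:
    """Warm-started solutions over a decreasing λ grid; rows = λ values.

    The descent stops early once the active set saturates the sample size
    (0.9 n nonzeros): below that point the problem is underdetermined, the
    solution is no longer unique, and such models are never competitive in
    cross-validation; remaining grid rows repeat the last solved model.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = Z.T @ Z
    c = Z.T @ y
    betas = np.zeros((len(lambdas), Z.shape[1]))
    beta = np.zeros(Z.shape[1])
    for i, lam in enumerate(lambdas):
        beta, sweeps = _cd_solve(G, c, float(lam), beta, tol, max_sweeps)
        if sweeps < 0:
            raise ConvergenceError(f"coordinate descent did not converge at λ={lam}")
        betas[i] = beta
        if np.count_nonzero(beta) > 0.9 * n:
            betas[i + 1:] = beta
            break
    return betas


def lasso_cv(Z: np.ndarray, y: np.ndarray, folds: int = 10,
             n_lambda: int = 100, decades: float = 4.0,
             seed: int | None = None, rule: str = "1se") -> LassoModel:
    """K-fold cross-validated LASSO with the one-standard-error λ rule.

    The λ grid is log-spaced over ``decades`` decades down from the
    path-entry bound λ_max of the full data.  The chosen λ is the largest
    one whose mean CV squared error is within one standard error of the
    minimum (``rule="min"`` picks the minimiser); the final model is
    refitted on all rows at the chosen λ.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds < 2:
        raise PulseError("need at least 2 folds")
    folds = min(folds, n)
    lam_max = lasso_lambda_max(Z, y)
    if lam_max <= 0:
        return LassoModel(lam=0.0, coef=np.zeros(Z.shape[1]))
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)
    # CV-grade tolerance, scaled to the regressand magnitude
    path_tol = 1e-6 * max(1.0, float(np.abs(y).max()))

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    sq_err = np.full((n, len(lambdas)), np.nan)
    for f in range(folds):
        te = fold_of == f
        tr = ~te
        if tr.sum() < 2 or te.sum() < 1:
            continue
        betas = lasso_path(Z[tr], y[tr], lambdas, tol=path_tol,
                           max_sweeps=30000)
        pred = Z[te] @ betas.T  # (n_te, n_lambda)
        sq_err[te] = (y[te, None] - pred) ** 2
    mse = np.nanmean(sq_err, axis=0)
    # SE of the per-fold mean errors around the grand mean
    fold_mse = np.array([np.nanmean(sq_err[fold_of == f], axis=0)
                         for f in range(folds)])
    se = np.nanstd(fold_mse, axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.nanargmin(mse))
    if rule == "1se":
        ok = np.flatnonzero(mse <= mse[i_min] + se[i_min])
        i_pick = int(ok[0])  # largest λ (grid is decreasing)
    else:
        i_pick = i_min
    lam = float(lambdas[i_pick])
    final = lasso_path(Z, y, lambdas[:i_pick + 1], tol=path_tol,
                       max_sweeps=30000)[-1]
    return LassoModel(lam=lam, coef=final, cv_lambdas=lambdas, cv_mse=mse, cv_se=se)


def format_model_equation(names: list[str], coef: np.ndarray,
                          decimals: int = 3) -> str:
    """Render a sparse linear model as e.g. ``Y = -0.010*C2_zuocun + ...``."""
    terms = []
    for name, b in zip(names, coef):
        if b == 0:
            continue
        sign = "-" if b < 0 else "+"
        terms.append(f"{sign} {abs(b):.{decimals}f}*{name}")
    if not terms:
        return "Y = 0"
    first = terms[0].replace("+ ", "").replace("- ", "-")
    return "Y = " + " ".join([first] + terms[1:])


# --- classification by predicted index / PCA scores -------------------------

@dataclasses.dataclass
class ClassificationResult:
    predicted: np.ndarray          # predicted group labels per row
    threshold: float
    misclassification: float
    flipped: bool                  # orientation auto-corrected
    component: int | None = None   # 1-based PC index when applicable
    p_value: float | None = None
    selected_features: list[str] | None = None

    @property
    def accuracy(self) -> float:
        return 1.0 - self.misclassification


def threshold_search(scores: np.ndarray, is_group1: np.ndarray
                     ) -> tuple[float, bool, float]:
    """Brute-force cut over midpoints of adjacent sorted scores.

    Returns (threshold, orientation_flipped, misclassification); orientation
    ``False`` means group 1 is predicted for scores above the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    is_group1 = np.asarray(is_group1, dtype=bool)
    order = np.argsort(scores)
    s = scores[order]
    cuts = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    best = (0.0, False, 1.0)
    n = len(scores)
    for c in cuts:
        above = scores > c
        err_plain = float(np.sum(above != is_group1)) / n
        err_flip = 1.0 - err_plain
        if err_plain < best[2]:
            best = (float(c), False, err_plain)
        if err_flip < best[2]:
            best = (float(c), True, err_flip)
    return best


def classify_by_index(yhat: np.ndarray, labels: np.ndarray, group1: str,
                      group2: str, threshold: float = 0.0) -> ClassificationResult:
    """Classify by the predicted index: group 1 when ŷ > threshold.

    The regressand is designed so its mean is 0, hence the default cut.
    Orientation is auto-corrected (and recorded) when accuracy < 0.5.
    """
    yhat = np.asarray(yhat, dtype=float)
    labels = np.asarray(labels)
    is_g1 = labels == group1
    pred1 = yhat > threshold
    err = float(np.sum(pred1 != is_g1)) / len(labels)
    flipped = err > 0.5
    if flipped:
        pred1 = ~pred1
        err = 1.0 - err
    predicted = np.where(pred1, group1, group2)
    return ClassificationResult(predicted=predicted, threshold=threshold,
                                misclassification=err, flipped=flipped)


def separation_pvalue(yhat: np.ndarray, labels: np.ndarray, group1: str,
                      n_perm: int = 10000, seed: int | None = None) -> float:
    """Two-sided label-permutation p-value for the group-mean difference of ŷ.

    Add-one smoothing: p = (b + 1) / (n_perm + 1) where b counts permutations
    with |Δmean| at least the observed one.
    """
    if n_perm <= 0:
        raise PulseError("n_perm must be positive")
    yhat = np.asarray(yhat, dtype=float)
    is_g1 = np.asarray(labels) == group1
    n1 = int(is_g1.sum())
    n = len(yhat)
    if n1 == 0 or n1 == n:
        raise PulseError("both groups must be present")
    total = yhat.sum()

    def stat(mask_sum1: np.ndarray) -> np.ndarray:
        m1 = mask_sum1 / n1
        m2 = (total - mask_sum1) / (n - n1)
        return np.abs(m1 - m2)

    obs = stat(np.array([yhat[is_g1].sum()]))[0]
    rng = np.random.default_rng(seed)
    # vectorized permutations: pick n1 rows per permutation via argsort
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
    sums = yhat[idx].sum(axis=1)
    b = int(np.sum(stat(sums) >= obs - 1e-12))
    return (b + 1) / (n_perm + 1)


@dataclasses.dataclass
class PcaResult:
    loadings: np.ndarray                 # (n_components, d), orthonormal rows
    scores: np.ndarray                   # (n, n_components)
    explained_variance_ratio: np.ndarray
    per_component_misclassification: np.ndarray


def pca_classify(Z: np.ndarray, labels: np.ndarray, group1: str, group2: str,
                 component: int | str | tuple = "search",
                 max_components: int = 10
                 ) -> tuple[PcaResult, ClassificationResult]:
    """PCA score thresholding for two groups.

    ``component``: a 1-based index, ``"search"`` (best of the first
    ``max_components``), or a pair (i, j) — then Fisher's linear
    discriminant on the two score columns gives the 1-D index to threshold.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    is_g1 = labels == group1
    rank = min(Z.shape[0] - 1, Z.shape[1])
    n_comp = min(max_components, rank)
    want = max(component) if isinstance(component, tuple) else (
        n_comp if component == "search" else int(component))
    if want > rank:
        raise PulseError(f"component {want} exceeds the data rank {rank}")
    n_comp = max(n_comp, want)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z)

    errs = np.array([threshold_search(scores[:, c], is_g1)[2]
                     for c in range(n_comp)])
    res = PcaResult(loadings=pca.components_, scores=scores,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    per_component_misclassification=errs)

    if isinstance(component, tuple):
        i, j = (component[0] - 1, component[1] - 1)
        pair = scores[:, [i, j]]
        mu1 = pair[is_g1].mean(axis=0)
        mu2 = pair[~is_g1].mean(axis=0)
        cov = np.cov(pair[is_g1].T) * (is_g1.sum() - 1) + \
            np.cov(pair[~is_g1].T) * ((~is_g1).sum() - 1)
        cov /= len(labels) - 2
        w = np.linalg.solve(cov + 1e-9 * np.eye(2), mu1 - mu2)
        index = pair @ w
        comp_used = None
    else:
        c = int(np.argmin(errs)) if component == "search" else int(component) - 1
        index = scores[:, c]
        comp_used = c + 1
    thr, flipped, err = threshold_search(index, is_g1)
    pred1 = (index > thr) ^ flipped
    cls = ClassificationResult(predicted=np.where(pred1, group1, group2),
                               threshold=thr, misclassification=err,
                               flipped=flipped, component=comp_used)
    return res, cls


# --- repeated rounds: selection frequency and held-out accuracy -------------

@dataclasses.dataclass
class SelectionReport:
    """Per-feature selection stability over R repeated train/holdout rounds.

    ``table`` columns: used_times (rounds selecting the feature),
    importance (mean |standardized coefficient| over selecting rounds),
    mean and sd of the raw feature over all subjects.
    """

    table: pd.DataFrame
    rounds: int
    accuracies: np.ndarray
    method: str

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def _stratified_split(labels: np.ndarray, holdout: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    test = np.zeros(len(labels), dtype=bool)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        n_te = max(1, int(round(holdout * len(idx))))
        test[rng.choice(idx, size=n_te, replace=False)] = True
    return ~test, test


def _fit_predict_round(Ztr, ytr, Zte, labels_tr, group1, group2, method,
                       k_max, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (selected column indices, full-width coef, test index ŷ)."""
    d = Ztr.shape[1]
    beta = np.zeros(d)
    if method == "efbls":
        res = efbls_select(Ztr, ytr, k_max=k_max)
        beta[res.features] = res.coef
        sel = np.array(res.features, dtype=int)
    elif method == "lasso":
        m = lasso_cv(Ztr, ytr, folds=5, n_lambda=60,
                     seed=int(rng.integers(2 ** 31)))
        beta = m.coef
        sel = m.nonzero
    elif method == "pca":
        is_g1 = labels_tr == group1
        rank = min(Ztr.shape[0] - 1, d)
        pca = PCA(n_components=min(10, rank))
        str_scores = pca.fit_transform(Ztr)
        errs = [threshold_search(str_scores[:, c], is_g1)[2]
                for c in range(str_scores.shape[1])]
        c = int(np.argmin(errs))
        thr, flipped, _ = threshold_search(str_scores[:, c], is_g1)
        yhat_te = Zte @ pca.components_[c] - (thr + pca.mean_ @ pca.components_[c])
        if flipped:
            yhat_te = -yhat_te
        return np.empty(0, dtype=int), beta, yhat_te
    else:
        raise PulseError(f"unknown method {method!r}")
    yhat_tr = Ztr @ beta
    flipped = classify_by_index(yhat_tr, labels_tr, group1, group2).flipped
    yhat_te = Zte @ beta
    if flipped:
        yhat_te = -yhat_te
    return sel, beta, yhat_te


def repeated_rounds_report(X: np.ndarray, labels: np.ndarray, group1: str,
                           group2: str, method: str = "efbls", R: int = 20,
                           holdout: float = 0.25, seed: int = 0,
                           k_max: int = K_MAX,
                           feature_names: list[str] | None = None
                           ) -> SelectionReport:
    """R rounds of stratified subsampling: select on train, score on holdout.

    Per round the features are standardized on the training rows only, the
    designed regressand is rebuilt from the training group sizes, the method
    selects/fits, and held-out rows are classified by their predicted index
    (threshold 0, orientation fixed on train).  The report aggregates
    selection counts ("used times"), mean absolute standardized coefficients
    and raw feature moments.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if R < 2:
        raise PulseError("need at least 2 rounds")
    for g in (group1, group2):
        if (labels == g).sum() < 4:
            raise PulseError(f"group {g!r} has fewer than 4 members; cannot stratify")
    d = X.shape[1]
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(d)]
    rng = np.random.default_rng(seed)

    used = np.zeros(d, dtype=int)
    imp_sum = np.zeros(d)
    accs = np.zeros(R)
    for r in range(R):
        tr, te = _stratified_split(labels, holdout, rng)
        Ztr, st = standardize(X[tr])
        Zte = st.transform(X[te])
        ytr = regressand_for_labels(labels[tr], group1, group2)
        sel, beta, yhat_te = _fit_predict_round(
            Ztr, ytr, Zte, labels[tr], group1, group2, method, k_max, rng)
        used[sel] += 1
        imp_sum[sel] += np.abs(beta[sel])
        pred1 = yhat_te > 0.0
        accs[r] = float(np.mean(pred1 == (labels[te] == group1)))

    with np.errstate(invalid="ignore"):
        importance = np.where(used > 0, imp_sum / np.maximum(used, 1), 0.0)
    table = pd.DataFrame({
        "feature": names,
        "used_times": used,
        "importance": importance,
        "mean": X.mean(axis=0),
        "sd": X.std(axis=0, ddof=1),
    }).sort_values(["used_times", "importance"],
                   ascending=False).reset_index(drop=True)
    return SelectionReport(table=table, rounds=R, accuracies=accs, method=method)


def calibrate_k_max(X: np.ndarray, labels: np.ndarray, group1: str, group2: str,
                    k_start: int = K_MAX, rounds: int = 20,
                    ceiling: float = 0.65, holdout: float = 0.25,
                    seed: int = 0) -> int:
    """Permutation guard on the regressor cap.

    Starting from ``k_start``, the cap is reduced until EFBLS on
    label-permuted data keeps mean held-out accuracy below ``ceiling`` over
    ``rounds`` permuted rounds — i.e. until the selector can no longer
    manufacture spurious separation at that capacity.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    for k in range(k_start, 0, -1):
        perm_labels = rng.permutation(labels)
        rep = repeated_rounds_report(X, perm_labels, group1, group2,
                                     method="efbls", R=rounds, holdout=holdout,
                                     seed=int(rng.integers(2 ** 31)), k_max=k)
        if rep.mean_accuracy < ceiling:
            return k
    return 1
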