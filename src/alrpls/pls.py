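"""PLS1 regression and PLS-DA, from scratch.

Single-response NIPALS partial least squares with the validation machinery
used by chemometrics packages: cross-validated component selection (Q^2 =
1 - PRESS/TSS over held-out predictions), VIP scores, delete-a-group
jackknife confidence intervals for the regression coefficients, DMOD
(distance to model in X space) outlier screening and a permutation test of
the cross-validated Q^2.

Columns of X are mean-centered and scaled to unit variance before fitting;
the response is centered. Discriminant analysis codes the two classes as
+1/-1 and assigns each sample to the class whose code is nearest to its
predicted value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PlsModel",
    "CvReport",
    "VipVector",
    "JackknifeCI",
    "DmodReport",
    "assign_folds",
    "fit_pls",
    "choose_ncomp",
    "q_squared",
    "misclassification",
    "vip",
    "jackknife_ci",
    "dmod",
    "permutation_test",
]


@dataclass
class PlsModel:
    """Fitted PLS1 model in centered/scaled coordinates.

    ``weights`` (W), ``loadings`` (P) and ``scores`` (T) follow the NIPALS
    convention; ``coef`` is the coefficient vector b on the scaled X such
    that yhat = y_mean + Xscaled @ b. ``kept`` maps retained columns back
    to the input (constant columns are dropped with a recorded index).
    """

    n_components: int
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    kept: np.ndarray
    mode: str = "regression"
    ssy_per_component: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def coef_full(self) -> np.ndarray:
        """Coefficients on the original column set (dropped columns = 0)."""
        b = np.zeros(len(self.x_mean))
        b[self.kept] = self.coef
        return b

    @property
    def coef_raw(self) -> np.ndarray:
        """Coefficients in raw (unscaled) X units, dropped columns = 0.

        Comparable across refits on different sample subsets, whose
        autoscaling factors differ.
        """
        b = np.zeros(len(self.x_mean))
        b[self.kept] = self.coef / self.x_scale[self.kept]
        return b

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.x_mean) / self.x_scale

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = self.transform_x(x)[:, self.kept]
        return self.y_mean + xs @ self.coef

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Nearest-code class assignment for +1/-1 dummy coding."""
        return np.where(self.predict(x) >= 0.0, 1.0, -1.0)

    def r2(self, x: np.ndarray, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(x)
        tss = ((y - y.mean()) ** 2).sum()
        if tss == 0:
            raise ValueError("response has zero variance")
        return float(1.0 - (resid**2).sum() / tss)


def _prepare(x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(y) != x.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values are not supported")
    return x, y


def fit_pls(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    mode: str = "regression",
) -> PlsModel:
    """Fit PLS1 by NIPALS (deterministic; no random initialization).

    Constant columns are dropped before scaling. If ``n_components``
    exceeds what the data support (X deflated to numerical zero), the
    component count is truncated.
    """
    x, y = _prepare(x, y)
    n, j = x.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < 3:
        raise ValueError("need at least 3 samples")

    x_mean = x.mean(axis=0)
    x_sd = x.std(axis=0, ddof=1)
    # relative tolerance: an exactly-constant column can carry ~1e-16 jitter
    kept = np.nonzero(x_sd > 1e-12 * (np.abs(x_mean) + 1.0))[0]
    if len(kept) == 0:
        raise ValueError("all X columns are constant")
    x_scale = np.where(x_sd > 0, x_sd, 1.0)
    xs = ((x - x_mean) / x_scale)[:, kept]
    y_mean = float(y.mean())
    yc = y - y_mean
    if np.allclose(yc, 0):
        raise ValueError("response has zero variance")

    jj = len(kept)
    a_max = min(n_components, n - 1, jj)
    w_list, p_list, q_list, t_list, ssy = [], [], [], [], []
    e, f = xs.copy(), yc.copy()
    eps = 1e-12 * max(np.linalg.norm(xs), 1.0)
    for _ in range(a_max):
        wv = e.T @ f
        nw = np.linalg.norm(wv)
        if nw <= eps:
            break
        wv /= nw
        t = e @ wv
        tt = float(t @ t)
        if tt <= eps**2:
            break
        p = e.T @ t / tt
        q = float(f @ t / tt)
        e = e - np.outer(t, p)
        f = f - q * t
        w_list.append(wv)
        p_list.append(p)
        q_list.append(q)
        t_list.append(t)
        ssy.append(q * q * tt)
    if not w_list:
        raise ValueError("no usable PLS component (X orthogonal to y?)")

    w = np.column_stack(w_list)
    p = np.column_stack(p_list)
    q = np.asarray(q_list)
    t = np.column_stack(t_list)
    # b = W (P'W)^{-1} q maps the scaled X directly to predictions
    b = w @ np.linalg.solve(p.T @ w, q)
    return PlsModel(
        n_components=len(q_list),
        weights=w,
        loadings=p,
        y_loadings=q,
        scores=t,
        coef=b,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        kept=kept,
        mode=mode,
        ssy_per_component=np.asarray(ssy),
    )


def assign_folds(
    n: int,
    folds: int,
    seed: int,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic fold assignment, stratified by ``labels`` if given.

    Depends only on (n, folds, seed, labels), so every stage of a run that
    shares these reuses identical folds.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if labels is None:
        order = rng.permutation(n)
        assign[order] = np.arange(n) % folds
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            idx = np.nonzero(labels == lab)[0]
            order = rng.permutation(len(idx))
            assign[idx[order]] = np.arange(len(idx)) % folds
    return assign


def _cv_predictions(
    x: np.ndarray,
    y: np.ndarray,
    a: int,
    fold_assign: np.ndarray,
    mode: str = "regression",
) -> np.ndarray:
    """Held-out predictions: refit on 6/7, predict the remaining 1/7."""
    yhat = np.empty(len(y), dtype=float)
    for g in np.unique(fold_assign):
        train = fold_assign != g
        model = fit_pls(x[train], y[train], a, mode=mode)
        yhat[~train] = model.predict(x[~train])
    return yhat


@dataclass
class CvReport:
    """Cross-validation summary for component selection."""

    folds: int
    q2_per_component: list[float]
    chosen_components: int
    r2: float
    misclassification_fit: float | None
    misclassification_cv: float | None
    cv_predictions: np.ndarray
    fold_assign: np.ndarray
    seed: int


def q_squared(
    x: np.ndarray,
    y: np.ndarray,
    a: int,
    folds: int = 7,
    seed: int = 0,
    fold_assign: np.ndarray | None = None,
    mode: str = "regression",
) -> float:
    """Cross-validated Q^2 = 1 - PRESS/TSS.

    PRESS pools squared errors of held-out predictions; TSS is about the
    overall response mean.
    """
    x, y = _prepare(x, y)
    if fold_assign is None:
        labels = y if mode == "discriminant" else None
        fold_assign = assign_folds(len(y), folds, seed, labels)
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("response has zero variance")
    yhat = _cv_predictions(x, y, a, fold_assign, mode=mode)
    return float(1.0 - ((y - yhat) ** 2).sum() / tss)


def misclassification(
    x: np.ndarray,
    labels: np.ndarray,
    a: int,
    folds: int = 7,
    seed: int = 0,
    fold_assign: np.ndarray | None = None,
) -> tuple[float, float]:
    """(training, cross-validated) misclassification rates for PLS-DA.

    ``labels`` must already be coded +1/-1. Each sample is assigned to the
    class whose code is nearest to its predicted value.
    """
    x, y = _prepare(x, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need two classes")
    if not np.all(np.isin(classes, [-1.0, 1.0])):
        raise ValueError("labels must be coded +1/-1")
    if fold_assign is None:
        fold_assign = assign_folds(len(y), folds, seed, y)
    model = fit_pls(x, y, a, mode="discriminant")
    fit_rate = float(np.mean(model.classify(x) != y))
    yhat = _cv_predictions(x, y, a, fold_assign, mode="discriminant")
    cv_rate = float(np.mean(np.where(yhat >= 0, 1.0, -1.0) != y))
    return fit_rate, cv_rate


def choose_ncomp(
    x: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    folds: int = 7,
    seed: int = 0,
    eps_comp: float = 0.01,
    mode: str = "regression",
    fold_assign: np.ndarray | None = None,
) -> CvReport:
    """Select the number of latent components by 7-fold cross-validation.

    Components are added while the cumulative Q^2 improves by at least
    ``eps_comp``; at least one component is always kept. Fold assignment is
    stratified by class in discriminant mode and fully determined by the
    seed.
    """
    x, y = _prepare(x, y)
    n = len(y)
    if fold_assign is None:
        labels = y if mode == "discriminant" else None
        fold_assign = assign_folds(n, folds, seed, labels)
    folds_actual = len(np.unique(fold_assign))
    max_a = max(1, min(max_components, n - int(np.ceil(n / folds_actual)) - 1))

    q2s: list[float] = []
    chosen = 1
    for a in range(1, max_a + 1):
        q2s.append(q_squared(x, y, a, fold_assign=fold_assign, mode=mode))
        if a == 1:
            continue
        if q2s[-1] - q2s[chosen - 1] >= eps_comp:
            chosen = a
        elif a > chosen + 1:
            break  # two consecutive non-improving components: stop early

    model = fit_pls(x, y, chosen, mode=mode)
    r2 = model.r2(x, y)
    mis_fit = mis_cv = None
    if mode == "discriminant":
        mis_fit, mis_cv = misclassification(x, y, chosen, fold_assign=fold_assign)
    return CvReport(
        folds=folds_actual,
        q2_per_component=q2s,
        chosen_components=chosen,
        r2=r2,
        misclassification_fit=mis_fit,
        misclassification_cv=mis_cv,
        cv_predictions=_cv_predictions(x, y, chosen, fold_assign, mode=mode),
        fold_assign=fold_assign,
        seed=seed,
    )


@dataclass
class VipVector:
    """Per-feature variable importance in projection; mean(VIP^2) = 1."""

    values: np.ndarray
    feature_indices: np.ndarray  # indices into the original X columns


def vip(model: PlsModel) -> VipVector:
    """VIP_j = sqrt(J * sum_a[SSY_a (w_ja/||w_a||)^2] / sum_a SSY_a).

    SSY_a is the response variance explained by component a; with unit-norm
    weight vectors the squared VIPs average to exactly 1.
    """
    ssy = model.ssy_per_component
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance")
    w = model.weights
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    jj = w.shape[0]
    v = np.sqrt(jj * (wn**2 @ ssy) / total)
    return VipVector(values=v, feature_indices=model.kept)


@dataclass
class JackknifeCI:
    """Delete-a-group jackknife CIs for PLS regression coefficients."""

    estimate: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    excludes_zero: np.ndarray
    feature_indices: np.ndarray
    level: float


def jackknife_ci(
    x: np.ndarray,
    y: np.ndarray,
    a: int,
    folds: int = 7,
    seed: int = 0,
    level: float = 0.95,
    fold_assign: np.ndarray | None = None,
    mode: str = "regression",
) -> JackknifeCI:
    """Jackknife the coefficient vector over the CV segments.

    For each fold g the model is refit without fold g giving b^(g);
    SE_j = sqrt((G-1)/G * sum_g (b_j^(g) - mean_g b_j)^2) and the interval
    is b_full +- t_{G-1} SE. A coefficient whose interval excludes zero is
    flagged. Coefficients are expressed in raw X units so that refits with
    different autoscaling factors are comparable.
    """
    x, y = _prepare(x, y)
    if fold_assign is None:
        labels = y if mode == "discriminant" else None
        fold_assign = assign_folds(len(y), folds, seed, labels)
    groups = np.unique(fold_assign)
    g = len(groups)
    if g < 3:
        raise ValueError("need at least 3 folds for a jackknife SE")

    full = fit_pls(x, y, a, mode=mode)
    j = x.shape[1]
    b_g = np.zeros((g, j))
    for i, grp in enumerate(groups):
        sub = fit_pls(x[fold_assign != grp], y[fold_assign != grp], a, mode=mode)
        b_g[i] = sub.coef_raw
    b_bar = b_g.mean(axis=0)
    se = np.sqrt((g - 1) / g * ((b_g - b_bar) ** 2).sum(axis=0))
    tcrit = stats.t.ppf(0.5 + level / 2, df=g - 1)
    est = full.coef_raw
    lower = est - tcrit * se
    upper = est + tcrit * se
    return JackknifeCI(
        estimate=est,
        se=se,
        lower=lower,
        upper=upper,
        excludes_zero=(lower > 0) | (upper < 0),
        feature_indices=np.arange(j),
        level=level,
    )


@dataclass
class DmodReport:
    """Per-sample normalized distance to the model in X-residual space."""

    distances: np.ndarray
    critical_value: float
    outliers: np.ndarray  # boolean flags


def dmod(model: PlsModel, x: np.ndarray, alpha: float = 0.05) -> DmodReport:
    """DMOD: residual X distance of each sample after A components.

    Each sample's residual standard deviation is normalized by the pooled
    model residual SD; a sample is flagged when its squared normalized
    distance exceeds the F quantile at ``alpha`` with (J'-A) and
    (n-A-1)(J'-A) degrees of freedom — the convention used by chemometrics
    software for the distance-to-model criterion.
    """
    xs = model.transform_x(np.asarray(x, dtype=float))[:, model.kept]
    n, jj = xs.shape
    a = model.n_components
    t = xs @ model.weights @ np.linalg.inv(model.loadings.T @ model.weights)
    resid = xs - t @ model.loadings.T
    df_col = max(jj - a, 1)
    s_i = np.sqrt((resid**2).sum(axis=1) / df_col)
    df_pool = max(n - a - 1, 1)
    s0 = np.sqrt((resid**2).sum() / (df_pool * df_col))
    # residuals at numerical-noise level (e.g. A = rank(X)) mean no sample
    # is off the model plane
    if s0 <= 1e-10 * np.sqrt((xs**2).mean() + 1e-300):
        return DmodReport(
            distances=np.zeros(n),
            critical_value=np.inf,
            outliers=np.zeros(n, dtype=bool),
        )
    d = s_i / s0
    crit = float(np.sqrt(stats.f.ppf(1 - alpha, df_col, df_pool * df_col)))
    return DmodReport(distances=d, critical_value=crit, outliers=d > crit)


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    a: int,
    folds: int = 7,
    n_perm: int = 199,
    seed: int = 0,
    mode: str = "regression",
) -> tuple[float, float, np.ndarray]:
    """Permutation test of the cross-validated Q^2.

    The response is permuted ``n_perm`` times; the p-value uses the +1
    convention p = (1 + #{Q2_perm >= Q2_obs}) / (1 + n_perm), so
    p >= 1/(n_perm+1) always. Returns (p_value, observed Q2, null Q2s).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 for p to reach 0.05")
    x, y = _prepare(x, y)
    rng = np.random.default_rng(seed)
    labels = y if mode == "discriminant" else None
    fold_assign = assign_folds(len(y), folds, seed, labels)
    q2_obs = q_squared(x, y, a, fold_assign=fold_assign, mode=mode)
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        labels_p = yp if mode == "discriminant" else None
        fa = assign_folds(len(y), folds, seed + 1 + i, labels_p)
        null[i] = q_squared(x, yp, a, fold_assign=fa, mode=mode)
    p = (1.0 + np.sum(null >= q2_obs)) / (1.0 + n_perm)
    return float(p), float(q2_obs), null
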