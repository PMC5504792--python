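"""Logistic quality-score models and sparse selection.

Three routes to a sparse model are provided, mirroring standard practice
for base-call quality calibration:

* :func:`fit_mle` — unpenalized maximum likelihood via iteratively
  reweighted least squares (Newton-Raphson) with step-halving;
* :func:`backward_eliminate` — greedy backward deletion under AIC
  (``2k - 2L``) or BIC (``k ln n - 2L``), where ``k`` counts the non-zero
  parameters including the intercept;
* :func:`fit_l1` — L1 / elastic-net penalized likelihood
  ``min -L(beta) + lambda * (alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2)``
  with the intercept unpenalized, solved by a glmnet-style proximal-Newton
  coordinate descent on the raw (unstandardized) feature scale.

No feature standardization is applied before penalization: coefficients are
reported on the raw feature scale, and the penalty therefore weighs features
according to their natural units.  This matters for which features L1
shrinks first and is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from . import io_formats


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist (coefficients diverge)."""


class CollinearityError(np.linalg.LinAlgError):
    """Rank-deficient design; names the (near-)collinear columns."""


class ConvergenceError(RuntimeError):
    """Penalized solver failed to reach the KKT tolerance."""


@dataclass
class QualityModel:
    """A fitted logistic quality model.

    ``beta`` is aligned with ``feature_names`` (intercept first); features
    removed by selection carry an exact zero.  ``knots``/``trim_*`` copy the
    feature-matrix metadata so scoring is train-consistent.
    """

    feature_names: list[str]
    beta: np.ndarray
    method: str
    lam: float | None = None
    alpha: float | None = None
    n_train: int | None = None
    loglik: float | None = None
    knots: np.ndarray | None = None
    trim_avg: tuple = (0.02, 3.0)
    trim_sd: tuple = (0.02, 1.0)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.method not in io_formats.MODEL_METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if len(self.feature_names) != self.beta.size:
            raise ValueError("feature_names/beta length mismatch")

    @property
    def support(self) -> list[str]:
        """Names of features with non-zero coefficients."""
        return [n for n, b in zip(self.feature_names, self.beta) if b != 0.0]

    @property
    def k(self) -> int:
        """Number of non-zero parameters (intercept included)."""
        return int(np.count_nonzero(self.beta))


@dataclass
class FitReport:
    iterations: int
    converged: bool
    grad_norm: float
    t_scores: dict | None = None
    deletion_trace: list = field(default_factory=list)  # [(feature, criterion), ...]


# ---------------------------------------------------------------------------
# likelihood and information criteria


def log_likelihood(beta, X, y) -> float:
    """Bernoulli log-likelihood (nats) of labels y under the logistic model.

    Returns -inf when a probability saturates at the wrong label.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    # log p for y=1, log(1-p) for y=0; stable even at eta = +/-inf
    with np.errstate(invalid="ignore"):
        terms = np.where(y == 1, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta))
    return float(terms.sum())


def aic(k: int, loglik: float) -> float:
    return 2.0 * k - 2.0 * loglik


def bic(k: int, n: int, loglik: float) -> float:
    return k * np.log(n) - 2.0 * loglik


# ---------------------------------------------------------------------------
# IRLS core


def _diagnose_collinearity(X, names):
    """Name columns involved in an (near-)exact linear dependence."""
    Xs = X / np.maximum(np.abs(X).max(axis=0), 1e-300)
    _, R = np.linalg.qr(Xs)
    diag = np.abs(np.diag(R))
    bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
    return [names[j] for j in bad]


def _irls(X, y, beta0=None, tol=1e-8, max_iter=100, names=None):
    """Newton-Raphson/IRLS maximizer of the logistic log-likelihood.

    Step-halving keeps the log-likelihood non-decreasing.  Returns
    ``(beta, loglik, iterations, converged, grad_inf_norm)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = log_likelihood(beta, X, y)
    converged = False
    it = 0
    grad_inf = np.inf
    # divergence is judged on the standardized-coefficient scale so that
    # legitimately large coefficients on small-scale columns do not trip it
    col_scale = np.sqrt(np.einsum("ij,ij->j", X, X) / n)
    for it in range(1, max_iter + 1):
        prob = expit(X @ beta)
        grad = X.T @ (y - prob)
        grad_inf = float(np.abs(grad).max())
        w = np.clip(prob * (1.0 - prob), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            c = cho_factor(H)
            step = cho_solve(c, grad)
        except np.linalg.LinAlgError:
            bad = _diagnose_collinearity(X, names)
            if bad:
                raise CollinearityError(
                    f"design is rank deficient (collinear columns: {bad})"
                ) from None
            # numerically near-singular but full rank: minimum-norm step
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving on the log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = log_likelihood(cand, X, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        # perfect separation: likelihood approaches its supremum of 0 while
        # coefficients diverge (large-but-finite coefficients with a bounded
        # likelihood are legitimate for near-collinear transforms)
        if np.abs(beta * col_scale).max() > 30.0 and ll_new > -1e-8 * n:
            raise SeparationError(
                "coefficients diverging towards a perfect fit; "
                "data are separated and the MLE does not exist"
            )
        if abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    prob = expit(X @ beta)
    grad_inf = float(np.abs(X.T @ (y - prob)).max())
    return beta, ll, it, converged, grad_inf


def _check_labels(y):
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise SeparationError("all labels identical; logistic MLE does not exist")
    return y.astype(float)


def _fisher_t_scores(beta, X, y, names):
    """t = beta / SE with SE from the inverse observed Fisher information."""
    prob = expit(X @ beta)
    w = np.clip(prob * (1.0 - prob), 1e-10, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise CollinearityError("singular information matrix") from None
    se = np.sqrt(np.diag(cov))
    return {n: float(b / s) for n, b, s in zip(names, beta, se)}, se


def fit_mle(X, y, feature_names=None, metadata=None):
    """Maximum-likelihood logistic fit.

    ``metadata`` may be a FeatureMatrix (or anything with knots/trim_avg/
    trim_sd attributes) whose knot and trim settings are copied onto the
    model.  Returns ``(QualityModel, FitReport)``.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    beta, ll, it, conv, grad = _irls(X, y, names=names)
    tsc, _ = _fisher_t_scores(beta, X, y, names)
    model = QualityModel(
        feature_names=names, beta=beta, method="mle", n_train=n, loglik=ll,
        **_meta_kwargs(metadata),
    )
    return model, FitReport(iterations=it, converged=conv, grad_norm=grad, t_scores=tsc)


def _meta_kwargs(metadata):
    if metadata is None:
        return {}
    return {
        "knots": getattr(metadata, "knots", None),
        "trim_avg": tuple(getattr(metadata, "trim_avg", (0.02, 3.0))),
        "trim_sd": tuple(getattr(metadata, "trim_sd", (0.02, 1.0))),
    }


def drop_aliased_columns(X, feature_names):
    """Indices and names of a maximal linearly independent column subset.

    The full 75-column design is intrinsically aliased: the 48
    trinucleotide dummies plus the cycle-1 indicator sum to the intercept.
    Unpenalized fits (MLE, backward deletion) therefore drop aliased
    columns first, exactly as R's ``glm`` marks them NA; penalized fits
    need no such treatment.  The intercept (column 0) is always kept.
    Returns ``(kept_indices, dropped_names)``.
    """
    from scipy.linalg import qr as _qr

    X = np.asarray(X, dtype=float)
    norms = np.maximum(np.linalg.norm(X, axis=0), 1e-300)
    _, R, piv = _qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > 1e-9 * diag[0]))
    kept = sorted(piv[:rank])
    if 0 not in kept:  # force-keep the intercept, drop a dependent partner
        kept = sorted(set(kept[:-1]) | {0})
    dropped = [feature_names[j] for j in range(X.shape[1]) if j not in kept]
    return kept, dropped


# ---------------------------------------------------------------------------
# backward deletion under AIC / BIC


def backward_eliminate(X, y, criterion="bic", feature_names=None, metadata=None):
    """Greedy backward deletion.

    At each step every remaining non-intercept feature is tentatively
    removed, the model refitted, and the removal giving the lowest
    AIC/BIC is accepted if it improves on the current criterion; the
    procedure stops when no removal lowers the criterion.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]

    def crit(k, ll):
        return aic(k, ll) if criterion == "aic" else bic(k, n, ll)

    cols = list(range(p))
    beta_cur, ll, *_ = _irls(X, y, names=names)
    crit_cur = crit(len(cols), ll)
    trace = []
    total_iters = 1
    while len(cols) > 1:
        best = None
        for drop_pos, j in enumerate(cols):
            if j == 0:  # intercept exempt
                continue
            sub = cols[:drop_pos] + cols[drop_pos + 1:]
            warm = np.delete(beta_cur, drop_pos)
            b, ll_j, *_ = _irls(X[:, sub], y, beta0=warm,
                                names=[names[c] for c in sub])
            total_iters += 1
            c_j = crit(len(sub), ll_j)
            if best is None or c_j < best[0]:
                best = (c_j, drop_pos, b, ll_j)
        if best is None or best[0] >= crit_cur:
            break
        crit_cur, drop_pos, beta_cur, ll = best
        trace.append((names[cols[drop_pos]], float(crit_cur)))
        del cols[drop_pos]

    beta_full = np.zeros(p)
    beta_full[cols] = beta_cur
    tsc, _ = _fisher_t_scores(beta_cur, X[:, cols], y, [names[c] for c in cols])
    model = QualityModel(
        feature_names=names, beta=beta_full, method=f"be_{criterion}",
        n_train=n, loglik=ll, **_meta_kwargs(metadata),
    )
    report = FitReport(iterations=total_iters, converged=True,
                       grad_norm=0.0, t_scores=tsc, deletion_trace=trace)
    return model, report


# ---------------------------------------------------------------------------
# L1 / elastic-net penalized fit (proximal Newton + coordinate descent)


def _penalized_objective(beta, X, y, lam, alpha, pen_mask):
    pen = lam * (alpha * np.abs(beta[pen_mask]).sum()
                 + 0.5 * (1 - alpha) * np.square(beta[pen_mask]).sum())
    return -log_likelihood(beta, X, y) + pen


def _kkt_violation(beta, X, y, lam, alpha, pen_mask, col_scale=None):
    """Max violation of the stationarity conditions, on the 1/n scale.

    Violations are normalized by each column's root-mean-square scale so the
    tolerance is comparable across features with different natural units.
    """
    n = X.shape[0]
    grad = X.T @ (expit(X @ beta) - y) / n
    lam_n = lam / n
    v = np.zeros_like(beta)
    free = ~pen_mask
    v[free] = np.abs(grad[free])
    pen = pen_mask
    nz = pen & (beta != 0)
    v[nz] = np.abs(grad[nz] + lam_n * (1 - alpha) * beta[nz]
                   + lam_n * alpha * np.sign(beta[nz]))
    z = pen & (beta == 0)
    v[z] = np.maximum(0.0, np.abs(grad[z]) - lam_n * alpha)
    if col_scale is None:
        col_scale = np.sqrt(np.einsum("ij,ij->j", X, X) / n)
    return float((v / np.maximum(col_scale, 1.0)).max())


def fit_l1(X, y, lam, alpha=1.0, feature_names=None, metadata=None,
           beta0=None, tol=1e-6, max_outer=100):
    """Minimize ``-L(beta) + lam*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)``.

    The intercept (column 0) is never penalized.  ``alpha=1`` is the lasso,
    ``alpha<1`` the elastic net.  At ``lam=0`` the fit coincides with the
    MLE.  Convergence is declared when the maximum KKT stationarity
    violation of the 1/n-scaled objective drops below ``tol``.

    Cold starts are solved pathwise: a short geometric lambda sequence from
    the all-zero threshold down to ``lam``, each solution warm-starting the
    next (the standard lasso homotopy strategy).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n, p = X.shape
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]

    if lam == 0.0:
        beta, ll, *_ = _irls(X, y, beta0=beta0, names=names)
        return QualityModel(feature_names=names, beta=beta, method="l1" if alpha == 1 else "elastic_net",
                            lam=0.0, alpha=alpha, n_train=n, loglik=ll,
                            **_meta_kwargs(metadata))

    if beta0 is None and alpha > 0.0:
        lam_max = _lambda_max(X, y, alpha)
        if lam < lam_max:
            n_steps = int(np.ceil(np.log(lam_max / lam) / np.log(4.0)))
            path = np.geomspace(lam_max, lam, n_steps + 1)[1:-1]
            for lam_k in path:
                m = _fit_l1_direct(X, y, float(lam_k), alpha, names, metadata,
                                   beta0, tol, max_outer)
                beta0 = m.beta
    return _fit_l1_direct(X, y, lam, alpha, names, metadata, beta0, tol, max_outer)


def _lambda_max(X, y, alpha):
    """Smallest lambda at which every penalized coefficient is zero."""
    n = X.shape[0]
    pbar = y.mean()
    grad = X.T @ (y - pbar)  # at beta = (logit(pbar), 0, ..., 0)
    return float(np.abs(grad[1:]).max() / alpha) * 1.0000001


def _fit_l1_direct(X, y, lam, alpha, names, metadata, beta0, tol, max_outer):
    n, p = X.shape

    pen_mask = np.ones(p, dtype=bool)
    pen_mask[0] = False  # intercept
    col_scale = np.sqrt(np.einsum("ij,ij->j", X, X) / n)

    # The objective is kept on the raw feature scale, but the quadratic
    # subproblems are solved on centered, unit-variance columns for
    # conditioning; the per-coordinate soft thresholds carry the inverse
    # scales, so the solution maps back to the raw-scale problem exactly.
    mu = X.mean(axis=0)
    mu[0] = 0.0  # intercept column untouched
    sd = X.std(axis=0)
    sd[~pen_mask] = 1.0
    dead = pen_mask & (sd < 1e-12)  # constant penalized column: stays at 0
    sd[dead] = 1.0
    Z = np.asfortranarray((X - mu) / sd)
    Z[:, 0] = 1.0
    Z2 = np.asfortranarray(np.square(Z))

    def to_raw(bt):
        b = bt / sd
        b[0] = bt[0] - float((mu[1:] / sd[1:]) @ bt[1:])
        b[dead] = 0.0
        return b

    bt = np.zeros(p)  # coefficients on the transformed scale
    if beta0 is not None:
        b0 = np.asarray(beta0, dtype=float)
        bt = b0 * sd
        bt[0] = b0[0] + float(mu @ b0)
        bt[dead] = 0.0
    else:
        pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
        bt[0] = np.log(pbar / (1 - pbar))

    lam_l1 = lam * alpha / (n * sd)   # per-coordinate thresholds
    lam_l2 = lam * (1 - alpha) / (n * np.square(sd))
    obj = _penalized_objective(to_raw(bt), X, y, lam, alpha, pen_mask)
    # stop the inner CD once the quadratic gradient moves by < inner_tol,
    # which is directly comparable to the outer KKT tolerance
    inner_tol = 0.1 * tol

    for _ in range(max_outer):
        eta = Z @ bt
        prob = expit(eta)
        w = np.clip(prob * (1.0 - prob), 1e-6, None) / n
        r = (y - prob) / (w * n)  # working residual z - Z bt_new
        wr = w * r
        cjj = w @ Z2  # curvature of each coordinate
        cjj[dead] = 1.0

        bt_new = bt.copy()
        active: list = []
        full_pass = True
        for sweep in range(500):
            max_gdelta = 0.0
            idx = range(p) if full_pass else active
            for j in idx:
                if dead[j]:
                    continue
                zj = Z[:, j]
                bj = bt_new[j]
                g = float(zj @ wr) + cjj[j] * bj
                if pen_mask[j]:
                    bn = np.sign(g) * max(abs(g) - lam_l1[j], 0.0) / (cjj[j] + lam_l2[j])
                else:
                    bn = g / cjj[j]
                if bn != bj:
                    delta = bn - bj
                    r -= zj * delta
                    wr -= (w * zj) * delta
                    bt_new[j] = bn
                    max_gdelta = max(max_gdelta, cjj[j] * abs(delta))
            if full_pass:
                # a converged full pass is the exit condition
                if max_gdelta < inner_tol:
                    break
                active = [j for j in range(p)
                          if bt_new[j] != 0.0 or not pen_mask[j]]
                full_pass = False
            elif max_gdelta < inner_tol or sweep % 20 == 19:
                full_pass = True  # verify / pick up new entries

        # proximal-Newton step with halving on the true penalized objective
        direction = bt_new - bt
        scale = 1.0
        for _ in range(30):
            cand = bt + scale * direction
            obj_new = _penalized_objective(to_raw(cand), X, y, lam, alpha, pen_mask)
            if obj_new <= obj + 1e-12:
                break
            scale *= 0.5
        bt = bt + scale * direction
        obj = obj_new

        beta = to_raw(bt)
        if _kkt_violation(beta, X, y, lam, alpha, pen_mask, col_scale) <= tol:
            ll = log_likelihood(beta, X, y)
            return QualityModel(
                feature_names=names, beta=beta,
                method="l1" if alpha == 1.0 else "elastic_net",
                lam=float(lam), alpha=float(alpha), n_train=n, loglik=ll,
                **_meta_kwargs(metadata),
            )
    raise ConvergenceError(
        f"no KKT convergence after {max_outer} outer iterations "
        f"(violation {_kkt_violation(to_raw(bt), X, y, lam, alpha, pen_mask, col_scale):.3g}, "
        f"lambda={lam}, alpha={alpha}, n={n}, p={p})"
    )


def l1_path(X, y, lam_grid, alpha=1.0, feature_names=None, metadata=None, tol=1e-6):
    """Fit the penalized model along a lambda grid with warm starts.

    Returns models in the order of ``lam_grid`` (internally solved from the
    largest lambda down).
    """
    lam_grid = list(lam_grid)
    order = np.argsort(lam_grid)[::-1]
    models = {}
    beta0 = None
    for i in order:
        m = fit_l1(X, y, lam_grid[i], alpha=alpha, feature_names=feature_names,
                   metadata=metadata, beta0=beta0, tol=tol)
        beta0 = m.beta
        models[i] = m
    return [models[i] for i in range(len(lam_grid))]


def select_lambda_cv(X, y, lam_grid, folds=5, seed=0, alpha=1.0, full_output=False):
    """Choose lambda by stratified K-fold cross-validation maximizing AUC.

    Ties are broken toward the larger lambda (the sparser model).  The fold
    split is deterministic given ``seed``.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    lam_grid = sorted(set(float(v) for v in lam_grid))
    if not lam_grid:
        raise ValueError("empty lambda grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples < {folds} folds; "
            "reduce folds or resample (stratification cannot place both "
            "classes in every fold)"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = np.zeros((folds, len(lam_grid)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        beta0 = None
        for i in range(len(lam_grid) - 1, -1, -1):  # large -> small, warm start
            m = fit_l1(X[tr], y[tr], lam_grid[i], alpha=alpha, beta0=beta0)
            beta0 = m.beta
            eta = X[te] @ m.beta
            aucs[f, i] = roc_auc_score(y[te], eta)
    mean_auc = aucs.mean(axis=0)
    best = int(np.flatnonzero(mean_auc >= mean_auc.max() - 1e-12)[-1])
    lam_star = lam_grid[best]
    if full_output:
        return lam_star, {"lambdas": lam_grid, "mean_auc": mean_auc.tolist(),
                          "fold_auc": aucs.tolist()}
    return lam_star


# ---------------------------------------------------------------------------
# t-score contributions


def t_scores(model: QualityModel, X, y) -> dict:
    """Per-feature contribution t = coefficient / standard error.

    Standard errors come from the inverse observed Fisher information of an
    unpenalized refit restricted to the model's support (for unpenalized
    methods the refit reproduces the fit itself).  The numerator is the
    model's own coefficient.
    """
    if not model.support:
        raise ValueError("model support is empty")
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    cols = [model.feature_names.index(nm) for nm in model.support]
    Xs = X[:, cols]
    beta_refit, *_ = _irls(Xs, y, names=model.support)
    _, se = _fisher_t_scores(beta_refit, Xs, y, model.support)
    beta_model = model.beta[cols]
    return {nm: float(b / s) for nm, b, s in zip(model.support, beta_model, se)}


def t_score_table(model: QualityModel, X, y, path=None):
    """Tabulate coefficients and t-scores; optionally write as TSV."""
    import pandas as pd

    from .features import FEATURE_DESCRIPTIONS

    tsc = t_scores(model, X, y)
    rows = []
    for nm, b in zip(model.feature_names, model.beta):
        rows.append({
            "feature": nm,
            "description": FEATURE_DESCRIPTIONS.get(nm, ""),
            "coefficient": b,
            "t_score": tsc.get(nm, np.nan),
        })
    df = pd.DataFrame(rows)
    if path is not None:
        with io_formats.atomic_write(path) as fh:
            df.to_csv(fh, sep="\t", index=False)
    return df
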