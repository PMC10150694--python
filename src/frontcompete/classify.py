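"""Per-timepoint prediction of turning direction from synchronized features.

Each interpolated timepoint gets its own sparse classifier: an L1-penalized
(lasso) or elastic-net logistic regression trained on 67 events and evaluated
on a held-out test set of 33, with the penalty strength chosen by 10-fold
cross-validation (minimum mean binomial deviance over a glmnet-style lambda
path).  Labels encode right-turning cells as 1 and left-turning as 0.  The
resulting held-out accuracy trajectory over rescaled time localises when in
the decision-making process the cell's features become predictive of the
outcome; the summary statistic is the earliest timepoint whose accuracy
reaches the 70% threshold.

A sparse-group-lasso variant treats each feature's whole 15-timepoint
trajectory as one group: group-sparse selection runs first over the flattened
events x (features * timepoints) matrix, then per-timepoint elastic-net
models are fit on the surviving features only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierConfig",
    "TimepointModel",
    "AccuracyTrajectory",
    "split",
    "standardize_timepoint",
    "fit_at_timepoint",
    "fit_sparse_group_lasso",
    "accuracy_trajectory",
    "evaluate_tensor",
]


@dataclass
class ClassifierConfig:
    n_train: int = 67
    n_test: int = 33
    folds: int = 10
    penalty: str = "lasso"            # lasso | elastic_net | sparse_group_lasso
    alpha: float = 0.8                # elastic-net mixing; lasso == 1
    lambda_rule: str = "min"          # min | 1se
    accuracy_threshold: float = 0.70
    seed: int = 0
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3
    sgl_mix: float = 0.5              # within-group L1 weight of the SGL
    standardize_mode: str = "across"  # across | per_cell

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.penalty not in ("lasso", "elastic_net", "sparse_group_lasso"):
            raise ValueError(f"unknown penalty {self.penalty!r}")


@dataclass
class TimepointModel:
    timepoint: int
    coef: np.ndarray                 # dense (n_features,), mostly zero
    intercept: float
    lam: float
    feature_names: list = field(default_factory=list)
    imputation_means: np.ndarray | None = None
    standardize_mean: np.ndarray | None = None
    standardize_scale: np.ndarray | None = None

    @property
    def nonzero(self) -> dict:
        idx = np.flatnonzero(self.coef)
        names = (self.feature_names if self.feature_names
                 else [f"f{j:04d}" for j in range(self.coef.size)])
        return {names[j]: float(self.coef[j]) for j in idx}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class AccuracyTrajectory:
    accuracies: np.ndarray
    threshold: float
    earliest: int | None             # earliest index with acc >= threshold

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracies, dtype=float)
        if np.any((a < 0) | (a > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


# --------------------------------------------------------------------------
# Train/test split
# --------------------------------------------------------------------------

def split(event_ids, config: ClassifierConfig) -> tuple[np.ndarray,
                                                        np.ndarray]:
    """Seed-reproducible uniform random 67/33 partition of the events."""
    ids = np.asarray(event_ids)
    if ids.size != config.n_train + config.n_test:
        raise ValueError(
            f"dataset size {ids.size} != n_train + n_test "
            f"({config.n_train} + {config.n_test})")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(ids.size)
    return ids[perm[:config.n_train]], ids[perm[config.n_train:]]


# --------------------------------------------------------------------------
# Standardisation
# --------------------------------------------------------------------------

def standardize_timepoint(X_train: np.ndarray, X_test: np.ndarray,
                          mode: str = "across"
                          ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Standardise features by the training mean and standard error.

    Each feature is centred on its mean across training events and divided by
    the standard error of that mean (sd / sqrt(n_train), sample sd); the test
    matrix reuses the training statistics.  Missing values are mean-imputed
    with training means first.  Zero-variance features are set to 0 and
    flagged.  ``mode="per_cell"`` instead centres each event (row) on its own
    feature average before the scaling — an alternative reading of
    "subtracting the cell average", off by default.
    """
    Xtr = np.array(X_train, dtype=float)
    Xte = np.array(X_test, dtype=float)
    n = Xtr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training events")
    col_means = np.nanmean(Xtr, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    for X in (Xtr, Xte):
        nan = ~np.isfinite(X)
        if nan.any():
            X[nan] = np.broadcast_to(col_means, X.shape)[nan]
    if mode == "per_cell":
        Xtr = Xtr - Xtr.mean(axis=1, keepdims=True)
        Xte = Xte - Xte.mean(axis=1, keepdims=True)
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sem = sd / np.sqrt(n)
    flagged = sem == 0
    scale = np.where(flagged, 1.0, sem)
    Ztr = (Xtr - mean) / scale
    Zte = (Xte - mean) / scale
    Ztr[:, flagged] = 0.0
    Zte[:, flagged] = 0.0
    stats = {"mean": mean, "sem": sem, "zero_variance": flagged,
             "imputation_means": col_means}
    return Ztr, Zte, stats


# --------------------------------------------------------------------------
# Penalized logistic regression over a lambda path
# --------------------------------------------------------------------------

def _lambda_path(X: np.ndarray, y: np.ndarray,
                 config: ClassifierConfig) -> np.ndarray:
    n = X.shape[0]
    alpha = 1.0 if config.penalty == "lasso" else max(config.alpha, 1e-3)
    resid = y - y.mean()
    lam_max = np.max(np.abs(X.T @ resid)) / (n * alpha)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambda)


def _refit_intercept(X: np.ndarray, y: np.ndarray,
                     coef: np.ndarray) -> float:
    """Unpenalized 1-D MLE of the intercept given fixed coefficients
    (the intercept is never penalized, as in the reference glmnet)."""
    offset = X @ coef
    b = 0.0
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(offset + b)))
        g = float(np.mean(p - y))
        h = float(np.mean(p * (1.0 - p)))
        if h < 1e-12:
            break
        step = g / h
        b -= np.clip(step, -4.0, 4.0)
        if abs(step) < 1e-10:
            break
    return b


def _fit_one(X: np.ndarray, y: np.ndarray, lam: float,
             config: ClassifierConfig) -> LogisticRegression:
    n = X.shape[0]
    C = 1.0 / max(n * lam, 1e-12)
    if config.penalty == "lasso":
        est = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 intercept_scaling=100.0, max_iter=500,
                                 tol=1e-6)
        est.fit(X, y)
        # liblinear shrinks the (scaled) intercept too; restore the
        # unpenalized intercept at the fitted coefficients
        est.intercept_ = np.array([_refit_intercept(X, y,
                                                    est.coef_.ravel())])
    else:
        est = LogisticRegression(l1_ratio=config.alpha, C=C,
                                 solver="saga", max_iter=3000, tol=1e-4)
        est.fit(X, y)
    return est


def fit_at_timepoint(X: np.ndarray, y: np.ndarray,
                     config: ClassifierConfig | None = None,
                     timepoint: int = 0,
                     feature_names: list | None = None) -> TimepointModel:
    """Fit a sparse logistic classifier with CV-selected penalty strength.

    ``X`` is the standardized events x features matrix, ``y`` the binary
    outcome (right = 1).  The lambda path runs from the smallest value that
    zeroes every coefficient down by ``lambda_min_ratio``; 10-fold stratified
    CV picks the lambda with minimum mean held-out binomial deviance (or the
    one-standard-error lambda when ``lambda_rule == "1se"``).
    """
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    path = _lambda_path(X, y, config)
    # fold count cannot exceed the minority-class size
    n_folds = int(min(config.folds, np.bincount(y).min()))
    n_folds = max(n_folds, 2)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                         random_state=config.seed)
    deviance = np.zeros((n_folds, path.size))
    for f, (tr, va) in enumerate(cv.split(X, y)):
        for j, lam in enumerate(path):
            est = _fit_one(X[tr], y[tr], lam, config)
            p = est.predict_proba(X[va])[:, 1]
            deviance[f, j] = 2.0 * log_loss(y[va], p, labels=[0, 1])
    mean_dev = deviance.mean(axis=0)
    j_min = int(np.argmin(mean_dev))
    if config.lambda_rule == "1se":
        se = deviance.std(axis=0, ddof=1) / np.sqrt(n_folds)
        ok = mean_dev <= mean_dev[j_min] + se[j_min]
        j_min = int(np.flatnonzero(ok)[0])   # path is decreasing in lambda
    lam = float(path[j_min])
    est = _fit_one(X, y, lam, config)
    return TimepointModel(timepoint=timepoint,
                          coef=est.coef_.ravel().copy(),
                          intercept=float(est.intercept_[0]), lam=lam,
                          feature_names=list(feature_names or []))


# --------------------------------------------------------------------------
# Sparse group lasso
# --------------------------------------------------------------------------

def _sgl_prox(beta: np.ndarray, step: float, lam: float, mix: float,
              group_size: int) -> np.ndarray:
    """Prox of lam * (mix * l1 + (1 - mix) * sqrt(T) * group l2)."""
    b = np.sign(beta) * np.maximum(np.abs(beta) - step * lam * mix, 0.0)
    B = b.reshape(-1, group_size)
    norms = np.linalg.norm(B, axis=1, keepdims=True)
    thr = step * lam * (1.0 - mix) * np.sqrt(group_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(norms > 0, np.maximum(0.0, 1.0 - thr / norms), 0.0)
    return (B * shrink).ravel()


def _sgl_fit(X: np.ndarray, y: np.ndarray, lam: float, mix: float,
             group_size: int, max_iter: int = 400,
             tol: float = 1e-6) -> tuple[np.ndarray, float]:
    """FISTA for sparse-group-lasso logistic regression."""
    n, p = X.shape
    # Lipschitz constant of the logistic gradient: ||X||_2^2 / (4n)
    v = np.ones(p) / np.sqrt(p)
    for _ in range(25):
        v = X.T @ (X @ v)
        v /= np.linalg.norm(v)
    L = float(v @ (X.T @ (X @ v))) / (4.0 * n) + 1e-12
    step = 1.0 / L
    beta = np.zeros(p)
    b0 = 0.0
    zb, z0, tk = beta.copy(), b0, 1.0
    for _ in range(max_iter):
        z = X @ zb + z0
        prob = 1.0 / (1.0 + np.exp(-z))
        g = X.T @ (prob - y) / n
        g0 = float(np.mean(prob - y))
        new_beta = _sgl_prox(zb - step * g, step, lam, mix, group_size)
        new_b0 = z0 - step * g0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        zb = new_beta + (tk - 1.0) / t_next * (new_beta - beta)
        z0 = new_b0 + (tk - 1.0) / t_next * (new_b0 - b0)
        delta = np.max(np.abs(new_beta - beta), initial=0.0)
        beta, b0, tk = new_beta, new_b0, t_next
        if delta < tol:
            break
    return beta, b0


def fit_sparse_group_lasso(tensor_values: np.ndarray, y: np.ndarray,
                           config: ClassifierConfig | None = None,
                           train_idx: np.ndarray | None = None,
                           test_idx: np.ndarray | None = None) -> dict:
    """Group-sparse feature selection over whole trajectories, then
    per-timepoint elastic-net models on the surviving features.

    ``tensor_values`` is (events, n_points, n_features); one group is formed
    per feature (its full trajectory over the interpolated timepoints), so
    the number of groups equals the number of features.  The group penalty
    strength is chosen by 5-fold CV deviance over a short path.  Returns a
    dict with ``selected_groups`` (feature indices), the per-timepoint
    ``models`` and the held-out ``trajectory``.
    """
    config = config or ClassifierConfig(penalty="sparse_group_lasso")
    V = np.asarray(tensor_values, dtype=float)
    y = np.asarray(y, dtype=int)
    n, T, p = V.shape
    if train_idx is None or test_idx is None:
        cfg = ClassifierConfig(**{**config.__dict__,
                                  "n_train": config.n_train,
                                  "n_test": n - config.n_train})
        train_idx, test_idx = split(np.arange(n), cfg)
    # groups contiguous: (n, p*T) with feature-major ordering
    Xflat_tr = V[train_idx].transpose(0, 2, 1).reshape(len(train_idx), p * T)
    Xflat_te = V[test_idx].transpose(0, 2, 1).reshape(len(test_idx), p * T)
    Ztr, Zte, _ = standardize_timepoint(Xflat_tr, Xflat_te)
    ytr, yte = y[train_idx], y[test_idx]
    if np.unique(ytr).size < 2:
        raise ValueError("y must contain both classes")

    resid = ytr - ytr.mean()
    G = (Ztr.T @ resid).reshape(p, T)
    lam_max_grp = np.max(np.linalg.norm(G, axis=1)) / (
        len(ytr) * max(1e-9, (1 - config.sgl_mix) * np.sqrt(T)
                       + config.sgl_mix))
    path = np.geomspace(lam_max_grp, lam_max_grp * 0.05, 8)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=config.seed)
    dev = np.zeros((5, path.size))
    for f, (tr, va) in enumerate(cv.split(Ztr, ytr)):
        for j, lam in enumerate(path):
            beta, b0 = _sgl_fit(Ztr[tr], ytr[tr], lam, config.sgl_mix, T)
            prob = 1.0 / (1.0 + np.exp(-(Ztr[va] @ beta + b0)))
            dev[f, j] = 2.0 * log_loss(ytr[va], prob, labels=[0, 1])
    lam = float(path[int(np.argmin(dev.mean(axis=0)))])
    beta, _ = _sgl_fit(Ztr, ytr, lam, config.sgl_mix, T)
    group_norms = np.linalg.norm(beta.reshape(p, T), axis=1)
    selected = np.flatnonzero(group_norms > 1e-10)

    models, accs = [], []
    enet_cfg = ClassifierConfig(**{**config.__dict__,
                                   "penalty": "elastic_net"})
    sub = selected if selected.size else np.arange(min(p, 1))
    for t in range(T):
        Xtr_t, Xte_t, _ = standardize_timepoint(V[train_idx][:, t, sub],
                                                V[test_idx][:, t, sub])
        model = fit_at_timepoint(Xtr_t, ytr, enet_cfg, timepoint=t)
        models.append(model)
        accs.append(float(np.mean(model.predict(Xte_t) == yte)))
    traj = accuracy_trajectory_from_accs(np.array(accs),
                                         config.accuracy_threshold)
    return {"selected_groups": selected, "lambda": lam,
            "models": models, "trajectory": traj,
            "train_idx": train_idx, "test_idx": test_idx}


# --------------------------------------------------------------------------
# Accuracy trajectories
# --------------------------------------------------------------------------

def accuracy_trajectory_from_accs(accs: np.ndarray,
                                  threshold: float) -> AccuracyTrajectory:
    reach = np.flatnonzero(np.asarray(accs) >= threshold)
    return AccuracyTrajectory(accuracies=np.asarray(accs, dtype=float),
                              threshold=threshold,
                              earliest=int(reach[0]) if reach.size else None)


def accuracy_trajectory(models, X_test_per_timepoint, y_test,
                        config: ClassifierConfig | None = None
                        ) -> AccuracyTrajectory:
    """Held-out accuracy per timepoint (0.5 probability cut) and the
    earliest timepoint reaching the accuracy threshold."""
    config = config or ClassifierConfig()
    y_test = np.asarray(y_test, dtype=int)
    if y_test.size == 0:
        raise ValueError("empty test set")
    accs = []
    for model, X in zip(models, X_test_per_timepoint):
        accs.append(float(np.mean(model.predict(X) == y_test)))
    return accuracy_trajectory_from_accs(np.array(accs),
                                         config.accuracy_threshold)


# --------------------------------------------------------------------------
# End-to-end evaluation of a synchronized tensor
# --------------------------------------------------------------------------

def evaluate_tensor(tensor, config: ClassifierConfig | None = None,
                    timepoints=None) -> dict:
    """Split, standardize, fit and score one classifier per timepoint.

    ``tensor`` is a SyncFeatureTensor (events x timepoints x features).
    ``timepoints`` restricts the fit to a subset of timepoint indices
    (accuracies elsewhere are reported as NaN); by default all are fit.
    """
    config = config or ClassifierConfig()
    n = tensor.n_events
    cfg = config
    if config.n_train + config.n_test != n:
        cfg = ClassifierConfig(**{**config.__dict__,
                                  "n_train": int(round(n * 0.67)),
                                  "n_test": n - int(round(n * 0.67))})
    train_idx, test_idx = split(np.arange(n), cfg)
    y = tensor.labels
    ytr, yte = y[train_idx], y[test_idx]
    sel = range(tensor.n_points) if timepoints is None else timepoints
    models: dict[int, TimepointModel] = {}
    accs = np.full(tensor.n_points, np.nan)
    if cfg.penalty == "sparse_group_lasso":
        out = fit_sparse_group_lasso(tensor.values, y, cfg,
                                     train_idx, test_idx)
        out["config"] = cfg
        return out
    for t in sel:
        Xtr, Xte, stats = standardize_timepoint(
            tensor.values[train_idx, t, :], tensor.values[test_idx, t, :],
            mode=cfg.standardize_mode)
        model = fit_at_timepoint(Xtr, ytr, cfg, timepoint=t,
                                 feature_names=tensor.feature_names)
        model.imputation_means = stats["imputation_means"]
        models[t] = model
        accs[t] = float(np.mean(model.predict(Xte) == yte))
    fit_accs = accs[~np.isnan(accs)]
    traj = accuracy_trajectory_from_accs(
        np.where(np.isnan(accs), 0.0, accs), cfg.accuracy_threshold)
    traj.accuracies = accs
    return {"train_idx": train_idx, "test_idx": test_idx,
            "models": models, "trajectory": traj, "config": cfg,
            "fit_accuracies": fit_accs}
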