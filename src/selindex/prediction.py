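"""Cross-year genomic prediction of selection-index values (Models 1-5).

Index values estimated in historical years are treated as a response and
carried to an unobserved target year through a mixed model

    I = mu (+ beta_Y * year) + s + g_YC + e

with ``s ~ N(0, sigma_s^2 G)`` a line effect structured by the genomic
relationship matrix, and optionally ``g_YC ~ N(0, sigma_YC^2 Z K Z')`` a
year-level environmental-covariate effect expanded to lines through a
linear or Gaussian kernel over years.  Model 1 has neither year trend nor
EC effect; Model 2 adds the linear EC kernel; Model 3 adds the year trend
to Model 1; Model 4 adds both; Model 5 is Model 4 with the Gaussian EC
kernel.  Variance components are estimated by multi-kernel EM-REML; target
lines are predicted by BLUP projection through G, and the target year's EC
row is synthesized by one of four policies (average of training years, or
a copy of a designated year's vector).

The registry of 41 sub-models enumerates every combination of model,
training-year set and EC policy explored in the study layout (4 historical
years predicting the next one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .index_core import ConditioningError
from .kernels import ECTable, KernelMatrix

__all__ = [
    "PredictionTask",
    "MixedModelFit",
    "build_submodel_registry",
    "fit_mixed_model",
    "predict_target",
    "evaluate_predictions",
    "summarize_correlations",
]

log = logging.getLogger(__name__)

ECPolicy = Literal[
    "none", "avg_training", "of_training_year", "of_previous_year", "of_two_years_ago"
]


@dataclass(frozen=True)
class PredictionTask:
    """One sub-model: model family, training years and EC policy."""

    submodel_id: int
    model: str  # "M1".."M5"
    training_years: tuple
    ec_policy: ECPolicy
    target_year: object

    def __post_init__(self) -> None:
        if self.model in ("M1", "M3"):
            if self.ec_policy != "none":
                raise ValueError(f"{self.model} admits no EC effect")
        elif self.ec_policy == "none":
            raise ValueError(f"{self.model} requires an EC policy")


@dataclass
class MixedModelFit:
    """Converged multi-kernel REML fit for one prediction task."""

    task: PredictionTask
    mu_hat: float
    beta_year: float | None
    sigma_s_sq: float
    sigma_yc_sq: float | None
    sigma_e_sq: float
    loglik: float
    n_iter: int
    converged: bool
    train_lines: list
    train_years: list
    s_blup: np.ndarray
    resid_projection: np.ndarray  # P @ (centered response), reused for prediction
    year_mean: float | None  # centering constant for the year covariate


def _year_int(y) -> int:
    return int(y)


def build_submodel_registry(
    years_available: Sequence, target_year
) -> list[PredictionTask]:
    """Enumerate the 41 sub-model tasks of the study layout.

    With four historical years the year sets are: all four, each single
    year, the last three and the last two; these are crossed with the
    model families and EC policies exactly as in the study's catalogue
    (counts 7/13/3/9/9 for Models 1-5).  With fewer historical years only
    the tasks whose training sets exist are kept.
    """
    years = sorted(years_available, key=_year_int)
    if len(years) < 2:
        raise ValueError("at least 2 historical years are required")
    all_years = tuple(years)
    singles = [(y,) for y in years]
    last3 = tuple(years[-3:]) if len(years) >= 3 else None
    last2 = tuple(years[-2:])
    multi_sets = [s for s in (all_years, last3, last2) if s is not None and len(s) >= 2]
    # drop duplicates while preserving order (e.g. 2-year history)
    seen: set = set()
    multi_sets = [s for s in multi_sets if not (s in seen or seen.add(s))]

    tasks: list[PredictionTask] = []
    sid = 0

    def add(model: str, yrs: tuple, policy: ECPolicy) -> None:
        nonlocal sid
        sid += 1
        tasks.append(
            PredictionTask(
                submodel_id=sid,
                model=model,
                training_years=yrs,
                ec_policy=policy,
                target_year=target_year,
            )
        )

    # Model 1: all multi-year sets and singles, no EC
    add("M1", all_years, "none")
    for s in singles:
        add("M1", s, "none")
    for s in multi_sets[1:]:
        add("M1", s, "none")
    # Model 2: avg over multi-year sets; per-single "of training year";
    # previous-year and two-years-ago copies over multi-year sets
    add("M2", all_years, "avg_training")
    for s in singles:
        add("M2", s, "of_training_year")
    for s in multi_sets[1:]:
        add("M2", s, "avg_training")
    for s in multi_sets:
        add("M2", s, "of_previous_year")
    for s in multi_sets:
        add("M2", s, "of_two_years_ago")
    # Model 3: year trend, multi-year sets only
    for s in multi_sets:
        add("M3", s, "none")
    # Model 4: trend + linear EC kernel
    for pol in ("avg_training", "of_previous_year", "of_two_years_ago"):
        for s in multi_sets:
            add("M4", s, pol)
    # Model 5: trend + Gaussian EC kernel; the catalogue lists the
    # two-years-ago block in the order (last3, all, last2)
    for pol in ("avg_training", "of_previous_year"):
        for s in multi_sets:
            add("M5", s, pol)
    m5_two = [s for s in (last3, all_years, last2) if s is not None]
    seen2: set = set()
    for s in m5_two:
        if s not in seen2 and len(s) >= 2:
            seen2.add(s)
            add("M5", s, "of_two_years_ago")
    return tasks


def _synth_ec_row(ec: ECTable, task: PredictionTask) -> np.ndarray:
    """Target-year EC vector per the task's policy (on the raw covariates)."""
    years = list(ec.years)
    pos = {y: i for i, y in enumerate(years)}
    train = [y for y in task.training_years if y in pos]
    missing = [y for y in task.training_years if y not in pos]
    if missing:
        raise ValueError(f"EC table lacks training years {missing}")
    tgt = _year_int(task.target_year)
    if task.ec_policy == "avg_training":
        return ec.covariates[[pos[y] for y in train]].mean(axis=0)
    if task.ec_policy == "of_training_year":
        if len(train) != 1:
            raise ValueError("of_training_year policy requires a single training year")
        return ec.covariates[pos[train[0]]].copy()
    lag = 1 if task.ec_policy == "of_previous_year" else 2
    want = tgt - lag
    match = [y for y in years if _year_int(y) == want]
    if not match:
        raise ValueError(
            f"EC policy {task.ec_policy!r} needs year {want}, absent from EC table"
        )
    return ec.covariates[pos[match[0]]].copy()


def _ec_kernel_with_target(ec: ECTable, task: PredictionTask) -> KernelMatrix:
    """Year kernel over training years plus the synthesized target row.

    Standardization (center/scale, ddof=0) is learned on the training
    years only and applied unchanged to the target row.  Degenerate
    cases (a single training year, or no varying covariate) fall back to
    an all-ones kernel: identical EC information means identical
    environments.
    """
    train = [y for y in ec.years if y in task.training_years]
    idx = [list(ec.years).index(y) for y in train]
    M = ec.covariates[idx]
    row = _synth_ec_row(ec, task)
    labels = train + [task.target_year]
    n_aug = len(labels)
    if len(train) < 2:
        log.warning("single training year: EC kernel degenerates to all ones")
        return KernelMatrix(labels=labels, K=np.ones((n_aug, n_aug)), kind="expanded")
    sd = M.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        log.warning("no varying EC columns on training years; all-ones kernel")
        return KernelMatrix(labels=labels, K=np.ones((n_aug, n_aug)), kind="expanded")
    mean = M[:, keep].mean(axis=0)
    S = np.vstack([(M[:, keep] - mean) / sd[keep], (row[keep] - mean) / sd[keep]])
    if task.model == "M5":
        sq = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=2)
        tr = sq[:-1, :-1]
        off = tr[np.triu_indices_from(tr, k=1)]
        h = float(np.median(off))
        if h <= 0:
            log.warning("zero EC distances among training years; all-ones kernel")
            return KernelMatrix(labels=labels, K=np.ones((n_aug, n_aug)), kind="expanded")
        return KernelMatrix(labels=labels, K=np.exp(-sq / h), kind="ec_gaussian")
    K = S @ S.T / int(keep.sum())
    return KernelMatrix(labels=labels, K=K, kind="ec_linear")


def _em_reml_multikernel(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    max_iter: int = 200,
    tol_param: float = 1e-6,
    tol_loglik: float = 1e-8,
) -> tuple[np.ndarray, float, np.ndarray, int, bool, np.ndarray]:
    """EM-REML for V = sum_c sigma_c^2 K_c + sigma_e^2 I.

    Classical update sigma_c^2 <- sigma_c^2 + sigma_c^4 (y'P K_c P y -
    tr(P K_c)) / rank(K_c), which never decreases the restricted
    log-likelihood.  Returns (variances incl. residual last, loglik,
    fixed-effect estimates, n_iter, converged, P y).
    """
    n = y.size
    Ks = kernels + [np.eye(n)]
    ranks = []
    for K in Ks:
        vals = np.linalg.eigvalsh(K)
        ranks.append(max(int((vals > 1e-8 * max(vals[-1], 1e-300)).sum()), 1))
    vy = float(np.var(y, ddof=1)) or 1.0
    sig = np.full(len(Ks), vy / len(Ks))
    ll_old = -np.inf
    converged = False
    Py = np.zeros(n)
    beta = np.zeros(X.shape[1])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        V = sum(s * K for s, K in zip(sig, Ks))
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError("mixed-model covariance singular") from exc
        XtVinv = X.T @ Vinv
        XtVX = XtVinv @ X
        XtVX_inv = np.linalg.inv(XtVX)
        beta = XtVX_inv @ (XtVinv @ y)
        P = Vinv - XtVinv.T @ XtVX_inv @ XtVinv
        Py = P @ y
        sign, ldV = np.linalg.slogdet(V)
        _, ldX = np.linalg.slogdet(XtVX)
        ll = -0.5 * (ldV + ldX + float(y @ Py))
        new = sig.copy()
        for c, K in enumerate(Ks):
            KPy = K @ Py
            new[c] = sig[c] + sig[c] ** 2 * (float(Py @ KPy) - float((P * K.T).sum())) / ranks[c]
            new[c] = max(new[c], 1e-12 * vy)
        delta = np.abs(new - sig).max() / max(sig.max(), 1e-12)
        sig = new
        if delta < tol_param and abs(ll - ll_old) < tol_loglik and n_iter > 1:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return sig, ll_old, beta, n_iter, converged, Py


def fit_mixed_model(
    task: PredictionTask,
    I_train: "pd.DataFrame",
    G: KernelMatrix,
    ec: ECTable | None = None,
    center_within_year: bool = True,
    max_iter: int = 200,
) -> MixedModelFit:
    """REML fit of the task's model to training-year index values.

    ``I_train`` needs columns ``line_id``, ``year`` and ``index``.  Index
    values are centered within training year by default (year-specific P
    and C put different years on different scales; centering cannot change
    the Pearson evaluation metric but stabilizes the fit).
    """
    df = I_train[I_train["year"].isin(task.training_years)].dropna(subset=["index"])
    if df.empty:
        raise ValueError("no training observations for the task's years")
    if len(df) < 30:
        log.warning("only %d training observations", len(df))
    df = df.copy()
    if center_within_year:
        df["index"] = df["index"] - df.groupby("year")["index"].transform("mean")
    lines = df["line_id"].tolist()
    y = df["index"].to_numpy(dtype=float)
    Gtt = G.align(lines)
    year_num = df["year"].map(_year_int).to_numpy(dtype=float)
    year_mean: float | None = None
    if task.model in ("M3", "M4", "M5"):
        year_mean = float(year_num.mean())
        X = np.column_stack([np.ones_like(y), year_num - year_mean])
    else:
        X = np.ones((y.size, 1))
    kernels = [Gtt]
    if task.ec_policy != "none":
        if ec is None:
            raise ValueError("task requires an EC table")
        K_year = _ec_kernel_with_target(ec, task)
        pos = {yr: i for i, yr in enumerate(K_year.labels)}
        idx = np.array([pos[yr] for yr in df["year"]])
        kernels.append(K_year.K[np.ix_(idx, idx)])
    sig, ll, beta, n_iter, converged, Py = _em_reml_multikernel(
        y, X, kernels, max_iter=max_iter
    )
    sigma_s_sq = float(sig[0])
    sigma_yc_sq = float(sig[1]) if task.ec_policy != "none" else None
    sigma_e_sq = float(sig[-1])
    s_blup = sigma_s_sq * (Gtt @ Py)
    return MixedModelFit(
        task=task,
        mu_hat=float(beta[0]),
        beta_year=float(beta[1]) if X.shape[1] > 1 else None,
        sigma_s_sq=sigma_s_sq,
        sigma_yc_sq=sigma_yc_sq,
        sigma_e_sq=sigma_e_sq,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        train_lines=lines,
        train_years=df["year"].tolist(),
        s_blup=s_blup,
        resid_projection=Py,
        year_mean=year_mean,
    )


def predict_target(
    fit: MixedModelFit,
    target_lines: Sequence,
    G: KernelMatrix,
    ec: ECTable | None = None,
) -> np.ndarray:
    """Predicted index values for target-year lines.

    The genomic part projects the training BLUPs through G in
    conditional-mean form, ``s_new = G_nt G_tt^{-1} s_hat`` (ridge of
    1e-6 * mean(diag) added if G_tt is singular); the EC part predicts the
    target year's effect from the augmented year kernel; the fixed part
    adds the intercept and, for Models 3-5, the year trend evaluated at
    the target year.
    """
    task = fit.task
    pos = {l: i for i, l in enumerate(G.labels)}
    try:
        it = [pos[l] for l in fit.train_lines]
        inew = [pos[l] for l in target_lines]
    except KeyError as exc:
        raise KeyError(f"line {exc.args[0]!r} missing from G") from None
    Gtt = G.K[np.ix_(it, it)]
    Gnt = G.K[np.ix_(inew, it)]
    try:
        s_new = Gnt @ np.linalg.solve(Gtt, fit.s_blup)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * float(np.mean(np.diag(Gtt)))
        log.info("G_tt singular; adding ridge %.3e", ridge)
        s_new = Gnt @ np.linalg.solve(Gtt + ridge * np.eye(Gtt.shape[0]), fit.s_blup)
    pred = np.full(len(target_lines), fit.mu_hat, dtype=float)
    if fit.beta_year is not None:
        pred += fit.beta_year * (_year_int(task.target_year) - fit.year_mean)
    pred += s_new
    if task.ec_policy != "none":
        if ec is None:
            raise ValueError("task requires an EC table")
        K_year = _ec_kernel_with_target(ec, task)
        posy = {yr: i for i, yr in enumerate(K_year.labels)}
        # covariance of the target year's EC effect with each training obs
        k_row = K_year.K[posy[task.target_year]]
        # EC effect prediction: sigma_yc^2 * k(target, year_i) (P y)_i summed
        cov_vec = np.array([k_row[posy[yr]] for yr in fit.train_years])
        pred += fit.sigma_yc_sq * (cov_vec @ fit.resid_projection)
    return pred


def evaluate_predictions(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted index values."""
    obs = np.asarray(observed, dtype=float)
    pre = np.asarray(predicted, dtype=float)
    ok = ~(np.isnan(obs) | np.isnan(pre))
    obs, pre = obs[ok], pre[ok]
    if obs.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(obs) == 0 or np.std(pre) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(obs, pre)[0, 1])


def summarize_correlations(
    results: Mapping[PredictionTask, float], positive_only: bool = False
) -> dict:
    """Per-training-set min/mean/max of the task correlations.

    ``positive_only`` drops r <= 0 before aggregating; groups left empty
    by the filter are marked absent (None), mirroring the reporting
    convention for unavailable cells.
    """
    groups: dict[tuple, list[float]] = {}
    for task, r in results.items():
        groups.setdefault(task.training_years, []).append(float(r))
    out = {}
    for yrs, vals in sorted(groups.items(), key=lambda kv: (len(kv[0]), kv[0])):
        key = "-".join(str(y) for y in yrs)
        use = [v for v in vals if v > 0] if positive_only else vals
        if not use:
            out[key] = {"min": None, "mean": None, "max": None, "n": 0}
        else:
            out[key] = {
                "min": float(np.min(use)),
                "mean": float(np.mean(use)),
                "max": float(np.max(use)),
                "n": len(use),
            }
    return out
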