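"""Multilevel random-effects meta-analysis by REML.

The model for the vector of observed effects ``y`` (length k) is

    y = X beta + sum_u Z_u b_u + e,   b_u ~ N(0, sigma2_u A_u),   e ~ N(0, M)

where each random component ``u`` (phylogeny, species, study, observation,
...) groups effects via a 0/1 incidence ``Z_u`` and may carry a known
correlation matrix ``A_u`` among its groups (the Brownian matrix for the
phylogeny; identity otherwise), and ``M`` is the known sampling covariance
(diagonal ``v_i``, with optional correlation ``rho_within`` between effects
sharing host individuals).  Variance components are estimated by restricted
maximum likelihood; fixed effects by GLS at the REML optimum; inference is
Wald-type with normal quantiles, and the omnibus moderator test is the
chi-square ``QM`` statistic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .data import Dataset, fisher_transform
from .phylo import CorrMatrix, brownian_correlation, prune, tip_labels

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class RandomComponent:
    """One grouping layer contributing variance ``sigma2`` to the model.

    ``groups`` is a dataset column name or an ``effect_id -> label`` mapping;
    ``corr`` is a known correlation matrix over group labels, the string
    ``"brownian"`` (resolved from the tree at fit time over the ``groups``
    labels), or None for identity.
    """

    name: str
    groups: str | Mapping[str, str]
    corr: CorrMatrix | str | None = None

    def labels_for(self, table: pd.DataFrame) -> np.ndarray:
        if isinstance(self.groups, str):
            if self.groups not in table.columns:
                raise ModelError(
                    f"component {self.name!r}: no column {self.groups!r}"
                )
            lab = table[self.groups]
        else:
            lab = table["effect_id"].map(self.groups)
        if lab.isna().any():
            raise ModelError(f"component {self.name!r}: effects without a group")
        return lab.astype(str).to_numpy()


@dataclass
class ModelSpec:
    """Fixed design plus ordered random components.

    The fixed design is intercept-only, one categorical moderator (with or
    without intercept), two moderators plus their interaction, or one
    continuous covariate.  ``rho_within`` adds sampling correlation between
    effects sharing an ``experiment_id`` (0.5 in the standard shared-host
    variant).  ``scale`` chooses the analysis scale: raw ``r`` or Fisher-z.
    """

    random: list[RandomComponent] = field(default_factory=list)
    moderator: str | None = None
    intercept: bool = True
    interaction: tuple[str, str] | None = None
    covariate: str | None = None
    center_covariate: bool = True
    rho_within: float | None = None
    scale: str = "r"


@dataclass
class FitOptions:
    starts: Sequence[float] = (1e-4, 1e-2, 1e-1)  # multipliers of Var(y)
    maxiter: int = 200
    gtol: float = 1e-8
    ci_level: float = 0.95
    use_t: bool = False  # documented switch; default Wald-z
    fix_sigma2: Mapping[str, float] | None = None


@dataclass
class FitResult:
    beta: np.ndarray
    beta_names: list[str]
    beta_cov: np.ndarray
    sigma2: dict[str, float]
    ll_reml: float
    k: int
    p_fixed: int
    qm: tuple[float, int, float] | None
    ci: np.ndarray  # (p, 2)
    converged: bool
    diagnostics: dict
    scale: str
    y: np.ndarray
    v: np.ndarray
    fitted: np.ndarray
    tested: list[int]
    level_k: dict[str, int] | None = None
    inputs_hash: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "scale": self.scale,
            "coefficients": [
                {
                    "name": nm,
                    "estimate": float(b),
                    "se": float(s),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p": float(p),
                }
                for nm, b, s, (lo, hi), p in zip(
                    self.beta_names, self.beta, self.se, self.ci, self.p_values
                )
            ],
            "sigma2": {k: float(x) for k, x in self.sigma2.items()},
            "ll_reml": float(self.ll_reml),
            "qm": None
            if self.qm is None
            else {"statistic": self.qm[0], "df": self.qm[1], "p": self.qm[2]},
            "converged": self.converged,
            "level_k": self.level_k,
            "inputs_hash": self.inputs_hash,
        }


# ---------------------------------------------------------------------------
# covariance assembly


def build_sampling_cov(
    v: np.ndarray,
    experiment_ids: Sequence[str] | None = None,
    rho_within: float | None = None,
) -> np.ndarray:
    """Known sampling covariance M: diag(v), plus ``rho * sqrt(v_i v_j)``
    between effects sharing an experiment (same host individuals)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ModelError("all sampling variances must be positive")
    M = np.diag(v)
    if rho_within is None:
        return M
    if not (0.0 <= rho_within < 1.0):
        raise ModelError("rho_within must be in [0, 1)")
    if experiment_ids is None:
        raise ModelError("rho_within given without experiment identifiers")
    ids = np.asarray(experiment_ids)
    s = np.sqrt(v)
    same = ids[:, None] == ids[None, :]
    M = np.where(same, rho_within * np.outer(s, s), 0.0)
    np.fill_diagonal(M, v)
    return M


def _incidence_cov(labels: np.ndarray, corr: CorrMatrix | None) -> np.ndarray:
    """G = Z A Z' for a one-group-per-effect incidence Z."""
    if corr is None:
        return (labels[:, None] == labels[None, :]).astype(float)
    missing = set(labels) - set(corr.labels)
    if missing:
        raise ModelError(f"correlation matrix lacks groups: {sorted(missing)}")
    pos = {lab: i for i, lab in enumerate(corr.labels)}
    idx = np.array([pos[lab] for lab in labels])
    return corr.matrix[np.ix_(idx, idx)]


def build_marginal_cov(
    sigma2: Sequence[float], G_list: Sequence[np.ndarray], M: np.ndarray
) -> np.ndarray:
    """V = M + sum_u sigma2_u Z_u A_u Z_u'."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ModelError("variance components must be non-negative")
    V = M.copy()
    for s2, G in zip(sigma2, G_list):
        if s2 > 0:
            V += s2 * G
    return V


def _chol(V: np.ndarray):
    """Cholesky with a single 1e-10 diagonal jitter retry."""
    try:
        return cho_factor(V, lower=True)
    except LinAlgError:
        logger.warning("V not positive definite; retrying with 1e-10 jitter")
        return cho_factor(V + 1e-10 * np.eye(V.shape[0]), lower=True)


def _reml_pieces(V, y, X):
    cf = _chol(V)
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    cfX = cho_factor(XtViX, lower=True)
    beta = cho_solve(cfX, X.T @ Viy)
    Py = Viy - ViX @ beta
    logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    logdet_X = 2.0 * np.sum(np.log(np.diag(cfX[0])))
    quad = float(y @ Py)
    return cf, cfX, ViX, beta, Py, logdet_V, logdet_X, quad


def reml_loglik(
    sigma2: Sequence[float],
    y: np.ndarray,
    X: np.ndarray,
    G_list: Sequence[np.ndarray],
    M: np.ndarray,
) -> float:
    """Restricted log-likelihood at the given variance components.

    ``-1/2 [(k - p) log 2pi + log|V| + log|X'V^-1 X| + (y - X beta)'V^-1 (y - X beta)]``
    with ``beta`` the GLS estimate; all solves via Cholesky.
    """
    V = build_marginal_cov(sigma2, G_list, M)
    k, p = X.shape
    _, _, _, _, _, logdet_V, logdet_X, quad = _reml_pieces(V, y, X)
    return -0.5 * ((k - p) * LOG_2PI + logdet_V + logdet_X + quad)


def _nll_and_grad(sigma2, y, X, G_list, M):
    """Negative REML log-likelihood and its gradient w.r.t. sigma2.

    d ll / d sigma2_u = -1/2 [tr(P G_u) - (Py)' G_u (Py)],
    P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1.
    """
    V = build_marginal_cov(sigma2, G_list, M)
    k, p = X.shape
    cf, cfX, ViX, beta, Py, logdet_V, logdet_X, quad = _reml_pieces(V, y, X)
    ll = -0.5 * ((k - p) * LOG_2PI + logdet_V + logdet_X + quad)
    Vi = cho_solve(cf, np.eye(k))
    grad = np.empty(len(G_list))
    for u, G in enumerate(G_list):
        tr_ViG = float(np.sum(Vi * G))
        W = ViX.T @ G @ ViX  # (p, p)
        tr_corr = float(np.sum(cho_solve(cfX, W) * np.eye(p)))
        tr_PG = tr_ViG - tr_corr
        grad[u] = -0.5 * (tr_PG - float(Py @ G @ Py))
    return -ll, -grad


def _optimize_reml(y, X, G_list, M, opts: FitOptions, free_idx, fixed_vals):
    """Maximize REML over log sigma2 of the free components."""
    vy = max(float(np.var(y)), 1e-8)

    def pack(theta):
        s2 = fixed_vals.copy()
        s2[free_idx] = np.exp(theta)
        return s2

    def fun(theta):
        nll, grad = _nll_and_grad(pack(theta), y, X, G_list, M)
        return nll, grad[free_idx] * np.exp(theta)

    lb, ub = np.log(1e-12 * vy), np.log(1e4 * vy)
    best = None
    n_evals = 0
    for mult in opts.starts:
        theta0 = np.full(len(free_idx), np.log(mult * vy))
        res = optimize.minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(lb, ub)] * len(free_idx),
            options={"maxiter": opts.maxiter, "gtol": opts.gtol},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    s2_hat = pack(best.x)
    return s2_hat, -best.fun, {
        "optimizer": "L-BFGS-B(log sigma2)",
        "n_starts": len(opts.starts),
        "n_evals": n_evals,
        "success": bool(best.success),
        "message": str(best.message),
    }


def _fit_reml_core(y, X, G_list, M, names, opts: FitOptions):
    """REML estimation with multistart and a profiled zero-boundary pass."""
    n_comp = len(G_list)
    fixed_vals = np.zeros(n_comp)
    fix = dict(opts.fix_sigma2 or {})
    free_idx = np.array(
        [i for i, nm in enumerate(names) if nm not in fix], dtype=int
    )
    for i, nm in enumerate(names):
        if nm in fix:
            fixed_vals[i] = float(fix[nm])

    if n_comp == 0 or len(free_idx) == 0:
        s2 = fixed_vals
        ll = reml_loglik(s2, y, X, G_list, M)
        return s2, ll, {"optimizer": "none (no free components)", "success": True}

    s2_hat, ll_hat, diag = _optimize_reml(y, X, G_list, M, opts, free_idx, fixed_vals)

    # Boundary handling: components that ran to the floor are compared, with
    # the others re-profiled, against an exact-zero fit.
    vy = max(float(np.var(y)), 1e-8)
    near_zero = [i for i in free_idx if s2_hat[i] < 1e-7 * vy]
    if near_zero:
        sub_free = np.array([i for i in free_idx if i not in near_zero], dtype=int)
        fv = fixed_vals.copy()
        fv[near_zero] = 0.0
        if len(sub_free):
            s2_zero, ll_zero, _ = _optimize_reml(
                y, X, G_list, M, opts, sub_free, fv
            )
        else:
            s2_zero = fv
            ll_zero = reml_loglik(s2_zero, y, X, G_list, M)
        if ll_zero >= ll_hat - 1e-8:
            s2_hat, ll_hat = s2_zero, ll_zero
            diag["boundary_components"] = [names[i] for i in near_zero]
    return s2_hat, ll_hat, diag


# ---------------------------------------------------------------------------
# design matrices


def _dummies(col: pd.Series) -> pd.DataFrame:
    levels = sorted(col.dropna().unique())
    out = pd.DataFrame(
        {lev: (col == lev).astype(float) for lev in levels}, index=col.index
    )
    return out


def build_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], list[int]]:
    """Fixed-effect design matrix, coefficient names, and the indices tested
    by the omnibus QM (non-intercept terms; interaction terms only when an
    interaction is specified)."""
    k = len(table)
    if spec.interaction is not None:
        m1, m2 = spec.interaction
        d1, d2 = _dummies(table[m1]), _dummies(table[m2])
        if d1.shape[1] < 2 or d2.shape[1] < 2:
            raise ModelError("interaction needs >= 2 levels per moderator")
        cols = [np.ones(k)]
        names = ["intercept"]
        for lev in d1.columns[1:]:
            cols.append(d1[lev].to_numpy())
            names.append(f"{m1}[{lev}]")
        for lev in d2.columns[1:]:
            cols.append(d2[lev].to_numpy())
            names.append(f"{m2}[{lev}]")
        tested = []
        for l1 in d1.columns[1:]:
            for l2 in d2.columns[1:]:
                tested.append(len(cols))
                cols.append(d1[l1].to_numpy() * d2[l2].to_numpy())
                names.append(f"{m1}[{l1}]:{m2}[{l2}]")
        X = np.column_stack(cols)
    elif spec.moderator is not None:
        d = _dummies(table[spec.moderator])
        if d.shape[1] < 2:
            raise ModelError(
                f"moderator {spec.moderator!r} has fewer than two levels"
            )
        if spec.intercept:
            X = np.column_stack([np.ones(k)] + [d[l].to_numpy() for l in d.columns[1:]])
            names = ["intercept"] + [
                f"{spec.moderator}[{l}]" for l in d.columns[1:]
            ]
            tested = list(range(1, X.shape[1]))
        else:
            X = d.to_numpy(dtype=float)
            names = [f"{spec.moderator}[{l}]" for l in d.columns]
            tested = []
    elif spec.covariate is not None:
        x = table[spec.covariate].to_numpy(dtype=float)
        if spec.center_covariate:
            x = x - x.mean()
        X = np.column_stack([np.ones(k), x])
        names = ["intercept", spec.covariate]
        tested = [1]
    else:
        X = np.ones((k, 1))
        names = ["intercept"]
        tested = []
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed design is rank deficient after category drops")
    return X, names, tested


def _analysis_scale(table: pd.DataFrame, scale: str):
    r = table["r"].to_numpy(dtype=float)
    n = table["n"].to_numpy(dtype=float)
    if np.any(np.isnan(r)):
        raise ModelError("dataset has missing r; run impute_directionless first")
    if scale == "r":
        v = table["v"].to_numpy(dtype=float)
        if np.any(np.isnan(v)) or np.any(v <= 0):
            raise ModelError("dataset has missing or non-positive v")
        return r, v
    if scale == "z":
        if np.any(np.abs(r) >= 1):
            raise ModelError("|r| = 1 cannot be Fisher-transformed")
        return np.arctanh(r), 1.0 / (n - 3.0)
    raise ModelError(f"unknown analysis scale {scale!r}")


def fit_mlma(
    dataset: Dataset,
    spec: ModelSpec,
    tree=None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the multilevel random-effects meta-analytic model by REML.

    Records with a missing value of any moderator in the fixed design are
    dropped listwise.  A component whose ``corr`` is ``"brownian"`` gets the
    Brownian correlation matrix of ``tree`` pruned to the dataset's species.
    Deterministic given inputs and options.
    """
    opts = options or FitOptions()
    table = dataset.table
    used_cols = [c for c in (spec.moderator, spec.covariate) if c]
    if spec.interaction:
        used_cols += list(spec.interaction)
    if used_cols:
        keep = table[used_cols].notna().all(axis=1)
        table = table[keep].reset_index(drop=True)
    if len(table) == 0:
        raise ModelError("no records left after listwise deletion")

    y, v = _analysis_scale(table, spec.scale)
    X, names, tested = build_design(table, spec)
    k, p = X.shape
    if k <= p:
        raise ModelError("more fixed coefficients than effects")

    G_list, comp_names = [], []
    for comp in spec.random:
        labels = comp.labels_for(table)
        corr = comp.corr
        if isinstance(corr, str):
            if corr != "brownian":
                raise ModelError(f"unknown corr spec {corr!r}")
            if tree is None:
                raise ModelError(f"component {comp.name!r} needs a tree")
            species = sorted(set(labels))
            tips = set(tip_labels(tree))
            missing = set(species) - tips
            if missing:
                raise ModelError(f"tree lacks species: {sorted(missing)}")
            sub = prune(tree, species) if len(tips) > len(species) else tree
            corr = brownian_correlation(sub)
        G_list.append(_incidence_cov(labels, corr))
        comp_names.append(comp.name)

    M = build_sampling_cov(
        v,
        table["experiment_id"].to_numpy() if spec.rho_within is not None else None,
        spec.rho_within,
    )

    s2_hat, ll, diag = _fit_reml_core(y, X, G_list, M, comp_names, opts)

    V = build_marginal_cov(s2_hat, G_list, M)
    _, cfX, _, beta, _, _, _, _ = _reml_pieces(V, y, X)
    beta_cov = cho_solve(cfX, np.eye(p))
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    se = np.sqrt(np.diag(beta_cov))
    if opts.use_t:
        q = stats.t.ppf(0.5 + opts.ci_level / 2.0, df=k - p)
    else:
        q = stats.norm.ppf(0.5 + opts.ci_level / 2.0)
    ci = np.column_stack([beta - q * se, beta + q * se])

    qm = None
    if tested:
        qm = _qm_from(beta, beta_cov, tested)

    level_k = None
    if spec.moderator is not None and spec.interaction is None:
        level_k = table[spec.moderator].value_counts().astype(int).to_dict()

    h = hashlib.sha256()
    for arr in (y, v, X):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update(repr(sorted(zip(comp_names, map(float, s2_hat)))).encode())

    return FitResult(
        beta=beta,
        beta_names=names,
        beta_cov=beta_cov,
        sigma2={nm: float(s2) for nm, s2 in zip(comp_names, s2_hat)},
        ll_reml=float(ll),
        k=k,
        p_fixed=p,
        qm=qm,
        ci=ci,
        converged=bool(diag.get("success", True)),
        diagnostics=diag,
        scale=spec.scale,
        y=y,
        v=v,
        fitted=X @ beta,
        tested=tested,
        level_k=level_k,
        inputs_hash=h.hexdigest()[:16],
    )


def _qm_from(beta, beta_cov, tested):
    idx = np.asarray(tested, dtype=int)
    b = beta[idx]
    C = beta_cov[np.ix_(idx, idx)]
    try:
        cf = cho_factor(C, lower=True)
    except LinAlgError as exc:
        raise ModelError("singular covariance of tested coefficients") from exc
    stat = float(b @ cho_solve(cf, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


def qm_test(fit: FitResult, tested: Sequence[int] | None = None):
    """Wald chi-square omnibus test of a coefficient subset.

    Defaults to all non-intercept coefficients (or the interaction terms for
    an interaction fit).  Returns ``(statistic, df, p)``.
    """
    if tested is None:
        tested = fit.tested or [
            i for i, nm in enumerate(fit.beta_names) if nm != "intercept"
        ]
    if not tested:
        raise ModelError("no coefficients to test")
    return _qm_from(fit.beta, fit.beta_cov, list(tested))
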