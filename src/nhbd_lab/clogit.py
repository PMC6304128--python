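"""Conditional logistic regression for matched use-availability strata.

Each stratum pairs one used (established) territory with its matched
available territories.  Conditioning on "one case per stratum" removes
the stratum intercepts, leaving the likelihood

    L(beta) = prod_s  exp(x_case . beta) / sum_{j in s} exp(x_j . beta),

a per-stratum softmax.  The maximizer is found by Newton-Raphson on the
exact gradient and observed information, with step-halving; Wald
standard errors come from the inverse information at the optimum.
Covariates constant within every stratum cancel from the likelihood and
are rejected by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

Z_95 = 1.96  # normal quantile used for the reported 95% Wald intervals


def _group_structure(groups: np.ndarray):
    """Sort order, segment starts and case bookkeeping for the strata."""
    order = np.argsort(groups, kind="stable")
    g = np.asarray(groups)[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    return order, starts


def _clogit_ll_score_info(beta, X, case_idx, starts, want_derivs=True):
    """Log-likelihood (and score / information) of the sorted design."""
    eta = X @ beta
    gmax = np.maximum.reduceat(eta, starts)
    sizes = np.diff(np.r_[starts, len(eta)])
    e = np.exp(eta - np.repeat(gmax, sizes))
    denom = np.add.reduceat(e, starts)
    ll = float(eta[case_idx].sum() - (np.log(denom) + gmax).sum())
    if not want_derivs:
        return ll, None, None
    p = e / np.repeat(denom, sizes)
    Xp = X * p[:, None]
    mu = np.add.reduceat(Xp, starts)  # (S, k) per-stratum means
    score = X[case_idx].sum(axis=0) - mu.sum(axis=0)
    info = Xp.T @ X - mu.T @ mu
    return ll, score, info


def conditional_loglik(beta, X, y, groups) -> float:
    """Evaluate the matched conditional log-likelihood at ``beta``."""
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    y = np.asarray(y)
    order, starts = _group_structure(np.asarray(groups))
    Xs, ys = X[order], y[order]
    case_idx = np.flatnonzero(ys == 1)
    ll, _, _ = _clogit_ll_score_info(beta, Xs, case_idx, starts, want_derivs=False)
    return ll


class ConditionalLogisticRegression(BaseEstimator):
    """Matched-set conditional logit, sklearn-style.

    Parameters
    ----------
    max_iter, tol
        Newton-Raphson stops when the largest score component falls
        below ``tol`` (default 1e-8) or after ``max_iter`` iterations.
    drop_constant
        ``'raise'`` (default) rejects covariates constant within every
        stratum by name; ``'drop'`` removes them with a log message.
    separation_threshold
        A non-converged fit whose largest \\|coefficient\\| exceeds this is
        flagged as (quasi-)complete separation and reports no intervals.
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-8,
        drop_constant: str = "raise",
        separation_threshold: float = 15.0,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.drop_constant = drop_constant
        self.separation_threshold = separation_threshold

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (stratum ids) are required")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
            names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y)
        groups = np.asarray(groups)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-D array")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must be binary (0 available / 1 established)")
        if len(X) != len(y) or len(y) != len(groups):
            raise ValueError("X, y and groups must have equal length")

        order, starts = _group_structure(groups)
        Xs, ys = X[order], y[order]
        sizes = np.diff(np.r_[starts, len(ys)])
        cases_per = np.add.reduceat(ys == 1, starts)
        if np.any(cases_per != 1) or np.any(sizes < 2):
            raise ValueError(
                "every stratum needs exactly one case and at least one control"
            )

        # covariates constant within every stratum cancel from the likelihood
        seg_min = np.minimum.reduceat(Xs, starts, axis=0)
        seg_max = np.maximum.reduceat(Xs, starts, axis=0)
        constant = np.all(seg_min == seg_max, axis=0)
        if constant.any():
            bad = [names[j] for j in np.flatnonzero(constant)]
            if self.drop_constant == "raise":
                raise ValueError(
                    f"covariates constant within every stratum: {bad} "
                    "(they cancel from the conditional likelihood)"
                )
            logger.info("dropping stratum-constant covariates: %s", bad)
            keep = ~constant
            Xs = Xs[:, keep]
            names = [n for n, k in zip(names, keep) if k]
        if Xs.shape[1] == 0:
            raise ValueError("no informative covariates remain")

        # linearly dependent covariates (after within-stratum centering,
        # which is what the conditional likelihood sees) leave the
        # information singular: reject or drop them like aliased terms
        sizes2 = np.diff(np.r_[starts, len(ys)])
        means = np.add.reduceat(Xs, starts, axis=0) / sizes2[:, None]
        Xc = Xs - np.repeat(means, sizes2, axis=0)
        from scipy import linalg as sla

        R, piv = sla.qr(Xc, mode="r", pivoting=True)[0:2] if Xc.shape[1] > 1 else (None, None)
        if R is not None:
            diag = np.abs(np.diag(R))
            rank = int((diag > max(diag[0], 1.0) * 1e-10).sum()) if diag[0] > 0 else 0
            if rank < Xs.shape[1]:
                bad = [names[j] for j in sorted(piv[rank:])]
                if self.drop_constant == "raise":
                    raise ValueError(f"linearly dependent covariates: {bad}")
                logger.info("dropping aliased covariates: %s", bad)
                keep = np.ones(Xs.shape[1], bool)
                keep[piv[rank:]] = False
                Xs = Xs[:, keep]
                names = [n for n, k_ in zip(names, keep) if k_]

        case_idx = np.flatnonzero(ys == 1)
        k = Xs.shape[1]
        beta = np.zeros(k)
        ll, score, info = _clogit_ll_score_info(beta, Xs, case_idx, starts)
        ll0 = ll
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            try:
                delta = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            # step-halving keeps the log-likelihood monotone
            step = 1.0
            for _ in range(40):
                trial = beta + step * delta
                ll_new, score_new, info_new = _clogit_ll_score_info(
                    trial, Xs, case_idx, starts
                )
                if ll_new >= ll - 1e-12:
                    break
                step /= 2
            else:
                break
            beta, ll, score, info = trial, ll_new, score_new, info_new
        else:
            n_iter = self.max_iter
        if not converged and np.max(np.abs(score)) < self.tol:
            converged = True

        # a coefficient running off to +-inf flattens the likelihood, so the
        # score can fall under tol at a huge |beta|: treat as separation
        separation = bool(np.max(np.abs(beta)) > self.separation_threshold)
        if separation:
            converged = False

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = k
        self.coef_ = beta
        self.llf_ = ll
        self.llnull_ = ll0
        self.converged_ = converged
        self.separation_ = bool(separation)
        self.n_iter_ = n_iter
        self.n_strata_ = len(starts)
        self.nobs_ = len(ys)
        self._starts = starts
        if converged:
            cov = np.linalg.inv(info)
            self.cov_params_ = cov
            self.se_ = np.sqrt(np.diag(cov))
            self.zvalues_ = beta / self.se_
            self.pvalues_ = 2 * stats.norm.sf(np.abs(self.zvalues_))
            self.conf_int_ = np.column_stack(
                [beta - Z_95 * self.se_, beta + Z_95 * self.se_]
            )
        else:
            # a non-converged (possibly separated) fit reports no inference
            self.cov_params_ = None
            self.se_ = np.full(k, np.nan)
            self.zvalues_ = np.full(k, np.nan)
            self.pvalues_ = np.full(k, np.nan)
            self.conf_int_ = None
        return self

    # -- introspection ----------------------------------------------------

    def loglik(self, beta, X, y, groups) -> float:
        """Conditional log-likelihood of arbitrary data at ``beta``."""
        return conditional_loglik(beta, X, y, groups)

    def predict_proba(self, X, groups):
        """Within-stratum softmax probabilities of being the case."""
        X = np.asarray(X, float)
        groups = np.asarray(groups)
        order, starts = _group_structure(groups)
        eta = X[order] @ self.coef_
        sizes = np.diff(np.r_[starts, len(eta)])
        gmax = np.maximum.reduceat(eta, starts)
        e = np.exp(eta - np.repeat(gmax, sizes))
        p = e / np.repeat(np.add.reduceat(e, starts), sizes)
        out = np.empty_like(p)
        out[order] = p
        return out


@dataclass(frozen=True)
class CLogitFit:
    """Tidy summary of one conditional-logit fit."""

    table: pd.DataFrame  # variable, beta, se, z, p, ci_lo, ci_hi
    llf: float
    llnull: float
    converged: bool
    separation: bool
    n_strata: int

    def coef(self, variable: str) -> float:
        return float(self.table.set_index("variable").loc[variable, "beta"])


def fit_conditional_logit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    outcome_col: str = "outcome",
    stratum_col: str = "stratum",
    max_iter: int = 100,
    tol: float = 1e-8,
    drop_constant: str = "raise",
) -> CLogitFit:
    """Fit the matched conditional logit on a long-format table."""
    est = ConditionalLogisticRegression(
        max_iter=max_iter, tol=tol, drop_constant=drop_constant
    )
    est.fit(data[list(covariates)], data[outcome_col].to_numpy(), data[stratum_col].to_numpy())
    ci = est.conf_int_ if est.conf_int_ is not None else np.full((est.n_features_in_, 2), np.nan)
    table = pd.DataFrame(
        {
            "variable": est.feature_names_in_,
            "beta": est.coef_,
            "se": est.se_,
            "z": est.zvalues_,
            "p": est.pvalues_,
            "ci_lo": ci[:, 0],
            "ci_hi": ci[:, 1],
        }
    )
    return CLogitFit(
        table, est.llf_, est.llnull_, est.converged_, est.separation_, est.n_strata_
    )


def simulate_strata(
    n_strata: int,
    beta: Mapping[str, float],
    rng: np.random.Generator,
    n_controls: int = 11,
    nhbd_prevalence: float = 0.3,
) -> pd.DataFrame:
    """Simulate matched strata directly from the conditional-logit model.

    Each stratum holds ``1 + n_controls`` candidate records; the NHBD
    covariate is Bernoulli(``nhbd_prevalence``), any other named
    covariate is standard normal, and the case (outcome 1) is drawn with
    the softmax probability ``exp(x.beta) / sum exp(x.beta)`` — the exact
    data-generating process the regression assumes.  Used for type-I
    calibration and parameter-recovery simulations.
    """
    names = list(beta)
    b = np.asarray([beta[n] for n in names], float)
    size = 1 + n_controls
    rows = []
    for s in range(n_strata):
        X = np.empty((size, len(names)))
        for j, name in enumerate(names):
            if name == "nhbd":
                X[:, j] = rng.random(size) < nhbd_prevalence
            else:
                X[:, j] = rng.standard_normal(size)
        eta = X @ b
        p = np.exp(eta - eta.max())
        case = rng.choice(size, p=p / p.sum())
        for i in range(size):
            rows.append(
                {"stratum": s, "outcome": int(i == case),
                 **{n: X[i, j] for j, n in enumerate(names)}}
            )
    return pd.DataFrame(rows)


#: Keep-priority of the correlation screen, highest first: the habitat
#: variables retained in the reference model specification.
DEFAULT_KEEP_PRIORITY: tuple[str, ...] = (
    "nhbd",
    "natal_distance",
    "pct_forest",
    "pct_water",
    "pct_mountain",
    "main_road_density",
    "bear_index",
    "slope",
    "human_accessibility",
    "moose_harvest_density",
    "human_density",
    "wolf_pair_density",
)


def correlation_screen(
    table: pd.DataFrame,
    threshold: float = 0.6,
    priority: Sequence[str] | None = None,
) -> list[str]:
    """Iteratively drop one member of each over-correlated variable pair.

    While any pair has \\|Pearson r\\| > ``threshold``, the pair member
    ranked lower on the keep-priority list is removed (variables not on
    the list rank below all listed ones, in column order).  Returns the
    retained column names in their original order.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if len(table) < 2:
        raise ValueError("need at least two rows to estimate correlations")
    priority = list(priority if priority is not None else DEFAULT_KEEP_PRIORITY)
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]

    def rank(c: str) -> int:
        return priority.index(c) if c in priority else len(priority) + cols.index(c)

    keep = list(cols)
    while True:
        corr = table[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(corr.argmax(), corr.shape)
        if corr[i, j] <= threshold:
            break
        drop = keep[i] if rank(keep[i]) > rank(keep[j]) else keep[j]
        logger.info("correlation screen: dropping %s (|r|=%.3f)", drop, corr[i, j])
        keep.remove(drop)
    return keep


def fit_model_suite(
    data: pd.DataFrame,
    covariates: Sequence[str],
    outcome_col: str = "outcome",
    stratum_col: str = "stratum",
    sex_col: str = "sex",
    category_col: str = "distance_category",
    nhbd_col: str = "nhbd",
    wolf_density_col: str = "wolf_pair_density",
    interactions: Sequence[str] = ("nhbd:wolf_pair_density", "nhbd:sex"),
    alpha: float = 0.05,
    include_combined_sexes: bool = True,
) -> pd.DataFrame:
    """Per-sex / per-distance-category fits plus one pooled interaction fit.

    Separate models are fitted for each sex x distance-category cell (the
    per-panel presentation) and — since the distance-category hypothesis
    is defined irrespective of sex, which is stratum-constant and cancels
    anyway — for each distance category over both sexes (groups
    ``all/<category>``; disable with ``include_combined_sexes=False``).
    One pooled model over all strata adds the NHBD x wolf-density and
    NHBD x sex interaction terms (sex coded F=1, M=0).  Returns a tidy
    coefficient table with a ``significant`` flag at ``alpha``.  Cells
    with fewer than two strata, or where the fit cannot proceed, are
    skipped with a logged reason.
    """
    covariates = list(covariates)
    rows = []

    def emit(group: str, fit: CLogitFit | None, n_strata: int, note: str = ""):
        if fit is None:
            rows.append(
                {"group": group, "variable": None, "beta": np.nan, "se": np.nan,
                 "z": np.nan, "p": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                 "converged": False, "significant": False, "n_strata": n_strata,
                 "note": note}
            )
            return
        for _, r in fit.table.iterrows():
            rows.append(
                {"group": group, "variable": r["variable"], "beta": r["beta"],
                 "se": r["se"], "z": r["z"], "p": r["p"], "ci_lo": r["ci_lo"],
                 "ci_hi": r["ci_hi"], "converged": fit.converged,
                 "significant": bool(fit.converged and r["p"] < alpha),
                 "n_strata": fit.n_strata, "note": note}
            )

    cells: list[tuple[str, pd.DataFrame]] = [
        (f"{sex}/{cat}", sub)
        for (sex, cat), sub in data.groupby(
            [sex_col, category_col], observed=True, sort=True
        )
    ]
    if include_combined_sexes:
        cells += [
            (f"all/{cat}", sub)
            for cat, sub in data.groupby(category_col, observed=True, sort=True)
        ]
    for label, sub in cells:
        n_strata = sub[stratum_col].nunique()
        if n_strata < 2:
            logger.info("skipping %s: only %d strata", label, n_strata)
            emit(label, None, n_strata, "too few strata")
            continue
        try:
            fit = fit_conditional_logit(
                sub, covariates, outcome_col, stratum_col, drop_constant="drop"
            )
        except ValueError as err:
            logger.info("skipping %s: %s", label, err)
            emit(label, None, n_strata, str(err))
            continue
        emit(label, fit, n_strata)

    pooled = data.copy()
    pooled_covs = list(covariates)
    for term in interactions:
        left, right = term.split(":")
        if right == "sex":
            other = (pooled[sex_col] == "F").astype(float)
        else:
            other = pooled[right].astype(float)
        name = f"{left}_x_{right}"
        pooled[name] = pooled[nhbd_col if left == "nhbd" else left].astype(float) * other
        pooled_covs.append(name)
    try:
        fit = fit_conditional_logit(
            pooled, pooled_covs, outcome_col, stratum_col, drop_constant="drop"
        )
        emit("pooled", fit, pooled[stratum_col].nunique())
    except ValueError as err:
        logger.info("skipping pooled fit: %s", err)
        emit("pooled", None, pooled[stratum_col].nunique(), str(err))
    return pd.DataFrame(rows)
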