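"""Group-based trajectory analysis (GBTA).

GBTA assumes the cohort is composed of a small number of latent groups, each
following its own polynomial trajectory of age acceleration over the five
post-injury time bins.  For participant ``i`` with observations ``y_ij`` at
(centered) time bins ``t_ij`` the model is a finite mixture

    P(y_i) = sum_g  pi_g  *  prod_j  f( y_ij ; x(t_ij)' beta_g , sigma )

with ``x(t)`` the polynomial basis (intercept-only, linear or quadratic),
``sigma`` a residual SD shared across groups, and ``f`` a censored-normal
density (default censoring bounds are infinite, i.e. a plain normal).  The
mixture is maximised by EM from multiple starts; models of varying group
number and polynomial order are compared by BIC (``loglik - 0.5*k*log(N)``,
larger = better).  A fitted model then passes posterior classification QC
only if, for every group, (1) the average posterior probability of assignment
(APP) is at least 0.7, (2) the odds of correct classification (OCC) exceed 5,
and (3) the estimated group probability approximately equals the observed
assignment share.

The time regressor is the time-bin index 1-5 centered at 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from csfaging.stats import contingency_test, oneway_anova

__all__ = [
    "GbtaSpec",
    "GbtaFit",
    "QCReport",
    "fit_gbta",
    "bic",
    "model_search",
    "occ",
    "posterior_qc",
    "profile_groups",
]

TIME_CENTER = 3.0
_PI_FLOOR = 1e-10
_SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GbtaSpec:
    """Specification of one candidate trajectory model.

    ``orders`` is either a single polynomial order applied to every group or
    a per-group tuple; orders are 0 (intercept-only), 1 (linear) or
    2 (quadratic).  ``censor_low``/``censor_high`` are the censored-normal
    bounds (default infinite: plain normal).
    """

    n_groups: int
    orders: int | tuple[int, ...] = 0
    censor_low: float = -math.inf
    censor_high: float = math.inf
    n_starts: int = 5
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    shared_sigma: bool = True

    def order_tuple(self) -> tuple[int, ...]:
        o = self.orders
        if isinstance(o, int):
            o = (o,) * self.n_groups
        if len(o) != self.n_groups:
            raise ValueError("orders tuple length must equal n_groups")
        if any(d not in (0, 1, 2) for d in o):
            raise ValueError("orders must be 0 (flat), 1 (linear) or 2 (quadratic)")
        return tuple(o)

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not self.censor_low < self.censor_high:
            raise ValueError("censor_low must be < censor_high")
        self.order_tuple()

    @property
    def n_params(self) -> int:
        """Free parameters: trajectory coefficients + (G-1) weights + variance(s)."""
        n_sigma = 1 if self.shared_sigma else self.n_groups
        return sum(d + 1 for d in self.order_tuple()) + (self.n_groups - 1) + n_sigma


@dataclass
class GbtaFit:
    """A fitted trajectory mixture, groups canonically ordered by intercept."""

    spec: GbtaSpec
    pi: np.ndarray
    coefficients: list[np.ndarray]
    sigma: np.ndarray  # per group (identical entries when shared)
    loglik: float
    n_params: int
    n_participants: int
    n_obs: int
    posteriors: pd.DataFrame  # participants x groups
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def bic(self) -> float:
        """Participant-count BIC (larger is better)."""
        return bic(self, self.n_participants)

    @property
    def bic_obs(self) -> float:
        """Observation-count BIC, also printed by the classic macro."""
        return bic(self, self.n_obs)

    @property
    def assignment(self) -> pd.Series:
        """Modal group per participant (1-based labels)."""
        idx = self.posteriors.to_numpy().argmax(axis=1)
        return pd.Series(idx + 1, index=self.posteriors.index, name="group")

    def group_mean(self, group: int, time_bin: float | np.ndarray) -> np.ndarray:
        """Fitted trajectory mean of 1-based ``group`` at raw time bin(s)."""
        t = np.asarray(time_bin, dtype=float) - TIME_CENTER
        return np.polynomial.polynomial.polyval(t, self.coefficients[group - 1])


def _prepare_panel(panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    required = {"participant_id", "time_bin", "value"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel needs columns {sorted(required)}")
    clean = panel.dropna(subset=["value", "time_bin"])
    pids = list(pd.unique(clean["participant_id"]))
    pidx = clean["participant_id"].map({p: i for i, p in enumerate(pids)}).to_numpy()
    t = clean["time_bin"].to_numpy(dtype=float) - TIME_CENTER
    y = clean["value"].to_numpy(dtype=float)
    return y, t, pidx, pids


def _design(t: np.ndarray, order: int) -> np.ndarray:
    return np.vander(t, order + 1, increasing=True)


def _obs_loglik(y: np.ndarray, mu: np.ndarray, sigma: float, lo: float, hi: float) -> np.ndarray:
    """Per-observation censored-normal log density."""
    ll = stats.norm.logpdf(y, mu, sigma)
    if np.isfinite(lo):
        at_lo = y <= lo
        if at_lo.any():
            ll = np.where(at_lo, stats.norm.logcdf(lo, mu, sigma), ll)
    if np.isfinite(hi):
        at_hi = y >= hi
        if at_hi.any():
            ll = np.where(at_hi, stats.norm.logsf(hi, mu, sigma), ll)
    return ll


def _mixture_eval(
    y, t, pidx, n_pid, pi, coefficients, sigma, lo, hi
) -> tuple[float, np.ndarray]:
    """Log-likelihood and participant posteriors for given parameters."""
    G = len(pi)
    logw = np.zeros((n_pid, G))
    for g in range(G):
        mu = _design(t, len(coefficients[g]) - 1) @ coefficients[g]
        ll = _obs_loglik(y, mu, sigma[g], lo, hi)
        logw[:, g] = np.bincount(pidx, weights=ll, minlength=n_pid)
    logw += np.log(np.maximum(pi, _PI_FLOOR))
    norm = logsumexp(logw, axis=1)
    post = np.exp(logw - norm[:, None])
    return float(norm.sum()), post


def _m_step_closed_form(y, t, pidx, post, orders, shared_sigma):
    """Exact weighted-least-squares M-step for the uncensored model."""
    G = post.shape[1]
    w_obs = post[pidx]  # n_obs x G
    coefficients, sq = [], np.empty(G)
    wsum = np.empty(G)
    for g in range(G):
        X = _design(t, orders[g])
        w = w_obs[:, g]
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X + 1e-12 * np.eye(X.shape[1]), XtW @ y)
        coefficients.append(beta)
        r = y - X @ beta
        sq[g] = float(w @ (r * r))
        wsum[g] = float(w.sum())
    if shared_sigma:
        sigma = np.full(G, max(math.sqrt(sq.sum() / len(y)), _SIGMA_FLOOR))
    else:
        sigma = np.maximum(np.sqrt(sq / np.maximum(wsum, 1e-12)), _SIGMA_FLOOR)
    pi = post.mean(axis=0)
    pi = np.maximum(pi, _PI_FLOOR)
    pi = pi / pi.sum()
    return pi, coefficients, sigma


def _m_step_censored(y, t, pidx, post, orders, shared_sigma, lo, hi, coefficients, sigma):
    """Numeric generalized-EM M-step under finite censoring bounds."""
    G = post.shape[1]
    w_obs = post[pidx]
    sizes = [d + 1 for d in orders]
    n_sig = 1 if shared_sigma else G

    def unpack(x):
        cs, off = [], 0
        for s in sizes:
            cs.append(x[off : off + s])
            off += s
        logsig = x[off : off + n_sig]
        sig = np.exp(np.repeat(logsig, G) if shared_sigma else logsig)
        return cs, sig[:G]

    def negQ(x):
        cs, sig = unpack(x)
        total = 0.0
        for g in range(G):
            mu = _design(t, orders[g]) @ cs[g]
            total += float(w_obs[:, g] @ _obs_loglik(y, mu, sig[g], lo, hi))
        return -total

    x0 = np.concatenate(coefficients + [np.log(sigma[:n_sig])])
    res = optimize.minimize(negQ, x0, method="L-BFGS-B")
    cs, sig = unpack(res.x if res.fun <= negQ(x0) else x0)
    pi = post.mean(axis=0)
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum(), [np.asarray(c) for c in cs], np.maximum(sig, _SIGMA_FLOOR)


def _initial_params(y, t, pidx, n_pid, spec, rng, jitter):
    """Quantile split of participant mean values into G groups (+ jitter)."""
    orders = spec.order_tuple()
    G = spec.n_groups
    pid_mean = np.bincount(pidx, weights=y, minlength=n_pid) / np.bincount(pidx, minlength=n_pid)
    qs = np.quantile(pid_mean, np.linspace(0, 1, G + 1)[1:-1]) if G > 1 else np.array([])
    labels = np.searchsorted(qs, pid_mean)
    coefficients = []
    for g in range(G):
        mask = labels == g
        center = pid_mean[mask].mean() if mask.any() else pid_mean.mean()
        beta = np.zeros(orders[g] + 1)
        beta[0] = center + (rng.normal(0.0, jitter) if jitter else 0.0)
        coefficients.append(beta)
    resid_sd = float(np.std(y - pid_mean[pidx])) or 1.0
    sigma = np.full(G, max(resid_sd, np.std(y) / max(G, 1), 0.5))
    counts = np.bincount(labels, minlength=G).astype(float)
    pi = np.maximum(counts, 1.0)
    return pi / pi.sum(), coefficients, sigma


def fit_gbta(panel: pd.DataFrame, spec: GbtaSpec) -> GbtaFit:
    """Fit a trajectory mixture by EM, best of ``spec.n_starts`` starts.

    The log-likelihood is non-decreasing across EM iterations (exact
    closed-form M-step for the uncensored model; generalized EM with a
    warm-started numeric M-step under finite censoring bounds).  Groups in
    the returned fit are ordered by ascending intercept.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    y, t, pidx, pids = _prepare_panel(panel)
    n_pid = len(pids)
    if n_pid < spec.n_groups:
        raise ValueError(f"{spec.n_groups} groups but only {n_pid} participants")
    orders = spec.order_tuple()
    lo, hi = spec.censor_low, spec.censor_high
    censored = np.isfinite(lo) or np.isfinite(hi)
    y_sd = float(np.std(y)) or 1.0

    best: GbtaFit | None = None
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_starts)
    for start, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        jitter = 0.0 if start == 0 else 0.5 * y_sd
        pi, coefficients, sigma = _initial_params(y, t, pidx, n_pid, spec, rng, jitter)
        trace: list[float] = []
        converged = False
        loglik, post = _mixture_eval(y, t, pidx, n_pid, pi, coefficients, sigma, lo, hi)
        trace.append(loglik)
        for _ in range(spec.max_iter):
            if censored:
                pi, coefficients, sigma = _m_step_censored(
                    y, t, pidx, post, orders, spec.shared_sigma, lo, hi, coefficients, sigma
                )
            else:
                pi, coefficients, sigma = _m_step_closed_form(
                    y, t, pidx, post, orders, spec.shared_sigma
                )
            new_loglik, post = _mixture_eval(y, t, pidx, n_pid, pi, coefficients, sigma, lo, hi)
            trace.append(new_loglik)
            if abs(new_loglik - loglik) <= spec.tol * max(abs(loglik), 1.0):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
        fit = GbtaFit(
            spec=spec,
            pi=pi,
            coefficients=coefficients,
            sigma=sigma,
            loglik=loglik,
            n_params=spec.n_params,
            n_participants=n_pid,
            n_obs=len(y),
            posteriors=pd.DataFrame(post, index=pd.Index(pids, name="participant_id")),
            converged=converged,
            loglik_trace=trace,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return _canonical_order(best)


def _canonical_order(fit: GbtaFit) -> GbtaFit:
    order = np.argsort([c[0] for c in fit.coefficients], kind="stable")
    post = fit.posteriors.to_numpy()[:, order]
    fit.pi = fit.pi[order]
    fit.coefficients = [fit.coefficients[g] for g in order]
    fit.sigma = fit.sigma[order]
    fit.posteriors = pd.DataFrame(
        post, index=fit.posteriors.index, columns=[f"group_{g + 1}" for g in range(len(order))]
    )
    return fit


def bic(fit: GbtaFit, N: int) -> float:
    """BIC on the "larger is better" scale: ``loglik - 0.5 * k * log(N)``."""
    if N <= 0:
        raise ValueError("N must be positive")
    return fit.loglik - 0.5 * fit.n_params * math.log(N)


def model_search(
    panel: pd.DataFrame,
    G_range: range | tuple[int, ...] = range(1, 7),
    order_menu: tuple[int, ...] = (0, 1, 2),
    seed: int = 0,
    **spec_kwargs,
) -> tuple[pd.DataFrame, GbtaFit]:
    """Fit every (G, shared polynomial order) candidate; pick the BIC-best.

    Returns the search table (one row per candidate: G, order, loglik, k,
    BIC on both participant and observation counts, convergence or error)
    and the best fit by participant-count BIC.  Failures in individual
    candidates are recorded in the table without aborting the search.
    """
    rows = []
    best_fit: GbtaFit | None = None
    candidates = [(G, o) for G in G_range for o in order_menu]
    if not candidates:
        raise ValueError("empty model-search grid")
    for G, order in candidates:
        spec = GbtaSpec(n_groups=G, orders=order, seed=seed, **spec_kwargs)
        row: dict = {"n_groups": G, "order": order}
        try:
            fit = fit_gbta(panel, spec)
            row.update(
                loglik=fit.loglik,
                k=fit.n_params,
                bic=fit.bic,
                bic_obs=fit.bic_obs,
                converged=fit.converged,
                error="",
            )
            if best_fit is None or fit.bic > best_fit.bic:
                best_fit = fit
        except (ValueError, np.linalg.LinAlgError) as exc:
            row.update(loglik=np.nan, k=np.nan, bic=np.nan, bic_obs=np.nan, converged=False, error=str(exc))
        rows.append(row)
    if best_fit is None:
        raise RuntimeError("every candidate model failed to fit")
    return pd.DataFrame(rows), best_fit


def occ(app_g: float, pi_g: float) -> float:
    """Odds of correct classification for one group.

    OCC_g = [APP_g / (1 - APP_g)] / [pi_g / (1 - pi_g)]; equals 1 when
    classification is no better than chance, infinity when APP = 1.
    """
    if not 0.0 < pi_g < 1.0:
        raise ValueError(f"pi_g must lie in (0, 1), got {pi_g}")
    if not 0.0 <= app_g <= 1.0:
        raise ValueError(f"app_g must lie in [0, 1], got {app_g}")
    if app_g == 1.0:
        return math.inf
    return (app_g / (1.0 - app_g)) / (pi_g / (1.0 - pi_g))


@dataclass
class QCReport:
    """Posterior classification QC for a fitted trajectory model."""

    table: pd.DataFrame  # per group: n_assigned, share, pi, app, occ, flags, reason
    app_min: float
    occ_min: float
    prop_tol: float

    @property
    def passed(self) -> bool:
        return bool(self.table[["app_ok", "occ_ok", "prop_ok"]].to_numpy().all())

    @property
    def failing_groups(self) -> list[int]:
        bad = ~self.table[["app_ok", "occ_ok", "prop_ok"]].all(axis=1)
        return list(self.table.loc[bad, "group"])


def posterior_qc(fit: GbtaFit, app_min: float = 0.7, occ_min: float = 5.0, prop_tol: float = 0.1) -> QCReport:
    """Apply the three posterior QC criteria to a fitted model.

    Per group g: APP_g is the mean posterior probability among participants
    modally assigned to g (must be >= ``app_min``); OCC_g must exceed
    ``occ_min``; and the estimated probability pi_g must agree with the
    observed assignment share within ``prop_tol``.  A group with no modal
    members fails with an explicit reason.
    """
    post = fit.posteriors.to_numpy()
    assign = post.argmax(axis=1)
    G = post.shape[1]
    n = len(assign)
    rows = []
    for g in range(G):
        members = assign == g
        n_g = int(members.sum())
        share = n_g / n if n else np.nan
        pi_g = float(fit.pi[g])
        if n_g == 0:
            rows.append(
                {"group": g + 1, "n_assigned": 0, "share": 0.0, "pi": pi_g,
                 "app": np.nan, "occ": np.nan, "app_ok": False, "occ_ok": False,
                 "prop_ok": False, "reason": "no modally assigned members"}
            )
            continue
        app_g = float(post[members, g].mean())
        occ_g = occ(app_g, pi_g) if 0.0 < pi_g < 1.0 else math.inf
        rows.append(
            {
                "group": g + 1,
                "n_assigned": n_g,
                "share": share,
                "pi": pi_g,
                "app": app_g,
                "occ": occ_g,
                "app_ok": app_g >= app_min,
                "occ_ok": occ_g > occ_min,
                "prop_ok": abs(pi_g - share) <= prop_tol,
                "reason": "",
            }
        )
    return QCReport(table=pd.DataFrame(rows), app_min=app_min, occ_min=occ_min, prop_tol=prop_tol)


def profile_groups(fit: GbtaFit, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-group participant characteristics with between-group tests.

    ``covariates`` is one row per participant (indexed or keyed by
    ``participant_id``).  Continuous variables get mean (SD) per group and a
    one-way ANOVA p-value; categorical variables get n (%) per level and a
    chi-square / Fisher p-value.  With a single group no tests are run.
    Participants that cannot be joined to an assignment are reported in the
    ``unjoined`` attribute of the returned frame.
    """
    cov = covariates.copy()
    if "participant_id" in cov.columns:
        cov = cov.set_index("participant_id")
    assign = fit.assignment
    joined = cov.join(assign, how="inner")
    unjoined = sorted(set(cov.index) - set(assign.index))
    groups = sorted(assign.unique())
    single = len(groups) == 1
    rows = []
    for col in cov.columns:
        series = joined[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 5:
            by_group = [series[joined["group"] == g].dropna() for g in groups]
            cells = {f"group_{g}": f"{v.mean():.2f} ({v.std(ddof=1):.2f})" for g, v in zip(groups, by_group)}
            p = np.nan
            if not single and all(len(v) > 0 for v in by_group) and sum(map(len, by_group)) > len(groups):
                _, p = oneway_anova(by_group)
            rows.append({"variable": col, "level": "", **cells, "p": p, "test": "" if single else "anova"})
        else:
            tab = pd.crosstab(series.astype(str), joined["group"])
            tab = tab.reindex(columns=groups, fill_value=0)
            p, method = np.nan, ""
            if not single and tab.to_numpy().sum() > 0 and tab.shape[0] >= 2:
                try:
                    with warnings.catch_warnings():
                        # sparse levels are routine here; the method used is
                        # recorded in the output table
                        warnings.simplefilter("ignore", UserWarning)
                        _, p, method = contingency_test(tab.to_numpy())
                except ValueError:
                    p, method = np.nan, "untestable"
            totals = tab.sum(axis=0)
            for level, counts in tab.iterrows():
                cells = {
                    f"group_{g}": f"{counts[g]} ({100 * counts[g] / totals[g]:.1f})" if totals[g] else "0"
                    for g in groups
                }
                rows.append({"variable": col, "level": str(level), **cells, "p": p, "test": method})
    out = pd.DataFrame(rows)
    out.attrs["unjoined"] = unjoined
    out.attrs["group_sizes"] = assign.value_counts().sort_index().to_dict()
    return out
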