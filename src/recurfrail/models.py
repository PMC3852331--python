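"""Poisson gap-time models for recurrent events.

Three piecewise-exponential models for the hazard of ending a sickness-absence
episode, all estimated as Poisson regressions on person-period records with
offset ``log n_jik``:

* **CPM** — conditional Poisson model: baseline log-hazard per
  (interval, event order) cell, no random effect.  Event dependence only.
* **FPM** — frailty Poisson model: baseline per interval shared across event
  orders, multiplicative gamma frailty per individual.  Heterogeneity only.
* **CFPM** — conditional frailty Poisson model: order-stratified baseline
  *and* gamma frailty, capturing both sources of within-individual
  correlation.

The hazard for individual ``i``, event order ``k``, interval ``j`` is
``lambda_jk * exp(x' beta + omega_i)`` with ``u_i = exp(omega_i)`` gamma with
mean 1 and variance ``theta`` (shape = rate = 1/theta), the identifiable
convention for a multiplicative frailty.  The frailty is integrated out in
closed form by gamma-Poisson conjugacy, so no numerical integration is needed.

Fixed-effects models are fitted by profiling: given ``beta`` the baseline
cell log-hazards have the closed-form optimum ``log(events / expected
exposure)``, leaving a smooth low-dimensional problem in ``beta`` alone.
Frailty models are fitted by quasi-Newton (L-BFGS-B) over
``(baseline, beta, log theta)`` with analytic gradients, warm-started from
the fixed-effects fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .episodes import ValidationError
from .expansion import IntervalGrid

__all__ = [
    "ModelSpec",
    "CPM",
    "FPM",
    "CFPM",
    "MODEL_SPECS",
    "Design",
    "FitResult",
    "build_design",
    "poisson_loglik",
    "gamma_frailty_marginal_loglik",
    "fit",
    "predict_episode_hazard",
    "sensitivity_fit",
    "read_fit_table",
]

#: Log-hazard at which unidentified (zero-event) baseline cells are pinned.
LOG_HAZARD_FLOOR = -20.0
#: Below this, an estimated frailty variance is reported as the boundary 0.
THETA_BOUNDARY = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Which correlation sources a model accounts for.

    (stratify, frailty) = (True, False) is the CPM, (False, True) the FPM and
    (True, True) the CFPM.  ``covariates`` restricts the model to a subset of
    the schema; ``None`` means all schema covariates.
    """

    stratify_baseline_by_order: bool
    frailty: bool
    covariates: tuple[str, ...] | None = None
    name: str = ""


CPM = ModelSpec(True, False, name="cpm")
FPM = ModelSpec(False, True, name="fpm")
CFPM = ModelSpec(True, True, name="cfpm")
MODEL_SPECS = {"cpm": CPM, "fpm": FPM, "cfpm": CFPM}


@dataclass
class Design:
    """Numeric design built from a person-period table.

    ``cell_codes[r]`` indexes the free baseline cell of record ``r`` or is -1
    when the record falls in a pinned (zero-event) cell.  ``X`` holds the
    treatment-coded covariate contrasts versus each reference level.
    """

    X: np.ndarray
    contrasts: list[tuple[str, str]]
    cells: list[tuple[int, ...]]          # free (j,) or (j, k) cells
    pinned_cells: list[tuple[int, ...]]
    cell_codes: np.ndarray
    d: np.ndarray
    exposure: np.ndarray
    log_exposure: np.ndarray
    indiv_codes: np.ndarray
    individuals: np.ndarray
    spec: ModelSpec
    schema: dict[str, list[str]]

    @property
    def n_records(self) -> int:
        return self.d.size

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_contrasts(self) -> int:
        return self.X.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.individuals.size

    @property
    def n_params(self) -> int:
        """Free parameters excluding theta."""
        return self.n_cells + self.n_contrasts


def build_design(records: pd.DataFrame, spec: ModelSpec,
                 schema: dict[str, list[str]]) -> Design:
    """Turn person-period records into the numeric design of a model.

    Raises on covariate labels absent from the schema; warns (and pins) for
    baseline cells with exposure but no events, whose log-hazards are
    unidentified.
    """
    if len(records) == 0:
        raise ValidationError("empty person-period table")
    covs = list(schema) if spec.covariates is None else list(spec.covariates)
    for c in covs:
        if c not in records.columns:
            raise ValidationError(f"covariate {c!r} not in person-period records")
        if c not in schema:
            raise ValidationError(f"covariate {c!r} not in schema")

    d = records["event"].to_numpy(dtype=float)
    exposure = records["exposure_days"].to_numpy(dtype=float)
    if (exposure <= 0).any():
        raise ValidationError("non-positive exposure in person-period records")

    contrasts: list[tuple[str, str]] = []
    cols = []
    for c in covs:
        levels = schema[c]
        values = records[c].astype(str)
        unseen = set(values.unique()) - set(levels)
        if unseen:
            raise ValidationError(f"covariate {c!r}: labels {sorted(unseen)} not in schema")
        for lev in levels[1:]:
            contrasts.append((c, lev))
            cols.append((values == lev).to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))

    if spec.stratify_baseline_by_order:
        keys = list(zip(records["interval_j"].astype(int), records["order_k"].astype(int)))
    else:
        keys = [(j,) for j in records["interval_j"].astype(int)]
    cell_of = {}
    all_cells: list[tuple[int, ...]] = []
    raw_codes = np.empty(len(records), dtype=np.int64)
    for r, key in enumerate(keys):
        code = cell_of.setdefault(key, len(all_cells))
        if code == len(all_cells):
            all_cells.append(key)
        raw_codes[r] = code
    events_per_cell = np.bincount(raw_codes, weights=d, minlength=len(all_cells))

    free_mask = events_per_cell > 0
    free_cells = [c for c, ok in zip(all_cells, free_mask) if ok]
    pinned = [c for c, ok in zip(all_cells, free_mask) if not ok]
    if pinned:
        warnings.warn(
            "baseline cell(s) with exposure but no events pinned at the hazard "
            f"floor: {pinned[:20]}{' ...' if len(pinned) > 20 else ''}",
            RuntimeWarning, stacklevel=2)
    remap = np.full(len(all_cells), -1, dtype=np.int64)
    remap[free_mask] = np.arange(int(free_mask.sum()))
    cell_codes = remap[raw_codes]

    individuals, indiv_codes = np.unique(records["individual_id"].to_numpy(), return_inverse=True)
    return Design(
        X=X, contrasts=contrasts, cells=free_cells, pinned_cells=pinned,
        cell_codes=cell_codes, d=d, exposure=exposure,
        log_exposure=np.log(exposure), indiv_codes=indiv_codes,
        individuals=individuals, spec=spec, schema={c: list(schema[c]) for c in schema},
    )


def _linear_predictor(alpha: np.ndarray, beta: np.ndarray, design: Design) -> np.ndarray:
    cell_term = np.where(design.cell_codes >= 0,
                         alpha[np.maximum(design.cell_codes, 0)], LOG_HAZARD_FLOOR)
    return cell_term + design.X @ beta + design.log_exposure


def _split(params: np.ndarray, design: Design):
    params = np.asarray(params, dtype=float)
    return params[: design.n_cells], params[design.n_cells: design.n_params]


def poisson_loglik(params, design: Design):
    """Fixed-effects Poisson log-likelihood and its gradient.

    ``params = (alpha_1..alpha_C, beta_1..beta_p)``.  The ``log d!`` term is
    identically zero for binary ``d`` and is dropped.
    """
    alpha, beta = _split(params, design)
    eta = _linear_predictor(alpha, beta, design)
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise FloatingPointError(f"non-finite linear predictor at record {bad}")
    mu = np.exp(eta)
    ll = float(np.sum(design.d * eta - mu))
    resid = design.d - mu
    g_alpha = np.bincount(np.maximum(design.cell_codes, 0),
                          weights=np.where(design.cell_codes >= 0, resid, 0.0),
                          minlength=design.n_cells)
    g_beta = design.X.T @ resid
    return ll, np.concatenate([g_alpha, g_beta])


def _frailty_terms(D: np.ndarray, M: np.ndarray, a: float):
    """Per-individual marginal log-likelihood terms and d/da, stably.

    For integer event counts ``D`` the gammaln difference is the finite sum
    ``sum_{r<D} log(a + r)``, which stays accurate for very large ``a``
    (theta -> 0) where direct gammaln differencing loses precision.
    """
    term = -a * np.log1p(M / a) - D * np.log(a + M)
    dterm = -np.log1p(M / a) + (M - D) / (a + M)
    Dmax = int(D.max()) if D.size else 0
    for r in range(Dmax):
        mask = D > r
        term[mask] += np.log(a + r)
        dterm[mask] += 1.0 / (a + r)
    return term, dterm


def gamma_frailty_marginal_loglik(params, design: Design):
    """Marginal log-likelihood of the gamma-frailty Poisson model + gradient.

    ``params = (alpha, beta, theta)`` with ``theta`` the frailty variance on
    its natural scale.  The per-individual frailty is integrated out in
    closed form: with ``a = 1/theta``, ``D_i = sum d`` and ``M_i = sum mu``,

        log L_i = sum d*log(mu) + log Gamma(a + D_i) - log Gamma(a)
                  + a*log(a) - (a + D_i)*log(a + M_i)

    which converges to the fixed-effects Poisson log-likelihood as
    ``theta -> 0``.
    """
    params = np.asarray(params, dtype=float)
    theta = float(params[-1])
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    alpha, beta = _split(params[:-1], design)
    if theta < 1e-14:
        ll, g = poisson_loglik(params[:-1], design)
        return ll, np.concatenate([g, [0.0]])
    a = 1.0 / theta
    eta = _linear_predictor(alpha, beta, design)
    mu = np.exp(eta)
    D = np.bincount(design.indiv_codes, weights=design.d,
                    minlength=design.n_individuals)
    M = np.bincount(design.indiv_codes, weights=mu,
                    minlength=design.n_individuals)
    term, dterm = _frailty_terms(D, M, a)
    ll = float(np.sum(design.d * eta) + np.sum(term))

    w = (a + D) / (a + M)            # E[u_i | data], the shrunken frailty
    w_rec = w[design.indiv_codes]
    resid = design.d - w_rec * mu
    g_alpha = np.bincount(np.maximum(design.cell_codes, 0),
                          weights=np.where(design.cell_codes >= 0, resid, 0.0),
                          minlength=design.n_cells)
    g_beta = design.X.T @ resid
    g_theta = float(np.sum(dterm)) * (-a * a)   # chain rule: da/dtheta = -1/theta^2
    return ll, np.concatenate([g_alpha, g_beta, [g_theta]])


@dataclass
class FitResult:
    """Estimates of one fitted model."""

    model: str
    params: pd.DataFrame                  # term, level, estimate, se, hr, ci_low, ci_high
    baseline: pd.DataFrame                # interval_j[, order_k], log_hazard, pinned
    theta: float
    theta_se: float | None
    theta_boundary: bool
    log_likelihood: float
    converged: bool
    iterations: int
    n_records: int
    n_individuals: int
    n_events: int
    grid: IntervalGrid | None = None
    spec: ModelSpec | None = None
    schema: dict[str, list[str]] = field(default_factory=dict)

    def hazard_ratios(self) -> pd.DataFrame:
        return self.params[["term", "level", "hr", "ci_low", "ci_high"]].copy()

    def to_csv(self, path, metadata_path=None) -> None:
        """Fit-output CSV (one row per parameter) + JSON metadata sidecar."""
        rows = self.params[["term", "level", "estimate", "se", "hr", "ci_low", "ci_high"]]
        rows.to_csv(path, index=False, encoding="utf-8")
        if metadata_path is not None:
            meta = {
                "model": self.model,
                "theta": self.theta,
                "theta_se": self.theta_se,
                "theta_boundary": self.theta_boundary,
                "log_likelihood": self.log_likelihood,
                "converged": self.converged,
                "iterations": self.iterations,
                "n_records": self.n_records,
                "n_individuals": self.n_individuals,
                "n_events": self.n_events,
                "grid_cuts": list(self.grid.cuts) if self.grid else None,
                "baseline": self.baseline.to_dict(orient="records"),
            }
            with open(metadata_path, "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=2)


def read_fit_table(path) -> pd.DataFrame:
    """Read a fit-output CSV back as a (term, level, hr, ci) table."""
    df = pd.read_csv(path, encoding="utf-8")
    need = {"term", "level", "hr", "ci_low", "ci_high"}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"fit table {path}: missing column(s) {sorted(missing)}")
    return df


def _profile_alpha(beta: np.ndarray, design: Design, free: np.ndarray):
    """Closed-form optimal baseline log-hazards given beta (free records only)."""
    mu0 = design.exposure[free] * np.exp(design.X[free] @ beta)
    codes = design.cell_codes[free]
    S = np.bincount(codes, weights=mu0, minlength=design.n_cells)
    D = np.bincount(codes, weights=design.d[free], minlength=design.n_cells)
    return np.log(D) - np.log(S)


def _fit_fixed(design: Design, options: dict):
    free = design.cell_codes >= 0
    Xf, df_, = design.X[free], design.d[free]

    def negll(beta):
        alpha = _profile_alpha(beta, design, free)
        eta = alpha[design.cell_codes[free]] + Xf @ beta + design.log_exposure[free]
        mu = np.exp(eta)
        # envelope theorem: at the profiled alpha the alpha-gradient vanishes
        return -float(np.sum(df_ * eta - mu)), -(Xf.T @ (df_ - mu))

    beta0 = np.zeros(design.n_contrasts)
    if design.n_contrasts:
        res = optimize.minimize(negll, beta0, jac=True, method="BFGS",
                                options={"gtol": options.get("gtol", 1e-8),
                                         "maxiter": options.get("max_iter", 500)})
        beta, n_iter = res.x, res.nit
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-5
    else:
        beta, n_iter, converged = beta0, 0, True
    alpha = _profile_alpha(beta, design, free)
    ll = -negll(beta)[0]

    # covariance of beta from the full Hessian via the Schur complement:
    # H = [[diag(A), B], [B', C]] with A per-cell and C the contrast block.
    mu = design.exposure[free] * np.exp(alpha[design.cell_codes[free]] + Xf @ beta)
    codes = design.cell_codes[free]
    A = np.bincount(codes, weights=mu, minlength=design.n_cells)
    if design.n_contrasts:
        B = np.stack([np.bincount(codes, weights=mu * Xf[:, p], minlength=design.n_cells)
                      for p in range(design.n_contrasts)], axis=1)
        C = (Xf * mu[:, None]).T @ Xf
        info = C - B.T @ (B / A[:, None])
        cov_beta = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    else:
        se = np.empty(0)
    return alpha, beta, se, ll, converged, int(n_iter)


def _fd_hessian(grad_fn, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        step = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2 * step)
    return (H + H.T) / 2


def _fit_frailty(design: Design, options: dict):
    alpha0, beta0, _, _, _, _ = _fit_fixed(design, options)
    log_theta0 = np.log(options.get("theta_start", 0.5))
    z0 = np.concatenate([alpha0, beta0, [log_theta0]])

    def negll(z):
        params = np.concatenate([z[:-1], [np.exp(z[-1])]])
        ll, g = gamma_frailty_marginal_loglik(params, design)
        g = g.copy()
        g[-1] *= np.exp(z[-1])          # d/d(log theta)
        return -ll, -g

    bounds = [(None, None)] * design.n_params + [(np.log(1e-8), np.log(1e3))]
    res = optimize.minimize(
        negll, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": options.get("max_iter", 2000),
                 "ftol": options.get("ftol", 1e-12),
                 "gtol": options.get("gtol", 1e-7)})
    z = res.x
    theta = float(np.exp(z[-1]))
    boundary = theta < THETA_BOUNDARY
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
    ll = -float(res.fun)
    alpha, beta = z[: design.n_cells], z[design.n_cells: design.n_params]

    grad_only = lambda zz: negll(zz)[1]
    H = _fd_hessian(grad_only, z)
    if boundary:
        # theta on the boundary: drop its row/column from the information
        H = H[:-1, :-1]
    cov = np.linalg.pinv(H)
    diag = np.clip(np.diag(cov), 0, None)
    se_beta = np.sqrt(diag[design.n_cells: design.n_params])
    if boundary:
        theta_se = None
    else:
        # delta method from log theta back to theta
        theta_se = float(np.sqrt(diag[-1]) * theta)
    return alpha, beta, se_beta, theta, theta_se, boundary, ll, converged, int(res.nit)


def fit(records: pd.DataFrame, spec: ModelSpec, schema: dict[str, list[str]],
        grid: IntervalGrid | None = None, **options) -> FitResult:
    """Fit a CPM, FPM or CFPM to a person-period table.

    Standard errors are Wald (inverse observed information at the optimum);
    hazard ratios are ``exp(beta)`` with 95% CI ``exp(beta +/- 1.96 se)``.  A
    frailty variance estimated at the boundary is reported as 0 with
    ``theta_boundary=True``.  Non-convergence sets ``converged=False`` rather
    than raising.
    """
    design = build_design(records, spec, schema)
    if design.d.sum() < 1:
        raise ValidationError("no events in person-period table")

    if spec.frailty:
        alpha, beta, se, theta, theta_se, boundary, ll, conv, nit = \
            _fit_frailty(design, options)
        if boundary:
            theta = 0.0
    else:
        alpha, beta, se, ll, conv, nit = _fit_fixed(design, options)
        theta, theta_se, boundary = 0.0, None, False

    z = 1.959963984540054
    params = pd.DataFrame({
        "term": [t for t, _ in design.contrasts],
        "level": [l for _, l in design.contrasts],
        "estimate": beta,
        "se": se,
    })
    params["hr"] = np.exp(params["estimate"])
    params["ci_low"] = np.exp(params["estimate"] - z * params["se"])
    params["ci_high"] = np.exp(params["estimate"] + z * params["se"])

    if spec.stratify_baseline_by_order:
        base = pd.DataFrame(design.cells + design.pinned_cells,
                            columns=["interval_j", "order_k"])
    else:
        base = pd.DataFrame(design.cells + design.pinned_cells, columns=["interval_j"])
    base["log_hazard"] = np.concatenate(
        [alpha, np.full(len(design.pinned_cells), LOG_HAZARD_FLOOR)])
    base["pinned"] = [False] * design.n_cells + [True] * len(design.pinned_cells)
    sort_keys = [c for c in ("order_k", "interval_j") if c in base.columns]
    base = base.sort_values(sort_keys).reset_index(drop=True)

    return FitResult(
        model=spec.name or ("cfpm" if spec.frailty and spec.stratify_baseline_by_order
                            else "custom"),
        params=params, baseline=base, theta=theta, theta_se=theta_se,
        theta_boundary=boundary, log_likelihood=ll, converged=conv,
        iterations=nit, n_records=design.n_records,
        n_individuals=design.n_individuals, n_events=int(design.d.sum()),
        grid=grid, spec=spec, schema=design.schema,
    )


def predict_episode_hazard(fit_result: FitResult, covariates: dict,
                           order_k: int, interval_j: int) -> float:
    """Population-level hazard per day for a covariate pattern and (j, k) cell.

    The frailty enters at its mean (1), so the returned rate is
    ``exp(log_hazard_jk + x' beta)``.
    """
    base = fit_result.baseline
    if "order_k" in base.columns:
        row = base[(base["interval_j"] == interval_j) & (base["order_k"] == order_k)]
    else:
        row = base[base["interval_j"] == interval_j]
    if len(row) == 0:
        raise ValidationError(f"baseline cell (j={interval_j}, k={order_k}) not estimated")
    if bool(row["pinned"].iloc[0]):
        raise ValidationError(
            f"baseline cell (j={interval_j}, k={order_k}) is unidentified (no events)")
    eta = float(row["log_hazard"].iloc[0])
    for _, p in fit_result.params.iterrows():
        name, level = p["term"], p["level"]
        if name not in fit_result.schema:
            continue
        value = str(covariates.get(name, fit_result.schema[name][0]))
        if value not in fit_result.schema[name]:
            raise ValidationError(f"covariate {name!r}: level {value!r} not in schema")
        if value == level:
            eta += float(p["estimate"])
    return float(np.exp(eta))


def sensitivity_fit(cohort, spec: ModelSpec, interval_lengths, **options):
    """Refit one model over several interval lengths (cut-point sensitivity).

    The approximation of the underlying hazard by piecewise constants depends
    on the grid; comparing hazard ratios across interval lengths is the
    recommended check that the conclusions are not an artefact of the cuts.
    Returns ``{interval_length: FitResult}``.
    """
    from .expansion import expand_cohort, grid_from_durations

    out = {}
    for L in interval_lengths:
        grid = grid_from_durations(cohort.episodes["duration_days"], int(L))
        pp = expand_cohort(cohort, grid)
        out[int(L)] = fit(pp, spec, cohort.schema, grid=grid, **options)
    return out
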