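"""Distributional regression for BCCG/BCPE reference centiles.

Each distribution parameter (mu, sigma, nu and, for BCPE, tau) is linked to
its own additive predictor in age and height: log link for mu, sigma and
tau, identity for nu.  Smooth terms are penalized cubic B-splines
(second-order difference penalty) whose smoothing strength is chosen on an
effective-degrees-of-freedom grid by minimizing the Schwarz Bayesian
Criterion, SBC = -2 logL + df log(n).  Fitting maximizes the penalized
log-likelihood by cyclic per-parameter block updates (mu, then sigma, nu,
tau), each block solved by L-BFGS with analytic gradients; the procedure is
deterministic given data, spec and control.

Predictor formulas are strings in a small mgcv-like language::

    "1"                      intercept only
    "1 + age"                linear age effect
    "1 + s(age) + s(height)" penalized smooths (df selected by SBC)
    "1 + s(age, df=3)"       smooth with fixed effective df
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from scipy.interpolate import BSpline

__all__ = [
    "Control",
    "ModelSpec",
    "FitResult",
    "fit",
    "sbc",
    "select_model",
    "predict_params",
    "centile",
    "default_candidates",
]

_NU_EPS = 1e-6
_VAR_COLUMNS = {"age": "age", "height": "height_cm"}


def sbc(logL: float, df: float, n: int) -> float:
    """Schwarz Bayesian Criterion, -2 logL + df log(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * logL + df * np.log(n)


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class Control:
    """Fitting controls: basis size, edf search grid, convergence."""

    n_knots: int = 12          # interior knots at covariate quantiles
    degree: int = 3            # cubic B-splines
    edf_grid: tuple = (1, 2, 3, 5, 8)  # per smooth term; 1 = linear
    default_edf: float = 3.0   # held value while other terms are searched
    max_cycles: int = 200
    tol: float = 1e-6          # absolute penalized-objective change
    inner_maxiter: int = 40
    tau_bounds: tuple = (0.35, 8.0)
    log_height: bool = True    # model height on the log scale (allometric)


@dataclass(frozen=True)
class ModelSpec:
    """Per-parameter predictor structure for one BCCG/BCPE model."""

    family: str = "BCCG"
    mu: str = "1 + s(age) + s(height)"
    sigma: str = "1 + age"
    nu: str = "1"
    tau: str = "1"

    def __post_init__(self):
        if self.family not in ("BCCG", "BCPE"):
            raise ValueError(f"unknown family {self.family!r}")
        for pname in self.param_names:
            terms = parse_terms(getattr(self, pname))
            if ("intercept",) not in terms:
                raise ValueError(f"{pname} predictor must contain an intercept")
        if self.family == "BCCG" and self.tau != "1":
            raise ValueError("BCCG specs carry no tau predictor")
        if self.tau != "1":
            raise ValueError("tau is intercept-only in this implementation")

    @property
    def param_names(self):
        return ("mu", "sigma", "nu", "tau") if self.family == "BCPE" else ("mu", "sigma", "nu")


_TERM_RE = re.compile(r"^s\(\s*(\w+)\s*(?:,\s*df\s*=\s*([0-9.]+)\s*)?\)$")


def parse_terms(formula: str):
    """Parse a predictor formula into term tuples."""
    terms = []
    for tok in (t.strip() for t in formula.split("+")):
        if tok == "1":
            terms.append(("intercept",))
        elif m := _TERM_RE.match(tok):
            var = m.group(1)
            if var not in _VAR_COLUMNS:
                raise ValueError(f"unknown covariate {var!r}")
            df = float(m.group(2)) if m.group(2) else None
            terms.append(("smooth", var, df))
        elif tok in _VAR_COLUMNS:
            terms.append(("linear", tok))
        else:
            raise ValueError(f"cannot parse term {tok!r}")
    return terms


# ---------------------------------------------------------------------------
# penalized B-spline smooth term

class _SmoothBasis:
    """Cubic B-spline smooth with second-order difference penalty.

    The basis is reparameterized into an unpenalized linear column plus
    penalized deviation columns with identity penalty: the penalty null
    space (constant + linear trend) is absorbed by the model's intercept
    and the explicit linear column, so lambda -> inf shrinks the term to a
    straight line (effective df 1).
    """

    def __init__(self, x, n_knots, degree):
        x = np.asarray(x, dtype=float)
        self.x_min, self.x_max = float(x.min()), float(x.max())
        self.x_mean = float(x.mean())
        interior = np.unique(np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1]))
        self.degree = degree
        self.knots = np.r_[
            [self.x_min] * (degree + 1), interior, [self.x_max] * (degree + 1)
        ]
        B = BSpline.design_matrix(x, self.knots, degree).toarray()
        K = B.shape[1]
        D2 = np.diff(np.eye(K), n=2, axis=0)
        P = D2.T @ D2
        w, U = np.linalg.eigh(P)
        keep = w > 1e-8 * w.max()
        self.Rt = U[:, keep] / np.sqrt(w[keep])  # (K, K-2)
        Zraw = B @ self.Rt
        C = np.column_stack([np.ones_like(x), x - self.x_mean])
        self.A, *_ = np.linalg.lstsq(C, Zraw, rcond=None)  # (2, K-2)
        self.Z = Zraw - C @ self.A
        self.sv2 = np.linalg.svd(self.Z, compute_uv=False) ** 2

    @property
    def n_pen(self):
        return self.Z.shape[1]

    def lambda_for_edf(self, edf_target: float, weight: float) -> float:
        """Penalty giving the requested extra effective df beyond linear."""
        extra = edf_target - 1.0
        if extra <= 1e-9:
            return 1e12
        ws2 = weight * self.sv2

        def f(loglam):
            lam = 10.0**loglam
            return float(np.sum(ws2 / (ws2 + lam))) - extra

        lo, hi = -10.0, 14.0
        if f(lo) < 0:  # basis cannot supply that much flexibility
            return 10.0**lo
        return 10.0 ** optimize.brentq(f, lo, hi, xtol=1e-10)

    def design(self, xnew):
        """(linear column, penalized columns) at new covariate values.

        Beyond the training range the spline deviation is extended flat
        (basis evaluated at the clamped covariate); the linear column
        continues, so extrapolation is linear.
        """
        xnew = np.asarray(xnew, dtype=float)
        xc = np.clip(xnew, self.x_min, self.x_max)
        B = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        Zraw = B @ self.Rt
        C = np.column_stack([np.ones_like(xc), xc - self.x_mean])
        return xnew - self.x_mean, Zraw - C @ self.A


# ---------------------------------------------------------------------------
# likelihood internals (fast array versions)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _pe_scale(tau):
    c = np.sqrt(2.0 ** (-2.0 / tau) * np.exp(special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)))
    return c * 2.0 ** (1.0 / tau)


def _z_and_aux(logy_mu_ratio, sigma, nu):
    L = logy_mu_ratio
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    u = np.exp(np.where(small, 0.0, nu) * L)
    z = np.where(small, L / sigma, (u - 1.0) / (nu_safe * sigma))
    return z, u, small, nu_safe


def _logpdf(y, logy, mu, sigma, nu, tau=None):
    L = logy - np.log(mu)
    z, _, _, _ = _z_and_aux(L, sigma, nu)
    if tau is None:
        logkern = -0.5 * z * z - _LOG_SQRT_2PI
    else:
        s = _pe_scale(tau)
        logkern = (
            np.log(tau) - np.log(2.0) - special.gammaln(1.0 / tau) - np.log(s)
            - np.abs(z / s) ** tau
        )
    return (nu - 1.0) * logy - nu * np.log(mu) - np.log(sigma) + logkern


def _kernel_score(z, tau=None):
    if tau is None:
        return -z
    s = _pe_scale(tau)
    az = np.abs(z / s)
    az = np.where(az == 0, 1e-300, az)
    return -(tau / s) * az ** (tau - 1.0) * np.sign(z)


def _scores(y, logy, mu, sigma, nu, tau=None):
    """Per-observation d loglik / d(mu, sigma, nu)."""
    L = logy - np.log(mu)
    z, u, small, nu_safe = _z_and_aux(L, sigma, nu)
    g = _kernel_score(z, tau)
    dz_dmu = np.where(small, -1.0, -u) / (sigma * mu)
    d_mu = -nu / mu + g * dz_dmu
    d_sigma = -(1.0 + g * z) / sigma
    dz_dnu = np.where(small, L * L / (2.0 * sigma), (u * L) / (nu_safe * sigma) - z / nu_safe)
    d_nu = L + g * dz_dnu
    return d_mu, d_sigma, d_nu


# ---------------------------------------------------------------------------
# fit machinery

_LINKS = {"mu": "log", "sigma": "log", "nu": "identity", "tau": "log"}


@dataclass
class _ParamDesign:
    X: np.ndarray          # (n, p)
    lam: np.ndarray        # (p,) penalty per column (0 = unpenalized)
    layout: list           # term descriptors for prediction/serialization


def _build_design(name, terms, data_cols, bases, edfs, weights):
    cols, lam, layout = [np.ones(len(next(iter(data_cols.values()))))], [0.0], [("intercept",)]
    for t in terms:
        if t[0] == "intercept":
            continue
        if t[0] == "linear":
            x = data_cols[t[1]]
            m = float(x.mean())
            cols.append(x - m)
            lam.append(0.0)
            layout.append(("linear", t[1], m))
        else:  # smooth
            basis = bases[(name, t[1])]
            edf = edfs[(name, t[1])]
            lam_t = basis.lambda_for_edf(edf, weights[name])
            cols.append(data_cols[t[1]] - basis.x_mean)
            lam.append(0.0)
            cols.append(basis.Z)
            lam.extend([lam_t] * basis.n_pen)
            layout.append(("smooth", t[1], basis, edf, lam_t))
    X = np.column_stack(cols)
    return _ParamDesign(X=X, lam=np.asarray(lam, dtype=float), layout=layout)


def _theta(eta, link):
    return np.exp(eta) if link == "log" else eta


class _FitState:
    def __init__(self, y, designs, family, control):
        self.y = np.asarray(y, dtype=float)
        self.logy = np.log(self.y)
        self.designs = designs
        self.family = family
        self.control = control
        self.beta = {p: np.zeros(d.X.shape[1]) for p, d in designs.items()}
        self.eta = {}
        self.tau_eta = np.log(2.0)
        self.barrier_hit = False

    def refresh(self, pname):
        self.eta[pname] = self.designs[pname].X @ self.beta[pname]

    def params(self):
        mu = _theta(self.eta["mu"], "log")
        sigma = _theta(self.eta["sigma"], "log")
        nu = self.eta["nu"]
        tau = np.exp(self.tau_eta) if self.family == "BCPE" else None
        return mu, sigma, nu, tau

    def loglik(self):
        mu, sigma, nu, tau = self.params()
        lp = _logpdf(self.y, self.logy, mu, sigma, nu, tau)
        bad = ~np.isfinite(lp)
        if np.any(bad):
            self.barrier_hit = True
            lp = np.where(bad, -1e10, lp)
        return float(lp.sum())

    def penalty(self):
        return 0.5 * sum(float(d.lam @ (b * b)) for d, b in
                         ((self.designs[p], self.beta[p]) for p in self.designs))

    def objective(self):
        return self.loglik() - self.penalty()


def _update_block(state: _FitState, pname: str):
    d = state.designs[pname]
    X, lam = d.X, d.lam
    link = _LINKS[pname]
    idx = {"mu": 0, "sigma": 1, "nu": 2}[pname]

    def negobj(b):
        eta = X @ b
        state.eta[pname] = eta
        mu, sigma, nu, tau = state.params()
        lp = _logpdf(state.y, state.logy, mu, sigma, nu, tau)
        bad = ~np.isfinite(lp)
        if np.any(bad):
            state.barrier_hit = True
            lp = np.where(bad, -1e10, lp)
        val = float(lp.sum()) - 0.5 * float(lam @ (b * b))
        dtheta = _scores(state.y, state.logy, mu, sigma, nu, tau)[idx]
        if np.any(bad):
            dtheta = np.where(bad, 0.0, dtheta)
        deta = dtheta * (mu if pname == "mu" else sigma if pname == "sigma" else 1.0)
        grad = X.T @ deta - lam * b
        return -val, -grad

    res = optimize.minimize(
        negobj, state.beta[pname], jac=True, method="L-BFGS-B",
        options=dict(maxiter=state.control.inner_maxiter, ftol=1e-12, gtol=1e-8),
    )
    state.beta[pname] = res.x
    state.refresh(pname)


def _update_tau(state: _FitState):
    lo, hi = np.log(state.control.tau_bounds[0]), np.log(state.control.tau_bounds[1])

    def negobj(te):
        state.tau_eta = te
        return -state.loglik()

    res = optimize.minimize_scalar(negobj, bounds=(lo, hi), method="bounded",
                                   options=dict(xatol=1e-6))
    state.tau_eta = float(res.x)


def _fit_inner(y, designs, family, control, warm=None):
    state = _FitState(y, designs, family, control)
    if warm is not None:
        for p in state.beta:
            if warm[0][p].shape == state.beta[p].shape:
                state.beta[p] = warm[0][p].copy()
        state.tau_eta = warm[1]
    else:
        # mu: ridge regression of log y on X_mu; sigma: robust residual scale
        Xm, lam = designs["mu"].X, designs["mu"].lam
        G = Xm.T @ Xm + np.diag(lam + 1e-8)
        state.beta["mu"] = np.linalg.solve(G, Xm.T @ state.logy)
        resid = state.logy - Xm @ state.beta["mu"]
        s0 = max(float(np.std(resid)), 1e-3)
        state.beta["sigma"][0] = np.log(s0)
        state.beta["nu"][0] = 1.0
    for p in designs:
        state.refresh(p)

    trace = []
    prev = -np.inf
    converged = False
    order = ["mu", "sigma", "nu"]
    for cycle in range(control.max_cycles):
        for p in order:
            _update_block(state, p)
        if family == "BCPE":
            _update_tau(state)
        obj = state.loglik() - state.penalty()
        trace.append(obj)
        if np.isfinite(obj) and abs(obj - prev) < control.tol:
            converged = True
            break
        prev = obj
    return state, trace, converged


@dataclass
class FitResult:
    """One fitted BCCG/BCPE distributional-regression model."""

    spec: ModelSpec
    control: Control
    beta: dict
    tau_eta: float
    layouts: dict            # param -> design layout
    logL: float
    df: float
    sbc: float
    n: int
    converged: bool
    n_cycles: int
    trace: list
    train_range: dict        # var -> (min, max), on the modelling scale
    transforms: dict = field(default_factory=dict)  # var -> covariate transform
    scope: str = ""
    barrier_hit: bool = False
    leaderboard: list = field(default_factory=list)

    @property
    def family(self):
        return self.spec.family

    # -- serialization so tables can be regenerated without refitting ------
    def to_json(self) -> str:
        def enc_layout(layout):
            out = []
            for t in layout:
                if t[0] == "smooth":
                    _, var, basis, edf, lam = t
                    out.append(dict(kind="smooth", var=var, edf=edf, lam=lam,
                                    knots=basis.knots.tolist(), degree=basis.degree,
                                    Rt=basis.Rt.tolist(), A=basis.A.tolist(),
                                    x_mean=basis.x_mean, x_min=basis.x_min,
                                    x_max=basis.x_max))
                elif t[0] == "linear":
                    out.append(dict(kind="linear", var=t[1], mean=t[2]))
                else:
                    out.append(dict(kind="intercept"))
            return out

        d = dict(
            spec=dict(family=self.spec.family, mu=self.spec.mu, sigma=self.spec.sigma,
                      nu=self.spec.nu, tau=self.spec.tau),
            beta={p: b.tolist() for p, b in self.beta.items()},
            tau_eta=self.tau_eta,
            layouts={p: enc_layout(lo) for p, lo in self.layouts.items()},
            logL=self.logL, df=self.df, sbc=self.sbc, n=self.n,
            converged=self.converged, n_cycles=self.n_cycles,
            train_range=self.train_range, transforms=self.transforms,
            scope=self.scope,
        )
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        d = json.loads(s)

        def dec_layout(items):
            out = []
            for t in items:
                if t["kind"] == "smooth":
                    basis = _SmoothBasis.__new__(_SmoothBasis)
                    basis.knots = np.asarray(t["knots"])
                    basis.degree = t["degree"]
                    basis.Rt = np.asarray(t["Rt"])
                    basis.A = np.asarray(t["A"])
                    basis.x_mean = t["x_mean"]
                    basis.x_min = t["x_min"]
                    basis.x_max = t["x_max"]
                    out.append(("smooth", t["var"], basis, t["edf"], t["lam"]))
                elif t["kind"] == "linear":
                    out.append(("linear", t["var"], t["mean"]))
                else:
                    out.append(("intercept",))
            return out

        return cls(
            spec=ModelSpec(**d["spec"]), control=Control(),
            beta={p: np.asarray(b) for p, b in d["beta"].items()},
            tau_eta=d["tau_eta"],
            layouts={p: dec_layout(lo) for p, lo in d["layouts"].items()},
            logL=d["logL"], df=d["df"], sbc=d["sbc"], n=d["n"],
            converged=d["converged"], n_cycles=d["n_cycles"], trace=[],
            train_range={k: tuple(v) for k, v in d["train_range"].items()},
            transforms=d.get("transforms", {}),
            scope=d.get("scope", ""),
        )


def _apply_transform(x, name):
    if name is None:
        return x
    if name == "log":
        return np.log(x)
    raise ValueError(f"unknown covariate transform {name!r}")


def _design_rows(layout, covs):
    cols = [np.ones(len(covs["age"]))]
    for t in layout:
        if t[0] == "intercept":
            continue
        if t[0] == "linear":
            cols.append(covs[t[1]] - t[2])
        else:
            _, var, basis, edf, lam = t
            lin, Z = basis.design(covs[var])
            cols.append(lin)
            cols.append(Z)
    return np.column_stack(cols)


def fit(data, column: str, spec: ModelSpec, control: Control = Control(),
        scope: str = "") -> FitResult:
    """Fit one model to the analysis records of one sex and one measure.

    ``data`` needs columns ``age``, ``height_cm`` and the response
    ``column`` (mmHg, positive).  Smooth-term effective df without an
    explicit ``df=`` are selected on ``control.edf_grid`` by SBC, one term
    at a time in formula order.
    """
    y = np.asarray(data[column], dtype=float)
    if len(y) < 50:
        raise ValueError("need at least 50 records")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("responses must be finite and > 0")
    transforms = {"height": "log"} if control.log_height else {}
    data_cols = {v: _apply_transform(np.asarray(data[c], dtype=float),
                                     transforms.get(v))
                 for v, c in _VAR_COLUMNS.items()}
    for v, x in data_cols.items():
        if np.any(~np.isfinite(x)):
            raise ValueError(f"covariate {v} contains non-finite values")

    terms = {p: parse_terms(getattr(spec, p)) for p in spec.param_names}
    bases = {}
    for p, ts in terms.items():
        for t in ts:
            if t[0] == "smooth":
                bases[(p, t[1])] = _SmoothBasis(data_cols[t[1]], control.n_knots, control.degree)

    # curvature weights for the edf <-> lambda calibration
    s0 = max(float(np.std(np.log(y))), 1e-3)
    weights = {"mu": 1.0 / s0**2, "sigma": 2.0, "nu": float(s0**2)}

    smooth_slots = [(p, t[1], t[2]) for p, ts in terms.items() for t in ts if t[0] == "smooth"]
    edfs = {(p, v): (df if df is not None else control.default_edf)
            for p, v, df in smooth_slots}

    def df_total(edf_map):
        tot = 0.0
        for p, ts in terms.items():
            if p == "tau":
                continue
            for t in ts:
                if t[0] == "intercept" or t[0] == "linear":
                    tot += 1.0
                else:
                    tot += edf_map[(p, t[1])]
        return tot

    def run(edf_map, warm=None):
        designs = {p: _build_design(p, terms[p], data_cols, bases, edf_map, weights)
                   for p in terms if p != "tau"}
        state, trace, conv = _fit_inner(y, designs, spec.family, control, warm)
        ll = state.loglik()
        return state, trace, conv, ll

    warm = None
    selectable = [(p, v) for p, v, df in smooth_slots if df is None]
    state, trace, conv, ll = run(edfs, None)
    best = (state, trace, conv, ll, dict(edfs))
    for p, v in selectable:
        results = []
        for e in control.edf_grid:
            trial = dict(best[4])
            trial[(p, v)] = float(e)
            if trial == best[4]:
                st, tr, cv, l2 = best[:4]
            else:
                st, tr, cv, l2 = run(trial, warm=(best[0].beta, best[0].tau_eta))
            crit = sbc(l2, df_total(trial), len(y))
            results.append((crit, e, (st, tr, cv, l2, trial)))
        results.sort(key=lambda r: (r[0], r[1]))
        best = results[0][2]

    state, trace, conv, ll = best[:4]
    edfs = best[4]
    df = df_total(edfs) + (1.0 if spec.family == "BCPE" else 0.0)
    layouts = {p: state.designs[p].layout for p in state.designs}
    return FitResult(
        spec=spec, control=control,
        beta={p: state.beta[p].copy() for p in state.beta},
        tau_eta=state.tau_eta, layouts=layouts,
        logL=ll, df=df, sbc=sbc(ll, df, len(y)), n=len(y),
        converged=conv, n_cycles=len(trace), trace=trace,
        train_range={v: (float(x.min()), float(x.max())) for v, x in data_cols.items()},
        transforms=transforms,
        scope=scope, barrier_hit=state.barrier_hit,
    )


def select_model(data, column: str, candidates, control: Control = Control(),
                 scope: str = "") -> FitResult:
    """Fit all candidate specs and return the converged one with minimal SBC.

    Ties break toward fewer df, then candidate order; the full leaderboard
    is attached to the returned fit.
    """
    if not candidates:
        raise ValueError("need at least one candidate spec")
    fits = []
    for i, spec in enumerate(candidates):
        try:
            fits.append((i, fit(data, column, spec, control, scope)))
        except Exception as err:  # noqa: BLE001 - keep the trace, try the rest
            fits.append((i, err))
    ok = [(i, f) for i, f in fits if isinstance(f, FitResult) and f.converged]
    if not ok:
        raise RuntimeError(f"all candidates failed or diverged: {fits}")
    ok.sort(key=lambda t: (round(t[1].sbc, 9), t[1].df, t[0]))
    best = ok[0][1]
    best.leaderboard = [
        dict(index=i, spec=f.spec if isinstance(f, FitResult) else None,
             sbc=(f.sbc if isinstance(f, FitResult) else None),
             df=(f.df if isinstance(f, FitResult) else None),
             converged=isinstance(f, FitResult) and f.converged,
             error=None if isinstance(f, FitResult) else repr(f))
        for i, f in fits
    ]
    return best


def default_candidates(family: str = "BCCG"):
    """Default candidate set: smooth age+height in mu; intercept or linear
    age in sigma and nu; intercept-only tau for BCPE."""
    out = []
    for sig in ("1", "1 + age"):
        for nu in ("1", "1 + age"):
            out.append(ModelSpec(family=family, mu="1 + s(age) + s(height)",
                                 sigma=sig, nu=nu))
    return out


def predict_params(fit_result: FitResult, age, height):
    """Distribution parameters at (age, height); extrapolation is flagged.

    Returns (params dict, extrapolated bool array).
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    height = np.atleast_1d(np.asarray(height, dtype=float))
    age, height = np.broadcast_arrays(age, height)
    covs = {
        "age": _apply_transform(age, fit_result.transforms.get("age")),
        "height": _apply_transform(height, fit_result.transforms.get("height")),
    }
    out = {}
    for p, layout in fit_result.layouts.items():
        X = _design_rows(layout, covs)
        eta = X @ fit_result.beta[p]
        out[p] = _theta(eta, _LINKS[p])
    if fit_result.family == "BCPE":
        out["tau"] = np.full_like(age, np.exp(fit_result.tau_eta))
    lo_a, hi_a = fit_result.train_range["age"]
    lo_h, hi_h = fit_result.train_range["height"]
    span_a, span_h = hi_a - lo_a, hi_h - lo_h
    ta, th = covs["age"], covs["height"]
    extrap = (
        (ta < lo_a - 0.05 * span_a) | (ta > hi_a + 0.05 * span_a)
        | (th < lo_h - 0.05 * span_h) | (th > hi_h + 0.05 * span_h)
    )
    return out, extrap


def centile(fit_result: FitResult, age, height, alpha):
    """Fitted percentile curve value(s) in mmHg at (age, height)."""
    pars, _ = predict_params(fit_result, age, height)
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise ValueError("alpha must lie in (0, 1)")
    if fit_result.family == "BCPE":
        tau = np.exp(fit_result.tau_eta)
        z = stats.gennorm.ppf(alpha, tau, scale=_pe_scale(tau))
    else:
        z = stats.norm.ppf(alpha)
    mu, sigma, nu = pars["mu"], pars["sigma"], pars["nu"]
    small = np.abs(nu) < _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    arg = 1.0 + nu * sigma * z
    if np.any(~small & (arg <= 0)):
        raise ValueError("Box-Cox argument <= 0: percentile undefined")
    out = np.where(small, mu * np.exp(sigma * z),
                   mu * np.exp(np.log(np.where(arg > 0, arg, 1.0)) / nu_safe))
    return out if out.shape else float(out)
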