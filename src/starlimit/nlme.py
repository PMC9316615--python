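"""Nonlinear mixed-effects fitting of learning curves.

The model for the composite score of subject ``i`` on trial ``t`` with
device ``d`` is

    y_{idt} = f(t; P0_d, A_d + a_i, r_d + rho_i, c_d) + eps_{idt}

where ``f`` is one of the saturating curves in :mod:`starlimit.curves`,
``(a_i, rho_i)`` are independent Gaussian per-subject deviations on the
plateau ``A`` and the rate ``r`` (diagonal covariance, shared across the two
devices within a subject), and ``eps`` is Gaussian residual noise.  Fixed
effects are device-specific for ``A`` and ``r``; ``P0`` and ``c`` may be
pooled across devices (the default) or freed per device.

Estimation maximizes the Laplace-approximated marginal likelihood: the
per-subject random-effect integral is replaced by its value at the posterior
mode with a Gaussian curvature correction, the mode being located by a
damped (Gauss-Newton backed) Newton iteration vectorized across subjects.
Standard errors come from the observed information (numerical Hessian of the
marginal log-likelihood at the optimum); degrees of freedom for fixed-effect
t statistics use the containment heuristic ``n_subjects - n_fixed``.

Multistart (jittered copies of data-driven starting values with fixed
sub-seeds) guards against local optima; the best log-likelihood wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .curves import CurveSpec, get_curve

__all__ = [
    "NLMEFit",
    "fit_nlme",
    "compare_models",
    "predict_fixed_curve",
    "marginal_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)
_SD_FLOOR = 1e-4  # lower bound for standard deviations on the log scale
_SINGULAR_SD = 1e-2  # below this a random-effect sd is treated as zero


@dataclass
class NLMEFit:
    """A fitted nonlinear mixed-effects learning curve."""

    curve: str
    fixed: pd.DataFrame  # columns: param, device, estimate, se, df
    random_sd: Dict[str, float]
    resid_sd: float
    loglik: float
    aic: float
    n_subjects: int
    n_obs: int
    converged: bool
    shared: Tuple[str, ...]
    devices: Tuple[str, ...]
    notes: List[str] = field(default_factory=list)
    data_fingerprint: Tuple = ()
    theta: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None

    @property
    def k_params(self) -> int:
        return len(self.fixed) + len(self.random_sd) + 1

    def fixed_effect(self, param: str, device: Optional[str] = None):
        """Return (estimate, se, df) for a fixed effect.

        ``device`` is ignored for pooled parameters.
        """
        rows = self.fixed[self.fixed["param"] == param]
        if rows.empty:
            raise KeyError(f"no fixed effect for parameter {param!r}")
        if len(rows) > 1:
            if device is None:
                raise KeyError(f"parameter {param!r} is device-specific; name a device")
            rows = rows[rows["device"] == device]
            if rows.empty:
                raise KeyError(f"no {param!r} estimate for device {device!r}")
        row = rows.iloc[0]
        return float(row["estimate"]), float(row["se"]), float(row["df"])


class _Panel:
    """Padded per-subject arrays (n_subjects x max_trials) with mask."""

    def __init__(self, frame: pd.DataFrame, devices: Sequence[str]):
        self.subjects = list(pd.unique(frame["subject_id"]))
        self.devices = tuple(devices)
        n = len(self.subjects)
        counts = frame.groupby("subject_id", sort=False).size()
        m = int(counts.max())
        self.t = np.ones((n, m))
        self.y = np.zeros((n, m))
        self.dev = np.zeros((n, m), dtype=int)
        self.mask = np.zeros((n, m), dtype=bool)
        dev_code = {d: k for k, d in enumerate(self.devices)}
        for i, sid in enumerate(self.subjects):
            sub = frame[frame["subject_id"] == sid]
            mi = len(sub)
            self.t[i, :mi] = sub["trial"].to_numpy(dtype=float)
            self.y[i, :mi] = sub["score"].to_numpy(dtype=float)
            self.dev[i, :mi] = [dev_code[d] for d in sub["device"]]
            self.mask[i, :mi] = True
        self.n_subjects = n
        self.n_obs = int(self.mask.sum())
        self.m_per_subject = self.mask.sum(axis=1)


class _Layout:
    """Maps the flat parameter vector theta to curve parameters per obs."""

    def __init__(self, curve: CurveSpec, devices: Sequence[str], shared: Sequence[str]):
        self.curve = curve
        self.devices = tuple(devices)
        self.entries: List[Tuple[str, Optional[str]]] = []
        for p in curve.param_names:
            if p in shared or len(self.devices) == 1:
                self.entries.append((p, None))
            else:
                for d in self.devices:
                    self.entries.append((p, d))
        self.n_fixed = len(self.entries)
        # indices into theta for each curve param, per device code
        self.index: Dict[str, np.ndarray] = {}
        for p in curve.param_names:
            idx = []
            for dcode, d in enumerate(self.devices):
                for j, (pp, dd) in enumerate(self.entries):
                    if pp == p and (dd is None or dd == d):
                        idx.append(j)
                        break
            self.index[p] = np.array(idx, dtype=int)

    def obs_params(self, fixed: np.ndarray, panel: _Panel) -> List[np.ndarray]:
        """Per-observation curve parameter arrays (before random effects)."""
        return [fixed[self.index[p]][panel.dev] for p in self.curve.param_names]


class _LaplaceEngine:
    """Laplace-approximated marginal log-likelihood, vectorized over subjects."""

    def __init__(
        self,
        curve: CurveSpec,
        panel: _Panel,
        layout: _Layout,
        re_params: Sequence[str] = ("A", "r"),
    ):
        self.curve = curve
        self.panel = panel
        self.layout = layout
        self.re_params = tuple(re_params)
        self.re_idx = [curve.param_names.index(p) for p in self.re_params]
        self.d = len(self.re_params)
        self.u_cache = np.zeros((panel.n_subjects, self.d))

    # -- conditional model pieces -------------------------------------------
    def _with_re(self, base_params: List[np.ndarray], u: np.ndarray) -> List[np.ndarray]:
        params = [p.copy() for p in base_params]
        for k, j in enumerate(self.re_idx):
            params[j] = params[j] + u[:, k : k + 1]
        return params

    def _rss(self, base_params, u) -> np.ndarray:
        f = self.curve._value(self._with_re(base_params, u), self.panel.t)
        w = np.where(self.panel.mask, self.panel.y - f, 0.0)
        return np.einsum("ij,ij->i", w, w)

    def _q(self, base_params, u, sig_re, sig_e) -> np.ndarray:
        """Per-subject negative joint log-density (y, u)."""
        rss = self._rss(base_params, u)
        m = self.panel.m_per_subject
        out = 0.5 * m * (_LOG2PI + 2.0 * np.log(sig_e)) + rss / (2.0 * sig_e**2)
        for k in range(self.d):
            out += (
                0.5 * (_LOG2PI + 2.0 * np.log(sig_re[k]))
                + u[:, k] ** 2 / (2.0 * sig_re[k] ** 2)
            )
        return out

    def _q_subset(self, base_params, u_sub, sig_re, sig_e, idx):
        """q for a subset of subjects (rows ``idx``), given their u rows."""
        params = []
        for k, p in enumerate(base_params):
            params.append(p[idx])
        for k, j in enumerate(self.re_idx):
            params[j] = params[j] + u_sub[:, k : k + 1]
        f = self.curve._value(params, self.panel.t[idx])
        mask = self.panel.mask[idx]
        w = np.where(mask, self.panel.y[idx] - f, 0.0)
        rss = np.einsum("ij,ij->i", w, w)
        m = self.panel.m_per_subject[idx]
        out = 0.5 * m * (_LOG2PI + 2.0 * np.log(sig_e)) + rss / (2.0 * sig_e**2)
        for k in range(self.d):
            out += (
                0.5 * (_LOG2PI + 2.0 * np.log(sig_re[k]))
                + u_sub[:, k] ** 2 / (2.0 * sig_re[k] ** 2)
            )
        return out

    def _grad_q(self, base_params, u, sig_re, sig_e):
        """Gradient of q wrt u, plus Gauss-Newton Hessian blocks."""
        params = self._with_re(base_params, u)
        f = self.curve._value(params, self.panel.t)
        G = self.curve._grad(params, self.panel.t)  # (n_params, n, m)
        J = np.stack([G[j] for j in self.re_idx])  # (d, n, m)
        J = np.where(self.panel.mask[None], J, 0.0)
        w = np.where(self.panel.mask, self.panel.y - f, 0.0)
        g = -np.einsum("kij,ij->ik", J, w) / sig_e**2
        H = np.einsum("kij,lij->ikl", J, J) / sig_e**2
        for k in range(self.d):
            g[:, k] += u[:, k] / sig_re[k] ** 2
            H[:, k, k] += 1.0 / sig_re[k] ** 2
        return g, H

    def _hess_q_fd(self, base_params, u, sig_re, sig_e) -> np.ndarray:
        """Exact-curvature Hessian of q via central differences of the gradient."""
        n = self.panel.n_subjects
        H = np.empty((n, self.d, self.d))
        for k in range(self.d):
            h = 1e-4 * (1.0 + np.abs(u[:, k]))
            up = u.copy()
            up[:, k] += h
            um = u.copy()
            um[:, k] -= h
            gp, _ = self._grad_q(base_params, up, sig_re, sig_e)
            gm, _ = self._grad_q(base_params, um, sig_re, sig_e)
            H[:, :, k] = (gp - gm) / (2.0 * h[:, None])
        return 0.5 * (H + H.transpose(0, 2, 1))

    # -- mode finding --------------------------------------------------------
    def _find_modes(self, base_params, sig_re, sig_e, max_iter=60, tol=1e-12):
        if self.d == 0:
            return self.u_cache.copy()
        u = self.u_cache.copy()
        q = self._q(base_params, u, sig_re, sig_e)
        active = np.ones(self.panel.n_subjects, dtype=bool)
        for _ in range(max_iter):
            g, H = self._grad_q(base_params, u, sig_re, sig_e)
            step = np.zeros_like(u)
            step[active] = -np.linalg.solve(H[active], g[active, :, None])[..., 0]
            # stop subjects whose Newton decrement is below the q-scale tol
            decrement = -0.5 * np.einsum("ik,ik->i", g, step)
            active &= decrement > tol
            if not active.any():
                break
            alpha = np.ones(self.panel.n_subjects)
            pending = active.copy()
            for _ in range(20):
                idx = np.flatnonzero(pending)
                trial_u = u[idx] + alpha[idx, None] * step[idx]
                sub_q = self._q_subset(base_params, trial_u, sig_re, sig_e, idx)
                better = sub_q < q[idx] - 1e-13
                good = idx[better]
                u[good] = trial_u[better]
                q[good] = sub_q[better]
                pending[good] = False
                if not pending.any():
                    break
                alpha[pending] *= 0.5
            # subjects that could not improve at any step length are at the mode
            active &= ~pending
        self.u_cache = u
        return u

    def neg_loglik(self, theta: np.ndarray) -> float:
        fixed = theta[: self.layout.n_fixed]
        sig_re = np.exp(theta[self.layout.n_fixed : self.layout.n_fixed + self.d])
        sig_e = float(np.exp(theta[-1]))
        base_params = self.layout.obs_params(fixed, self.panel)
        u = self._find_modes(base_params, sig_re, sig_e)
        q = self._q(base_params, u, sig_re, sig_e)
        if self.d == 0:
            loglik = -float(np.sum(q))
            return -loglik if np.isfinite(loglik) else 1e10
        H = self._hess_q_fd(base_params, u, sig_re, sig_e)
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            # fall back to the always-PD Gauss-Newton curvature
            _, Hgn = self._grad_q(base_params, u, sig_re, sig_e)
            bad = sign <= 0
            sgn2, ld2 = np.linalg.slogdet(Hgn)
            logdet = np.where(bad, ld2, logdet)
        loglik = np.sum(-q + 0.5 * self.d * _LOG2PI - 0.5 * logdet)
        if not np.isfinite(loglik):
            return 1e10
        return -float(loglik)


def _starting_theta(
    frame: pd.DataFrame, curve: CurveSpec, layout: _Layout, re_params: Sequence[str]
) -> np.ndarray:
    by_dev_first = frame[frame["trial"] == frame["trial"].min()].groupby("device")[
        "score"
    ].mean()
    tmax = frame["trial"].max()
    last3 = frame[frame["trial"] >= tmax - 2]
    by_dev_last = last3.groupby("device")["score"].mean()
    subj_last = last3.groupby("subject_id")["score"].mean()
    fixed = np.zeros(layout.n_fixed)
    for j, (p, d) in enumerate(layout.entries):
        if p == "P0":
            fixed[j] = by_dev_first.get(d, by_dev_first.mean())
        elif p == "A":
            fixed[j] = by_dev_last.get(d, by_dev_last.mean())
        elif p == "r":
            fixed[j] = 0.0
        elif p == "c":
            fixed[j] = 1.0
    sd_A0 = max(float(subj_last.std(ddof=1)) if len(subj_last) > 1 else 1.0, 1.0)
    sd_r0 = 0.2
    sd_e0 = max(float(frame["score"].std(ddof=1)) / 2.0, 1.0)
    re_sd0 = {"A": sd_A0, "r": sd_r0}
    return np.concatenate(
        [fixed, np.log([re_sd0.get(p, 0.5) for p in re_params]), [np.log(sd_e0)]]
    )


def _bounds(layout: _Layout, curve: CurveSpec, d: int):
    bounds = []
    for p, _ in layout.entries:
        if p in curve.positive_params:
            bounds.append((1e-3, 20.0))
        elif p == "r":
            bounds.append((-20.0, 20.0))
        else:
            bounds.append((None, None))
    bounds += [(np.log(_SD_FLOOR), np.log(1e3))] * (d + 1)
    return bounds


def _numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xp = x.copy()
        xp[i] += h[i]
        xm = x.copy()
        xm[i] -= h[i]
        fp[i] = fun(xp)
        fm[i] = fun(xm)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = x.copy()
            xpp[[i, j]] += h[[i, j]]
            xmm = x.copy()
            xmm[[i, j]] -= h[[i, j]]
            H[i, j] = H[j, i] = (
                fun(xpp) - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fun(xmm)
            ) / (2.0 * h[i] * h[j])
    return H


def fit_nlme(
    frame: pd.DataFrame,
    curve,
    shared: Sequence[str] = ("P0", "c"),
    re_params: Sequence[str] = ("A", "r"),
    n_starts: int = 5,
    seed: int = 0,
    score_col: str = "score",
    compute_se: bool = True,
) -> NLMEFit:
    """Fit a saturating curve to trial scores by Laplace-approximate ML.

    ``frame`` needs columns ``subject_id``, ``device``, ``trial`` and the
    score column.  ``shared`` lists curve parameters pooled across devices;
    ``A`` and ``r`` are always device-specific when two devices are present.
    Non-convergence is flagged, never silent; a random-effect standard
    deviation estimated at (numerically) zero triggers a refit with that
    random effect pinned at zero, recorded in ``notes``.
    """
    if isinstance(curve, str):
        curve = get_curve(curve)
    frame = frame.rename(columns={score_col: "score"})[
        ["subject_id", "device", "trial", "score"]
    ].copy()
    if not np.all(np.isfinite(frame["score"])):
        raise ValueError("scores must be finite")
    devices = tuple(d for d in ("exoscope", "microscope") if d in set(frame["device"]))
    if not devices:
        devices = tuple(sorted(set(frame["device"])))
    panel = _Panel(frame, devices)
    if panel.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    per = frame.groupby(["subject_id", "device"]).size()
    if per.min() < 3:
        raise ValueError("need at least 3 trials per subject-device")
    re_params = tuple(p for p in re_params if p in curve.param_names)
    layout = _Layout(curve, devices, shared)
    engine = _LaplaceEngine(curve, panel, layout, re_params)
    theta0 = _starting_theta(frame, curve, layout, re_params)
    bounds = _bounds(layout, curve, len(re_params))

    rng = np.random.default_rng(seed)
    # start 1 is data-driven; start 2 (when n_starts >= 2) pins the
    # random-effect SDs near zero so boundary (singular) solutions are
    # reachable; further starts jitter the data-driven values
    theta_small = theta0.copy()
    theta_small[layout.n_fixed : layout.n_fixed + len(re_params)] = np.log(5e-3)
    starts = [theta0, theta_small]
    best = None
    for s in range(max(1, int(n_starts))):
        th = starts[s].copy() if s < 2 else theta0.copy()
        if s >= 2:
            jitter = rng.normal(size=th.shape)
            scales = np.concatenate(
                [
                    np.array(
                        [2.0 if p in ("P0", "A") else 0.3 for p, _ in layout.entries]
                    ),
                    0.3 * np.ones(len(re_params) + 1),
                ]
            )
            th = th + jitter * scales
        th = np.clip(
            th,
            [b[0] if b[0] is not None else -np.inf for b in bounds],
            [b[1] if b[1] is not None else np.inf for b in bounds],
        )
        engine.u_cache[:] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                engine.neg_loglik,
                th,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 400, "eps": 1e-5, "maxfun": 20000},
            )
        if best is None or res.fun < best.fun:
            best = res
    res = best
    # polish with a finer finite-difference step; matters when the surface
    # is steep (near-zero residual variance)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polish = minimize(
            engine.neg_loglik,
            res.x,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "eps": 1e-7, "maxfun": 10000},
        )
    if polish.fun <= res.fun:
        polish.success = polish.success or res.success
        res = polish

    notes: List[str] = []
    sd_re = np.exp(res.x[layout.n_fixed : layout.n_fixed + len(re_params)])
    singular = [p for p, sd in zip(re_params, sd_re) if sd < _SINGULAR_SD]
    if singular:
        kept = tuple(p for p in re_params if p not in singular)
        notes.append(
            f"random-effect sd for {singular} estimated at zero; refit with it pinned"
        )
        refit = fit_nlme(
            frame, curve, shared=shared, re_params=kept, n_starts=n_starts,
            seed=seed, compute_se=compute_se,
        )
        refit.notes = notes + refit.notes
        for p in singular:
            refit.random_sd[p] = 0.0
        return refit

    loglik = -float(res.fun)
    k = layout.n_fixed + len(re_params) + 1
    aic = 2.0 * k - 2.0 * loglik

    if compute_se:
        hess = _numeric_hessian(engine.neg_loglik, res.x)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        diag = np.diag(cov)
        ok_se = np.all(np.isfinite(diag[: layout.n_fixed])) and np.all(
            diag[: layout.n_fixed] > 0
        )
        if not ok_se:
            notes.append("observed information not positive definite; SEs unreliable")
            diag = np.abs(diag)
        ses = np.sqrt(diag[: layout.n_fixed])
    else:
        cov = None
        ok_se = True
        ses = np.full(layout.n_fixed, np.nan)
    df = max(panel.n_subjects - layout.n_fixed, 1)
    fixed_tbl = pd.DataFrame(
        {
            "param": [p for p, _ in layout.entries],
            "device": [d if d is not None else "(pooled)" for _, d in layout.entries],
            "estimate": res.x[: layout.n_fixed],
            "se": ses,
            "df": float(df),
        }
    )
    random_sd = {p: float(sd) for p, sd in zip(re_params, sd_re)}
    fingerprint = (panel.n_subjects, panel.n_obs, round(float(frame["score"].sum()), 6))
    return NLMEFit(
        curve=curve.name,
        fixed=fixed_tbl,
        random_sd=random_sd,
        resid_sd=float(np.exp(res.x[-1])),
        loglik=loglik,
        aic=aic,
        n_subjects=panel.n_subjects,
        n_obs=panel.n_obs,
        converged=bool(res.success) and ok_se,
        shared=tuple(shared),
        devices=devices,
        notes=notes,
        data_fingerprint=fingerprint,
        theta=res.x.copy(),
        cov=cov,
    )


def marginal_loglik(
    frame: pd.DataFrame,
    curve,
    fixed: Dict[str, object],
    random_sd: Dict[str, float],
    resid_sd: float,
    shared: Sequence[str] = ("P0", "c"),
    score_col: str = "score",
) -> float:
    """Laplace marginal log-likelihood at given parameter values (no fitting).

    ``fixed`` maps each curve parameter to a value, or to a
    ``{device: value}`` dict for device-specific effects.  Useful for
    diagnostics and for checking the approximation against numerical
    integration on small instances.
    """
    if isinstance(curve, str):
        curve = get_curve(curve)
    frame = frame.rename(columns={score_col: "score"})[
        ["subject_id", "device", "trial", "score"]
    ].copy()
    devices = tuple(d for d in ("exoscope", "microscope") if d in set(frame["device"]))
    if not devices:
        devices = tuple(sorted(set(frame["device"])))
    panel = _Panel(frame, devices)
    re_params = tuple(p for p in random_sd if p in curve.param_names)
    layout = _Layout(curve, devices, shared)
    engine = _LaplaceEngine(curve, panel, layout, re_params)
    vec = np.zeros(layout.n_fixed)
    for j, (p, d) in enumerate(layout.entries):
        v = fixed[p]
        vec[j] = float(v[d]) if isinstance(v, dict) else float(v)
    theta = np.concatenate(
        [vec, np.log([random_sd[p] for p in re_params]), [np.log(resid_sd)]]
    )
    return -engine.neg_loglik(theta)


def compare_models(fits: Sequence[NLMEFit]) -> pd.DataFrame:
    """Rank fitted curves by AIC (ascending), log-likelihood alongside.

    All fits must come from the same data; ties order alphabetically.
    """
    if not fits:
        raise ValueError("no fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits were produced on different datasets")
    tbl = pd.DataFrame(
        {
            "curve": [f.curve for f in fits],
            "aic": [f.aic for f in fits],
            "loglik": [f.loglik for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    tbl = tbl.sort_values(["aic", "curve"], kind="mergesort").reset_index(drop=True)
    tbl.index = tbl.index + 1
    tbl.index.name = "rank"
    return tbl


def predict_fixed_curve(fit: NLMEFit, device: str, t_grid) -> np.ndarray:
    """Population-average trajectory for one device at the fixed effects."""
    if device not in fit.devices:
        raise KeyError(f"device {device!r} not in fit (has {fit.devices})")
    curve = get_curve(fit.curve)
    params = []
    for p in curve.param_names:
        rows = fit.fixed[fit.fixed["param"] == p]
        if len(rows) > 1:
            rows = rows[rows["device"] == device]
        params.append(float(rows.iloc[0]["estimate"]))
    return curve.value(params, np.asarray(t_grid, dtype=float))
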