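"""Variational Laplace inversion of a modulation model against two-condition
evoked responses.

A model (one binary modulation pattern over connection groups) is fitted
jointly to the baseline-condition and modulated-condition evoked responses
over a peristimulus window (default 1-200 ms).  Free parameters are
log-scaling factors — extrinsic connection strengths (tied within mirrored
groups), condition gains on switched-on groups, self-connection condition
gains, and the exogenous input amplitude — so positivity is structural.
Under Gaussian priors on the log-parameters and Gaussian sensor noise with
one precision hyperparameter per condition, a Gauss-Newton ascent with
Levenberg-Marquardt damping maximizes the variational free energy

    F = accuracy - complexity
      = E_q[log p(y | theta)] - KL(q(theta) || p(theta)) - prior penalty on
        the noise log-precisions,

which lower-bounds the log model evidence and is the model-comparison score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import Evoked
from .dynamics import DCMParameters, InstabilityError, simulate_sources
from .forward import LeadField
from .network import ModelSpace

__all__ = [
    "PriorSpec",
    "DCMPosterior",
    "build_parameterization",
    "predict_response",
    "invert",
    "free_energy",
    "gaussian_kl",
]

log = logging.getLogger(__name__)

MAX_ITER = 64
F_TOL = 0.01
N_CONVERGED = 3
LAMBDA_MAX = 32.0


@dataclass
class PriorSpec:
    """Prior variances per parameter class (log-scale parameters, mean 0)."""

    extrinsic_var: float = 1.0 / 16.0
    gain_var: float = 1.0 / 16.0
    input_var: float = 1.0 / 16.0
    noise_lambda_mean: float = 0.0
    noise_lambda_var: float = 32.0


@dataclass
class DCMPosterior:
    """Gaussian posterior over the estimated log-parameters."""

    param_names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    lambdas: np.ndarray  # noise log-precision per condition (scaled data)
    model_index: int
    n_iterations: int
    converged: bool
    fit_window_ms: tuple[float, float]
    gain_map: dict[str, list[str]] = field(default_factory=dict)
    data_scale: float = 1.0
    f_history: list = field(default_factory=list)  # accepted-iteration free energies

    def to_json(self) -> dict:
        return {
            "param_names": self.param_names,
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "free_energy": self.free_energy,
            "lambdas": self.lambdas.tolist(),
            "model_index": int(self.model_index),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "fit_window_ms": list(self.fit_window_ms),
            "gain_map": self.gain_map,
            "data_scale": self.data_scale,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DCMPosterior":
        return cls(
            param_names=list(obj["param_names"]),
            mean=np.asarray(obj["mean"], float),
            cov=np.asarray(obj["cov"], float),
            free_energy=float(obj["free_energy"]),
            lambdas=np.asarray(obj["lambdas"], float),
            model_index=int(obj["model_index"]),
            n_iterations=int(obj["n_iterations"]),
            converged=bool(obj["converged"]),
            fit_window_ms=tuple(obj["fit_window_ms"]),
            gain_map={k: list(v) for k, v in obj["gain_map"].items()},
            data_scale=float(obj.get("data_scale", 1.0)),
        )


# ---------------------------------------------------------------------------
# Parameterization


@dataclass
class Parameterization:
    """Maps a flat log-parameter vector onto DCMParameters."""

    names: list[str]
    prior_mean: np.ndarray
    prior_var: np.ndarray
    gain_map: dict[str, list[str]]  # gain param -> modulated connection names
    _appliers: list = field(default_factory=list)

    def apply(self, base: DCMParameters, theta: np.ndarray) -> DCMParameters:
        p = base.copy()
        for f, th in zip(self._appliers, theta):
            f(p, float(th))
        return p


def build_parameterization(
    space: ModelSpace, pattern: np.ndarray, priors: PriorSpec
) -> Parameterization:
    """Free parameters for one model.

    * one extrinsic log-scale per connection group (applied to every member
      connection's A strength);
    * one condition log-gain per switched-ON group (B of member connections,
      or the self-gains for an explicit self group);
    * per-node self log-gains when the space has no explicit self group
      (self-connection modulation is then estimated in every model);
    * one input log-amplitude.
    """
    names: list[str] = []
    pm: list[float] = []
    pv: list[float] = []
    appliers: list = []
    gain_map: dict[str, list[str]] = {}

    def add(name, var, fn):
        names.append(name)
        pm.append(0.0)
        pv.append(var)
        appliers.append(fn)

    for grp in space.groups:
        if grp.kind == "self-group":
            continue
        conns = [c.name for c in grp.members]

        def scale_A(p, th, conns=conns):
            for cn in conns:
                p.A[cn] = p.A[cn] * np.exp(th)

        add(f"a:{grp.name}", priors.extrinsic_var, scale_A)

    has_self_group = any(g.kind == "self-group" for g in space.groups)
    for grp, on in zip(space.groups, pattern):
        if not on:
            continue
        if grp.kind == "self-group":
            nodes = [c.source for c in grp.members]

            def set_selfB(p, th, nodes=nodes):
                for nd in nodes:
                    p.self_B[nd] = np.exp(th)

            add("b:self", priors.gain_var, set_selfB)
            gain_map["b:self"] = [f"{n}->{n}" for n in nodes]
        else:
            conns = [c.name for c in grp.members]

            def set_B(p, th, conns=conns):
                for cn in conns:
                    p.B[cn] = np.exp(th)

            add(f"b:{grp.name}", priors.gain_var, set_B)
            gain_map[f"b:{grp.name}"] = conns

    if not has_self_group:
        for node in space.network.node_names:

            def set_nodeB(p, th, node=node):
                p.self_B[node] = np.exp(th)

            add(f"b:self:{node}", priors.gain_var, set_nodeB)
            gain_map[f"b:self:{node}"] = [f"{node}->{node}"]

    def scale_amp(p, th):
        p.input_amplitude = p.input_amplitude * np.exp(th)

    add("u:amp", priors.input_var, scale_amp)

    return Parameterization(
        names=names,
        prior_mean=np.array(pm),
        prior_var=np.array(pv),
        gain_map=gain_map,
        _appliers=appliers,
    )


# ---------------------------------------------------------------------------
# Prediction


def predict_response(
    params: DCMParameters,
    pattern: np.ndarray,
    space: ModelSpace,
    leadfield: LeadField,
    window_ms: tuple[float, float] = (1.0, 200.0),
    dt: float = 1.0 / 480.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless two-condition sensor predictions over the fit window.

    Returns (times_ms, predictions) with predictions shaped
    (2, n_sensors, n_times); condition order (baseline, modulated).
    """
    preds = []
    for condition in ("baseline", "modulated"):
        act = simulate_sources(
            params, pattern, space, condition, duration_ms=window_ms[1] + 5.0, dt=dt
        )
        m = (act.times_ms >= window_ms[0] - 1e-9) & (act.times_ms <= window_ms[1] + 1e-9)
        sensor = leadfield.gain.T @ act.values[m].T
        preds.append(sensor)
        times_ms = act.times_ms[m]
    return times_ms, np.stack(preds)


# ---------------------------------------------------------------------------
# Free-energy pieces


def gaussian_kl(
    mu_q: np.ndarray, cov_q: np.ndarray, mu_p: np.ndarray, cov_p_diag: np.ndarray
) -> float:
    """KL(q || p) between a full-covariance Gaussian q and a diagonal
    Gaussian prior p."""
    p = mu_q.size
    P0 = 1.0 / cov_p_diag
    e = mu_q - mu_p
    sign, logdet_q = np.linalg.slogdet(cov_q)
    if sign <= 0:
        raise ValueError("posterior covariance must be positive definite")
    logdet_p = float(np.sum(np.log(cov_p_diag)))
    return 0.5 * (
        float(np.sum(P0 * np.diag(cov_q))) + float(e @ (P0 * e)) - p + logdet_p - logdet_q
    )


def _accuracy_terms(
    resid_c: list[np.ndarray], JtJ_c: list[np.ndarray], cov: np.ndarray, lambdas: np.ndarray
) -> float:
    acc = 0.0
    for r, JtJ, lam in zip(resid_c, JtJ_c, lambdas):
        N = r.size
        pi = np.exp(lam)
        acc += -0.5 * pi * (float(r @ r) + float(np.sum(JtJ * cov)))
        acc += 0.5 * N * (lam - np.log(2.0 * np.pi))
    return acc


def _lambda_penalty(lambdas: np.ndarray, priors: PriorSpec) -> float:
    d = lambdas - priors.noise_lambda_mean
    return -0.5 * float(np.sum(d * d)) / priors.noise_lambda_var


def _update_lambdas(
    resid_c: list[np.ndarray], JtJ_c: list[np.ndarray], cov: np.ndarray, priors: PriorSpec
) -> np.ndarray:
    """MAP noise log-precisions given the current posterior (Newton steps on
    the free energy, which is concave in lambda)."""
    out = np.empty(len(resid_c))
    for i, (r, JtJ) in enumerate(zip(resid_c, JtJ_c)):
        N = r.size
        s = float(r @ r) + float(np.sum(JtJ * cov))
        s = max(s, 1e-300)
        lam = min(np.log(N / s), LAMBDA_MAX)
        for _ in range(5):
            g = -0.5 * np.exp(lam) * s + 0.5 * N - (lam - priors.noise_lambda_mean) / priors.noise_lambda_var
            h = -0.5 * np.exp(lam) * s - 1.0 / priors.noise_lambda_var
            lam = min(lam - g / h, LAMBDA_MAX)
        out[i] = lam
    return out


# ---------------------------------------------------------------------------
# Inversion


def invert(
    data: tuple[Evoked, Evoked],
    pattern: np.ndarray,
    space: ModelSpace,
    leadfield: LeadField,
    base_params: DCMParameters,
    priors: PriorSpec | None = None,
    window_ms: tuple[float, float] = (1.0, 200.0),
    model_index: int = -1,
    seed: int = 0,
    max_iter: int = MAX_ITER,
    fd_step: float = 1e-3,
) -> DCMPosterior:
    """Fit one modulation model to a (baseline, modulated) evoked pair.

    Gauss-Newton/EM ascent on the variational free energy with
    Levenberg-Marquardt damping; deterministic given the inputs.  On
    non-convergence the last accepted iterate is returned with
    ``converged=False`` (never an exception); singular curvature is
    ridge-regularized with a log entry.
    """
    priors = priors or PriorSpec()
    par = build_parameterization(space, pattern, priors)
    p = len(par.names)

    y_c = []
    for ev in data:
        cropped = ev.crop(*window_ms)
        y_c.append(cropped.data.ravel())
        if cropped.data.shape[1] == 0:
            raise ValueError("data window does not cover the fit window")
    scale = float(np.sqrt(np.mean(np.concatenate(y_c) ** 2)))
    if not np.isfinite(scale):
        raise ValueError("non-finite data")
    if scale == 0:
        scale = 1.0
    y_c = [y / scale for y in y_c]

    def predict(theta: np.ndarray) -> list[np.ndarray]:
        params = par.apply(base_params, theta)
        _, preds = predict_response(params, pattern, space, leadfield, window_ms)
        n_t = y_c[0].size // leadfield.gain.shape[1]
        if preds.shape[2] != n_t:
            preds = preds[:, :, :n_t]
        return [preds[0].ravel() / scale, preds[1].ravel() / scale]

    theta = par.prior_mean.copy()
    P0 = 1.0 / par.prior_var

    def jacobian(theta: np.ndarray, g0: list[np.ndarray]) -> list[np.ndarray]:
        J = [np.empty((y.size, p)) for y in y_c]
        for k in range(p):
            th = theta.copy()
            th[k] += fd_step
            gk = predict(th)
            for c in range(2):
                J[c][:, k] = (gk[c] - g0[c]) / fd_step
        return J

    nu = 1e-4  # LM damping
    lambdas = np.full(2, priors.noise_lambda_mean)
    g0 = predict(theta)
    resid = [y - g for y, g in zip(y_c, g0)]
    J = jacobian(theta, g0)
    JtJ = [j.T @ j for j in J]
    cov = np.diag(par.prior_var.copy())
    lambdas = _update_lambdas(resid, JtJ, cov, priors)
    F = -np.inf
    f_history: list[float] = []
    converged = False
    n_small = 0
    n_it = 0

    for n_it in range(1, max_iter + 1):
        pis = np.exp(lambdas)
        H = sum(pi * jtj for pi, jtj in zip(pis, JtJ)) + np.diag(P0)
        grad = sum(
            pi * (j.T @ r) for pi, j, r in zip(pis, J, resid)
        ) - P0 * (theta - par.prior_mean)

        accepted = False
        best_rejected = -np.inf
        for _ in range(8):
            Hd = H + nu * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                log.info("singular curvature; adding ridge")
                step = np.linalg.solve(Hd + 1e-6 * np.eye(p), grad)
            theta_new = theta + step
            try:
                g_new = predict(theta_new)
            except InstabilityError:
                nu = min(nu * 10.0, 1e8)
                continue
            resid_new = [y - g for y, g in zip(y_c, g_new)]
            J_new = jacobian(theta_new, g_new)
            JtJ_new = [j.T @ j for j in J_new]
            H_new = sum(
                pi * jtj for pi, jtj in zip(np.exp(lambdas), JtJ_new)
            ) + np.diag(P0)
            try:
                cov_new = np.linalg.inv(H_new)
            except np.linalg.LinAlgError:
                cov_new = np.linalg.inv(H_new + 1e-6 * np.eye(p))
            lam_new = _update_lambdas(resid_new, JtJ_new, cov_new, priors)
            F_new = (
                _accuracy_terms(resid_new, JtJ_new, cov_new, lam_new)
                - gaussian_kl(theta_new, cov_new, par.prior_mean, par.prior_var)
                + _lambda_penalty(lam_new, priors)
            )
            if F_new > F or not np.isfinite(F):
                theta, g0, resid, J, JtJ = theta_new, g_new, resid_new, J_new, JtJ_new
                cov, lambdas = cov_new, lam_new
                dF = F_new - F
                F = F_new
                f_history.append(float(F))
                nu = max(nu / 10.0, 1e-8)
                accepted = True
                break
            best_rejected = max(best_rejected, F_new)
            nu = min(nu * 10.0, 1e8)
        if not accepted:
            # no step improves F: at a (local) optimum when the surface is flat
            if np.isfinite(F) and F - best_rejected < F_TOL:
                converged = True
            break
        if np.isfinite(dF) and dF < F_TOL:
            n_small += 1
            if n_small >= N_CONVERGED:
                converged = True
                break
        else:
            n_small = 0

    if not converged:
        log.info("inversion stopped without formal convergence at iteration %d", n_it)
    cov = 0.5 * (cov + cov.T)
    return DCMPosterior(
        param_names=list(par.names),
        mean=theta,
        cov=cov,
        free_energy=float(F),
        lambdas=lambdas,
        model_index=model_index,
        n_iterations=n_it,
        converged=converged,
        fit_window_ms=window_ms,
        gain_map=par.gain_map,
        data_scale=scale,
        f_history=f_history,
    )


def free_energy(
    posterior: DCMPosterior,
    data: tuple[Evoked, Evoked],
    space: ModelSpace,
    pattern: np.ndarray,
    leadfield: LeadField,
    base_params: DCMParameters,
    priors: PriorSpec | None = None,
) -> float:
    """Recompute the free energy of a stored posterior against data.

    Accuracy (expected log-likelihood under the posterior, Gaussian noise at
    the stored precisions) minus complexity (KL posterior || prior, plus the
    noise-precision penalty).
    """
    priors = priors or PriorSpec()
    eig = np.linalg.eigvalsh(0.5 * (posterior.cov + posterior.cov.T))
    if eig.min() <= -1e-10 * max(1.0, eig.max()):
        raise ValueError("posterior covariance is not positive semi-definite")
    par = build_parameterization(space, pattern, priors)
    if par.names != posterior.param_names:
        raise ValueError("posterior does not match this model's parameterization")
    scale = posterior.data_scale
    y_c = [ev.crop(*posterior.fit_window_ms).data.ravel() / scale for ev in data]
    params = par.apply(base_params, posterior.mean)
    _, preds = predict_response(
        params, pattern, space, leadfield, posterior.fit_window_ms
    )
    g_c = [preds[0].ravel() / scale, preds[1].ravel() / scale]
    resid = [y[: g.size] - g for y, g in zip(y_c, g_c)]
    # Jacobian at the posterior mean for the trace (expected-energy) term
    J = []
    for k in range(len(par.names)):
        th = posterior.mean.copy()
        th[k] += 1e-3
        params_k = par.apply(base_params, th)
        _, preds_k = predict_response(
            params_k, pattern, space, leadfield, posterior.fit_window_ms
        )
        J.append(
            np.stack([(preds_k[c].ravel() / scale - g_c[c]) / 1e-3 for c in range(2)])
        )
    Jc = [np.column_stack([J[k][c] for k in range(len(J))]) for c in range(2)]
    JtJ = [j.T @ j for j in Jc]
    return (
        _accuracy_terms(resid, JtJ, posterior.cov, posterior.lambdas)
        - gaussian_kl(posterior.mean, posterior.cov, par.prior_mean, par.prior_var)
        + _lambda_penalty(posterior.lambdas, priors)
    )
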