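"""Multi-source Jansen-Rit neural mass dynamics with typed extrinsic coupling.

Each modelled source contains three neuronal populations — spiny stellate
cells, pyramidal cells and inhibitory interneurons — coupled through standard
second-order synaptic kernels:

    v'' = H * k * u(t) - 2 k v' - k^2 v,        k = 1 / tau

where ``u`` is presynaptic firing, ``H`` the synaptic gain (mV) and ``tau``
the time constant.  Firing is a sigmoid of membrane potential, expressed as a
deviation from baseline so the resting state sits at the origin.  Extrinsic
(between-source) connections follow laminar targeting rules: forward
connections drive the stellate population, backward connections drive the
pyramidal and inhibitory populations, lateral connections drive all three.
Inter-source conduction uses a single uniform delay.  The output of a source
is its pyramidal depolarization, the quantity seen by the sensor-level
forward model.

Condition-specific effects enter as multiplicative gains B on connection
strengths: B = 1 on a connection means the two experimental conditions are
indistinguishable on that connection.  Self-gains scale a source's
sensitivity to its extrinsic and exogenous inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .network import Connection, NetworkSpec, ModelSpace, enumerate_connections

__all__ = [
    "SigmoidParams",
    "DCMParameters",
    "SourceActivity",
    "InstabilityError",
    "sigmoid_rate",
    "exogenous_input",
    "effective_connectivity",
    "simulate_sources",
    "default_parameters",
]

CONDITIONS = ("baseline", "modulated")


class InstabilityError(RuntimeError):
    """Raised when the integration diverges for a parameter draw."""


@dataclass(frozen=True)
class SigmoidParams:
    e0: float = 2.5  # half of the maximum firing rate, 1/s
    v0: float = 6.0  # potential at half-maximum, mV
    r: float = 0.56  # slope, 1/mV


@dataclass
class DCMParameters:
    """Generative-model parameters for one network.

    Extrinsic strengths ``A`` and condition gains ``B`` are keyed by
    connection name ("LOCC->LvOT").  ``self_gain`` (baseline) and
    ``self_B`` (condition gain) are keyed by node name.  ``C`` holds
    exogenous input gains per node (nonzero at the occipital sources by
    default).  Synaptic constants are shared across sources.
    """

    network: NetworkSpec
    A: dict[str, float]
    B: dict[str, float]
    C: dict[str, float]
    self_gain: dict[str, float]
    self_B: dict[str, float]
    H_e: float = 3.25  # mV
    H_i: float = 22.0  # mV
    tau_e: float = 0.010  # s
    tau_i: float = 0.020  # s
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    # intrinsic coupling constants (classic Jansen-Rit ratios)
    gamma1: float = 135.0
    gamma2: float = 108.0
    gamma3: float = 33.75
    gamma4: float = 33.75
    # inter-source conduction delay; default is 8 samples at the 480 Hz
    # recording grid so the delayed coupling is exact on the default step
    delay_ms: float = 8000.0 / 480.0
    input_onset_ms: float = 60.0
    input_width_ms: float = 16.0
    input_amplitude: float = 150.0

    def copy(self) -> "DCMParameters":
        return replace(
            self,
            A=dict(self.A),
            B=dict(self.B),
            C=dict(self.C),
            self_gain=dict(self.self_gain),
            self_B=dict(self.self_B),
        )

    def validate(self) -> None:
        for d, what in ((self.A, "A"), (self.B, "B"), (self.self_B, "self_B")):
            for k, v in d.items():
                if what == "A" and v < 0:
                    raise ValueError(f"A[{k}] must be nonnegative")
                if what != "A" and v <= 0:
                    raise ValueError(f"{what}[{k}] must be positive")
        if min(self.H_e, self.H_i, self.tau_e, self.tau_i) <= 0:
            raise ValueError("synaptic gains and time constants must be positive")


@dataclass
class SourceActivity:
    """Pyramidal depolarization per source over time."""

    values: np.ndarray  # (n_times, n_sources), mV
    dt: float  # s
    times_ms: np.ndarray  # peristimulus, ms
    condition: str
    source_names: list[str]


#: default extrinsic strengths by connection class (dimensionless scaling of
#: delayed presynaptic firing; conventional forward > backward > lateral order)
DEFAULT_A_BY_CLASS = {"forward": 32.0, "backward": 16.0, "lateral": 4.0}


def default_parameters(
    network: NetworkSpec,
    connections: list[Connection] | None = None,
    input_nodes: tuple[str, ...] | None = None,
) -> DCMParameters:
    """Defaults: every admissible connection present at its class-default
    strength, all gains 1, exogenous input at the lowest-level sources."""
    if connections is None:
        connections = [c for c in enumerate_connections(network) if c.klass != "diagonal"]
    A = {c.name: DEFAULT_A_BY_CLASS[c.klass] for c in connections}
    B = {c.name: 1.0 for c in connections}
    if input_nodes is None:
        lo = min(n.level for n in network.nodes)
        input_nodes = tuple(n.name for n in network.nodes if n.level == lo)
    C = {n: (1.0 if n in input_nodes else 0.0) for n in network.node_names}
    ones = {n: 1.0 for n in network.node_names}
    return DCMParameters(
        network=network, A=A, B=B, C=C, self_gain=dict(ones), self_B=dict(ones)
    )


def sigmoid_rate(v, params: SigmoidParams = SigmoidParams()):
    """Population firing rate (1/s): monotone sigmoid bounded in (0, 2*e0),
    equal to e0 at v = v0."""
    v = np.asarray(v, dtype=float)
    out = 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.v0 - v)))
    return out if out.ndim else float(out)


def _sigmoid_deviation(v, params: SigmoidParams):
    """Firing expressed as deviation from baseline (v = 0) firing."""
    return sigmoid_rate(v, params) - sigmoid_rate(0.0, params)


def exogenous_input(
    t_ms, onset_ms: float = 60.0, width_ms: float = 16.0, amplitude: float = 1.0
):
    """Exogenous drive: Gaussian bump peaking at ``onset_ms`` with SD
    ``width_ms``, scaled by ``amplitude``; effectively zero for t <= 0."""
    if width_ms <= 0:
        raise ValueError("width must be positive")
    t = np.asarray(t_ms, dtype=float)
    out = amplitude * np.exp(-0.5 * ((t - onset_ms) / width_ms) ** 2)
    return out if out.ndim else float(out)


def effective_connectivity(
    params: DCMParameters, pattern: np.ndarray, space: ModelSpace, condition: str
) -> dict[str, dict[str, float]]:
    """Condition-specific connection strengths.

    Baseline returns the A strengths (and baseline self-gains) unchanged.
    The modulated condition multiplies A by B on every connection belonging
    to a switched-on group of ``pattern`` — and applies the self-connection
    gains always, unless self-connections are governed by an explicit
    self-group in the space (then only when that group is on).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    params.validate()
    strengths = dict(params.A)
    selfs = dict(params.self_gain)
    if condition == "modulated":
        for grp, on in zip(space.groups, pattern):
            if not on:
                continue
            for c in grp.members:
                if c.klass == "self":
                    selfs[c.source] = selfs[c.source] * params.self_B[c.source]
                else:
                    strengths[c.name] = strengths[c.name] * params.B[c.name]
        if not any(g.kind == "self-group" for g in space.groups):
            for n in selfs:
                selfs[n] = selfs[n] * params.self_B[n]
    return {"A": strengths, "self": selfs}


@njit(cache=True)
def _jr_deriv(
    vv, vd, delayed, uval,
    AF, AB, AL, self_gain, C,
    He, Hi, ke, ki, g1, g2, g3, g4, s_max, v0, r, s0,
):  # pragma: no cover - exercised through simulate_sources
    n = AF.shape[0]
    kd = np.empty((4, n))
    for i in range(n):
        pyr_i = vv[1, i] - vv[2, i]
        f_pyr = s_max / (1.0 + np.exp(r * (v0 - pyr_i))) - s0
        f_st = s_max / (1.0 + np.exp(r * (v0 - vv[0, i]))) - s0
        f_ii = s_max / (1.0 + np.exp(r * (v0 - vv[3, i]))) - s0
        fwd = 0.0
        bwd = 0.0
        lat = 0.0
        for j in range(n):
            fwd += AF[i, j] * delayed[j]
            bwd += AB[i, j] * delayed[j]
            lat += AL[i, j] * delayed[j]
        ext_st = self_gain[i] * (fwd + lat + C[i] * uval)
        ext_pb = self_gain[i] * (bwd + lat)
        kd[0, i] = He * ke * (g1 * f_pyr + ext_st) - 2.0 * ke * vd[0, i] - ke * ke * vv[0, i]
        kd[1, i] = He * ke * (g2 * f_st + ext_pb) - 2.0 * ke * vd[1, i] - ke * ke * vv[1, i]
        kd[2, i] = Hi * ki * (g4 * f_ii) - 2.0 * ki * vd[2, i] - ki * ki * vv[2, i]
        kd[3, i] = He * ke * (g3 * f_pyr + ext_pb) - 2.0 * ke * vd[3, i] - ke * ke * vv[3, i]
    return kd


@njit(cache=True)
def _integrate_jr(
    AF, AB, AL, self_gain, C, u,  # coupling: (n,n) row=target; (n,) ; input (T,)
    He, Hi, ke, ki, g1, g2, g3, g4, s_max, v0, r, s0,
    dt, delay_steps, guard,
):  # pragma: no cover - exercised through simulate_sources
    n = AF.shape[0]
    T = u.shape[0]
    # states: PSPs v1 (stellate), v2 (pyr excit), v3 (pyr inhib), v4 (inhib
    # interneuron) and their derivatives; classical RK4 with the delayed
    # firing linearly interpolated at the half step
    v = np.zeros((4, n))
    dv = np.zeros((4, n))
    vp = np.zeros((T, n))  # pyramidal depolarization v2 - v3
    fire_hist = np.zeros((T + 1, n))  # delayed pyramidal firing deviation

    args = (AF, AB, AL, self_gain, C, He, Hi, ke, ki, g1, g2, g3, g4, s_max, v0, r, s0)
    for t in range(T):
        # record the state at time t, then step to t+1
        for i in range(n):
            p = v[1, i] - v[2, i]
            vp[t, i] = p
            fire_hist[t, i] = s_max / (1.0 + np.exp(r * (v0 - p))) - s0
            if np.abs(p) > guard:
                return vp, 1
        td = t - delay_steps
        if td >= 0:
            d0 = fire_hist[td]
            d1 = fire_hist[td + 1] if delay_steps >= 1 else fire_hist[td]
        else:
            d0 = np.zeros(n)
            d1 = np.zeros(n)
        dh = 0.5 * (d0 + d1)
        u0 = u[t]
        u1 = u[t + 1] if t + 1 < T else u[t]
        uh = 0.5 * (u0 + u1)

        k1d = _jr_deriv(v, dv, d0, u0, *args)
        k1v = dv
        k2d = _jr_deriv(v + 0.5 * dt * k1v, dv + 0.5 * dt * k1d, dh, uh, *args)
        k2v = dv + 0.5 * dt * k1d
        k3d = _jr_deriv(v + 0.5 * dt * k2v, dv + 0.5 * dt * k2d, dh, uh, *args)
        k3v = dv + 0.5 * dt * k2d
        k4d = _jr_deriv(v + dt * k3v, dv + dt * k3d, d1, u1, *args)
        k4v = dv + dt * k3d
        v = v + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        dv = dv + dt / 6.0 * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
    return vp, 0


def _coupling_matrices(
    params: DCMParameters, eff: dict[str, dict[str, float]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    net = params.network
    n = len(net.nodes)
    AF = np.zeros((n, n))
    AB = np.zeros((n, n))
    AL = np.zeros((n, n))
    conn_class = {c.name: c.klass for c in enumerate_connections(net)}
    for name, a in eff["A"].items():
        src, tgt = name.split("->")
        i, j = net.index(tgt), net.index(src)
        k = conn_class[name]
        if k == "forward":
            AF[i, j] = a
        elif k == "backward":
            AB[i, j] = a
        elif k == "lateral":
            AL[i, j] = a
        else:
            raise ValueError(f"cannot place connection {name} of class {k}")
    sg = np.array([eff["self"][nm] for nm in net.node_names])
    C = np.array([params.C.get(nm, 0.0) for nm in net.node_names])
    return AF, AB, AL, sg, C


def simulate_sources(
    params: DCMParameters,
    pattern: np.ndarray,
    space: ModelSpace,
    condition: str,
    duration_ms: float = 300.0,
    dt: float = 1.0 / 480.0,
    start_ms: float = 0.0,
    guard_mv: float = 1e3,
) -> SourceActivity:
    """Deterministic integration of the coupled network from rest.

    Integrates from ``start_ms`` to ``duration_ms`` peristimulus with a
    fixed-step explicit (Heun) scheme at step ``dt`` and returns the
    pyramidal depolarization per source.  Raises :class:`InstabilityError`
    if any potential exceeds ``guard_mv``.
    """
    if dt > 0.0025 + 1e-12:
        raise ValueError("dt must be <= 2.5 ms for a stable explicit step")
    eff = effective_connectivity(params, pattern, space, condition)
    AF, AB, AL, sg, C = _coupling_matrices(params, eff)
    times_ms = np.arange(start_ms, duration_ms + 1e-9, dt * 1000.0)
    u = exogenous_input(
        times_ms, params.input_onset_ms, params.input_width_ms, params.input_amplitude
    )
    sig = params.sigmoid
    s_max = 2.0 * sig.e0
    s0 = sigmoid_rate(0.0, sig)
    delay_steps = int(round(params.delay_ms / 1000.0 / dt))
    vp, status = _integrate_jr(
        AF, AB, AL, sg, C, np.asarray(u, float),
        params.H_e, params.H_i, 1.0 / params.tau_e, 1.0 / params.tau_i,
        params.gamma1, params.gamma2, params.gamma3, params.gamma4,
        s_max, sig.v0, sig.r, s0,
        dt, delay_steps, guard_mv,
    )
    if status != 0:
        raise InstabilityError(
            f"integration diverged (|v| > {guard_mv} mV); condition={condition}, "
            f"H_e={params.H_e}, H_i={params.H_i}, max |A|="
            f"{max(abs(a) for a in eff['A'].values()) if eff['A'] else 0}"
        )
    return SourceActivity(
        values=vp,
        dt=dt,
        times_ms=times_ms,
        condition=condition,
        source_names=list(params.network.node_names),
    )
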