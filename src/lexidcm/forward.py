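"""Analytic spherical MEG forward model and equivalent current dipole fits.

Source activity is mapped to sensors through the closed-form magnetic field
of a current dipole in a homogeneous conducting sphere (Sarvas solution).
Volume currents in a spherical conductor are radially silent, so a radial
dipole produces no external field — a property the implementation inherits
from the closed form.  The axial-gradiometer array is approximated as
oriented point magnetometers on a helmet-like spherical cap.

Positions cross module boundaries in millimetres; SI units are used
internally (m, A*m, T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .containers import EpochSet, Evoked

__all__ = [
    "SensorArray",
    "LeadField",
    "DipoleFit",
    "helmet_array",
    "dipole_field",
    "dipole_leadfield",
    "build_leadfield",
    "project_to_sensors",
    "fit_ecd",
]

MU0_OVER_4PI = 1e-7  # T*m/A
HEAD_RADIUS_MM = 110.0


@dataclass
class SensorArray:
    """Point magnetometers: positions (n,3) mm, unit orientations (n,3)."""

    positions_mm: np.ndarray
    orientations: np.ndarray
    sphere_center_mm: np.ndarray = None
    sphere_radius_mm: float = HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, float))
        if self.sphere_center_mm is None:
            self.sphere_center_mm = np.zeros(3)
        self.sphere_center_mm = np.asarray(self.sphere_center_mm, float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("sensor orientations must be unit vectors")
        rad = np.linalg.norm(self.positions_mm - self.sphere_center_mm, axis=1)
        if np.any(rad <= self.sphere_radius_mm):
            raise ValueError("sensors must lie outside the model sphere")

    @property
    def n_sensors(self) -> int:
        return self.positions_mm.shape[0]


@dataclass
class LeadField:
    """Gain matrix: field per unit source amplitude, (n_sources, n_sensors)."""

    gain: np.ndarray
    source_locations_mm: np.ndarray
    source_orientations: np.ndarray

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]


@dataclass
class DipoleFit:
    locations_mm: np.ndarray  # (k, 3)
    moments: np.ndarray  # (k, 3), A*m
    residual_variance: float
    n_restarts: int
    prior_means_mm: np.ndarray
    prior_sd_mm: float
    seed: int


def helmet_array(
    n_sensors: int = 275,
    radius_mm: float = 130.0,
    coverage: float = 0.65,
    sphere_radius_mm: float = HEAD_RADIUS_MM,
) -> SensorArray:
    """Radially oriented sensors on a spherical cap (Fibonacci spacing).

    ``coverage`` is the fraction of the full sphere's polar angle covered
    from the vertex down, giving a helmet-like cap over the upper head.
    """
    i = np.arange(n_sensors)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # z from top of sphere down to the coverage limit
    z = 1.0 - coverage * (i + 0.5) / n_sensors * 2.0
    theta = golden * i
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return SensorArray(
        positions_mm=radius_mm * unit,
        orientations=unit,
        sphere_radius_mm=sphere_radius_mm,
    )


def _sarvas_field(r_mm: np.ndarray, q: np.ndarray, r0_mm: np.ndarray) -> np.ndarray:
    """Magnetic field (T) at points r (mm, sphere-centred) of a dipole with
    moment q (A*m) at r0 (mm, inside the sphere)."""
    r = np.atleast_2d(r_mm) * 1e-3
    r0 = np.asarray(r0_mm, float) * 1e-3
    q = np.asarray(q, float)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (R * a + R ** 2 - r @ r0)
    gradF = (
        (a ** 2 / R + adotr / a + 2.0 * a + 2.0 * R)[:, None] * r
        - (a + 2.0 * R + adotr / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * gradF
    )
    return B


def dipole_field(
    location_mm, moment, sensors: SensorArray
) -> np.ndarray:
    """Field along each sensor's orientation for a dipole (moment in A*m)."""
    loc = np.asarray(location_mm, float) - sensors.sphere_center_mm
    if np.linalg.norm(loc) >= sensors.sphere_radius_mm:
        raise ValueError(
            f"dipole at radius {np.linalg.norm(loc):.1f} mm is not strictly "
            f"inside the {sensors.sphere_radius_mm:.0f} mm sphere"
        )
    pos = sensors.positions_mm - sensors.sphere_center_mm
    B = _sarvas_field(pos, moment, loc)
    return np.einsum("ij,ij->i", B, sensors.orientations)


def dipole_leadfield(location_mm, orientation, sensors: SensorArray) -> np.ndarray:
    """Gain vector: sensor field per unit dipole moment (1 A*m) along
    ``orientation`` at ``location_mm``."""
    orientation = np.asarray(orientation, float)
    n = np.linalg.norm(orientation)
    if n == 0:
        raise ValueError("orientation must be nonzero")
    return dipole_field(location_mm, orientation / n, sensors)


def build_leadfield(
    locations_mm: np.ndarray,
    orientations: np.ndarray,
    sensors: SensorArray,
    moment_scale: float = 1e-8,
) -> LeadField:
    """Lead field for fixed-orientation sources.

    ``moment_scale`` converts one unit of source activity (mV of pyramidal
    depolarization) into dipole moment (A*m); the default 10 nA*m per unit
    gives fields in the physiological femtotesla range.
    """
    locations_mm = np.atleast_2d(locations_mm)
    orientations = np.atleast_2d(orientations)
    gain = np.stack(
        [
            moment_scale * dipole_leadfield(loc, ori, sensors)
            for loc, ori in zip(locations_mm, orientations)
        ]
    )
    return LeadField(gain, locations_mm, orientations)


def tangential_orientations(locations_mm: np.ndarray) -> np.ndarray:
    """A deterministic tangential unit orientation per source location
    (radial components are magnetically silent in the sphere)."""
    locations_mm = np.atleast_2d(locations_mm)
    out = []
    for loc in locations_mm:
        rhat = loc / np.linalg.norm(loc)
        trial = np.array([0.0, 0.0, 1.0])
        if abs(rhat @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        t = trial - (trial @ rhat) * rhat
        out.append(t / np.linalg.norm(t))
    return np.array(out)


def project_to_sensors(
    activity_values: np.ndarray,
    leadfield: LeadField,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_trials: int = 1,
    times_ms: np.ndarray | None = None,
    condition: str = "",
) -> EpochSet:
    """Sensor time series: gain' * activity + i.i.d. Gaussian sensor noise.

    ``activity_values`` is (n_times, n_sources).  Returns an EpochSet with
    ``n_trials`` independent noise realizations around the same deterministic
    projection; ``noise_sd = 0`` gives identical, noiseless trials.
    """
    act = np.asarray(activity_values, float)
    if act.ndim != 2 or act.shape[1] != leadfield.n_sources:
        raise ValueError(
            f"activity shape {act.shape} does not match {leadfield.n_sources} sources"
        )
    clean = leadfield.gain.T @ act.T  # (n_sensors, n_times)
    rng = np.random.default_rng(seed)
    data = np.repeat(clean[None], n_trials, axis=0)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    if times_ms is None:
        times_ms = np.arange(act.shape[0], dtype=float)
    return EpochSet(data, times_ms, [condition] * n_trials, provenance="simulated")


def _moments_for_locations(
    locs_mm: np.ndarray, snapshot: np.ndarray, sensors: SensorArray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares dipole moments for fixed locations; returns (moments,
    predicted field)."""
    k = locs_mm.shape[0]
    basis = []
    for loc in locs_mm:
        for axis in np.eye(3):
            basis.append(dipole_field(loc, axis, sensors))
    G = np.array(basis).T  # (n_sensors, 3k)
    coef, *_ = np.linalg.lstsq(G, snapshot, rcond=None)
    return coef.reshape(k, 3), G @ coef


def fit_ecd(
    snapshot: np.ndarray,
    k: int,
    prior_means_mm: np.ndarray,
    sensors: SensorArray,
    location_jitter_sd_mm: float = 6.0,
    prior_sd_mm: float = 10.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> DipoleFit:
    """Multi-start MAP equivalent-current-dipole fit to one sensor snapshot.

    Each restart perturbs the prior mean locations with Gaussian jitter
    (SD ``location_jitter_sd_mm`` per axis) and locally minimizes the
    normalized residual power plus a Gaussian location penalty
    (SD ``prior_sd_mm``); moments are profiled out linearly.  The best
    penalized fit over restarts is returned; deterministic given the seed.
    """
    snapshot = np.asarray(snapshot, float)
    prior_means_mm = np.atleast_2d(np.asarray(prior_means_mm, float))
    if prior_means_mm.shape != (k, 3):
        raise ValueError("prior means must be (k, 3)")
    inside = np.linalg.norm(prior_means_mm - sensors.sphere_center_mm, axis=1)
    if np.any(inside >= sensors.sphere_radius_mm):
        raise ValueError("prior means must lie inside the head sphere")
    rng = np.random.default_rng(seed)
    power = float(snapshot @ snapshot)
    norm = power if power > 0 else 1.0
    r_max = sensors.sphere_radius_mm - 1.0

    def clip_inside(locs: np.ndarray) -> np.ndarray:
        locs = locs.reshape(k, 3)
        rel = locs - sensors.sphere_center_mm
        rad = np.linalg.norm(rel, axis=1)
        bad = rad > r_max
        if np.any(bad):
            rel[bad] *= (r_max / rad[bad])[:, None]
            locs = sensors.sphere_center_mm + rel
        return locs

    def objective(x: np.ndarray) -> float:
        locs = clip_inside(x.copy())
        _, pred = _moments_for_locations(locs, snapshot, sensors)
        resid = snapshot - pred
        penalty = float(np.sum((locs - prior_means_mm) ** 2)) / (2.0 * prior_sd_mm ** 2)
        return float(resid @ resid) / norm + penalty / snapshot.size

    best = None
    n_fail = 0
    for _ in range(n_restarts):
        start = prior_means_mm + rng.normal(0.0, location_jitter_sd_mm, size=(k, 3))
        start = clip_inside(start.ravel())
        try:
            res = optimize.minimize(
                objective, start.ravel(), method="Nelder-Mead",
                options={"maxiter": 400 * k, "xatol": 1e-3, "fatol": 1e-12},
            )
        except (np.linalg.LinAlgError, FloatingPointError):
            n_fail += 1
            continue
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} ECD restarts diverged ({n_fail} failures); "
            f"snapshot power {power:.3e}"
        )
    locs = clip_inside(best.x.copy())
    moments, pred = _moments_for_locations(locs, snapshot, sensors)
    resid = snapshot - pred
    rv = float(resid @ resid) / norm if power > 0 else 0.0
    _warn_close_pairs(locs)
    return DipoleFit(
        locations_mm=locs,
        moments=moments,
        residual_variance=min(max(rv, 0.0), 1.0),
        n_restarts=n_restarts,
        prior_means_mm=prior_means_mm,
        prior_sd_mm=prior_sd_mm,
        seed=seed,
    )


def _warn_close_pairs(locs_mm: np.ndarray, min_sep_mm: float = 20.0) -> None:
    import warnings

    k = locs_mm.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            d = np.linalg.norm(locs_mm[i] - locs_mm[j])
            if d < min_sep_mm:
                warnings.warn(
                    f"fitted dipoles {i} and {j} are {d:.1f} mm apart "
                    f"(< {min_sep_mm:.0f} mm)",
                    stacklevel=3,
                )
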