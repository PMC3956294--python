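"""Quasi-steady-state models of nodal cdr2p accumulation.

Cdr2p is partitioned into a cytoplasmic pool (homogeneous concentration
rho_cyt = N_cyt / V), a dim cortical pool on the whole membrane
(rho_cor = N_cor / A_cor), and a nodal pool confined to a medial band
(rho_nod = N_nod / A_nod). Because molecular exchange (seconds to minutes)
is fast compared with cell growth (hours), each cell size is treated as a
quasi-steady state of the exchange kinetics.

Model I (uniform cortical intermediate): cytoplasmic cdr2p associates
anywhere on the membrane (parameter beta, um/s), dissociates back at rate
nu (1/s), and cortical cdr2p is taken up into nodes at rate alpha (1/s)
but only over the nodal band; nodal cdr2p dissociates at rate eta (1/s).
Balancing the fluxes,

    0 = beta*(A_cor/V)*N_cyt - nu*N_cor - alpha*(A_nod/A_cor)*N_cor
    0 = alpha*(A_nod/A_cor)*N_cor - eta*N_nod

whose exact solution is

    rho_nod = rho_cyt*(beta/eta) / (nu/alpha + A_nod/A_cor)
    rho_cor = rho_nod*eta/alpha.

With nu/alpha << 1 and A_nod roughly constant, rho_nod scales with the
total membrane area A_cor = 2*pi*R*L: the uniform cortical pool "measures"
the area and the fixed-size nodal band "reads it out".

The direct-to-node null model skips the cortical intermediate: association
and dissociation then happen over the same region, giving
rho_nod = (beta/eta)*rho_cyt independent of cell size — membrane
localization alone is not a size sensor.

Model II (modification model): cortical residence converts cdr2p to a
modified cytoplasmic form (density rho_cyt_mod) that binds only at the
nodal band (binding constant alpha, um/s) or spontaneously reverts at rate
mu (1/s). Its nodal density is

    rho_nod = (beta/eta)*(A_cor/A_nod) * rho_cyt / (mu*V/(alpha*A_nod) + 1)

which reduces to (beta/eta)*(A_cor/A_nod)*rho_cyt for mu = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CellGeometry

__all__ = [
    "UniformModelParams",
    "ModificationModelParams",
    "SteadyState",
    "SingularModelError",
    "SteadyStateSolverError",
    "FitError",
    "rho_cyt_at",
    "model1_closed_form",
    "model1_numeric",
    "model1_direct_null",
    "model2_closed_form",
    "model2_numeric",
    "fit_scaling_prefactor",
]


class SingularModelError(ValueError):
    """Model parameters make the steady state undefined (e.g. no exit flux)."""


class SteadyStateSolverError(RuntimeError):
    """Numeric steady-state solve failed to converge; carries residuals."""


class FitError(ValueError):
    """Scaling fit cannot be performed on the given data."""


@dataclass(frozen=True)
class UniformModelParams:
    """Model I rate constants and the cytoplasmic-concentration trend.

    beta : um/s, cytoplasm->membrane association (prefactor only)
    nu : 1/s, cortical dissociation
    alpha : 1/s, cortical->nodal uptake over the nodal band
    eta : 1/s, nodal dissociation (1/occupancy time, FRAP-derived)
    rho_cyt_ref : molecules/um^3 (arbitrary units allowed)
    cyt_slope : 1/um, relative change of rho_cyt per um of length
    L_ref : um, length at which rho_cyt equals rho_cyt_ref
    """

    beta: float = 1.0
    nu: float = 5e-3
    alpha: float = 1.0
    eta: float = 5e-3
    rho_cyt_ref: float = 1.0
    cyt_slope: float = -0.01
    L_ref: float = 10.5

    def __post_init__(self) -> None:
        for name in ("beta", "nu", "alpha", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rho_cyt_ref < 0:
            raise ValueError("rho_cyt_ref must be non-negative")

    def constant_cyt(self) -> "UniformModelParams":
        """Variant with a strictly constant cytoplasmic concentration."""
        return replace(self, cyt_slope=0.0)


@dataclass(frozen=True)
class ModificationModelParams:
    """Model II rate constants.

    beta : um/s, association of unmodified cytoplasmic cdr2p to the membrane
    nu : 1/s, cortical dissociation (releases the modified form)
    alpha : um/s, binding constant of modified cytoplasmic cdr2p to the band
    eta : 1/s, nodal dissociation
    mu : 1/s, spontaneous reversion of the modified cytoplasmic form
    """

    beta: float = 1.0
    nu: float = 0.5
    alpha: float = 0.5
    eta: float = 5e-3
    mu: float = 0.03
    rho_cyt_ref: float = 1.0
    cyt_slope: float = 0.0
    L_ref: float = 10.5

    def __post_init__(self) -> None:
        for name in ("beta", "nu", "alpha", "eta", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SteadyState:
    """Copy numbers and densities of the cdr2p pools at quasi-steady state."""

    rho_cyt: float
    rho_cor: float
    rho_nod: float
    N_cor: float
    N_nod: float
    rho_cyt_mod: float = 0.0


def rho_cyt_at(params, L: float) -> float:
    """Cytoplasmic concentration at length ``L`` (linear trend, clamped >= 0).

    rho_cyt(L) = rho_cyt_ref * (1 + cyt_slope*(L - L_ref)); the measured
    relative slope is about -0.01 per um, a small decrease with growth.
    """
    if L <= 0:
        raise ValueError(f"cell length must be positive, got {L}")
    val = params.rho_cyt_ref * (1.0 + params.cyt_slope * (L - params.L_ref))
    return max(val, 0.0)


def _pack(rho_cyt: float, rho_cor: float, rho_nod: float, geom: CellGeometry,
          rho_cyt_mod: float = 0.0) -> SteadyState:
    return SteadyState(
        rho_cyt=rho_cyt,
        rho_cor=rho_cor,
        rho_nod=rho_nod,
        N_cor=rho_cor * geom.A_cor,
        N_nod=rho_nod * geom.A_nod,
        rho_cyt_mod=rho_cyt_mod,
    )


def model1_closed_form(params: UniformModelParams, geom: CellGeometry) -> SteadyState:
    """Exact Model I steady state.

    rho_nod = rho_cyt*(beta/eta)/(nu/alpha + A_nod/A_cor) and
    rho_cor = rho_nod*eta/alpha. Raises :class:`SingularModelError` when the
    cortical pool has no exit at all (A_nod = 0 and nu = 0).
    """
    if geom.A_nod == 0 and params.nu == 0:
        raise SingularModelError("no cortical exit: A_nod = 0 and nu = 0")
    rho_cyt = rho_cyt_at(params, geom.L)
    frac = geom.A_nod / geom.A_cor
    if params.alpha == 0:
        rho_nod = 0.0
        rho_cor = params.beta * rho_cyt / params.nu if params.nu > 0 else 0.0
        return _pack(rho_cyt, rho_cor, rho_nod, geom)
    rho_nod = rho_cyt * (params.beta / params.eta) / (params.nu / params.alpha + frac)
    rho_cor = rho_nod * params.eta / params.alpha
    return _pack(rho_cyt, rho_cor, rho_nod, geom)


def model1_direct_null(params: UniformModelParams, geom: CellGeometry) -> SteadyState:
    """Direct-to-node null model: no cortical intermediate.

    Cytoplasmic cdr2p binds straight onto the nodes; balancing association
    (beta) against dissociation (eta) gives rho_nod = (beta/eta)*rho_cyt,
    independent of cell length and of A_nod. A membrane-localized protein
    with this wiring cannot sense cell area.
    """
    rho_cyt = rho_cyt_at(params, geom.L)
    rho_nod = (params.beta / params.eta) * rho_cyt
    return _pack(rho_cyt, 0.0, rho_nod, geom)


def model2_closed_form(params: ModificationModelParams, geom: CellGeometry) -> SteadyState:
    """Exact Model II steady state (modification model)."""
    if geom.A_nod == 0:
        raise SingularModelError("Model II needs a nodal band: A_nod = 0")
    rho_cyt = rho_cyt_at(params, geom.L)
    rho_cor = params.beta * rho_cyt / params.nu if params.nu > 0 else 0.0
    if params.alpha == 0:
        # uptake flux cut: everything reverts, nodal pool empties
        rho_cyt_mod = (
            params.nu * rho_cor * geom.A_cor / (params.mu * geom.V)
            if params.mu > 0 else 0.0
        )
        return _pack(rho_cyt, rho_cor, 0.0, geom, rho_cyt_mod)
    denom = params.mu * geom.V / (params.alpha * geom.A_nod) + 1.0
    rho_nod = (
        (params.beta / params.eta) * (geom.A_cor / geom.A_nod) * rho_cyt / denom
    )
    # rho_nod = (alpha/eta) * rho_cyt_mod
    rho_cyt_mod = rho_nod * params.eta / params.alpha
    return _pack(rho_cyt, rho_cor, rho_nod, geom, rho_cyt_mod)


def _newton_log(residual, jacobian, n0: np.ndarray, scale: float,
                tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Damped Newton iteration on u = log N for positive copy numbers.

    ``scale`` is the magnitude of the largest flux term; convergence is
    declared at residuals below ``tol * scale``.
    """
    u = np.log(np.maximum(n0, 1e-300))
    scale = max(scale, 1e-300)
    for _ in range(max_iter):
        n = np.exp(u)
        f = residual(n)
        if np.max(np.abs(f)) <= tol * scale:
            return n
        J = jacobian(n) * n[np.newaxis, :]  # chain rule through exp
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise SteadyStateSolverError(f"singular Jacobian; residuals {f}") from exc
        lam = 1.0
        f0 = np.linalg.norm(f)
        while lam > 1e-8:
            u_new = u + lam * step
            if np.linalg.norm(residual(np.exp(u_new))) < f0:
                break
            lam *= 0.5
        u = u + lam * step
    n = np.exp(u)
    f = residual(n)
    if np.max(np.abs(f)) <= tol * scale:
        return n
    raise SteadyStateSolverError(f"Newton did not converge; residuals {f}")


def model1_numeric(params: UniformModelParams, geom: CellGeometry) -> SteadyState:
    """Model I steady state by root-finding the two mass-action balances.

    Solves the same system the closed form integrates, by damped Newton on
    log copy numbers with an analytic Jacobian; agrees with
    :func:`model1_closed_form` to ~1e-12 relative. Kept as an independent
    route for cross-validation.
    """
    if geom.A_nod == 0 and params.nu == 0:
        raise SingularModelError("no cortical exit: A_nod = 0 and nu = 0")
    rho_cyt = rho_cyt_at(params, geom.L)
    if params.beta == 0 or rho_cyt == 0:
        return _pack(rho_cyt, 0.0, 0.0, geom)
    N_cyt = rho_cyt * geom.V
    b, nu, al, eta = params.beta, params.nu, params.alpha, params.eta
    frac = geom.A_nod / geom.A_cor
    influx = b * (geom.A_cor / geom.V) * N_cyt

    if geom.A_nod == 0 or al == 0:
        # nodal compartment decoupled
        N_cor = influx / nu
        return _pack(rho_cyt, N_cor / geom.A_cor, 0.0, geom)

    def residual(n):
        N_cor, N_nod = n
        return np.array([
            influx - nu * N_cor - al * frac * N_cor,
            al * frac * N_cor - eta * N_nod,
        ])

    def jacobian(n):
        return np.array([[-(nu + al * frac), 0.0], [al * frac, -eta]])

    n0 = np.array([influx / (nu + al * frac), influx / eta])
    N_cor, N_nod = _newton_log(residual, jacobian, n0, scale=influx)
    return _pack(rho_cyt, N_cor / geom.A_cor, N_nod / geom.A_nod, geom)


def model2_numeric(params: ModificationModelParams, geom: CellGeometry) -> SteadyState:
    """Model II steady state by root-finding the three balances.

    Unknowns are (N_cor, N_cyt_mod, N_nod); same Newton scheme as
    :func:`model1_numeric`, cross-validating :func:`model2_closed_form`.
    """
    if geom.A_nod == 0:
        raise SingularModelError("Model II needs a nodal band: A_nod = 0")
    rho_cyt = rho_cyt_at(params, geom.L)
    if params.beta == 0 or rho_cyt == 0:
        return _pack(rho_cyt, 0.0, 0.0, geom)
    N_cyt = rho_cyt * geom.V
    b, nu, al, eta, mu = params.beta, params.nu, params.alpha, params.eta, params.mu
    influx = b * (geom.A_cor / geom.V) * N_cyt
    k_nod = al * geom.A_nod / geom.V  # 1/s, uptake of the modified form

    if al == 0 and mu == 0:
        raise SteadyStateSolverError("modified pool has no exit (alpha = mu = 0)")
    if al == 0:
        N_cor = influx / nu
        N_mod = nu * N_cor / mu
        return _pack(rho_cyt, N_cor / geom.A_cor, 0.0, geom, N_mod / geom.V)

    def residual(n):
        N_cor, N_mod, N_nod = n
        return np.array([
            influx - nu * N_cor,
            nu * N_cor - mu * N_mod - k_nod * N_mod,
            k_nod * N_mod - eta * N_nod,
        ])

    def jacobian(n):
        return np.array([
            [-nu, 0.0, 0.0],
            [nu, -(mu + k_nod), 0.0],
            [0.0, k_nod, -eta],
        ])

    n0 = np.array([influx / nu, influx / (mu + k_nod), influx / eta])
    N_cor, N_mod, N_nod = _newton_log(residual, jacobian, n0, scale=influx)
    return _pack(
        rho_cyt, N_cor / geom.A_cor, N_nod / geom.A_nod, geom, N_mod / geom.V
    )


def fit_scaling_prefactor(
    lengths, densities, model: str = "model1", params=None,
    R: float = 1.5, w_nod: float = 3.0, curve=None,
):
    """Fit the single free prefactor of a scaling model to (L, density) data.

    All model variants predict rho_nod(L) up to one multiplicative constant
    (beta and the intensity calibration are pure prefactors), so the fit is
    linear: ``c = sum(g*d) / sum(g^2)`` with ``g(L)`` the unit-prefactor
    model curve.

    Parameters
    ----------
    lengths, densities : array-like
        Cell lengths (um) and measured nodal densities (a.u.).
    model : {"model1", "model2", "direct-null"}
        Which steady-state variant provides the curve shape.
    params : optional
        Model parameter set; defaults to the standard parameters.
    R, w_nod : float
        Radius and nodal band width used to build geometries (um).
    curve : callable, optional
        Unit-prefactor predicted value as a function of L. When given it
        replaces the steady-state density curve — used when the measured
        quantity is a transformed readout (e.g. a band-integrated
        intensity) rather than the density itself.

    Returns
    -------
    dict with ``prefactor``, ``predicted`` (at each input L), ``r2``.
    """
    L = np.asarray(lengths, dtype=float)
    d = np.asarray(densities, dtype=float)
    if L.size != d.size or L.size < 3:
        raise FitError(f"need >= 3 (L, density) pairs, got {L.size}")
    if np.any(d < 0) or not np.any(d > 0):
        raise FitError("densities must be non-negative with at least one positive")
    solvers = {
        "model1": (model1_closed_form, UniformModelParams),
        "model2": (model2_closed_form, ModificationModelParams),
        "direct-null": (model1_direct_null, UniformModelParams),
    }
    if model not in solvers:
        raise FitError(f"unknown model variant {model!r}")
    solve, default_cls = solvers[model]
    if params is None:
        params = default_cls()
    if curve is not None:
        g = np.array([curve(el) for el in L])
    else:
        g = np.array([
            solve(params, CellGeometry(L=el, R=R, w_nod=w_nod)).rho_nod
            for el in L
        ])
    c = float(np.dot(g, d) / np.dot(g, g))
    pred = c * g
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - np.mean(d)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return {"prefactor": c, "predicted": pred, "r2": r2}
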