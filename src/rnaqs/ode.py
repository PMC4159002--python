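"""Mass-action ODE models of replicator ecologies.

Two reaction schemes abstract the grid model to well-mixed dynamics:

* **helpers scheme** — units of replication X form complexes with other
  units, with helpers H and with parasites P (helpers and parasites can
  also pair up).  Every productive complex fires at rate ``kappa * theta``
  and the X-offspring branches into faithful copies (1-mu) and mutant
  classes (mu * lambda_H / lambda_P / lambda_J); parasites are copied
  without mutating.
* **stallers scheme** — units X, stallers S, parasites P and junk J.
  X-X complexes replicate X; P-X complexes replicate P (whose mutants are
  stallers or junk); X-S and P-S complexes form but never replicate, so
  stallers sequester partners.

``theta`` is a phenomenological competition term.  It is implemented as a
saturating resource factor theta(N) = max(0, 1 - N/Theta) with N the total
concentration (complexes counting twice: a complex occupies two grid
cells).  This closure keeps the dynamics bounded and makes the extinction
state an equilibrium, both structural features of the spatial model.
Dissociation rates default to b = 1 - a for each complex, mirroring the
grid rule k2 = 1 - k1; every species and complex decays at rate d.

Equilibria are continued in a free parameter by pseudo-arclength
continuation with finite-difference Jacobians; stability comes from the
eigenvalues of the state Jacobian, and fold / Hopf / transcritical points
are detected from sign structure along the branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


def _default_b(a):
    return 1.0 - a


# ---------------------------------------------------------------------------
# parameter sets


@dataclass(frozen=True)
class OdeParams1:
    """Helpers scheme: units X, helpers H, parasites P, junk J."""

    a_xx: float = 0.7
    a_xh: float = 0.7
    a_xp: float = 0.7
    a_hp: float = 0.7
    b_xx: float = None
    b_xh: float = None
    b_xp: float = None
    b_hp: float = None
    kappa: float = 1.0
    theta_cap: float = 1.0     # Theta, resource scale
    d: float = 0.03
    mu: float = 0.0
    lam_H: float = 0.0
    lam_P: float = 0.03
    include_parasites: bool = True
    # closure degree of freedom: orientation multiplicity of unit-unit
    # binding (two units can bind in either of two orientations; mixed
    # pairs only one).  The printed rates of this scheme are equal across
    # pair types, so they are read as per-orientation rates.
    xx_orientation_factor: float = 2.0

    def __post_init__(self):
        if self.lam_H + self.lam_P > 1.0 + 1e-12:
            raise ValueError("lam_H + lam_P must be <= 1")

    def b(self, name: str) -> float:
        """Dissociation rate of complex *name* (default 1 - a)."""
        v = getattr(self, "b_" + name)
        return _default_b(getattr(self, "a_" + name)) if v is None else v

    @property
    def lam_J(self):
        return 1.0 - self.lam_H - self.lam_P


@dataclass(frozen=True)
class OdeParams2:
    """Stallers scheme: units X, stallers S, parasites P, junk J.

    ``lam_S``/``lam_P``/``lam_J`` split the mutant offspring of units;
    ``lam_Sp``/``lam_Jp`` split the mutant offspring of parasites (stallers
    or junk only).  If the latter are omitted they default to the unit
    values renormalized over {S, J}.
    """

    a_xx: float = 0.9
    a_px: float = 0.8
    a_xs: float = 0.75
    a_ps: float = 0.75
    b_xx: float = None
    b_px: float = None
    b_xs: float = None
    b_ps: float = None
    kappa: float = 1.0
    theta_cap: float = 1.0
    d: float = 0.03
    mu: float = 0.4
    lam_S: float = 0.2
    lam_P: float = 0.0
    lam_Sp: float = None
    lam_Jp: float = None
    # here the printed unit-unit rate already exceeds the mixed-pair rates,
    # so it is read as a total rate (no extra orientation multiplicity)
    xx_orientation_factor: float = 1.0

    def __post_init__(self):
        if self.lam_S + self.lam_P > 1.0 + 1e-12:
            raise ValueError("lam_S + lam_P must be <= 1")

    def b(self, name: str) -> float:
        """Dissociation rate of complex *name* (default 1 - a)."""
        v = getattr(self, "b_" + name)
        return _default_b(getattr(self, "a_" + name)) if v is None else v

    @property
    def lam_J(self):
        return 1.0 - self.lam_S - self.lam_P

    def parasite_mutant_split(self) -> tuple:
        """(lam_Sp, lam_Jp): parasite mutants default to the unit values
        renormalized over {S, J}."""
        if self.lam_Sp is not None:
            return self.lam_Sp, (1.0 - self.lam_Sp
                                 if self.lam_Jp is None else self.lam_Jp)
        sj = self.lam_S + self.lam_J
        lam_sp = self.lam_S / sj if sj > 0 else 0.0
        return lam_sp, 1.0 - lam_sp


# ---------------------------------------------------------------------------
# models


class OdeModel:
    """Base: species names + parameter set + mass-action right-hand side."""

    species: tuple
    weights: np.ndarray     # cell occupancy per state variable (for theta)

    def __init__(self, params):
        self.params = params

    def rhs(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, t, y):      # solve_ivp signature
        return self.rhs(np.maximum(y, 0.0))

    def theta(self, y: np.ndarray) -> float:
        n = float(self.weights @ y)
        return max(0.0, 1.0 - n / self.params.theta_cap)

    def jacobian(self, y: np.ndarray, eps: float = 1e-7) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        f0 = self.rhs(y)
        jac = np.empty((y.size, y.size))
        for i in range(y.size):
            dy = y.copy()
            h = eps * max(1.0, abs(y[i]))
            dy[i] += h
            jac[:, i] = (self.rhs(dy) - f0) / h
        return jac

    def with_params(self, **kw):
        return type(self)(replace(self.params, **kw))


class HelperModel(OdeModel):
    """Reaction scheme with helpers (and optionally parasites)."""

    species = ("X", "H", "P", "J", "Cxx", "Cxh", "Cxp", "Chp")
    weights = np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=float)

    def __init__(self, params: OdeParams1):
        super().__init__(params)

    def rhs(self, y):
        p = self.params
        if np.any(np.asarray(y) < -1e-9):
            raise ValueError("state must be nonnegative")
        X, H, P, J, Cxx, Cxh, Cxp, Chp = y
        th = self.theta(np.asarray(y, dtype=float))
        # two units of replication can bind in either orientation (both
        # strands carry 5' and 3' tails), so unit-unit complexes form at a
        # multiple of the per-orientation rate; mixed pairs have one
        # orientation (helpers lack 3' ends, parasites lack 5' ends)
        F_xx = p.xx_orientation_factor * p.a_xx * X * X
        f_xx = p.kappa * th * Cxx
        f_xh = p.kappa * th * Cxh
        f_xp = p.kappa * th * Cxp
        f_hp = p.kappa * th * Chp
        b_xx, b_xh, b_xp, b_hp = (p.b("xx"), p.b("xh"), p.b("xp"), p.b("hp"))
        mut = p.mu * (f_xx + f_xh)        # mutant flux from X replication
        lam_P = p.lam_P if p.include_parasites else 0.0
        lam_J = p.lam_J if p.include_parasites else p.lam_J + p.lam_P
        # decay acts per molecule: a dying partner frees the survivor,
        # so each complex is destroyed by decay at rate 2d and returns one
        # constituent per destruction
        dX = (-2 * F_xx + 2 * b_xx * Cxx + f_xx * (2 + (1 - p.mu))
              - p.a_xh * X * H + b_xh * Cxh + f_xh * (1 + (1 - p.mu))
              - p.a_xp * X * P + b_xp * Cxp + f_xp
              + p.d * (2 * Cxx + Cxh + Cxp)
              - p.d * X)
        dH = (p.lam_H * mut
              - p.a_xh * X * H + b_xh * Cxh + f_xh
              - p.a_hp * H * P + b_hp * Chp + f_hp
              + p.d * (Cxh + Chp)
              - p.d * H)
        dP = (lam_P * mut
              - p.a_xp * X * P + b_xp * Cxp + 2 * f_xp
              - p.a_hp * H * P + b_hp * Chp + 2 * f_hp
              + p.d * (Cxp + Chp)
              - p.d * P)
        dJ = lam_J * mut - p.d * J
        dCxx = F_xx - b_xx * Cxx - f_xx - 2 * p.d * Cxx
        dCxh = p.a_xh * X * H - b_xh * Cxh - f_xh - 2 * p.d * Cxh
        dCxp = p.a_xp * X * P - b_xp * Cxp - f_xp - 2 * p.d * Cxp
        dChp = p.a_hp * H * P - b_hp * Chp - f_hp - 2 * p.d * Chp
        if not p.include_parasites:
            dP = dCxp = dChp = 0.0
        return np.array([dX, dH, dP, dJ, dCxx, dCxh, dCxp, dChp])


class StallerModel(OdeModel):
    """Reaction scheme with stallers (sequestering, unproductive complexes)."""

    species = ("X", "S", "P", "J", "Cxx", "Cpx", "Cxs", "Cps")
    weights = np.array([1, 1, 1, 1, 2, 2, 2, 2], dtype=float)

    def __init__(self, params: OdeParams2):
        super().__init__(params)

    def rhs(self, y):
        p = self.params
        if np.any(np.asarray(y) < -1e-9):
            raise ValueError("state must be nonnegative")
        X, S, P, J, Cxx, Cpx, Cxs, Cps = y
        th = self.theta(np.asarray(y, dtype=float))
        F_xx = p.xx_orientation_factor * p.a_xx * X * X
        f_xx = p.kappa * th * Cxx
        f_px = p.kappa * th * Cpx
        b_xx, b_px, b_xs, b_ps = (p.b("xx"), p.b("px"), p.b("xs"), p.b("ps"))
        lam_sp, lam_jp = p.parasite_mutant_split()
        # per-molecule decay: complexes destroyed at 2d, survivor freed
        dX = (-2 * F_xx + 2 * b_xx * Cxx + f_xx * (2 + (1 - p.mu))
              - p.a_px * P * X + b_px * Cpx + f_px
              - p.a_xs * X * S + b_xs * Cxs
              + p.d * (2 * Cxx + Cpx + Cxs)
              - p.d * X)
        dS = (p.mu * p.lam_S * f_xx + p.mu * lam_sp * f_px
              - p.a_xs * X * S + b_xs * Cxs
              - p.a_ps * P * S + b_ps * Cps
              + p.d * (Cxs + Cps)
              - p.d * S)
        dP = (p.mu * p.lam_P * f_xx
              - p.a_px * P * X + b_px * Cpx + f_px * (1 + (1 - p.mu))
              - p.a_ps * P * S + b_ps * Cps
              + p.d * (Cpx + Cps)
              - p.d * P)
        dJ = p.mu * p.lam_J * f_xx + p.mu * lam_jp * f_px - p.d * J
        dCxx = F_xx - b_xx * Cxx - f_xx - 2 * p.d * Cxx
        dCpx = p.a_px * P * X - b_px * Cpx - f_px - 2 * p.d * Cpx
        dCxs = p.a_xs * X * S - b_xs * Cxs - 2 * p.d * Cxs
        dCps = p.a_ps * P * S - b_ps * Cps - 2 * p.d * Cps
        return np.array([dX, dS, dP, dJ, dCxx, dCpx, dCxs, dCps])


# ---------------------------------------------------------------------------
# integration and equilibria


def integrate(model: OdeModel, y0, t_span, rtol=1e-8, atol=1e-10,
              t_eval=None):
    """Stiff-capable integration; the nonnegative orthant is preserved by
    evaluating the RHS on the clipped state."""
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    sol = solve_ivp(model, t_span, y0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    sol.y = np.maximum(sol.y, 0.0)
    return sol


def find_equilibrium(model: OdeModel, y_guess, tol=1e-10):
    """Newton-polish an equilibrium from a guess; returns None on failure."""
    sol = root(lambda y: model.rhs(np.maximum(y, 0.0)), np.asarray(y_guess, float),
               method="hybr", tol=tol)
    if not sol.success:
        return None
    y = np.maximum(sol.x, 0.0)
    if np.max(np.abs(model.rhs(y))) > 1e-6:
        return None
    return y


@dataclass
class BranchPoint:
    param: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool


@dataclass
class EquilibriumBranch:
    free_param: str
    points: list = field(default_factory=list)

    @property
    def params(self):
        return np.array([p.param for p in self.points])

    def states(self):
        return np.array([p.state for p in self.points])


@dataclass
class BifurcationPoint:
    kind: str          # fold | Hopf | transcritical | homoclinic_estimate
    param: float
    state: np.ndarray


def _branch_point(model, y, p_val):
    eig = np.linalg.eigvals(model.jacobian(y))
    return BranchPoint(param=float(p_val), state=y, eigenvalues=eig,
                       stable=bool(np.max(eig.real) < 0))


def continue_equilibria(model: OdeModel, free_param: str, p_start: float,
                        p_stop: float, y0_guess, step: float = 0.01,
                        max_points: int = 2000) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium branch.

    Follows the branch from ``p_start`` toward ``p_stop``, around folds if
    necessary.  Each accepted point records the state-Jacobian eigenvalues
    and a stability flag.  The branch is truncated (with the points found
    so far) if Newton correction fails repeatedly.
    """
    branch = EquilibriumBranch(free_param=free_param)
    direction = 1.0 if p_stop >= p_start else -1.0
    p_lo, p_hi = min(p_start, p_stop), max(p_start, p_stop)

    def model_at(p_val):
        return model.with_params(**{free_param: float(p_val)})

    y = find_equilibrium(model_at(p_start), y0_guess)
    if y is None:
        return branch
    branch.points.append(_branch_point(model_at(p_start), y, p_start))

    n = y.size
    # initial tangent: mostly along the parameter
    tangent = np.zeros(n + 1)
    tangent[-1] = direction
    z = np.concatenate([y, [p_start]])
    h = step
    failures = 0
    while len(branch.points) < max_points:
        z_pred = z + h * tangent

        def aug(zz):
            yy, pp = zz[:n], zz[n]
            return np.concatenate([model_at(pp).rhs(np.maximum(yy, 0.0)),
                                   [tangent @ (zz - z_pred)]])

        sol = root(aug, z_pred, method="hybr", tol=1e-10)
        ok = sol.success and np.max(np.abs(aug(sol.x)[:n])) < 1e-6
        if not ok:
            h *= 0.5
            failures += 1
            if failures > 8:
                break
            continue
        failures = 0
        z_new = sol.x
        z_new[:n] = np.maximum(z_new[:n], 0.0)
        new_tan = z_new - z
        norm = np.linalg.norm(new_tan)
        if norm > 0:
            tangent = new_tan / norm
        z = z_new
        p_val = z[n]
        branch.points.append(_branch_point(model_at(p_val), z[:n].copy(), p_val))
        h = min(step, h * 1.5)
        if p_val > p_hi + step or p_val < p_lo - step:
            break
    return branch


def detect_bifurcations(branch: EquilibriumBranch) -> list:
    """Classify qualitative changes along a continued branch.

    * fold: the continuation turns around in the free parameter while a
      real eigenvalue is near zero;
    * Hopf: the real part of the leading complex-conjugate pair changes
      sign;
    * transcritical: a state component hits zero along the branch (the
      branch meets the extinction/boundary equilibrium) with a real
      eigenvalue crossing.
    """
    out = []
    pts = branch.points
    for i in range(1, len(pts) - 1):
        dp_prev = pts[i].param - pts[i - 1].param
        dp_next = pts[i + 1].param - pts[i].param
        if dp_prev * dp_next < 0:
            real_eigs = pts[i].eigenvalues.real
            if np.min(np.abs(real_eigs)) < 0.1:
                out.append(BifurcationPoint("fold", pts[i].param, pts[i].state))
    for i in range(1, len(pts)):
        prev_c = pts[i - 1].eigenvalues[np.abs(pts[i - 1].eigenvalues.imag) > 1e-8]
        cur_c = pts[i].eigenvalues[np.abs(pts[i].eigenvalues.imag) > 1e-8]
        if prev_c.size and cur_c.size:
            if np.max(prev_c.real) * np.max(cur_c.real) < 0:
                out.append(BifurcationPoint("Hopf", pts[i].param, pts[i].state))
    for i in range(1, len(pts)):
        prev_min = np.min(pts[i - 1].state)
        cur_min = np.min(pts[i].state)
        if prev_min > 1e-6 and cur_min <= 1e-6:
            out.append(BifurcationPoint("transcritical", pts[i].param,
                                        pts[i].state))
    return out


def estimate_homoclinic(model_factory: Callable[[float], OdeModel],
                        param_values, y0, t_end: float = 4000.0,
                        period_blowup: float = 4.0):
    """Rough homoclinic-bifurcation locator via limit-cycle period growth.

    Integrates at each parameter value, measures the oscillation period of
    the X coordinate on the trailing half of the trajectory, and returns a
    ``homoclinic_estimate`` point at the first parameter where the period
    has grown by more than ``period_blowup`` relative to the first
    oscillatory value (or the cycle disappears after oscillating).  Returns
    None if no such signature is found.  This is an estimate, not a
    normal-form classification.
    """
    base_period = None
    prev = None
    for pv in param_values:
        model = model_factory(pv)
        sol = integrate(model, y0, (0.0, t_end),
                        t_eval=np.linspace(t_end / 2, t_end, 2000))
        x = sol.y[0]
        period = _oscillation_period(sol.t, x)
        if period is not None:
            if base_period is None:
                base_period = period
            elif period > period_blowup * base_period:
                return BifurcationPoint("homoclinic_estimate", float(pv),
                                        sol.y[:, -1])
        elif base_period is not None and prev is not None:
            return BifurcationPoint("homoclinic_estimate", float(pv),
                                    sol.y[:, -1])
        prev = pv
    return None


def _oscillation_period(t, x, rel_amp=0.05):
    """Mean peak-to-peak period of a clearly oscillating signal, else None."""
    if x.max() - x.min() < rel_amp * max(x.max(), 1e-12):
        return None
    peaks = [i for i in range(1, len(x) - 1)
             if x[i] >= x[i - 1] and x[i] > x[i + 1]]
    if len(peaks) < 3:
        return None
    return float(np.mean(np.diff(t[np.array(peaks)])))


def persistence_threshold(model_factory: Callable[[float], OdeModel],
                          param_values, y0, t_end: float = 3000.0,
                          tol: float = 1e-3):
    """Largest parameter value at which the replicator persists.

    Integrates from ``y0`` at each value (assumed sorted increasing) and
    reports the largest one whose trailing-average X stays above ``tol``;
    None if none does.  This measures the practically reachable viable
    regime rather than the exact bifurcation coordinate.
    """
    last_ok = None
    for pv in param_values:
        model = model_factory(pv)
        sol = integrate(model, y0, (0.0, t_end),
                        t_eval=np.linspace(0.9 * t_end, t_end, 50))
        if float(np.mean(sol.y[0])) > tol:
            last_ok = float(pv)
    return last_ok
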