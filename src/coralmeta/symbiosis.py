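"""Tripartite coral–Symbiodiniaceae–prokaryote symbiosis dynamics.

The model couples coral biomass H, Symbiodiniaceae density S, and
prokaryotic density B:

    dH/dt = r·H·(1 − H/(K + γ1·S + γ2·S·B)) − a1·S·H − a2·B·H
    dS/dt = g1·H·S·(1 + b1·B) − d1·S·(1 + e1·S + c1·B)
    dB/dt = g2·H·B·(1 + b2·S) − d2·B·(1 + e2·B + c2·S)

Coral grows logistically with a capacity expanded by symbiont benefits
(γ1, γ2) and pays per-partner costs (a1, a2); each microbial partner grows
with host biomass, gains from the other partner (b1, b2), and dies at an
independent rate (d1, d2) with crowding (e1, e2) and interpartner
competition (c1, c2).

On a boundary plane where one partner is absent, the surviving partner's
equilibrium density has the closed form

    λ_i = (1/e_i) · ((g_i/d_i)·H̄ − 1)

with H̄ the coral biomass at that boundary equilibrium; λ ≤ 0 means that
partner cannot invade at that biomass. The module finds all equilibria
(origin, coral-only at K, the two boundary planes, and interior coexistence)
by root-finding with an analytic Jacobian, classifies their stability, and
labels the regime: the in-model mutualism/parasitism criterion is whether
coral equilibrium biomass with symbionts present exceeds or falls below the
symbiont-free capacity K.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .errors import ConfigError, NumericalError

_PARAM_NAMES = (
    "r", "K", "gamma1", "gamma2", "a1", "a2",
    "g1", "g2", "b1", "b2", "d1", "d2", "e1", "e2", "c1", "c2",
)


@dataclass(frozen=True)
class SymbiosisParams:
    """Nonnegative model parameters; e_i and d_i must be strictly positive."""

    r: float = 1.0
    K: float = 1.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    g1: float = 1.0
    g2: float = 1.0
    b1: float = 0.0
    b2: float = 0.0
    d1: float = 0.5
    d2: float = 0.5
    e1: float = 1.0
    e2: float = 1.0
    c1: float = 0.0
    c2: float = 0.0

    def __post_init__(self):
        for name in _PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ConfigError(f"parameter {name} must be nonnegative")
        for name in ("d1", "d2", "e1", "e2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be > 0")
        if self.K <= 0:
            raise ConfigError("K must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SymbiosisParams":
        unknown = set(d) - set(_PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


#: Illustrative parameter sets spanning the qualitative regimes. These are
#: the package's own examples, chosen so each regime is realized and easy to
#: inspect; they are not estimates from any dataset.
EXAMPLE_PARAMS: dict[str, SymbiosisParams] = {
    "mutualism": SymbiosisParams(
        r=1.0, K=1.0, gamma1=1.0, a1=0.05, g1=1.0, d1=0.5, e1=1.0,
        g2=0.15, d2=1.0, e2=1.0,
    ),
    "parasitism": SymbiosisParams(
        r=1.0, K=1.0, gamma1=0.0, a1=0.2, g1=1.0, d1=0.5, e1=1.0,
        g2=0.2, d2=1.0, e2=1.0,
    ),
    "coexistence": SymbiosisParams(
        r=1.0, K=1.0, gamma1=1.0, gamma2=0.1, a1=0.05, a2=0.05,
        g1=1.0, g2=1.0, b1=0.1, b2=0.1, d1=0.5, d2=0.5,
        e1=1.0, e2=1.0, c1=0.2, c2=0.2,
    ),
    "exclusion": SymbiosisParams(
        r=1.0, K=1.0, gamma1=1.0, gamma2=0.1, a1=0.05, a2=0.05,
        g1=1.0, g2=1.0, b1=0.0, b2=0.0, d1=0.5, d2=0.5,
        e1=1.0, e2=1.0, c1=5.0, c2=5.0,
    ),
}


def derivatives(state, params: SymbiosisParams) -> np.ndarray:
    """(dH/dt, dS/dt, dB/dt) at one state."""
    H, S, B = state
    p = params
    cap = p.K + p.gamma1 * S + p.gamma2 * S * B
    if cap == 0:
        raise NumericalError("singular capacity: K + γ1·S + γ2·S·B = 0")
    dH = p.r * H * (1.0 - H / cap) - p.a1 * S * H - p.a2 * B * H
    dS = p.g1 * H * S * (1.0 + p.b1 * B) - p.d1 * S * (1.0 + p.e1 * S + p.c1 * B)
    dB = p.g2 * H * B * (1.0 + p.b2 * S) - p.d2 * B * (1.0 + p.e2 * B + p.c2 * S)
    return np.array([dH, dS, dB])


def jacobian(state, params: SymbiosisParams) -> np.ndarray:
    """Analytic Jacobian of the vector field."""
    H, S, B = state
    p = params
    cap = p.K + p.gamma1 * S + p.gamma2 * S * B
    dcap_dS = p.gamma1 + p.gamma2 * B
    dcap_dB = p.gamma2 * S
    J = np.empty((3, 3))
    J[0, 0] = p.r * (1.0 - 2.0 * H / cap) - p.a1 * S - p.a2 * B
    J[0, 1] = p.r * H**2 * dcap_dS / cap**2 - p.a1 * H
    J[0, 2] = p.r * H**2 * dcap_dB / cap**2 - p.a2 * H
    J[1, 0] = p.g1 * S * (1.0 + p.b1 * B)
    J[1, 1] = p.g1 * H * (1.0 + p.b1 * B) - p.d1 * (1.0 + 2.0 * p.e1 * S + p.c1 * B)
    J[1, 2] = p.g1 * H * S * p.b1 - p.d1 * S * p.c1
    J[2, 0] = p.g2 * B * (1.0 + p.b2 * S)
    J[2, 1] = p.g2 * H * B * p.b2 - p.d2 * B * p.c2
    J[2, 2] = p.g2 * H * (1.0 + p.b2 * S) - p.d2 * (1.0 + 2.0 * p.e2 * B + p.c2 * S)
    return J


def simulate(
    params: SymbiosisParams,
    initial,
    t_end: float,
    t_eval=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Adaptive integration of the model from a nonnegative initial state.

    Returns (t, states) with states of shape (len(t), 3). Tiny negative
    values within solver tolerance are clipped to 0.
    """
    y0 = np.asarray(initial, dtype=float)
    if (y0 < 0).any():
        raise ConfigError("initial state must be nonnegative")
    if t_end <= 0:
        raise ConfigError("t_end must be > 0")
    sol = solve_ivp(
        lambda t, y: derivatives(y, params),
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        jac=lambda t, y: jacobian(y, params),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"integration failed: {sol.message}")
    states = sol.y.T
    states[(states < 0) & (states > -100 * atol)] = 0.0
    return sol.t, states


def boundary_lambda(params: SymbiosisParams, partner: int, H_bar: float) -> float:
    """Closed-form partner density λ_i = (1/e_i)·((g_i/d_i)·H̄ − 1).

    ``partner`` is 1 (Symbiodiniaceae) or 2 (prokaryotes); ``H_bar`` the coral
    biomass of the boundary equilibrium where the *other* partner is absent.
    Negative values signal that the partner cannot invade at that biomass.
    """
    if partner not in (1, 2):
        raise ConfigError("partner must be 1 (S) or 2 (B)")
    g = params.g1 if partner == 1 else params.g2
    d = params.d1 if partner == 1 else params.d2
    e = params.e1 if partner == 1 else params.e2
    return (1.0 / e) * ((g / d) * H_bar - 1.0)


@dataclass
class Equilibrium:
    """One fixed point with residual, classification and stability."""

    state: np.ndarray
    kind: str          # trivial | coral-only | coral-algal | coral-prokaryote | coexistence
    stability: str     # stable | unstable | marginal
    residual: float
    eigenvalues: np.ndarray
    boundary: dict = field(default_factory=dict)  # H_bar / lambda values where applicable

    @property
    def H(self) -> float:
        return float(self.state[0])

    @property
    def S(self) -> float:
        return float(self.state[1])

    @property
    def B(self) -> float:
        return float(self.state[2])


def _classify_kind(state: np.ndarray, tol: float) -> str:
    H, S, B = state
    if H <= tol and S <= tol and B <= tol:
        return "trivial"
    if S <= tol and B <= tol:
        return "coral-only"
    if B <= tol:
        return "coral-algal"
    if S <= tol:
        return "coral-prokaryote"
    return "coexistence"


def _stability(state: np.ndarray, params: SymbiosisParams, tol: float = 1e-8) -> tuple[str, np.ndarray]:
    eig = np.linalg.eigvals(jacobian(state, params))
    mx = float(np.max(eig.real))
    if mx < -tol:
        return "stable", eig
    if mx > tol:
        return "unstable", eig
    return "marginal", eig


def _boundary_roots(params: SymbiosisParams, absent: str, H_max: float) -> list[np.ndarray]:
    """Equilibria on the B=0 (absent="B") or S=0 (absent="S") plane.

    On each plane the surviving partner's zero-growth condition gives its
    density as the λ closed form in H; substituting into the coral equation
    leaves a 1D root-finding problem in H.
    """
    p = params
    if absent == "B":
        g, d, e = p.g1, p.d1, p.e1
        def partner_density(H):
            return (g * H / d - 1.0) / e
        def f(H):
            S = partner_density(H)
            cap = p.K + p.gamma1 * S
            return p.r * (1.0 - H / cap) - p.a1 * S
        def to_state(H):
            return np.array([H, partner_density(H), 0.0])
    else:
        g, d, e = p.g2, p.d2, p.e2
        def partner_density(H):
            return (g * H / d - 1.0) / e
        def f(H):
            B = partner_density(H)
            return p.r * (1.0 - H / p.K) - p.a2 * B
        def to_state(H):
            return np.array([H, 0.0, partner_density(H)])

    H_min = d / g  # below this the partner density is negative
    if H_min >= H_max:
        return []
    grid = np.linspace(H_min * (1 + 1e-9), H_max, 400)
    vals = np.array([f(H) for H in grid])
    out = []
    for i in range(len(grid) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
            H_star = brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15)
            st = to_state(H_star)
            if st[1] >= 0 and st[2] >= 0:
                out.append(st)
    return out


def find_equilibria(
    params: SymbiosisParams,
    grid_points: int = 6,
    tol: float = 1e-9,
    state_max: float | None = None,
) -> list[Equilibrium]:
    """All nonnegative equilibria: analytic special points, boundary-plane
    roots, and multistart interior root-finding; duplicates merged.

    ``state_max`` bounds the search box (default scales with K and the
    boundary densities).
    """
    p = params
    H_max = state_max or max(
        10.0 * p.K,
        10.0 * p.K * (1.0 + p.gamma1 * 5.0),
        5.0,
    )
    candidates: list[np.ndarray] = [np.zeros(3), np.array([p.K, 0.0, 0.0])]
    candidates += _boundary_roots(params, "B", H_max)
    candidates += _boundary_roots(params, "S", H_max)

    # interior multistart in log-coordinates (keeps the search strictly
    # positive, away from the invariant planes and capacity singularities)
    def field_log(z):
        x = np.exp(z)
        return derivatives(x, params)

    def jac_log(z):
        x = np.exp(z)
        return jacobian(x, params) * x[None, :]

    axes = np.geomspace(1e-2, H_max, grid_points)
    for H0 in axes:
        for S0 in axes:
            for B0 in axes:
                with np.errstate(over="ignore", invalid="ignore"):
                    try:
                        sol = root(
                            field_log,
                            np.log(np.array([H0, S0, B0])),
                            jac=jac_log,
                            method="hybr",
                            tol=1e-12,
                        )
                    except (NumericalError, FloatingPointError):
                        continue
                if not sol.success or not np.all(np.isfinite(sol.x)):
                    continue
                st = np.exp(sol.x)
                st[st < 1e-10] = 0.0
                if np.linalg.norm(derivatives(st, params)) < 1e-8:
                    candidates.append(st)

    # merge duplicates
    merged: list[np.ndarray] = []
    for st in candidates:
        if not any(np.linalg.norm(st - m) < 1e-6 * (1 + np.linalg.norm(m)) for m in merged):
            merged.append(st)

    out: list[Equilibrium] = []
    kind_tol = 1e-7
    for st in merged:
        res = float(np.linalg.norm(derivatives(st, params)))
        if res > 1e-7:
            continue
        kind = _classify_kind(st, kind_tol)
        stab, eig = _stability(st, params)
        boundary = {}
        if kind == "coral-algal":
            boundary["H_bar_B"] = float(st[0])
            boundary["lambda1_B"] = boundary_lambda(params, 1, st[0])
            boundary["lambda2_B"] = boundary_lambda(params, 2, st[0])
        elif kind == "coral-prokaryote":
            boundary["H_bar_S"] = float(st[0])
            boundary["lambda1_S"] = boundary_lambda(params, 1, st[0])
            boundary["lambda2_S"] = boundary_lambda(params, 2, st[0])
        out.append(
            Equilibrium(
                state=st, kind=kind, stability=stab, residual=res,
                eigenvalues=eig, boundary=boundary,
            )
        )
    order = {"trivial": 0, "coral-only": 1, "coral-algal": 2, "coral-prokaryote": 3, "coexistence": 4}
    out.sort(key=lambda e: (order[e.kind], e.H))
    return out


def isoclines(
    params: SymbiosisParams,
    plane: tuple[str, float] = ("B", 0.0),
    bounds: tuple[float, float, float, float] = (0.0, 3.0, 0.0, 3.0),
    n: int = 200,
) -> dict[str, np.ndarray]:
    """Nullcline point sets of each rate equation restricted to a plane.

    ``plane`` fixes one variable, e.g. ("B", 0.0) for the (H, S) plane. Zero
    crossings of each rate are located by sign changes along grid edges with
    linear interpolation; each entry of the returned dict is an (m, 2) array
    of (x, y) points in the plane's free coordinates.
    """
    fixed_var, fixed_val = plane
    if fixed_var not in ("H", "S", "B"):
        raise ConfigError("plane variable must be H, S or B")
    free = [v for v in ("H", "S", "B") if v != fixed_var]
    x0, x1, y0, y1 = bounds
    if x1 <= x0 or y1 <= y0:
        raise ConfigError("grid bounds must be increasing")
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)

    def state_at(x, y):
        d = {fixed_var: fixed_val, free[0]: x, free[1]: y}
        return np.array([d["H"], d["S"], d["B"]])

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    F = np.empty((3, n, n))
    for i in range(n):
        for j in range(n):
            F[:, i, j] = derivatives(state_at(X[i, j], Y[i, j]), params)

    out = {}
    for k, name in enumerate(("H", "S", "B")):
        pts = []
        V = F[k]
        sx = V[:-1, :] * V[1:, :]
        ii, jj = np.nonzero(sx < 0)
        for i, j in zip(ii, jj):
            frac = V[i, j] / (V[i, j] - V[i + 1, j])
            pts.append((xs[i] + frac * (xs[i + 1] - xs[i]), ys[j]))
        sy = V[:, :-1] * V[:, 1:]
        ii, jj = np.nonzero(sy < 0)
        for i, j in zip(ii, jj):
            frac = V[i, j] / (V[i, j] - V[i, j + 1])
            pts.append((xs[i], ys[j] + frac * (ys[j + 1] - ys[j])))
        out[name] = np.array(pts) if pts else np.empty((0, 2))
    return out


@dataclass
class RegimeReport:
    """Qualitative regime labels plus the equilibria backing them."""

    coral_algal: str        # "mutualism" | "parasitism" | "no-symbiont"
    partners: str           # "coexistence" | "S-excluded" | "B-excluded" | "both-excluded"
    bistable: bool
    equilibria: list = field(default_factory=list)
    notes: str = ""


def classify_regime(params: SymbiosisParams, **kwargs) -> RegimeReport:
    """Label the coral-algal association and partner coexistence.

    Mutualism: a stable equilibrium with S > 0 has coral biomass above the
    symbiont-free capacity K; parasitism: below K. Coexistence: a stable
    equilibrium with both S > 0 and B > 0 exists; otherwise the report names
    the excluded partner(s). Multiple stable equilibria are all reported with
    basins noted as unresolved.
    """
    eqs = find_equilibria(params, **kwargs)
    stable = [e for e in eqs if e.stability == "stable"]
    tol = 1e-7
    with_S = [e for e in stable if e.S > tol]
    bistable = len(stable) > 1

    if not with_S:
        coral_algal = "no-symbiont"
    else:
        best = max(with_S, key=lambda e: e.H)
        rel = (best.H - params.K) / params.K
        coral_algal = "mutualism" if rel > 1e-6 else "parasitism"

    coexist = [e for e in stable if e.S > tol and e.B > tol]
    if coexist:
        partners = "coexistence"
    else:
        has_S = any(e.S > tol for e in stable)
        has_B = any(e.B > tol for e in stable)
        if has_S and not has_B:
            partners = "B-excluded"
        elif has_B and not has_S:
            partners = "S-excluded"
        elif has_S and has_B:
            partners = "bistable-exclusion"  # alternative stable single-partner states
        else:
            partners = "both-excluded"

    notes = "multiple stable equilibria; basins unresolved" if bistable else ""
    return RegimeReport(
        coral_algal=coral_algal,
        partners=partners,
        bistable=bistable,
        equilibria=eqs,
        notes=notes,
    )
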