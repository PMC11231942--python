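"""Random-distribution (mean-field) model of the BVOC emission game.

Ignoring spatial correlations, the number of emitters among the ``n``
individuals within signaling range of a focal plant is binomial with success
probability ``x_E``, the global emitter frequency. Averaging the compounded
inter-communication effect ``alpha2 ** k`` over that binomial gives the
closed form

    abar2(x_E) = (1 + (alpha2 - 1) * x_E) ** n,

which drives replicator dynamics ``dx_E/dt = g(x_E) = x_E (f_E - phi)``
with mean fitness ``phi``. The module provides the closed form (with an
explicit binomial-sum oracle for cross-checking), the equilibria and their
stability (ESS) classification, forward integration of the dynamics, and a
phase diagram over the (alpha1, alpha2) plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import fitness_emitter, fitness_nonemitter
from .params import ModelParams

__all__ = [
    "gross_inter_effect_meanfield",
    "binomial_gross_inter_oracle",
    "fitness_pair",
    "mean_fitness",
    "replicator_rhs",
    "replicator_slope",
    "interior_equilibrium",
    "coexistence_condition",
    "emission_viability_threshold",
    "emitter_fixation_bound",
    "Equilibrium",
    "EquilibriumReport",
    "classify_ess",
    "integrate_dynamics",
    "MeanFieldPhaseDiagram",
    "phase_diagram_meanfield",
]


def _check_frequency(x_e) -> None:
    x = np.asarray(x_e)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"x_e={x_e!r} outside valid range [0, 1]")


def gross_inter_effect_meanfield(x_e, alpha2: float, n: int):
    """Expected gross inter-communication effect at emitter frequency x_e.

    Closed form ``(1 + (alpha2 - 1) x_e) ** n`` of the binomial expectation
    of ``alpha2 ** k`` with k ~ Binomial(n, x_e).
    """
    _check_frequency(x_e)
    if not 0.0 < alpha2 < 1.0:
        raise ValueError(f"alpha2={alpha2!r} outside valid range (0, 1)")
    if n < 0:
        raise ValueError(f"n={n!r} must be >= 0")
    out = np.power(1.0 + (alpha2 - 1.0) * np.asarray(x_e), n)
    return out if out.ndim else float(out)


def binomial_gross_inter_oracle(x_e: float, alpha2: float, n: int) -> float:
    """Exact binomial sum ``sum_k alpha2**k * C(n,k) x_e**k (1-x_e)**(n-k)``.

    Independent brute-force oracle for :func:`gross_inter_effect_meanfield`;
    term-by-term summation with exact integer binomial coefficients,
    intended for n <= 64.
    """
    _check_frequency(x_e)
    return float(sum(
        alpha2 ** k * math.comb(n, k) * x_e ** k * (1.0 - x_e) ** (n - k)
        for k in range(n + 1)
    ))


def fitness_pair(x_e: float, params: ModelParams) -> tuple[float, float]:
    """(f_E, f_N) at emitter frequency x_e under the mean-field effect."""
    abar = gross_inter_effect_meanfield(x_e, params.alpha2, params.n)
    f_e = float(fitness_emitter(params.alpha1, abar, params.p, params.c, params.fhat))
    f_n = float(fitness_nonemitter(abar, params.p, params.fhat))
    return f_e, f_n


def mean_fitness(x_e: float, params: ModelParams) -> float:
    """Population mean fitness phi = x_E f_E + (1 - x_E) f_N."""
    f_e, f_n = fitness_pair(x_e, params)
    return x_e * f_e + (1.0 - x_e) * f_n


def replicator_rhs(x_e: float, params: ModelParams) -> float:
    """g(x_E) = x_E (f_E - phi) = x_E (1 - x_E)(f_E - f_N)."""
    f_e, f_n = fitness_pair(x_e, params)
    return x_e * (1.0 - x_e) * (f_e - f_n)


def replicator_slope(x_e: float, params: ModelParams, h: float = 1e-6) -> float:
    """dg/dx_E by central finite difference (the stability criterion).

    The replicator right-hand side extends smoothly beyond [0, 1], so the
    central difference is well defined at the boundary equilibria too.
    """

    def g(x: float) -> float:
        abar = (1.0 + (params.alpha2 - 1.0) * x) ** params.n
        f_e = (1.0 - params.p * params.alpha1 * abar) * (1.0 - params.c) * params.fhat
        f_n = (1.0 - params.p * abar) * params.fhat
        return x * (1.0 - x) * (f_e - f_n)

    return (g(x_e + h) - g(x_e - h)) / (2.0 * h)


def emission_viability_threshold(p: float, c: float) -> float:
    """Largest alpha1 at which emission can pay: (p - c) / (p (1 - c)).

    Emission is viable only if the emitter out-produces the non-emitter even
    with no inter-communication (all neighbors' signals ignored); that holds
    iff alpha1 is below this threshold. Nonpositive when c >= p.
    """
    return (p - c) / (p * (1.0 - c))


def emitter_fixation_bound(p: float, c: float, alpha2: float, n: int) -> float:
    """Lower band edge (alpha2^n p - c) / (alpha2^n p (1 - c)).

    Below this alpha1, the all-emitter state is an ESS; may be negative, in
    which case emitters never fix deterministically.
    """
    a = alpha2 ** n * p
    return (a - c) / (a * (1.0 - c))


def interior_equilibrium(params: ModelParams) -> Optional[float]:
    """Coexistence equilibrium x_E* in (0, 1), or None if absent.

    Solves f_E(x) = f_N(x): the gross effect must equal
    ``c / (p (1 + (c - 1) alpha1))``; inverting the closed form gives
    ``x_E* = (target**(1/n) - 1) / (alpha2 - 1)``. Returns None when the
    target is nonpositive or the root falls outside (0, 1).
    """
    denom = params.p * (1.0 + (params.c - 1.0) * params.alpha1)
    if denom <= 0.0:
        return None
    target = params.c / denom
    if target <= 0.0 or params.n == 0:
        return None
    x = (target ** (1.0 / params.n) - 1.0) / (params.alpha2 - 1.0)
    if 0.0 < x < 1.0:
        return float(x)
    return None


def coexistence_condition(params: ModelParams) -> bool:
    """True iff the coexistence band holds:
    (alpha2^n p - c)/(alpha2^n p (1-c)) < alpha1 < (p - c)/(p (1 - c))."""
    lo = emitter_fixation_bound(params.p, params.c, params.alpha2, params.n)
    hi = emission_viability_threshold(params.p, params.c)
    return lo < params.alpha1 < hi


@dataclass(frozen=True)
class Equilibrium:
    x_e: float
    kind: str  # monomorphic_nonemitter | monomorphic_emitter | coexistent
    stable: Optional[bool]  # None when the parameter point is marginal

    def to_dict(self) -> dict:
        return {"x_e": self.x_e, "kind": self.kind, "stable": self.stable}


@dataclass(frozen=True)
class EquilibriumReport:
    """All equilibria of the replicator dynamics with stability labels."""

    equilibria: tuple[Equilibrium, ...]
    params: ModelParams
    marginal: bool = False

    @property
    def stable_density(self) -> float:
        """Emitter density at the stable equilibrium (nan if marginal)."""
        for eq in self.equilibria:
            if eq.stable:
                return eq.x_e
        return float("nan")

    @property
    def regime(self) -> str:
        if self.marginal:
            return "marginal"
        for eq in self.equilibria:
            if eq.stable:
                return {
                    "monomorphic_emitter": "emitter-dominant",
                    "coexistent": "coexistent",
                    "monomorphic_nonemitter": "nonemitter-dominant",
                }[eq.kind]
        return "marginal"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "equilibria": [eq.to_dict() for eq in self.equilibria],
            "marginal": self.marginal,
            "regime": self.regime,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def classify_ess(params: ModelParams, boundary_tol: float = 1e-9) -> EquilibriumReport:
    """Classify every equilibrium as ESS / unstable via the sign of dg/dx_E.

    Stability is computed from the central finite difference of the
    replicator right-hand side at each equilibrium; the analytic band
    structure on alpha1 (fixation bound and viability threshold) determines
    whether the interior root exists. A point within ``boundary_tol`` of a
    band edge is labeled marginal and carries no stability claim.
    """
    lo = emitter_fixation_bound(params.p, params.c, params.alpha2, params.n)
    hi = emission_viability_threshold(params.p, params.c)
    marginal = (
        abs(params.alpha1 - lo) <= boundary_tol
        or abs(params.alpha1 - hi) <= boundary_tol
    )

    def stability(x: float) -> Optional[bool]:
        if marginal:
            return None
        return replicator_slope(x, params) < 0.0

    eqs = [Equilibrium(0.0, "monomorphic_nonemitter", stability(0.0))]
    x_int = interior_equilibrium(params)
    if x_int is not None and not marginal:
        eqs.append(Equilibrium(x_int, "coexistent", stability(x_int)))
    eqs.append(Equilibrium(1.0, "monomorphic_emitter", stability(1.0)))
    return EquilibriumReport(tuple(eqs), params, marginal)


def integrate_dynamics(
    x0: float,
    params: ModelParams,
    t_max: float = 5000.0,
    dt: float = 1.0,
    gtol: float = 1e-13,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-integrate dx_E/dt = g(x_E) from x0.

    Uses an explicit adaptive Runge–Kutta scheme; the state is clipped to
    [0, 1] inside the right-hand side and on output (the flow cannot leave
    [0, 1] analytically; clipping guards round-off). Returns (t, x_E)
    sampled every ``dt``. Integration stops early once |g| falls below
    ``gtol`` (the flow has reached an equilibrium to machine resolution);
    pass ``gtol=0`` to disable.

    Raises
    ------
    RuntimeError
        If the integrator fails or produces a non-finite state.
    """
    if not 0.0 <= x0 <= 1.0:
        raise ValueError(f"x0={x0!r} outside valid range [0, 1]")

    # scalar-math right-hand side: the integrator calls it thousands of
    # times, so avoid array allocation and re-validation on every call
    a2m1, n = params.alpha2 - 1.0, params.n
    fhat, c, p = params.fhat, params.c, params.p

    def rhs(_t: float, y) -> list[float]:
        x = min(max(float(y[0]), 0.0), 1.0)
        abar = (1.0 + a2m1 * x) ** n
        f_e = (1.0 - params.alpha1 * p * abar) * (1.0 - c) * fhat
        f_n = (1.0 - p * abar) * fhat
        return [x * (1.0 - x) * (f_e - f_n)]

    def converged(t: float, y) -> float:
        return abs(rhs(t, y)[0]) - gtol

    converged.terminal = gtol > 0.0

    t_eval = np.arange(0.0, t_max + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs, (0.0, t_max), [x0], t_eval=t_eval,
        method="RK45", rtol=rtol, atol=atol,
        events=converged if gtol > 0.0 else None,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    t, x = sol.t, sol.y[0]
    if gtol > 0.0 and sol.t_events and sol.t_events[0].size:
        # converged between sample points: append the equilibrium state
        t = np.append(t, sol.t_events[0][-1])
        x = np.append(x, sol.y_events[0][-1][0])
    return t, np.clip(x, 0.0, 1.0)


@dataclass(frozen=True)
class MeanFieldPhaseDiagram:
    """Stable equilibrium density over a grid of (alpha1, alpha2)."""

    alpha1_values: np.ndarray
    alpha2_values: np.ndarray
    stable_density: np.ndarray  # shape (len(alpha2), len(alpha1))
    regime: np.ndarray  # same shape, dtype object (strings)
    params_base: ModelParams

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.alpha1_values, self.alpha2_values)
        return pd.DataFrame({
            "alpha1": a1.ravel(),
            "alpha2": a2.ravel(),
            "stable_density": self.stable_density.ravel(),
            "regime": self.regime.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def phase_diagram_meanfield(
    alpha1_grid,
    alpha2_grid,
    params_base: ModelParams,
) -> MeanFieldPhaseDiagram:
    """Stable equilibrium emitter density for each (alpha1, alpha2) cell.

    Grid defaults elsewhere use a 0.01 step over the open unit interval;
    the diagram partitions into emitter-dominant, coexistent and
    nonemitter-dominant regions separated by the two closed-form curves
    alpha1 = (alpha2^n p - c)/(alpha2^n p (1-c)) and
    alpha1 = (p - c)/(p (1 - c)).
    """
    a1 = np.asarray(alpha1_grid, dtype=float)
    a2 = np.asarray(alpha2_grid, dtype=float)
    if np.any(a1 <= 0) or np.any(a1 > 1) or np.any(a2 <= 0) or np.any(a2 >= 1):
        raise ValueError("alpha grids must lie within (0, 1)")
    dens = np.empty((a2.size, a1.size))
    regime = np.empty((a2.size, a1.size), dtype=object)
    for i, alpha2 in enumerate(a2):
        for j, alpha1 in enumerate(a1):
            rep = classify_ess(params_base.with_(alpha1=float(alpha1),
                                                 alpha2=float(alpha2)))
            dens[i, j] = rep.stable_density
            regime[i, j] = rep.regime
    return MeanFieldPhaseDiagram(a1, a2, dens, regime, params_base)
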