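"""Pressure-driven intracellular signalling in vascular smooth muscle.

Seven normalized variables describe the state of one SMC ring:

====  =======================  ===================================
 i    variable                 role
====  =======================  ===================================
 0    Ca2+ concentration       drives LC20 phosphorylation
 1    ROCK activity            Ca2+-sensitization pathway
 2    HSP27 phosphorylation    promotes actin polymerization
 3    MLCP phosphorylation     inhibits LC20 dephosphorylation
 4    cofilin phosphorylation  promotes actin polymerization
 5    LC20 phosphorylation     enables cross-bridge cycling
 6    G-actin content          1 - F-actin (cortex stiffness)
====  =======================  ===================================

Each variable relaxes towards a target assembled from logistic links
chi_0..chi_8, each connecting one input (luminal pressure or an upstream
variable) to one equation:

    d xi_i/dt = (target_i(chi) - xi_i) / tau_ci          i = 0..4
    d xi_5/dt = [chi_5 (1 - xi_5) - (1 - chi_6) xi_5] / tau_c5
    d xi_6/dt = [(1-chi_7) + (1-chi_8) - (1-chi_7)(1-chi_8) - xi_6] / tau_c6

A time constant of exactly 0 marks the process as infinitesimally fast:
the variable is replaced each step by the algebraic steady state of its
own equation (quasi-steady update) instead of being integrated.

The ODE block is advanced with the explicit two-step Adams-Bashforth
scheme, bootstrapped by one forward-Euler step.  All arrays are
vectorized over wall nodes: a state of shape ``(n_nodes, 7)`` advances a
whole network in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChiLink",
    "SignallingParams",
    "SignallingState",
    "chi_eval",
    "step_signalling",
    "steady_state",
]

#: equation index fed by each link (links 5/6 both feed equation 5,
#: links 7/8 both feed equation 6)
_LINK_TO_EQ = (0, 1, 2, 3, 4, 5, 5, 6, 6)


@dataclass(frozen=True)
class ChiLink:
    """One logistic edge of the signalling graph.

    ``input`` is ``"pressure"`` (mmHg) or ``"xi0"``..``"xi6"``.
    Output is ``floor + (ceiling - floor) / (1 + exp(-slope (x - midpoint)))``.
    """

    input: str
    midpoint: float
    slope: float
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.floor <= self.ceiling <= 1.0):
            raise ValueError(
                f"chi link requires 0 <= floor <= ceiling <= 1, "
                f"got floor={self.floor}, ceiling={self.ceiling}"
            )
        if self.input != "pressure" and self.input not in {f"xi{i}" for i in range(7)}:
            raise ValueError(f"unknown chi input {self.input!r}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to chi link")
        # clip the exponent for overflow safety; the logistic saturates anyway
        z = np.clip(-self.slope * (x - self.midpoint), -700.0, 700.0)
        return self.floor + (self.ceiling - self.floor) / (1.0 + np.exp(z))


@dataclass(frozen=True)
class SignallingParams:
    """Time constants (s) and the nine logistic links of the graph.

    ``tau_c`` entries must be >= 0; 0 selects the quasi-steady algebraic
    update for that equation.  ``ca_max`` (nM) only scales the reported
    Ca2+ concentration, never the dynamics.
    """

    tau_c: tuple = (10.0, 10.0, 10.0, 0.0, 0.0, 0.0, 0.0)
    chi_table: tuple = ()
    ca_max: float = 230.0

    def __post_init__(self):
        if len(self.tau_c) != 7:
            raise ValueError("tau_c must have 7 entries")
        if any(t < 0 for t in self.tau_c):
            raise ValueError("time constants must be >= 0")
        if len(self.chi_table) != 9:
            raise ValueError("chi_table must have 9 links")

    def with_tau_c(self, tau: float) -> "SignallingParams":
        """Set the shared transduction constant tau_c0 = tau_c1 = tau_c2."""
        new = (tau, tau, tau) + tuple(self.tau_c[3:])
        return replace(self, tau_c=new)


def chi_eval(link_index: int, input_value, params: SignallingParams):
    """Evaluate logistic link ``link_index`` (0..8) at ``input_value``."""
    if not 0 <= link_index < len(params.chi_table):
        raise ValueError(f"unknown chi link index {link_index}")
    return params.chi_table[link_index](input_value)


@dataclass
class SignallingState:
    """Signalling levels at ``n`` wall nodes plus the AB2 history buffer."""

    xi: np.ndarray                      # (n, 7)
    rhs_prev: np.ndarray | None = None  # (n, 7) previous RHS, None before 1st step

    @classmethod
    def zeros(cls, n_nodes: int = 1) -> "SignallingState":
        """Initial condition used throughout: every xi = 0."""
        return cls(xi=np.zeros((n_nodes, 7)))

    @property
    def xi7(self) -> np.ndarray:
        """F-actin content, 1 - xi6 by definition."""
        return 1.0 - self.xi[:, 6]

    @property
    def ca_nM(self):
        return self.xi[:, 0]  # scaled by params.ca_max where reported

    def copy(self) -> "SignallingState":
        return SignallingState(
            xi=self.xi.copy(),
            rhs_prev=None if self.rhs_prev is None else self.rhs_prev.copy(),
        )


def _link_input(link: ChiLink, P, xi):
    if link.input == "pressure":
        return P
    return xi[:, int(link.input[2:])]


def _chi_all(params: SignallingParams, P, xi):
    """All nine link outputs for current (P, xi); shape (n, 9)."""
    return np.stack(
        [link(_link_input(link, P, xi)) for link in params.chi_table], axis=1
    )


def _targets(chi):
    """Algebraic steady state of each of the seven equations, shape (n, 7)."""
    t = np.empty((chi.shape[0], 7))
    t[:, :5] = chi[:, :5]
    # production/removal balance: chi5 (1-x) = (1-chi6) x
    t[:, 5] = chi[:, 5] / (chi[:, 5] + 1.0 - chi[:, 6])
    # OR-gate on depolymerization: 1 - chi7*chi8
    t[:, 6] = (1.0 - chi[:, 7]) + (1.0 - chi[:, 8]) - (1.0 - chi[:, 7]) * (1.0 - chi[:, 8])
    return t


def _rhs(params: SignallingParams, P, xi):
    """Right-hand sides of the seven equations (zero where tau = 0)."""
    chi = _chi_all(params, P, xi)
    tgt = _targets(chi)
    out = np.zeros_like(xi)
    for i, tau in enumerate(params.tau_c):
        if tau > 0.0:
            if i == 5:
                out[:, 5] = (chi[:, 5] * (1.0 - xi[:, 5])
                             - (1.0 - chi[:, 6]) * xi[:, 5]) / tau
            else:
                out[:, i] = (tgt[:, i] - xi[:, i]) / tau
    return out


def step_signalling(
    state: SignallingState,
    P_new,
    dt: float,
    params: SignallingParams,
    P_old=None,
) -> SignallingState:
    """Advance one time step.

    ``P_old`` is the nodal pressure at the current level (mmHg), used by
    the explicit scheme; ``P_new`` is the pressure at the new level, used
    only by quasi-steady links whose input is pressure.  If ``P_old`` is
    omitted the pressure is treated as constant over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    P_new = np.atleast_1d(np.asarray(P_new, dtype=float))
    P_old = P_new if P_old is None else np.atleast_1d(np.asarray(P_old, dtype=float))

    xi = state.xi
    f_n = _rhs(params, P_old, xi)
    if state.rhs_prev is None:  # bootstrap: forward Euler
        xi_new = xi + dt * f_n
    else:  # two-step Adams-Bashforth
        xi_new = xi + dt * (1.5 * f_n - 0.5 * state.rhs_prev)

    # quasi-steady variables: replace by the algebraic target using
    # new-level inputs, in dependency order
    quasi = [i for i, tau in enumerate(params.tau_c) if tau == 0.0]
    if quasi:
        for i in quasi:
            chi = _chi_all(params, P_new, xi_new)
            xi_new[:, i] = _targets(chi)[:, i]

    if np.any(xi_new < -1e-6) or np.any(xi_new > 1.0 + 1e-6):
        bad = np.unravel_index(
            np.argmax(np.maximum(xi_new - 1.0, -xi_new)), xi_new.shape
        )
        raise ValueError(
            "signalling variable left [0,1]: "
            f"xi{bad[1]} = {xi_new[bad]:.6g} at node {bad[0]} "
            "(parameter misconfiguration?)"
        )
    return SignallingState(xi=xi_new, rhs_prev=f_n)


def steady_state(P, params: SignallingParams, n_nodes: int | None = None,
                 tol: float = 1e-14, max_iter: int = 200) -> SignallingState:
    """Fixed point of the signalling graph at constant pressure ``P`` (mmHg).

    Solved by sweeping the equations in index order; for an acyclic
    wiring (any default) one sweep is exact, cyclic wirings iterate.
    """
    P = np.atleast_1d(np.asarray(P, dtype=float))
    if n_nodes is None:
        n_nodes = P.shape[0]
    xi = np.zeros((n_nodes, 7))
    for _ in range(max_iter):
        xi_old = xi.copy()
        for i in range(7):
            chi = _chi_all(params, P, xi)
            xi[:, i] = _targets(chi)[:, i]
        if np.max(np.abs(xi - xi_old)) < tol:
            break
    return SignallingState(xi=xi, rhs_prev=np.zeros_like(xi))
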