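"""Hypocotyl growth law and its coupling to the phyB signal.

Dark growth follows a per-capita, time-rescaled logistic law

    dL/dt = Theta(t - t_growth) * L * (alpha(t) - beta * L) / (1 + gamma * tau)

with tau = t - t_growth (the growth clock starts at initiation).  The form
satisfies the four qualitative constraints the data impose: for beta = 0
growth is exponential-type with instantaneous rate alpha_0 / (1 + gamma tau)
(linear for alpha_0 = gamma, sublinear below, superlinear above); for
beta > 0 it saturates at the asymptote alpha_0 / beta; the initial
per-capita rate is alpha_0 - beta L_0.  Its closed-form dark solution is

    L(t) = (alpha_0/beta) / (1 + (alpha_0/(beta L_0) - 1) (1 + gamma tau)^(-alpha_0/gamma)).

Light couples in through the active-phyB level u~(t), which depresses the
growth-rate parameter as

    alpha(t) = alpha_0 / (1 + K'^2 u~(t)^2),

where 1/K' is the signal level at which the rate is half-maximal.  Because
protein dynamics equilibrate long before growth initiation, light-grown
curves may use the steady signal level u_bar, for which the dark closed
form applies with alpha_0 -> alpha_0/(1 + K'^2 u_bar^2) and the end point is

    L' = (alpha_0/beta) / (1 + K'^2 u_bar^2).

For a line expressing z-fold wild-type phyB the steady signal is
u_bar = z f (all steady pools are linear in z), giving the abundance
response L'_M / L'_Col = (1 + K^2 f^2) / (1 + K^2 z^2 f^2) with
K = K' P_0^Col.

The growth form is pluggable (``GROWTH_FORMS``) so an absolute-rate
reading ``dL/dt = (alpha - beta L) / (1 + gamma tau)`` can be swapped in;
the per-capita form is the default everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp


@dataclass(frozen=True)
class GrowthParameters:
    """Parameters of the hypocotyl growth law.

    alpha0 [1/min] intrinsic growth-rate parameter; beta [1/(min mm)]
    limitation parameter (asymptote = alpha0/beta mm); gamma [1/min]
    time-rescaling (ageing) parameter; K_prime inhibition constant per
    P_0^Col concentration unit; L0 [mm] initial length; t_growth [min]
    growth initiation delay after germination induction.

    ``setup_beta_factor`` multiplies beta for the filter-paper setup, which
    limits growth differently from agar plates (printed factor 0.69; the
    alternative reading 7.58/13.29 = 0.57 can be configured).
    """

    alpha0: float = 2.83e-3
    beta: float = 2.1294e-4
    gamma: float = 5.0e-4
    K_prime: float = 6.87
    L0: float = 0.3
    t_growth: float = 2111.0
    setup_beta_factor: float = 0.69
    form: str = "per_capita"

    def __post_init__(self) -> None:
        for name in ("alpha0", "gamma", "K_prime", "L0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.setup_beta_factor <= 0:
            raise ValueError("setup_beta_factor must be positive")
        if self.form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth form {self.form!r}")

    @property
    def asymptote(self) -> float:
        """Dark end length alpha0/beta [mm]."""
        if self.beta == 0:
            return np.inf
        return self.alpha0 / self.beta

    def effective_beta(self, setup: str = "agar") -> float:
        if setup == "agar":
            return self.beta
        if setup == "filter_paper":
            return self.beta * self.setup_beta_factor
        raise ValueError(f"unknown setup {setup!r}")

    def with_(self, **kw) -> "GrowthParameters":
        return replace(self, **kw)


def _per_capita_rhs(L: float, alpha: float, beta: float, gamma: float,
                    tau: float) -> float:
    return L * (alpha - beta * L) / (1.0 + gamma * tau)


def _absolute_rhs(L: float, alpha: float, beta: float, gamma: float,
                  tau: float) -> float:
    return (alpha - beta * L) / (1.0 + gamma * tau)


GROWTH_FORMS: dict[str, Callable[[float, float, float, float, float], float]] = {
    "per_capita": _per_capita_rhs,
    "absolute": _absolute_rhs,
}


def _closed_form_per_capita(
    tau: np.ndarray, alpha0: float, beta: float, gamma: float, L0: float
) -> np.ndarray:
    """Dark solution of the per-capita form on the growth clock tau >= 0."""
    if L0 == 0.0:
        return np.zeros_like(tau)
    if gamma > 0:
        decay = (1.0 + gamma * tau) ** (-alpha0 / gamma)
    else:
        decay = np.exp(-alpha0 * tau)
    if beta == 0.0:
        return L0 / decay
    A = alpha0 / beta
    return A / (1.0 + (A / L0 - 1.0) * decay)


def dark_growth_length(
    t, gp: GrowthParameters, setup: str = "agar"
) -> np.ndarray | float:
    """Hypocotyl length in darkness at time(s) ``t`` (min), closed form.

    Constant at L0 before growth initiation; saturates at alpha0/beta.
    """
    return growth_length_constant_u(t, gp, 0.0, setup=setup)


def growth_length_constant_u(
    t, gp: GrowthParameters, u_bar: float, setup: str = "agar"
) -> np.ndarray | float:
    """Length under a constant signal level: closed form with the
    light-depressed rate alpha0 / (1 + K'^2 u_bar^2)."""
    if u_bar < 0:
        raise ValueError("signal level must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    tau = np.clip(t_arr - gp.t_growth, 0.0, None)
    alpha = gp.alpha0 / (1.0 + (gp.K_prime * u_bar) ** 2)
    beta = gp.effective_beta(setup)
    if gp.form == "per_capita":
        L = _closed_form_per_capita(tau, alpha, beta, gp.gamma, gp.L0)
    else:
        L = _integrate_growth(
            np.atleast_1d(tau), gp,
            lambda _tau: alpha / gp.alpha0 if gp.alpha0 else 1.0,
            beta,
        ).reshape(tau.shape)
    return L if t_arr.ndim else float(L)


def _integrate_growth(
    tau_grid: np.ndarray,
    gp: GrowthParameters,
    alpha_factor_of_tau: Callable[[float], float],
    beta: float,
) -> np.ndarray:
    """Numerically integrate the growth law on the growth clock."""
    rhs_form = GROWTH_FORMS[gp.form]

    def rhs(tau, y):
        alpha = gp.alpha0 * alpha_factor_of_tau(tau)
        return [rhs_form(y[0], alpha, beta, gp.gamma, tau)]

    tau_end = float(tau_grid.max(initial=0.0))
    if tau_end == 0.0:
        return np.full_like(tau_grid, gp.L0)
    pos = np.unique(tau_grid[tau_grid > 0])
    sol = solve_ivp(
        rhs, (0.0, tau_end), [gp.L0], t_eval=pos,
        method="LSODA", rtol=1e-9, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"growth integration failed: {sol.message}")
    lookup = dict(zip(pos, sol.y[0]))
    return np.array([gp.L0 if tau <= 0 else lookup[tau] for tau in tau_grid])


def simulate_growth(
    gp: GrowthParameters,
    u_times: Sequence[float],
    u_values: Sequence[float],
    t_grid: Sequence[float],
    setup: str = "agar",
) -> np.ndarray:
    """Integrate the growth law with a time-varying signal level.

    ``u_times``/``u_values`` give the active-phyB trajectory on the wall
    clock (minutes from germination induction); it is linearly interpolated
    and held constant beyond its last sample.  Reduces to
    :func:`dark_growth_length` for u identically zero.
    """
    u_times = np.asarray(u_times, dtype=float)
    u_values = np.asarray(u_values, dtype=float)
    if np.any(u_values < 0):
        raise ValueError("signal level must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)

    def alpha_factor(tau: float) -> float:
        t = tau + gp.t_growth
        u = float(np.interp(t, u_times, u_values))
        return 1.0 / (1.0 + (gp.K_prime * u) ** 2)

    tau_grid = np.clip(t_grid - gp.t_growth, 0.0, None)
    return _integrate_growth(tau_grid, gp, alpha_factor,
                             gp.effective_beta(setup))


def steady_state_length(
    gp: GrowthParameters, u_bar: float, setup: str = "agar"
) -> float:
    """Equilibrated hypocotyl end length L' = (alpha0/beta)/(1 + K'^2 u_bar^2)."""
    if u_bar < 0:
        raise ValueError("signal level must be non-negative")
    beta = gp.effective_beta(setup)
    if beta == 0:
        return np.inf
    return (gp.alpha0 / beta) / (1.0 + (gp.K_prime * u_bar) ** 2)


def relative_length_vs_abundance(z, K: float, f: float):
    """Hypocotyl end length of a z-fold expressor relative to wild type.

    With the steady signal u_bar = z f and K = K' P_0^Col:

        L'_M / L'_Col = (1 + K^2 f^2) / (1 + K^2 z^2 f^2)

    Equals 1 at z = 1 and decreases strictly in z whenever K f > 0.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("expression strength z must be positive")
    if K < 0 or f < 0:
        raise ValueError("K and f must be non-negative")
    ratio = (1.0 + (K * f) ** 2) / (1.0 + (K * z * f) ** 2)
    return ratio if ratio.ndim else float(ratio)


def threshold_crossing_time(
    gp: GrowthParameters, threshold: float, setup: str = "agar"
) -> float:
    """Wall-clock time at which the dark curve reaches ``threshold`` mm.

    Closed form for the per-capita form; used by the synthetic seedling
    generator to place growth onsets so that the operational growth-start
    definition (threshold crossing) matches a requested time.
    """
    if not gp.L0 < threshold:
        raise ValueError("threshold must exceed the initial length L0")
    beta = gp.effective_beta(setup)
    if gp.form != "per_capita":
        raise NotImplementedError("closed-form crossing needs the per-capita form")
    if beta > 0:
        A = gp.alpha0 / beta
        if threshold >= A:
            raise ValueError("threshold above the growth asymptote")
        decay = (A / threshold - 1.0) / (A / gp.L0 - 1.0)
    else:
        decay = gp.L0 / threshold
    # decay = (1 + gamma tau)^(-alpha0/gamma)  (or exp(-alpha0 tau) at gamma=0)
    if gp.gamma > 0:
        tau = ((decay ** (-gp.gamma / gp.alpha0)) - 1.0) / gp.gamma
    else:
        tau = -np.log(decay) / gp.alpha0
    return gp.t_growth + float(tau)
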