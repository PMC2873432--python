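"""Six-pool kinetic model of phytochrome B photoconversion and trafficking.

The model tracks phyB in three compartments (cytosol, nucleoplasm, nuclear
bodies), each holding the inactive Pr and the active Pfr conformer:

    pr_c, pfr_c   cytosolic pools
    pr_n, pfr_n   diffuse nucleoplasmic pools
    pr_ns, pfr_ns nuclear-body (NB) bound pools

Transitions (mass action, first order; all rates in 1/min):

* synthesis of Pr in the cytosol at ``k_s``,
* photoconversion Pr <-> Pfr at light-dependent rates ``k_1 = N * sigma_r``
  and ``k_2 = N * sigma_fr`` where ``N`` is the photon fluence rate,
* nuclear import of cytosolic Pfr at ``k_in``,
* NB association/dissociation of nuclear Pfr at ``k_3`` / ``k_4``,
* decomposition of NB-bound Pr back to the nucleoplasm at ``k_5``,
* thermal dark reversion Pfr -> Pr at ``k_r`` acting on the *diffuse*
  cytosolic and nucleoplasmic Pfr only (NB-bound Pfr is protected),
* degradation of every Pr pool at ``k_dr`` and every Pfr pool at ``k_dfr``.

Concentrations are normalised to the wild-type dark-adapted total
(``P_0^Col = 1``); an expression strength ``z`` scales the abundance of
over-expressor or knock-down lines.  With the convention ``k_s = z * k_dr``
the dark steady state total equals ``z`` exactly.

The system is linear and time-invariant within any constant-light interval,
``dx/dt = A x + b``; piecewise integration across a light program uses a
stiff solver with the analytic Jacobian ``A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

POOLS = ("pr_c", "pfr_c", "pr_n", "pfr_n", "pr_ns", "pfr_ns")
PR_INDEX = np.array([0, 2, 4])
PFR_INDEX = np.array([1, 3, 5])

SPECTRUM_CLASSES = ("dark", "red_660", "far_red_RG9")

#: signalling selectors -> pool indices that are summed
SIGNALING_SELECTORS = {
    "pfr_total": (1, 3, 5),
    "pfr_nuclear_sum": (3, 5),
    "pfr_n_diffuse": (3,),
    "pfr_ns": (5,),
    "pfr_cytosolic": (1,),  # for model selection: cytosolic-only signalling
}

# Integration tolerances; segment boundaries are hard restart points.
RTOL = 1e-8
ATOL = 1e-10
#: integrator values in [NEG_CLIP, 0) are clamped to zero, below raises.
#: The floor sits an order of magnitude above ATOL because the solver only
#: controls the local error to ~1e-10.
NEG_CLIP = -1e-9


class ConfigurationError(ValueError):
    """Invalid light program, spectrum class or model configuration."""


class IntegrationError(RuntimeError):
    """The stiff solver failed or produced unacceptably negative pools."""


@dataclass(frozen=True)
class PoolState:
    """Concentrations of the six phyB pools in units of P_0^Col."""

    pr_c: float = 0.0
    pfr_c: float = 0.0
    pr_n: float = 0.0
    pfr_n: float = 0.0
    pr_ns: float = 0.0
    pfr_ns: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pr_c, self.pfr_c, self.pr_n, self.pfr_n, self.pr_ns, self.pfr_ns],
            dtype=float,
        )

    @staticmethod
    def from_array(x: Sequence[float]) -> "PoolState":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError("pool state needs exactly six entries")
        return PoolState(*x)

    @property
    def ptot(self) -> float:
        return float(np.sum(self.as_array()))

    @property
    def pfr_total(self) -> float:
        return self.pfr_c + self.pfr_n + self.pfr_ns

    @property
    def pr_total(self) -> float:
        return self.pr_c + self.pr_n + self.pr_ns


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the pool model.

    ``sigma_total`` is the summed photoconversion cross-section
    (sigma_r + sigma_fr) per unit fluence rate; the per-class
    photoequilibria ``phi_red`` and ``phi_far_red`` split it into sigma_r
    and sigma_fr.  The defaults make a 5 min, 22 umol m-2 s-1 red pulse
    saturating and let the RG9 far-red class set 99.9 % Pr.

    ``k_s`` is not a free field: it is tied to ``z * k_dr`` so that the
    dark-adapted steady state total equals the expression strength ``z``.
    """

    k_3: float = 3.98
    k_4: float = 1.51
    k_r: float = 0.0321
    k_dr: float = 0.00061
    k_dfr: float = 0.0024
    k_in: float = 1.0
    k_5: float = 0.05
    z: float = 1.0
    sigma_total: float = 0.1
    phi_red: float = 0.87
    phi_far_red: float = 0.001

    def __post_init__(self) -> None:
        for name in ("k_3", "k_4", "k_r", "k_dr", "k_dfr", "k_in", "k_5",
                     "sigma_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.z <= 0:
            raise ValueError("expression strength z must be positive")
        if not 0.0 <= self.phi_red <= 1.0 or not 0.0 <= self.phi_far_red <= 1.0:
            raise ValueError("photoequilibria must lie in [0, 1]")

    @property
    def k_s(self) -> float:
        return self.z * self.k_dr

    def cross_sections(self, spectrum_class: str) -> tuple[float, float]:
        """(sigma_r, sigma_fr) for a spectrum class, per unit fluence rate."""
        if spectrum_class == "dark":
            return 0.0, 0.0
        if spectrum_class == "red_660":
            phi = self.phi_red
        elif spectrum_class == "far_red_RG9":
            phi = self.phi_far_red
        else:
            raise ConfigurationError(f"unknown spectrum class {spectrum_class!r}")
        return self.sigma_total * phi, self.sigma_total * (1.0 - phi)

    def with_(self, **kw) -> "RateConstants":
        return replace(self, **kw)


@dataclass(frozen=True)
class Segment:
    """One constant-light interval of a light program."""

    spectrum_class: str
    fluence_rate: float  # umol m-2 s-1
    minutes: float | None  # None = open-ended final segment

    def __post_init__(self) -> None:
        if self.spectrum_class not in SPECTRUM_CLASSES:
            raise ConfigurationError(
                f"unknown spectrum class {self.spectrum_class!r}"
            )
        if (self.fluence_rate == 0.0) != (self.spectrum_class == "dark"):
            raise ConfigurationError(
                "fluence_rate must be 0 exactly for dark segments"
            )
        if self.fluence_rate < 0:
            raise ConfigurationError("fluence_rate must be non-negative")
        if self.minutes is not None and self.minutes <= 0:
            raise ConfigurationError("segment duration must be positive")


@dataclass(frozen=True)
class LightProgram:
    """Piecewise-constant irradiation schedule."""

    segments: tuple[Segment, ...]

    def __init__(self, segments: Iterable[Segment]):
        segments = tuple(segments)
        if not segments:
            raise ConfigurationError("light program needs at least one segment")
        for seg in segments[:-1]:
            if seg.minutes is None:
                raise ConfigurationError(
                    "only the final segment may be open-ended"
                )
        object.__setattr__(self, "segments", segments)

    @staticmethod
    def darkness() -> "LightProgram":
        return LightProgram([Segment("dark", 0.0, None)])

    @staticmethod
    def constant(spectrum_class: str, fluence_rate: float) -> "LightProgram":
        return LightProgram([Segment(spectrum_class, fluence_rate, None)])

    @staticmethod
    def red_pulse_then_dark(
        fluence_rate: float = 22.0, pulse_minutes: float = 5.0
    ) -> "LightProgram":
        """Saturating red pulse followed by darkness (dark-reversion assay)."""
        return LightProgram(
            [
                Segment("red_660", fluence_rate, pulse_minutes),
                Segment("dark", 0.0, None),
            ]
        )

    def boundaries(self, t_end: float) -> list[tuple[float, float, Segment]]:
        """(start, stop, segment) triples covering [0, t_end]."""
        out = []
        t = 0.0
        for seg in self.segments:
            stop = t_end if seg.minutes is None else min(t + seg.minutes, t_end)
            if stop > t:
                out.append((t, stop, seg))
            t = t + (seg.minutes or 0.0)
            if t >= t_end:
                break
        if not out or out[-1][1] < t_end:
            # program shorter than requested span: hold the last segment
            last = self.segments[-1]
            start = out[-1][1] if out else 0.0
            out.append((start, t_end, last))
        return out


@dataclass(frozen=True)
class ModelVariant:
    """Submodel switches.

    ``photochemistry_only`` keeps a single Pr/Pfr compartment with synthesis,
    photoconversion and degradation; ``with_dark_reversion`` adds thermal
    reversion; ``full`` enables import, NB exchange and NB-Pr decomposition.
    ``nuclear_photoconversion`` applies k_1/k_2 symmetrically in the
    nucleoplasm and NBs (light reaches nuclear pools).
    """

    variant: str = "full"
    signaling_selector: str = "pfr_nuclear_sum"
    nuclear_photoconversion: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("photochemistry_only", "with_dark_reversion", "full"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.signaling_selector not in SIGNALING_SELECTORS:
            raise ConfigurationError(
                f"unknown signaling selector {self.signaling_selector!r}"
            )

    @property
    def enables_reversion(self) -> bool:
        return self.variant in ("with_dark_reversion", "full")

    @property
    def enables_trafficking(self) -> bool:
        return self.variant == "full"


FULL = ModelVariant("full")
PHOTOCHEMISTRY_ONLY = ModelVariant("photochemistry_only", "pfr_total")
WITH_DARK_REVERSION = ModelVariant("with_dark_reversion", "pfr_total")


def photoconversion_rates(
    segment: Segment, rc: RateConstants
) -> tuple[float, float]:
    """Light-dependent rates (k_1, k_2) = N * (sigma_r, sigma_fr)."""
    sigma_r, sigma_fr = rc.cross_sections(segment.spectrum_class)
    return segment.fluence_rate * sigma_r, segment.fluence_rate * sigma_fr


def system_matrix(
    rc: RateConstants,
    k_1: float,
    k_2: float,
    variant: ModelVariant = FULL,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear system ``dx/dt = A x + b`` for one constant-light interval."""
    A = np.zeros((6, 6))
    b = np.zeros(6)
    b[0] = rc.k_s

    def move(i: int, j: int, rate: float) -> None:
        A[i, i] -= rate
        A[j, i] += rate

    # photoconversion in the cytosol, and (optionally) nuclear pools
    pairs = [(0, 1)]
    if variant.enables_trafficking and variant.nuclear_photoconversion:
        pairs += [(2, 3), (4, 5)]
    for pr, pfr in pairs:
        move(pr, pfr, k_1)
        move(pfr, pr, k_2)

    if variant.enables_reversion:
        move(1, 0, rc.k_r)  # Pfr_c -> Pr_c
        if variant.enables_trafficking:
            move(3, 2, rc.k_r)  # Pfr_n -> Pr_n; NB-bound Pfr is protected

    if variant.enables_trafficking:
        move(1, 3, rc.k_in)  # Pfr_c -> Pfr_n
        move(3, 5, rc.k_3)  # Pfr_n -> Pfr_ns
        move(5, 3, rc.k_4)  # Pfr_ns -> Pfr_n
        move(4, 2, rc.k_5)  # Pr_ns -> Pr_n

    A[PR_INDEX, PR_INDEX] -= rc.k_dr
    A[PFR_INDEX, PFR_INDEX] -= rc.k_dfr
    return A, b


def pool_derivatives(
    state: PoolState,
    rc: RateConstants,
    k_1: float,
    k_2: float,
    variant: ModelVariant = FULL,
) -> PoolState:
    """Right-hand side of the pool ODEs at a given state."""
    x = state.as_array()
    if np.any(x < 0):
        raise ValueError("pool concentrations must be non-negative")
    A, b = system_matrix(rc, k_1, k_2, variant)
    return PoolState.from_array(A @ x + b)


def dark_adapted_state(rc: RateConstants) -> PoolState:
    """Etiolated initial condition: all phyB as cytosolic Pr at level z.

    Import in the scheme is Pfr-specific, so dark-synthesised phyB resides
    in the cytosol; this is a fixed point of the dark dynamics because
    k_s = z * k_dr.
    """
    return PoolState(pr_c=rc.z)


def steady_state_pools(
    rc: RateConstants,
    segment: Segment,
    variant: ModelVariant = FULL,
) -> PoolState:
    """Steady state under constant light, from the linear balance equations.

    Scales linearly in the expression strength z (the inhomogeneity k_s is
    the only source term and is proportional to z).
    """
    k_1, k_2 = photoconversion_rates(segment, rc)
    A, b = system_matrix(rc, k_1, k_2, variant)
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - needs k_d = 0
        raise IntegrationError("singular balance system") from exc
    return PoolState.from_array(np.where(np.abs(x) < 1e-15, 0.0, x))


def _clip_negative(y: np.ndarray, context: str) -> np.ndarray:
    low = y.min()
    if low < NEG_CLIP:
        raise IntegrationError(
            f"integration produced negative pool {low:.3e} ({context})"
        )
    return np.clip(y, 0.0, None)


def simulate_pools(
    rc: RateConstants,
    program: LightProgram,
    t_grid: Sequence[float],
    init: PoolState | None = None,
    variant: ModelVariant = FULL,
) -> pd.DataFrame:
    """Integrate the pool model across a light program.

    Returns a DataFrame with columns ``time_min`` and the six pool names,
    evaluated on ``t_grid`` (minutes from program start, increasing).
    Integration is piecewise per constant-light segment with state
    continuity at boundaries, using a stiff BDF solver with the analytic
    Jacobian of the linear system.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a non-empty increasing 1-d array")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after program start")
    if init is None:
        init = dark_adapted_state(rc)
    x = init.as_array()
    if np.any(x < 0):
        raise ValueError("initial state must be non-negative")

    rows = np.empty((len(t_grid), 6))
    filled = np.zeros(len(t_grid), dtype=bool)
    if t_grid[0] == 0.0:
        rows[0] = x
        filled[0] = True

    for seg_index, (start, stop, seg) in enumerate(
        program.boundaries(float(t_grid[-1]))
    ):
        k_1, k_2 = photoconversion_rates(seg, rc)
        A, b = system_matrix(rc, k_1, k_2, variant)
        mask = (~filled) & (t_grid > start) & (t_grid <= stop)
        # always evaluate the segment endpoint so the next segment starts
        # from the exact boundary state
        t_eval = np.unique(np.append(t_grid[mask], stop))
        sol = solve_ivp(
            lambda t, y: A @ y + b,
            (start, stop),
            x,
            method="BDF",
            t_eval=t_eval,
            jac=lambda t, y: A,
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success:
            raise IntegrationError(
                f"stiff solver failed in segment {seg_index}: {sol.message}"
            )
        values = _clip_negative(sol.y.T, f"segment {seg_index}")
        on_grid = np.isin(t_eval, t_grid[mask])
        rows[mask] = values[on_grid]
        filled[mask] = True
        x = values[-1]

    if not filled.all():  # pragma: no cover - boundaries() always spans t_grid
        raise IntegrationError("light program did not cover the time grid")

    out = pd.DataFrame(rows, columns=list(POOLS))
    out.insert(0, "time_min", t_grid)
    return out


def signaling_level(state, selector: str = "pfr_nuclear_sum"):
    """Active-phytochrome read-out u~ for a state or trajectory.

    ``state`` may be a :class:`PoolState`, a 6-vector, or a trajectory
    DataFrame from :func:`simulate_pools` (then a Series is returned).
    The default sums both nuclear Pfr pools; cytosolic Pfr never
    contributes under the provided selectors except ``pfr_total``.
    """
    if selector not in SIGNALING_SELECTORS:
        raise ConfigurationError(f"unknown signaling selector {selector!r}")
    idx = SIGNALING_SELECTORS[selector]
    if isinstance(state, pd.DataFrame):
        return sum(state[POOLS[i]] for i in idx)
    if isinstance(state, PoolState):
        x = state.as_array()
    else:
        x = np.asarray(state, dtype=float)
    return float(x[list(idx)].sum())


def trajectory_totals(traj: pd.DataFrame) -> pd.DataFrame:
    """Attach Ptot / total-Pfr / total-Pr columns to a pool trajectory."""
    out = traj.copy()
    out["ptot"] = traj[list(POOLS)].sum(axis=1)
    out["pfr_total"] = sum(traj[POOLS[i]] for i in PFR_INDEX)
    out["pr_total"] = sum(traj[POOLS[i]] for i in PR_INDEX)
    return out
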