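"""Virtual experiments: map pool-model trajectories to the five observables.

Each function reproduces one assay protocol:

* FRAP on a single nuclear body after 24 h red pretreatment,
* in vivo spectroscopy of relative Pfr during prolonged darkness after a
  saturating 5 min, 22 umol m-2 s-1 red pulse (dark reversion),
* immunoblot time course of total phyB under continuous red (degradation),
* immunoblot time course of total phyB accumulating in darkness after
  germination induction (synthesis onset / k_dr),
* fluence-rate response of day-4 relative hypocotyl length.

All observables are normalised and therefore invariant under the
expression strength z (the pool model is linear in z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import growth as growth_mod
from .growth import GrowthParameters
from .model import (
    FULL,
    LightProgram,
    ModelVariant,
    PoolState,
    RateConstants,
    Segment,
    signaling_level,
    simulate_pools,
    steady_state_pools,
    trajectory_totals,
)

EXPERIMENT_KINDS = (
    "frap",
    "dark_reversion",
    "degradation",
    "accumulation",
    "dark_growth",
    "fluence_response",
)


@dataclass(frozen=True)
class Protocol:
    """An assay protocol: light program, sampling grid and normalisation."""

    kind: str
    light_program: LightProgram | None = None
    sample_times: tuple[float, ...] = ()
    normalization: str = "default"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")


DEFAULT_FRAP_PRETREATMENT = LightProgram([Segment("red_660", 22.0, 1440.0)])


def frap_recovery_curve(
    rc: RateConstants,
    t_grid: Sequence[float],
    pretreatment: LightProgram = DEFAULT_FRAP_PRETREATMENT,
    bleach_fraction: float = 0.9,
    recovery_program: LightProgram | None = None,
) -> pd.DataFrame:
    """Normalised fluorescence of a bleached nuclear body over time.

    The fluorophore label is passive: bleached and visible molecules share
    all rate constants, so the labelled system is the same linear model.
    Bleaching instantaneously marks ``bleach_fraction`` of the NB-bound
    Pfr pool invisible.  The visible NB signal is divided by the
    unperturbed NB trajectory (the acquisition/decay correction) and
    rescaled to its post-recovery plateau, mirroring the normalisation of
    the assay; the curve rises monotonically to 1.  Recovery is governed
    by the NB exchange rates (timescale ~1/(k_3 + k_4)).
    """
    if not 0.0 <= bleach_fraction <= 1.0:
        raise ValueError("bleach_fraction must be in [0, 1]")
    t_grid = np.asarray(t_grid, dtype=float)
    if recovery_program is None:
        recovery_program = LightProgram.darkness()

    # state at bleach time: simulate the pretreatment explicitly
    if any(s.minutes is None for s in pretreatment.segments):
        raise ValueError("pretreatment program must have a finite duration")
    pre_end = sum(s.minutes for s in pretreatment.segments)
    pre = simulate_pools(rc, pretreatment, [0.0, pre_end])
    state0 = PoolState.from_array(pre.iloc[-1][["pr_c", "pfr_c", "pr_n",
                                                "pfr_n", "pr_ns", "pfr_ns"]])
    if state0.pfr_ns <= 0:
        raise ValueError("no NB-bound Pfr present at bleach time")

    grid = t_grid if t_grid[0] == 0.0 else np.concatenate([[0.0], t_grid])
    visible0 = PoolState.from_array(
        state0.as_array() * np.array([1, 1, 1, 1, 1, 1 - bleach_fraction])
    )
    visible = simulate_pools(rc, recovery_program, grid, init=visible0)
    unperturbed = simulate_pools(rc, recovery_program, grid, init=state0)

    ratio = visible["pfr_ns"].to_numpy() / unperturbed["pfr_ns"].to_numpy()
    plateau = ratio[-1]
    values = ratio / plateau if plateau > 0 else ratio
    out = pd.DataFrame({"time_min": grid, "value": values})
    return out[out["time_min"].isin(t_grid)].reset_index(drop=True)


def dark_reversion_curve(
    rc: RateConstants,
    t_grid: Sequence[float],
    model: str = "full",
    pulse: Segment = Segment("red_660", 22.0, 5.0),
    variant: ModelVariant = FULL,
    normalization: str = "post_pulse",
) -> pd.DataFrame:
    """Relative Pfr during darkness after a saturating red pulse.

    ``t_grid`` counts minutes of darkness (0 = lights off).  ``model``:

    * ``"full"`` — simulate the pulse explicitly from the dark-adapted
      state, then darkness; the observable is total Pfr over total
      phytochrome, normalised to its lights-off value
      (``normalization="ptot"`` skips the rescaling and reports Pfr/Ptot).
    * ``"single_exponential"`` — exp(-k_r t), the single first-order
      reading appropriate for phyB expressed heterologously without NB
      formation.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if model == "single_exponential":
        return pd.DataFrame(
            {"time_min": t_grid, "value": np.exp(-rc.k_r * t_grid)}
        )
    if model != "full":
        raise ValueError(f"unknown dark-reversion model {model!r}")
    program = LightProgram(
        [pulse, Segment("dark", 0.0, None)]
    )
    grid = t_grid + pulse.minutes
    if grid[0] > pulse.minutes:
        grid = np.concatenate([[pulse.minutes], grid])
    traj = trajectory_totals(simulate_pools(rc, program, grid, variant=variant))
    rel = (traj["pfr_total"] / traj["ptot"]).to_numpy()
    if normalization == "post_pulse":
        rel = rel / rel[0]
    elif normalization != "ptot":
        raise ValueError(f"unknown normalization {normalization!r}")
    keep = np.isin(grid, t_grid + pulse.minutes)
    return pd.DataFrame({"time_min": t_grid, "value": rel[keep][-len(t_grid):]})


def degradation_curve(
    rc: RateConstants,
    times: Sequence[float],
    fluence: float = 3.0,
    variant: ModelVariant = FULL,
) -> pd.DataFrame:
    """Total phyB under continuous red light, normalised to the dark level."""
    times = np.asarray(times, dtype=float)
    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    program = LightProgram.constant("red_660", fluence)
    traj = trajectory_totals(simulate_pools(rc, program, grid, variant=variant))
    ptot = traj["ptot"].to_numpy()
    values = ptot / ptot[0]
    keep = np.isin(grid, times)
    return pd.DataFrame({"time_min": times, "value": values[keep]})


def accumulation_curve(
    rc: RateConstants,
    times: Sequence[float],
    t_syn: float = 648.0,
) -> pd.DataFrame:
    """Total phyB accumulating in darkness after germination induction.

    In darkness only synthesis and Pr degradation act, so the total follows
    the closed form z (1 - exp(-k_dr (t - t_syn))) once synthesis starts at
    ``t_syn`` (and is zero before).  Units of P_0^Col.
    """
    times = np.asarray(times, dtype=float)
    tau = np.clip(times - t_syn, 0.0, None)
    values = rc.z * (1.0 - np.exp(-rc.k_dr * tau))
    return pd.DataFrame({"time_min": times, "value": values})


def steady_signal(
    rc: RateConstants,
    segment: Segment,
    variant: ModelVariant = FULL,
) -> float:
    """Steady-state signalling level u_bar under constant light."""
    state = steady_state_pools(rc, segment, variant)
    return signaling_level(state, variant.signaling_selector)


def fluence_rate_response(
    rc: RateConstants,
    gp: GrowthParameters,
    fluences: Sequence[float],
    duration: float = 5760.0,
    variant: ModelVariant = FULL,
    setup: str = "filter_paper",
) -> pd.DataFrame:
    """Relative hypocotyl length vs fluence rate of continuous red light.

    For each fluence the steady signal u_bar of the chosen submodel sets a
    constant growth rate; the curve reports L(duration) / L_dark(duration)
    for seedlings grown ``duration`` minutes (default four days) from
    germination induction.  Protein dynamics reach steady state well before
    growth initiation, so the steady-signal coupling is exact on this
    time scale.
    """
    fluences = np.asarray(fluences, dtype=float)
    if np.any(fluences <= 0):
        raise ValueError("fluence rates must be positive")
    L_dark = growth_mod.growth_length_constant_u(duration, gp, 0.0, setup=setup)
    values = []
    for N in fluences:
        u_bar = steady_signal(rc, Segment("red_660", float(N), None), variant)
        L = growth_mod.growth_length_constant_u(duration, gp, u_bar, setup=setup)
        values.append(L / L_dark)
    return pd.DataFrame({"fluence_umol": fluences, "value": values})


def half_life(times: Sequence[float], values: Sequence[float]) -> float:
    """Time at which a decaying curve halves, by log-linear interpolation.

    The curve must start at its maximum and cross half of its initial
    value within the sampled range.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2 or v[0] <= 0:
        raise ValueError("need a positive curve with at least two samples")
    if v[0] < v.max():
        raise ValueError("curve must start at its maximum")
    target = 0.5 * v[0]
    below = np.nonzero(v <= target)[0]
    if below.size == 0:
        raise ValueError("curve never reaches half of its initial value")
    j = below[0]
    if v[j] == target:
        return float(t[j])
    i = j - 1
    # log-linear between the bracketing samples
    log_ratio = np.log(v[i] / v[j])
    frac = np.log(v[i] / target) / log_ratio
    return float(t[i] + frac * (t[j] - t[i]))
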