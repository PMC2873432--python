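"""Synthetic data emulating the five assay types, from known ground truth.

Each generator evaluates the corresponding virtual experiment at the
ground-truth parameters and adds independent Gaussian measurement noise
per biological replicate, reporting the replicate mean and its standard
error — the same structure as the averaged laboratory data the model is
fitted to.

Study conditions baked into the defaults: 13 seedlings imaged hourly over
six days with growth initiation near 2111 min (SD 180 min between
seedlings); five averaged FRAP traces; a saturating 5 min, 22 umol m-2 s-1
red pulse before dark-reversion spectroscopy sampled out to 24 h;
immunoblot degradation series under 3 umol m-2 s-1 continuous red at
0/1/6/12/24 h; dark accumulation sampled from 12 h to four days with
synthesis onset 648 min on a 3.8x over-expressing line.  Noise scales
(FRAP 0.05, reversion 0.05, blots 0.1 on the normalised observables,
0.3 mm on lengths) emulate the published error bars.

Seeding: every kind draws from its own child stream of the spec seed, so
datasets of different kinds are independent and changing one kind's
replicate count never perturbs another kind's draws.

The seedling generator defines its ground-truth ``t_growth`` exactly as
the laboratory procedure does — the time at which the hypocotyl reaches
the 0.5 mm growth-start threshold — by placing the latent growth onset at
``t_cross - delta`` with ``delta`` the deterministic time to grow from seed
length to the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import experiments as vx
from .fitting import ExperimentDataset
from .growth import GrowthParameters, growth_length_constant_u, threshold_crossing_time
from .model import RateConstants

#: fixed substream index per dataset kind (seed isolation)
KIND_STREAMS = {
    "frap": 1,
    "dark_reversion": 2,
    "degradation": 3,
    "accumulation": 4,
    "dark_growth": 5,
    "fluence_response": 6,
    "abundance": 7,
}

DEFAULT_NOISE = {
    "frap": 0.05,
    "dark_reversion": 0.05,
    "degradation": 0.1,
    "accumulation": 0.1,
    "dark_growth": 0.3,  # mm
    "fluence_response": 0.05,
    "abundance": 0.05,
}

DEFAULT_REPLICATES = {
    "frap": 5,
    "dark_reversion": 4,
    "degradation": 4,
    "accumulation": 3,
    "fluence_response": 4,
    "abundance": 3,
}

DEFAULT_SAMPLE_TIMES = {
    "frap": tuple(np.arange(0.0, 6.01, 0.25)),
    "dark_reversion": (0.0, 15.0, 30.0, 60.0, 120.0, 240.0, 360.0, 720.0, 1440.0),
    "degradation": (0.0, 60.0, 360.0, 720.0, 1440.0),
    "accumulation": tuple(np.arange(720.0, 5761.0, 120.0)),
}

DEFAULT_FLUENCES = (0.001, 0.01, 0.1, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass
class SyntheticSpec:
    """Ground truth, noise model and replicate structure of a study."""

    rc: RateConstants = field(default_factory=RateConstants)
    gp: GrowthParameters = field(default_factory=GrowthParameters)
    noise: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    replicates: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    n_seedlings: int = 13
    t_growth_mean: float = 2111.0
    t_growth_jitter_sd: float = 180.0
    growth_threshold_mm: float = 0.5
    t_syn: float = 648.0
    accumulation_z: float = 3.8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise scales must be non-negative")
        if any(n < 1 for n in self.replicates.values()):
            raise ValueError("replicate counts must be at least 1")

    def rng(self, kind: str) -> np.random.Generator:
        """Independent child stream for one dataset kind."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(KIND_STREAMS[kind],))
        )

    def manifest(self) -> dict:
        """Ground truth and generator settings, for provenance records."""
        from dataclasses import asdict

        return {
            "seed": self.seed,
            "rate_constants": asdict(self.rc),
            "growth_parameters": asdict(self.gp),
            "noise": dict(self.noise),
            "replicates": dict(self.replicates),
            "n_seedlings": self.n_seedlings,
            "t_growth_mean": self.t_growth_mean,
            "t_growth_jitter_sd": self.t_growth_jitter_sd,
            "growth_threshold_mm": self.growth_threshold_mm,
            "t_syn": self.t_syn,
            "accumulation_z": self.accumulation_z,
        }


def _noisy_dataset(
    kind: str,
    times: np.ndarray,
    truth: np.ndarray,
    noise_sd: float,
    n_rep: int,
    rng: np.random.Generator,
    metadata: dict,
) -> ExperimentDataset:
    if noise_sd == 0.0:
        values, se = truth.copy(), np.zeros_like(truth)
    else:
        reps = truth[None, :] + rng.normal(0.0, noise_sd, size=(n_rep, len(truth)))
        values = reps.mean(axis=0)
        se = (
            reps.std(axis=0, ddof=1) / np.sqrt(n_rep)
            if n_rep > 1
            else np.full_like(truth, noise_sd)
        )
    metadata = dict(metadata)
    metadata.update(
        {"synthetic": True, "noise_sd": noise_sd, "n_replicates": n_rep}
    )
    return ExperimentDataset(kind=kind, times=times, values=values, se=se,
                             metadata=metadata)


def generate_timeseries(
    spec: SyntheticSpec,
    kind: str,
    sample_times: Sequence[float] | None = None,
) -> ExperimentDataset:
    """Replicate-averaged noisy dataset for one virtual-experiment kind."""
    rng = spec.rng(kind)
    noise = spec.noise.get(kind, 0.0)
    n_rep = spec.replicates.get(kind, 1)
    meta: dict = {"seed": spec.seed}

    if kind == "frap":
        times = np.asarray(DEFAULT_SAMPLE_TIMES[kind] if sample_times is None else sample_times, dtype=float)
        curve = vx.frap_recovery_curve(spec.rc, times)
        meta.update(bleach_fraction=0.9)
    elif kind == "dark_reversion":
        times = np.asarray(DEFAULT_SAMPLE_TIMES[kind] if sample_times is None else sample_times, dtype=float)
        curve = vx.dark_reversion_curve(spec.rc, times, model="full")
        meta.update(model="full")
    elif kind == "degradation":
        times = np.asarray(DEFAULT_SAMPLE_TIMES[kind] if sample_times is None else sample_times, dtype=float)
        curve = vx.degradation_curve(spec.rc, times, fluence=3.0)
        meta.update(fluence_umol=3.0)
    elif kind == "accumulation":
        times = np.asarray(DEFAULT_SAMPLE_TIMES[kind] if sample_times is None else sample_times, dtype=float)
        rc_line = spec.rc.with_(z=spec.accumulation_z)
        curve = vx.accumulation_curve(rc_line, times, t_syn=spec.t_syn)
        meta.update(genotype_z=spec.accumulation_z, t_syn=spec.t_syn)
    elif kind == "fluence_response":
        times = np.asarray(DEFAULT_FLUENCES if sample_times is None else sample_times, dtype=float)
        curve = vx.fluence_rate_response(
            spec.rc, spec.gp, times, setup="filter_paper"
        )
        meta.update(setup="filter_paper", duration_min=5760.0)
    else:
        raise ValueError(f"no time-series generator for kind {kind!r}")

    truth = curve["value"].to_numpy()
    return _noisy_dataset(kind, times, truth, noise, n_rep, rng, meta)


def generate_seedling_panel(
    spec: SyntheticSpec,
    n_seedlings: int | None = None,
    days: float = 6.0,
    setup: str = "agar",
) -> tuple[list[pd.DataFrame], dict]:
    """Per-seedling hourly dark-growth trajectories over ``days`` days.

    Each seedling's growth-start time (the 0.5 mm threshold crossing) is
    drawn around ``t_growth_mean`` with the configured jitter; hourly
    lengths carry additive measurement noise.  Returns the curves and a
    ground-truth record.
    """
    n = n_seedlings or spec.n_seedlings
    if n < 1:
        raise ValueError("need at least one seedling")
    rng = spec.rng("dark_growth")
    noise = spec.noise.get("dark_growth", 0.0)
    t_grid = np.arange(0.0, days * 1440.0 + 1.0, 60.0)

    # place the latent onset so the noiseless curve crosses the threshold
    # exactly at the drawn t_growth (the operational growth-start definition)
    delta = threshold_crossing_time(
        spec.gp.with_(t_growth=0.0), spec.growth_threshold_mm, setup=setup
    )
    crossings = spec.t_growth_mean + spec.t_growth_jitter_sd * rng.standard_normal(n)
    crossings = np.clip(crossings, delta + 1.0, None)

    curves = []
    for t_cross in crossings:
        gp_i = spec.gp.with_(t_growth=float(t_cross) - delta)
        length = np.asarray(
            growth_length_constant_u(t_grid, gp_i, 0.0, setup=setup)
        )
        if noise > 0:
            length = length + rng.normal(0.0, noise, size=length.shape)
        curves.append(pd.DataFrame({"time_min": t_grid, "length_mm": length}))
    truth = {
        "t_growth_mean": spec.t_growth_mean,
        "t_growth_draws": crossings,
        "asymptote_mm": spec.gp.alpha0 / spec.gp.effective_beta(setup),
        "setup": setup,
        "noise_sd_mm": noise,
    }
    return curves, truth


def generate_abundance_length_table(
    spec: SyntheticSpec,
    z_values: Sequence[float],
    fluence: float = 22.0,
) -> pd.DataFrame:
    """Relative phyB level vs relative hypocotyl length, Table-S1 style.

    Lengths come from the abundance-response ratio at ground truth (the
    steady signal per unit z is computed at the saturating red fluence),
    plus replicate noise; the z = 1 row is exactly (1, 1) before noise.
    """
    from .growth import relative_length_vs_abundance
    from .model import Segment

    z_values = np.asarray(z_values, dtype=float)
    if np.any(z_values <= 0):
        raise ValueError("z values must be positive")
    rng = spec.rng("abundance")
    noise = spec.noise.get("abundance", 0.0)
    n_rep = spec.replicates.get("abundance", 1)

    f = vx.steady_signal(
        spec.rc.with_(z=1.0), Segment("red_660", fluence, None)
    )
    K = spec.gp.K_prime  # concentrations are in P_0^Col units, so K = K'
    truth = np.asarray(relative_length_vs_abundance(z_values, K, f))
    if noise == 0.0:
        values, se = truth, np.zeros_like(truth)
    else:
        reps = truth[None, :] + rng.normal(0.0, noise, size=(n_rep, len(truth)))
        values = reps.mean(axis=0)
        se = (
            reps.std(axis=0, ddof=1) / np.sqrt(n_rep)
            if n_rep > 1
            else np.full_like(truth, noise)
        )
    return pd.DataFrame(
        {
            "relative_phyB": z_values,
            "relative_length": values,
            "se": se,
            "truth": truth,
        }
    )
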