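"""Seeded generator of synthetic LNP-mRNA uptake/secretion datasets.

A discrete-step, first-order bookkeeping simulator moves mRNA copies
between pools — medium, internalized, translatable (cytosolic), degraded,
EV — and produces protein from the translatable pool.  It is scaffolding
with the statistical and kinetic structure of the wet-lab measurements,
not a mechanistic model: the default rate constants are calibrated so that
per-cell copies peak at 1 h near 1355, per-EV copies peak at 5 h near 31,
medium retains under 20% of the dose at 5 h, and over 90% of cells score
payload-positive at 2 h.

Observation operators dress the latent pools in assay noise: Gaussian Cq
noise for qPCR (with a 7-point 10-fold standard series), multiplicative
lognormal noise for ELISA and NTA, and a lognormal cell-to-cell
heterogeneity model for payload positivity.  With their noise parameters
at zero every operator is an exact inverse of the quantification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import vegfa
from .particle_metrics import NtaMeasurement
from .stoichiometry import AVOGADRO
from .qpcr_quant import PERFECT_EFFICIENCY_SLOPE

__all__ = [
    "SimulationParams",
    "Trajectory",
    "SyntheticDataset",
    "default_params",
    "simulate_compartments",
    "observe_qpcr",
    "observe_elisa",
    "observe_positivity",
    "observe_nta",
    "observe_cpm",
    "generate_dataset",
    "STANDARD_SERIES_NG",
    "DEFAULT_TRUE_INTERCEPT",
]

#: The canonical 7-point 10-fold dilution series, ng.
STANDARD_SERIES_NG = tuple(100.0 / 10**i for i in range(7))

#: Cq of the noise-free true curve at 1 ng.
DEFAULT_TRUE_INTERCEPT = 20.0

_POOLS = (
    "medium",
    "cell_internalized",
    "cell_translatable",
    "degraded",
    "ev",
    "protein_lysate",
    "protein_secreted",
)


@dataclass(frozen=True)
class SimulationParams:
    """Rates, noise model and seed for the synthetic-data generator.

    Defaults are the shipped calibration (see module docstring).  Rates are
    per hour; fractions are dimensionless in [0, 1].
    """

    dose_copies: float = 6.5e12
    n_cells: float = 4e5
    k_uptake: float = 0.35
    f_escape: float = 5.831e-4
    k_process: float = 0.6
    k_deg: float = 1.3
    k_ev: float = 2.701
    ev_rate: float = 10.0
    k_translate: float = 3343.8
    f_secrete: float = 0.6
    heterogeneity_sigma: float = 1.0
    positivity_threshold: float = 50.0
    cq_sd: float = 0.2
    elisa_cv: float = 0.15
    nta_sigma: float = 0.15
    cpm_cv: float = 0.02
    seed: int = 0
    dt: float = 0.01
    wash_time_h: float | None = None

    def __post_init__(self) -> None:
        for name in ("dose_copies", "n_cells", "ev_rate", "k_translate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k_uptake", "k_process", "k_deg", "k_ev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("f_escape", "f_secrete"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("cq_sd", "elisa_cv", "nta_sigma", "cpm_cv", "heterogeneity_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.dt <= 0.05:
            raise ValueError(f"dt must be in (0, 0.05] h, got {self.dt}")


def default_params(seed: int = 0, **overrides) -> SimulationParams:
    """The shipped calibration, optionally overridden field by field."""
    return replace(SimulationParams(seed=seed), **overrides)


@dataclass(frozen=True)
class Trajectory:
    """Latent per-pool copy numbers on the full integration grid."""

    times: np.ndarray
    pools: dict[str, np.ndarray]
    params: SimulationParams

    def at(self, timepoint_h: float) -> dict[str, float]:
        return {k: float(np.interp(timepoint_h, self.times, v)) for k, v in self.pools.items()}

    def cell_copies(self, timepoint_h: float) -> float:
        """Total qPCR-detectable intracellular copies at a timepoint."""
        state = self.at(timepoint_h)
        return state["cell_internalized"] + state["cell_translatable"]

    def per_cell_copies(self, timepoint_h: float) -> float:
        return self.cell_copies(timepoint_h) / self.params.n_cells

    def cumulative_evs(self, timepoint_h: float) -> float:
        """EVs secreted since t0 (continuous budding at ev_rate per cell)."""
        return self.params.ev_rate * self.params.n_cells * timepoint_h

    def per_ev_copies(self, timepoint_h: float) -> float:
        if timepoint_h <= 0:
            raise ValueError("per-EV copies undefined at t = 0")
        return self.at(timepoint_h)["ev"] / self.cumulative_evs(timepoint_h)

    def medium_fraction(self, timepoint_h: float) -> float:
        return self.at(timepoint_h)["medium"] / self.params.dose_copies

    def conservation_error(self) -> float:
        """Max relative deviation of medium+cell+degraded+EV from the dose."""
        total = (
            self.pools["medium"]
            + self.pools["cell_internalized"]
            + self.pools["cell_translatable"]
            + self.pools["degraded"]
            + self.pools["ev"]
        )
        return float(np.max(np.abs(total - self.params.dose_copies)) / self.params.dose_copies)


def simulate_compartments(
    p: SimulationParams, timepoints: tuple[float, ...] | list[float]
) -> Trajectory:
    """Integrate the compartment bookkeeping up to the last timepoint.

    Forward-Euler mass action on a fixed grid (step ``p.dt`` <= 0.05 h).
    Copy conservation (medium + cell pools + degraded + EV = dose) holds at
    every step by construction.  An optional wash event empties the medium
    pool at ``p.wash_time_h``.
    """
    tps = sorted(float(t) for t in timepoints)
    if not tps:
        raise ValueError("at least one timepoint is required")
    if tps[0] < 0:
        raise ValueError("timepoints must be non-negative")
    n_steps = int(np.ceil(tps[-1] / p.dt + 1e-9))
    times = np.linspace(0.0, n_steps * p.dt, n_steps + 1)
    state = {name: np.zeros(n_steps + 1) for name in _POOLS}
    medium = p.dose_copies
    internal = translatable = degraded = ev = lysate = secreted = 0.0
    washed = p.wash_time_h is None
    for step in range(n_steps + 1):
        t = times[step]
        if not washed and t >= p.wash_time_h - 1e-12:
            degraded += medium  # removed from the dish, bookkept as lost dose
            medium = 0.0
            washed = True
        state["medium"][step] = medium
        state["cell_internalized"][step] = internal
        state["cell_translatable"][step] = translatable
        state["degraded"][step] = degraded
        state["ev"][step] = ev
        state["protein_lysate"][step] = lysate
        state["protein_secreted"][step] = secreted
        if step == n_steps:
            break
        dt = p.dt
        uptake = p.k_uptake * medium * dt
        escaped = uptake * p.f_escape
        lost_at_entry = uptake - escaped
        processed = p.k_process * internal * dt
        deg_internal = p.k_deg * internal * dt
        deg_translatable = p.k_deg * translatable * dt
        to_ev = p.k_ev * translatable * dt
        protein = p.k_translate * translatable * dt
        medium -= uptake
        internal += escaped - processed - deg_internal
        translatable += processed - deg_translatable - to_ev
        ev += to_ev
        degraded += lost_at_entry + deg_internal + deg_translatable
        lysate += protein * (1.0 - p.f_secrete)
        secreted += protein * p.f_secrete
        if min(medium, internal, translatable) < 0:
            raise RuntimeError("negative pool encountered; decrease dt")
    return Trajectory(times=times, pools=state, params=p)


def _copies_to_ng(copies: float, mw_g_per_mol: float) -> float:
    return copies / AVOGADRO * mw_g_per_mol * 1e9


def observe_qpcr(
    latent_copies: Mapping[str, float] | float,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    mw_g_per_mol: float = vegfa.FULL_LENGTH_MW,
    slope: float = PERFECT_EFFICIENCY_SLOPE,
    intercept: float = DEFAULT_TRUE_INTERCEPT,
    n_replicates: int = 6,
    technical_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit synthetic Cq tables for latent copy numbers plus standards.

    Copies are converted to ng through the construct molecular weight, to a
    true Cq through the noise-free curve, then Gaussian Cq noise (sd
    ``p.cq_sd``) is added per technical replicate.  Each latent value is
    observed as ``n_replicates`` biological replicates of
    ``technical_replicates`` wells, matching the assay layout; the 7-point
    10-fold standard series (100 to 0.0001 ng) shares the noise model.

    Returns ``(standards, unknowns)`` DataFrames in the CSV schemas the
    quantification pipeline consumes.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    if not isinstance(latent_copies, Mapping):
        latent_copies = {"sample": float(latent_copies)}
    std_rows = []
    for q in STANDARD_SERIES_NG:
        true_cq = intercept + slope * np.log10(q)
        for rep in range(technical_replicates):
            std_rows.append(
                {
                    "sample_id": f"std_{q:g}ng",
                    "quantity_ng": q,
                    "cq": true_cq + rng.normal(0.0, p.cq_sd),
                }
            )
    unk_rows = []
    for name, copies in latent_copies.items():
        if copies <= 0:
            raise ValueError(f"latent copies for {name!r} must be positive, got {copies}")
        true_cq = intercept + slope * np.log10(_copies_to_ng(copies, mw_g_per_mol))
        for bio in range(1, n_replicates + 1):
            for tech in range(1, technical_replicates + 1):
                unk_rows.append(
                    {
                        "sample_id": f"{name}_r{bio}",
                        "replicate": bio,
                        "technical_replicate": tech,
                        "cq": true_cq + rng.normal(0.0, p.cq_sd),
                    }
                )
    return pd.DataFrame(std_rows), pd.DataFrame(unk_rows)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    # multiplicative noise with mean exactly 1 and relative sd cv
    if cv == 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def observe_elisa(
    protein_copies: float,
    protein_mw_g_per_mol: float,
    volume_ml: float,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    n_replicates: int = 6,
) -> np.ndarray:
    """pg/mL ELISA readings for a latent protein copy number.

    Copies are converted to picograms through the protein molecular weight,
    divided by the assay volume, and multiplied by lognormal noise with
    mean 1 and coefficient of variation ``p.elisa_cv``.
    """
    if volume_ml <= 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    pg_total = protein_copies / AVOGADRO * protein_mw_g_per_mol * 1e12
    true_pg_ml = pg_total / volume_ml
    return true_pg_ml * _lognormal_factor(rng, p.elisa_cv, size=n_replicates)


def observe_positivity(
    mean_per_cell_copies: float,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    n_cells_sampled: int = 20_000,
    threshold_copies: float | None = None,
) -> float:
    """Fraction of cells whose payload exceeds the detection threshold.

    Per-cell copy numbers are lognormal across the population with shape
    ``p.heterogeneity_sigma`` around the latent mean.
    """
    if mean_per_cell_copies <= 0:
        raise ValueError("mean per-cell copies must be positive")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    if threshold_copies is None:
        threshold_copies = p.positivity_threshold
    if threshold_copies <= 0:
        return 1.0
    sigma = p.heterogeneity_sigma
    mu = np.log(mean_per_cell_copies) - sigma**2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=sigma, size=n_cells_sampled)
    return float(np.mean(draws > threshold_copies))


def observe_nta(
    concentration_per_ml: float,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    mean_size_nm: float = 105.0,
    n_captures: int = 3,
    dilution_factor: float = 5.0,
) -> NtaMeasurement:
    """Per-capture NTA sizes and (diluted) concentrations for one sample."""
    if rng is None:
        rng = np.random.default_rng(p.seed)
    sizes = mean_size_nm * _lognormal_factor(rng, p.nta_sigma, size=n_captures)
    concs = (
        concentration_per_ml
        / dilution_factor
        * _lognormal_factor(rng, p.nta_sigma, size=n_captures)
    )
    return NtaMeasurement(
        capture_sizes_nm=tuple(float(s) for s in sizes),
        capture_concentrations_per_ml=tuple(float(c) for c in concs),
        dilution_factor=dilution_factor,
    )


def observe_cpm(
    medium_fraction: float,
    p: SimulationParams,
    rng: np.random.Generator | None = None,
    blank_cpm: float = 30.0,
    full_scale_cpm: float = 5000.0,
    n_readings: int = 2,
) -> dict[str, float]:
    """Scintillation readings for the radiolabel remaining in the medium.

    The sample signal interpolates between a medium-only (0%) and a
    t0-spiked (100%) reference; duplicate readings are averaged.
    """
    if not 0.0 <= medium_fraction <= 1.0:
        raise ValueError(f"medium fraction must be in [0, 1], got {medium_fraction}")
    if rng is None:
        rng = np.random.default_rng(p.seed)

    def reading(true_cpm: float) -> float:
        return float(
            np.mean(true_cpm * _lognormal_factor(rng, p.cpm_cv, size=n_readings))
        )

    return {
        "sample_cpm": reading(blank_cpm + medium_fraction * full_scale_cpm),
        "blank_cpm": reading(blank_cpm),
        "ref0_cpm": reading(blank_cpm),
        "ref100_cpm": reading(blank_cpm + full_scale_cpm),
    }


@dataclass(frozen=True)
class SyntheticDataset:
    """A full synthetic study: latent truth plus observed assay tables."""

    trajectory: Trajectory
    qpcr_standards: pd.DataFrame
    qpcr_unknowns: pd.DataFrame
    elisa: pd.DataFrame
    cpm: pd.DataFrame
    nta: dict[float, NtaMeasurement]
    ground_truth: pd.DataFrame
    params: SimulationParams = field(repr=False)


def generate_dataset(
    p: SimulationParams,
    timepoints: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 24.0),
    protein_mw_g_per_mol: float = vegfa.PROTEIN_MW_KDA * 1000.0,
    mrna_mw_g_per_mol: float = vegfa.FULL_LENGTH_MW,
    elisa_volume_ml: float = 1.0,
    n_replicates: int = 6,
) -> SyntheticDataset:
    """Simulate the latent kinetics and observe every assay table.

    Independent RNG sub-streams (derived deterministically from the seed)
    drive each observation table, so regenerating with the same seed is
    bitwise reproducible and different seeds share the same ground truth.
    """
    traj = simulate_compartments(p, timepoints)
    children = np.random.SeedSequence(p.seed).spawn(4)
    rng_qpcr, rng_elisa, rng_cpm, rng_nta = (np.random.default_rng(s) for s in children)

    latent = {}
    for t in timepoints:
        if t > 0:
            latent[f"cell_{t:g}h"] = traj.cell_copies(t)
            latent[f"ev_{t:g}h"] = traj.at(t)["ev"]
    standards, unknowns = observe_qpcr(
        latent, p, rng=rng_qpcr, mw_g_per_mol=mrna_mw_g_per_mol, n_replicates=n_replicates
    )

    elisa_rows = []
    t_end = max(timepoints)
    state_end = traj.at(t_end)
    for compartment, pool in (("lysate", "protein_lysate"), ("supernatant", "protein_secreted")):
        readings = observe_elisa(
            state_end[pool], protein_mw_g_per_mol, elisa_volume_ml, p,
            rng=rng_elisa, n_replicates=n_replicates,
        )
        for rep, value in enumerate(readings, start=1):
            elisa_rows.append(
                {
                    "timepoint_h": t_end,
                    "compartment": compartment,
                    "replicate": rep,
                    "pg_per_ml": float(value),
                    "volume_ml": elisa_volume_ml,
                }
            )

    cpm_rows = []
    for t in timepoints:
        for rep in range(1, 4):
            row = observe_cpm(traj.medium_fraction(t), p, rng=rng_cpm)
            cpm_rows.append({"timepoint_h": t, "replicate": rep, **row})

    nta = {}
    for t in timepoints:
        if t > 0:
            conc = traj.cumulative_evs(t) / 1.0  # EV pellet resuspended in 1 mL
            nta[t] = observe_nta(conc, p, rng=rng_nta)

    truth_rows = []
    for t in timepoints:
        state = traj.at(t)
        truth_rows.append(
            {
                "timepoint_h": t,
                **state,
                "per_cell_copies": traj.per_cell_copies(t) if t > 0 else 0.0,
                "per_ev_copies": traj.per_ev_copies(t) if t > 0 else float("nan"),
                "cumulative_evs": traj.cumulative_evs(t),
                "medium_fraction": traj.medium_fraction(t),
            }
        )

    return SyntheticDataset(
        trajectory=traj,
        qpcr_standards=standards,
        qpcr_unknowns=unknowns,
        elisa=pd.DataFrame(elisa_rows),
        cpm=pd.DataFrame(cpm_rows),
        nta=nta,
        ground_truth=pd.DataFrame(truth_rows),
        params=p,
    )
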