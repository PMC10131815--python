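"""Particle-level summaries: NTA, LNP particle counts, radiolabel uptake.

The LNP particle count defaults to a transparent payload calibration
(copies per particle) rather than a light-scattering model; a geometric
sphere-volume estimate is provided as a clearly labelled approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .stoichiometry import mass_to_copies

__all__ = [
    "Formulation",
    "NtaMeasurement",
    "NtaSummary",
    "CpmReading",
    "UptakeResult",
    "LnpCountEstimate",
    "summarize_nta",
    "estimate_lnp_count",
    "uptake_fraction",
    "np_ratio",
]

_DEFAULT_MOLAR_FRACTIONS = {
    "MC3": 0.50,
    "cholesterol": 0.385,
    "DSPC": 0.10,
    "DMPE-PEG2000": 0.015,
}


@dataclass(frozen=True)
class Formulation:
    """An ionizable-lipid nanoparticle formulation.

    Defaults describe the study formulation: MC3:cholesterol:DSPC:DMPE-PEG2000
    at 50:38.5:10:1.5 mol%, 12.5 mM total lipid, 10:1 lipid:mRNA (w/w),
    85 nm z-average diameter, PDI 0.024, 99% encapsulation, 0.1 mg/mL mRNA.
    """

    molar_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MOLAR_FRACTIONS)
    )
    total_lipid_molar: float = 12.5e-3
    lipid_to_mrna_w_w: float = 10.0
    diameter_z_nm: float = 85.0
    pdi: float = 0.024
    encapsulation: float = 0.99
    mrna_conc_mg_ml: float = 0.1
    ionizable_lipid: str = "MC3"

    def __post_init__(self) -> None:
        total = sum(self.molar_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"lipid molar fractions must sum to 1, got {total}")
        if any(f <= 0 for f in self.molar_fractions.values()):
            raise ValueError("lipid molar fractions must be positive")
        if not 0.0 <= self.encapsulation <= 1.0:
            raise ValueError(f"encapsulation must be in [0, 1], got {self.encapsulation}")
        for name in ("total_lipid_molar", "lipid_to_mrna_w_w", "diameter_z_nm", "mrna_conc_mg_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ionizable_lipid not in self.molar_fractions:
            raise ValueError(f"ionizable lipid {self.ionizable_lipid!r} not in molar fractions")


@dataclass(frozen=True)
class NtaMeasurement:
    """Per-capture NTA readings for one sample (sizes in nm, conc per mL)."""

    capture_sizes_nm: tuple[float, ...]
    capture_concentrations_per_ml: tuple[float, ...]
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if len(self.capture_sizes_nm) == 0:
            raise ValueError("at least one capture is required")
        if len(self.capture_sizes_nm) != len(self.capture_concentrations_per_ml):
            raise ValueError("sizes and concentrations must have the same number of captures")
        if any(s <= 0 for s in self.capture_sizes_nm):
            raise ValueError("capture sizes must be positive")
        if any(c <= 0 for c in self.capture_concentrations_per_ml):
            raise ValueError("capture concentrations must be positive")
        if self.dilution_factor < 1.0:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution_factor}")


class NtaSummary(NamedTuple):
    mean_size_nm: float
    sem_size_nm: float | None
    mean_concentration_per_ml: float
    sem_concentration_per_ml: float | None


def _sem(values: np.ndarray) -> float | None:
    # single capture: SEM is not available, not zero
    if values.size < 2:
        return None
    return float(values.std(ddof=1) / math.sqrt(values.size))


def summarize_nta(m: NtaMeasurement) -> NtaSummary:
    """Mean +/- SEM size over captures; concentration scaled back to undiluted."""
    sizes = np.asarray(m.capture_sizes_nm, dtype=float)
    concs = np.asarray(m.capture_concentrations_per_ml, dtype=float) * m.dilution_factor
    return NtaSummary(
        mean_size_nm=float(sizes.mean()),
        sem_size_nm=_sem(sizes),
        mean_concentration_per_ml=float(concs.mean()),
        sem_concentration_per_ml=_sem(concs),
    )


class LnpCountEstimate(NamedTuple):
    particles: float
    copies_per_particle: float


def estimate_lnp_count(
    formulation: Formulation,
    dose_mrna_mass_g: float,
    mrna_mw_g_per_mol: float,
    copies_per_particle: float | None = None,
    mode: str = "calibration",
    core_density_g_cm3: float = 1.1,
) -> LnpCountEstimate:
    """Estimate how many particles carry a given mRNA dose.

    ``calibration`` mode (default) divides total dose copies by a known
    copies-per-particle constant.  ``geometric`` mode approximates the
    per-particle payload from the sphere volume at the z-average diameter,
    an assumed core density, and the lipid:mRNA w/w ratio; it is an
    order-of-magnitude sanity model, not a measurement.
    """
    if dose_mrna_mass_g <= 0:
        raise ValueError(f"dose mass must be positive, got {dose_mrna_mass_g}")
    dose_copies = mass_to_copies(dose_mrna_mass_g, mrna_mw_g_per_mol).copies
    if mode == "calibration":
        if copies_per_particle is None:
            raise ValueError("calibration mode requires a copies_per_particle constant")
        if copies_per_particle <= 0:
            raise ValueError("copies_per_particle must be positive")
        cpp = float(copies_per_particle)
    elif mode == "geometric":
        d_cm = formulation.diameter_z_nm * 1e-7
        volume_cm3 = math.pi / 6.0 * d_cm**3
        particle_mass_g = volume_cm3 * core_density_g_cm3
        mrna_mass_fraction = 1.0 / (formulation.lipid_to_mrna_w_w + 1.0)
        cpp = mass_to_copies(particle_mass_g * mrna_mass_fraction, mrna_mw_g_per_mol).copies
    else:
        raise ValueError(f"mode must be 'calibration' or 'geometric', got {mode!r}")
    return LnpCountEstimate(particles=dose_copies / cpp, copies_per_particle=cpp)


@dataclass(frozen=True)
class CpmReading:
    """Scintillation counts with medium-only (0%) and t0-spiked (100%) references."""

    sample_cpm: float
    blank_cpm: float
    ref_0pct_cpm: float
    ref_100pct_cpm: float

    def __post_init__(self) -> None:
        for name in ("sample_cpm", "blank_cpm", "ref_0pct_cpm", "ref_100pct_cpm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class UptakeResult(NamedTuple):
    uptake_pct: float
    remaining_pct: float
    clamped: bool


def uptake_fraction(r: CpmReading) -> UptakeResult:
    """Uptake percentage inferred from radioactivity remaining in the medium.

    All terms are blank-subtracted, remaining% interpolates the sample
    between the 0% and 100% references, and uptake% = 100 - remaining%,
    clamped to [0, 100] with a flag when clamping occurred.
    """
    ref0 = r.ref_0pct_cpm - r.blank_cpm
    ref100 = r.ref_100pct_cpm - r.blank_cpm
    if ref100 <= ref0:
        raise ValueError(
            f"invalid references: 100% CPM ({ref100}) must exceed 0% CPM ({ref0}) "
            "after blank subtraction"
        )
    sample = r.sample_cpm - r.blank_cpm
    remaining = 100.0 * (sample - ref0) / (ref100 - ref0)
    uptake = 100.0 - remaining
    clamped = not 0.0 <= uptake <= 100.0
    return UptakeResult(
        uptake_pct=min(100.0, max(0.0, uptake)), remaining_pct=remaining, clamped=clamped
    )


def np_ratio(
    formulation: Formulation,
    lipid_molar_masses: dict[str, float],
    mrna_mean_nt_mass_g_per_mol: float,
    mix_ratio_aq_to_eth: float = 3.0,
    amines_per_ionizable: float = 1.0,
) -> float:
    """Nitrogen-to-phosphate mole ratio of a formulation.

    Requires user-supplied lipid molar masses.  Moles of ionizable amine
    follow from the lipid molar composition; moles of phosphate from the
    mRNA mass implied by the lipid:mRNA w/w ratio divided by the mean
    nucleotide residue mass.  Because both streams are tied together by the
    w/w ratio, the aqueous:ethanol mixing ratio cancels from the arithmetic;
    the parameter is accepted for interface completeness only.
    """
    missing = set(formulation.molar_fractions) - set(lipid_molar_masses)
    if missing:
        raise ValueError(f"missing molar masses for lipids: {sorted(missing)}")
    if mrna_mean_nt_mass_g_per_mol <= 0:
        raise ValueError("mean nucleotide mass must be positive")
    mean_lipid_mass = sum(
        frac * lipid_molar_masses[name] for name, frac in formulation.molar_fractions.items()
    )
    n_moles = formulation.molar_fractions[formulation.ionizable_lipid] * amines_per_ionizable
    mrna_mass_per_lipid_mol = mean_lipid_mass / formulation.lipid_to_mrna_w_w
    p_moles = mrna_mass_per_lipid_mol / mrna_mean_nt_mass_g_per_mol
    return n_moles / p_moles
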