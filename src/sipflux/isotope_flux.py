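"""Isotope mass-balance potentials from microcosm SIP incubations.

Three pools carry the isotope label after a microcosm incubation with
13C-CH4 and 15N-N2:

* headspace 13C-CO2 (gas pool) — methane oxidized all the way to CO2,
* 13C in soil organic carbon (SOC) — methane-derived carbon assimilated
  into biomass,
* 15N in soil organic nitrogen (SON) — fixed dinitrogen.

Each potential is the atom-percent excess accumulated over the incubation,
converted to moles of labeled atoms in the pool, normalized per gram of
dry-weight soil (dws) per day:

    gas  :  (Cgas/100) * (dA/100) * (Vh/1000) / Vs * 1e9 / (m * t)
    soc  :  (Csoc/100) * (dA/100) * m / M     * 1e9 / (m * t)
    son  :  (Cson/100) * (dA/100) * m / M     * 1e9 / (m * t)

where Cgas is the headspace CO2 volume percent, Vh the headspace gas
volume (mL, 1-atm equivalent), Vs the molar gas volume (L/mol), Csoc/Cson
the organic C/N pools as percent of dry soil mass m (g), M the molar mass
of the heavy isotope (g/mol), dA the atom-percent excess over the day-0
baseline, and t the incubation length (days).  Results are nmol of
labeled C (or N) per g dws per day.  All unit conversions (percent to
fraction, mL to L, mol to nmol) are explicit; no composite scale constant
is hard-coded.  Note m cancels in the two soil-pool equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "IncubationSetup",
    "MicrocosmMeasurement",
    "PotentialResult",
    "DEPTH_LABELS",
    "atom_percent_excess",
    "co2_oxidation_potential",
    "soc_assimilation_potential",
    "n2_fixation_potential",
    "total_methane_oxidation",
    "depth_fold_ratios",
    "inverse_atom_excess",
    "compute_potentials",
]

DEPTH_LABELS = ("top_0_20", "mid_40_60", "deep_60_80")

#: natural-abundance atom-% baselines (advisory; used by the simulator)
NATURAL_ABUNDANCE_13C_PCT = 1.08
NATURAL_ABUNDANCE_15N_PCT = 0.3663


@dataclass(frozen=True)
class IncubationSetup:
    """Bottle geometry and physical constants shared by all bottles.

    ``headspace_volume_ml`` is the 1-atm-equivalent gas volume: the study
    design injects ~360 mL of gas mix into a 120-mL bottle to reach 3 atm,
    so the default is 360 mL rather than the nominal bottle headspace.
    ``molar_volume_l_per_mol`` defaults to 22.4 L/mol (STP); pass 22.414
    or a temperature-adjusted value if preferred.  Molar masses default to
    the nominal integer isotope masses; exact isotopic masses may be set.
    """

    dry_mass_g: float = 5.0
    incubation_days: float = 90.0
    headspace_volume_ml: float = 360.0
    molar_volume_l_per_mol: float = 22.4
    molar_mass_13c_g_per_mol: float = 13.0
    molar_mass_15n_g_per_mol: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "dry_mass_g",
            "incubation_days",
            "headspace_volume_ml",
            "molar_volume_l_per_mol",
            "molar_mass_13c_g_per_mol",
            "molar_mass_15n_g_per_mol",
        ):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.incubation_days < 1:
            raise ValueError(
                f"incubation_days must be >= 1, got {self.incubation_days!r}"
            )


def _check_pct(name: str, value: float) -> float:
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"{name} must lie in [0, 100], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class MicrocosmMeasurement:
    """One bottle's pool contents and atom-% readings at day 0 and day 90."""

    depth_label: str
    replicate_id: str
    co2_concentration_pct: float
    atom13_co2_day90_pct: float
    atom13_co2_day0_pct: float
    soc_content_pct: float
    atom13_soc_day90_pct: float
    atom13_soc_day0_pct: float
    son_content_pct: float
    atom15_son_day90_pct: float
    atom15_son_day0_pct: float
    treatment: str = "labeled"

    def __post_init__(self) -> None:
        if self.depth_label not in DEPTH_LABELS:
            raise ValueError(
                f"depth_label must be one of {DEPTH_LABELS}, got {self.depth_label!r}"
            )
        if self.treatment not in ("labeled", "control"):
            raise ValueError(f"treatment must be labeled|control, got {self.treatment!r}")
        for name in (
            "co2_concentration_pct",
            "atom13_co2_day90_pct",
            "atom13_co2_day0_pct",
            "soc_content_pct",
            "atom13_soc_day90_pct",
            "atom13_soc_day0_pct",
            "son_content_pct",
            "atom15_son_day90_pct",
            "atom15_son_day0_pct",
        ):
            _check_pct(name, getattr(self, name))


@dataclass(frozen=True)
class PotentialResult:
    """Per-bottle potentials (nmol per g dws per day) and quality flags."""

    co2_potential: float
    soc_potential: float
    total_ch4_oxidation: float
    co2_fraction: float  # NaN when total is 0
    n2_fixation: float
    flags: frozenset[str] = field(default_factory=frozenset)


def atom_percent_excess(a_day90_pct: float, a_day0_pct: float) -> float:
    """Atom-% excess: day-90 atom-% minus the day-0 baseline.

    Negative results (control drift) are returned unchanged; callers tag
    them with a ``negative_excess`` flag rather than clamping, so QC
    problems stay visible.
    """
    _check_pct("a_day90_pct", a_day90_pct)
    _check_pct("a_day0_pct", a_day0_pct)
    return float(a_day90_pct) - float(a_day0_pct)


# internal unit-conversion factors, spelled out
_PCT = 1e-2       # percent -> fraction
_ML_TO_L = 1e-3   # mL -> L
_MOL_TO_NMOL = 1e9


def co2_oxidation_potential(
    meas: MicrocosmMeasurement, setup: IncubationSetup
) -> float:
    """Methane-oxidation potential carried by headspace 13C-CO2.

    nmol 13C = (Cgas/100) * (dA/100) * (Vh mL -> L) / Vs mol -> nmol;
    the result is divided by (m * t).
    """
    d_a = atom_percent_excess(meas.atom13_co2_day90_pct, meas.atom13_co2_day0_pct)
    nmol = (
        meas.co2_concentration_pct * _PCT
        * d_a * _PCT
        * setup.headspace_volume_ml * _ML_TO_L
        / setup.molar_volume_l_per_mol
        * _MOL_TO_NMOL
    )
    return nmol / (setup.dry_mass_g * setup.incubation_days)


def soc_assimilation_potential(
    meas: MicrocosmMeasurement, setup: IncubationSetup
) -> float:
    """Methane-oxidation potential carried by 13C assimilated into SOC.

    nmol 13C = (Csoc/100) * m * (dA/100) / M mol -> nmol, over (m * t);
    the soil mass m cancels.
    """
    d_a = atom_percent_excess(meas.atom13_soc_day90_pct, meas.atom13_soc_day0_pct)
    nmol = (
        meas.soc_content_pct * _PCT
        * setup.dry_mass_g
        * d_a * _PCT
        / setup.molar_mass_13c_g_per_mol
        * _MOL_TO_NMOL
    )
    return nmol / (setup.dry_mass_g * setup.incubation_days)


def n2_fixation_potential(
    meas: MicrocosmMeasurement, setup: IncubationSetup
) -> float:
    """N2-fixation potential from 15N accumulated in SON (m cancels)."""
    d_a = atom_percent_excess(meas.atom15_son_day90_pct, meas.atom15_son_day0_pct)
    nmol = (
        meas.son_content_pct * _PCT
        * setup.dry_mass_g
        * d_a * _PCT
        / setup.molar_mass_15n_g_per_mol
        * _MOL_TO_NMOL
    )
    return nmol / (setup.dry_mass_g * setup.incubation_days)


def total_methane_oxidation(gas: float, soc: float) -> tuple[float, float]:
    """Total CH4-oxidation potential and its CO2 share.

    Returns ``(total, co2_fraction)`` where total = gas + soc and
    co2_fraction = gas/total for total > 0, NaN otherwise.
    """
    if not (math.isfinite(gas) and math.isfinite(soc)):
        raise ValueError("gas and soc potentials must be finite")
    total = gas + soc
    fraction = gas / total if total > 0 else math.nan
    return total, fraction


def bottle_potentials(
    meas: MicrocosmMeasurement, setup: IncubationSetup
) -> PotentialResult:
    """Evaluate all three potentials for one bottle, with quality flags."""
    gas = co2_oxidation_potential(meas, setup)
    soc = soc_assimilation_potential(meas, setup)
    son = n2_fixation_potential(meas, setup)
    total, fraction = total_methane_oxidation(gas, soc)
    flags = set()
    if gas < 0 or soc < 0 or son < 0:
        flags.add("negative_excess")
    if not (total > 0):
        flags.add("zero_total")
    return PotentialResult(
        co2_potential=gas,
        soc_potential=soc,
        total_ch4_oxidation=total,
        co2_fraction=fraction,
        n2_fixation=son,
        flags=frozenset(flags),
    )


def compute_potentials(
    measurements: Iterable[MicrocosmMeasurement] | pd.DataFrame,
    setup: IncubationSetup,
) -> pd.DataFrame:
    """Per-bottle potentials table for a set of measurements.

    Accepts either ``MicrocosmMeasurement`` objects or a dataframe with
    the microcosm CSV schema columns; returns one row per bottle with all
    :class:`PotentialResult` fields plus identifying metadata.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = [
            MicrocosmMeasurement(
                depth_label=row["depth_label"],
                replicate_id=str(row["replicate_id"]),
                treatment=row["treatment"],
                co2_concentration_pct=row["co2_concentration_pct"],
                atom13_co2_day90_pct=row["atom13_co2_day90_pct"],
                atom13_co2_day0_pct=row["atom13_co2_day0_pct"],
                soc_content_pct=row["soc_content_pct"],
                atom13_soc_day90_pct=row["atom13_soc_day90_pct"],
                atom13_soc_day0_pct=row["atom13_soc_day0_pct"],
                son_content_pct=row["son_content_pct"],
                atom15_son_day90_pct=row["atom15_son_day90_pct"],
                atom15_son_day0_pct=row["atom15_son_day0_pct"],
            )
            for _, row in measurements.iterrows()
        ]
    rows = []
    for meas in measurements:
        res = bottle_potentials(meas, setup)
        rows.append(
            {
                "depth_label": meas.depth_label,
                "replicate_id": meas.replicate_id,
                "treatment": meas.treatment,
                "co2_potential": res.co2_potential,
                "soc_potential": res.soc_potential,
                "total_ch4_oxidation": res.total_ch4_oxidation,
                "co2_fraction": res.co2_fraction,
                "n2_fixation": res.n2_fixation,
                "flags": ";".join(sorted(res.flags)),
            }
        )
    return pd.DataFrame(rows)


def depth_fold_ratios(
    per_depth_means: Mapping[str, float],
) -> dict[tuple[str, str], float]:
    """Ratio of mean potentials for every ordered depth pair.

    Full precision is retained; round to one decimal for display only.
    A zero or negative denominator yields NaN for that pair.
    """
    ratios: dict[tuple[str, str], float] = {}
    for a, mean_a in per_depth_means.items():
        for b, mean_b in per_depth_means.items():
            if a == b:
                continue
            ratios[(a, b)] = mean_a / mean_b if mean_b > 0 else math.nan
    return ratios


def inverse_atom_excess(
    target_potential: float,
    setup: IncubationSetup,
    which: str,
    *,
    co2_concentration_pct: float | None = None,
    soc_content_pct: float | None = None,
    son_content_pct: float | None = None,
) -> float:
    """Atom-% excess that would produce ``target_potential`` exactly.

    Algebraic inversion of the forward equations, used to construct
    fixtures and simulated measurements; the forward evaluation of the
    returned excess reproduces the target to floating-point precision.
    ``which`` selects the pool: ``co2``, ``soc`` or ``son``.
    """
    if target_potential < 0:
        raise ValueError("target_potential must be >= 0")
    nmol_total = target_potential * setup.dry_mass_g * setup.incubation_days
    if which == "co2":
        if co2_concentration_pct is None or co2_concentration_pct <= 0:
            raise ValueError("co2 inversion needs co2_concentration_pct > 0")
        denom = (
            co2_concentration_pct * _PCT
            * setup.headspace_volume_ml * _ML_TO_L
            / setup.molar_volume_l_per_mol
            * _MOL_TO_NMOL
        )
    elif which == "soc":
        if soc_content_pct is None or soc_content_pct <= 0:
            raise ValueError("soc inversion needs soc_content_pct > 0")
        denom = (
            soc_content_pct * _PCT
            * setup.dry_mass_g
            / setup.molar_mass_13c_g_per_mol
            * _MOL_TO_NMOL
        )
    elif which == "son":
        if son_content_pct is None or son_content_pct <= 0:
            raise ValueError("son inversion needs son_content_pct > 0")
        denom = (
            son_content_pct * _PCT
            * setup.dry_mass_g
            / setup.molar_mass_15n_g_per_mol
            * _MOL_TO_NMOL
        )
    else:
        raise ValueError(f"which must be co2|soc|son, got {which!r}")
    return nmol_total / denom / _PCT  # back to atom-% units
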