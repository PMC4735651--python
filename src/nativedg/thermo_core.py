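"""Thermodynamic primitives shared by the whole pipeline.

All free energies are kept in kcal/mol and entropies in kcal/mol/K
internally.  The common laboratory convention of quoting entropies in
cal/mol/K is handled only at I/O (see :func:`entropy_to_cal_per_mol_kelvin`
and its inverse).  Temperatures cross the API in degrees Celsius and are
converted to Kelvin exactly once, inside :class:`ThermoCondition`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "R_KCAL",
    "ABS_ZERO_CELSIUS",
    "ThermoCondition",
    "DeltaGEstimate",
    "EnthalpyEntropyFit",
    "keq_from_delta_g",
    "delta_g_from_keq",
    "delta_g_at_temperature",
    "entropy_to_cal_per_mol_kelvin",
    "entropy_from_cal_per_mol_kelvin",
]

#: Molar gas constant in kcal/mol/K (CODATA value divided by 4184 J/kcal).
R_KCAL = 1.98720425e-3

ABS_ZERO_CELSIUS = -273.15


@dataclass(frozen=True)
class ThermoCondition:
    """Temperature and buffer context fixing RT for all dG <-> Keq conversions.

    Parameters
    ----------
    temperature_celsius
        Reaction temperature in degrees Celsius; must exceed absolute zero.
    buffer_label
        Free-text buffer description, e.g. ``"PBS"`` or ``"TE 12.5 mM Mg2+"``.
        Estimates measured in different buffers are never pooled.
    """

    temperature_celsius: float
    buffer_label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature_celsius):
            raise ValueError(
                f"temperature must be finite, got {self.temperature_celsius!r}"
            )
        if self.temperature_celsius <= ABS_ZERO_CELSIUS:
            raise ValueError(
                f"temperature {self.temperature_celsius} degC is at or below "
                f"absolute zero ({ABS_ZERO_CELSIUS} degC)"
            )

    @property
    def kelvin(self) -> float:
        return self.temperature_celsius - ABS_ZERO_CELSIUS

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return R_KCAL * self.kelvin

    def same_as(self, other: "ThermoCondition", temp_tol: float = 1e-9) -> bool:
        return (
            abs(self.temperature_celsius - other.temperature_celsius) <= temp_tol
            and self.buffer_label == other.buffer_label
        )


@dataclass(frozen=True)
class DeltaGEstimate:
    """A standard free energy with its uncertainty and provenance.

    ``sd`` is the standard deviation attached to ``value`` (for an
    aggregated estimate, the s.d. of the mean); ``n_measurements`` counts
    the independent per-lane measurements that went into it.
    """

    value: float
    sd: float
    n_measurements: int = 1
    condition: ThermoCondition = field(default_factory=lambda: ThermoCondition(25.0))
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"delta-G value must be finite, got {self.value!r}")
        if not (self.sd >= 0.0):
            raise ValueError(f"sd must be >= 0, got {self.sd!r}")
        if self.n_measurements < 1:
            raise ValueError(
                f"n_measurements must be >= 1, got {self.n_measurements}"
            )


@dataclass(frozen=True)
class EnthalpyEntropyFit:
    """Result of a temperature-invariant dH/dS fit (dG(T) = dH - T*dS).

    Units are kcal/mol for ``dh`` and kcal/mol/K for ``ds``; ``sum_sq_z``
    is the weighted residual sum of squares of the fit.
    """

    dh: float
    ds: float
    dh_sd: float = 0.0
    ds_sd: float = 0.0
    sum_sq_z: float = 0.0

    def __post_init__(self) -> None:
        if self.sum_sq_z < 0.0:
            raise ValueError(f"sum_sq_z must be >= 0, got {self.sum_sq_z!r}")


def keq_from_delta_g(dg: float, cond: ThermoCondition) -> float:
    """Equilibrium constant exp(-dG/RT) for a reaction with standard free
    energy ``dg`` (kcal/mol) at condition ``cond``.

    Strictly positive and strictly decreasing in ``dg``.
    """
    if not math.isfinite(dg):
        raise ValueError(f"delta-G must be finite, got {dg!r}")
    return math.exp(-dg / cond.rt)


def delta_g_from_keq(keq: float, cond: ThermoCondition) -> float:
    """Standard free energy -RT*ln(Keq) in kcal/mol; exact inverse of
    :func:`keq_from_delta_g`."""
    if not (keq > 0.0) or not math.isfinite(keq):
        raise ValueError(f"Keq must be a finite positive number, got {keq!r}")
    return -cond.rt * math.log(keq)


def delta_g_at_temperature(fit: EnthalpyEntropyFit, cond: ThermoCondition) -> float:
    """Evaluate dG(T) = dH - T*dS (kcal/mol) at the condition's temperature."""
    return fit.dh - cond.kelvin * fit.ds


def entropy_to_cal_per_mol_kelvin(ds_kcal: float) -> float:
    """Convert an entropy from the internal kcal/mol/K to the reporting
    convention cal/mol/K."""
    return ds_kcal * 1000.0


def entropy_from_cal_per_mol_kelvin(ds_cal: float) -> float:
    """Inverse of :func:`entropy_to_cal_per_mol_kelvin`."""
    return ds_cal / 1000.0
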