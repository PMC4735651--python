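"""High-resolution-melt analysis: the comparison branch.

The standard-of-practice alternative to isothermal catalysed exchange is
to melt the XZ and YZ duplexes separately while recording a
duplex-sensitive fluorescence (intercalating dye), fit linear upper and
lower baselines, convert fluorescence to hybridization yield theta(T),
convert yield to a bimolecular association constant, fit van't Hoff lines
(ln K vs 1/T) for each duplex, and read the motif dG off the difference
of the two fits.  Every step of that chain amplifies noise, which is why
the melt-derived motif dG carries an order-of-magnitude larger s.d. than
the native-catalysis estimate on matched data.

Conventions: per-strand totals are equal (c each, M); the duplex is
non-self-complementary, so Keq = theta / (c (1-theta)^2) in M^-1; the
two-state melting temperature is dH / (dS + R ln(c/2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .gel_pipeline import aggregate_estimates
from .thermo_core import (
    R_KCAL,
    DeltaGEstimate,
    EnthalpyEntropyFit,
    ThermoCondition,
    delta_g_at_temperature,
)

__all__ = [
    "MeltCurve",
    "Baseline",
    "fit_baselines",
    "hybridization_yield",
    "keq_from_yield",
    "melting_temperature",
    "vant_hoff_from_curve",
    "motif_dg_from_melt_pair",
    "motif_dg_from_melt_replicates",
    "two_state_tm",
]

YIELD_CLIP = 1e-4
BASELINE_FRACTION = 0.15
THETA_FIT_WINDOW = (0.15, 0.85)


class Baseline(NamedTuple):
    intercept: float
    slope: float

    def __call__(self, temperature_c: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * temperature_c


@dataclass
class MeltCurve:
    """Temperature-fluorescence series for one duplex at equal strand totals."""

    temperatures: np.ndarray  # degrees C
    fluorescence: np.ndarray  # arbitrary units
    strand_total: float  # M, per strand
    label: str = "XZ"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence arrays differ in length")
        if self.temperatures.size < 20:
            raise ValueError(
                f"melt curve needs >= 20 points, got {self.temperatures.size}"
            )
        if not (self.strand_total > 0):
            raise ValueError(f"strand_total must be > 0, got {self.strand_total!r}")


def fit_baselines(
    curve: MeltCurve, fraction: float = BASELINE_FRACTION
) -> tuple[Baseline, Baseline]:
    """Least-squares lines over the coolest and warmest ``fraction`` of the
    temperature range; returns (upper, lower).

    With an intercalating dye the duplex-rich low-temperature plateau is
    the bright one, so the upper baseline comes from the coolest window.
    The baselines must not cross inside the data range.
    """
    t = curve.temperatures
    f = curve.fluorescence
    order = np.argsort(t)
    t, f = t[order], f[order]
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("melt curve has zero temperature span")
    n_win = max(2, int(round(fraction * len(t))))
    if 2 * n_win >= len(t):
        raise ValueError(
            f"baseline windows of {n_win} points overlap on a {len(t)}-point curve"
        )
    lo_slope, lo_int = np.polyfit(t[:n_win], f[:n_win], 1)
    hi_slope, hi_int = np.polyfit(t[-n_win:], f[-n_win:], 1)
    upper = Baseline(lo_int, lo_slope)
    lower = Baseline(hi_int, hi_slope)
    if not np.all(upper(t) > lower(t)):
        raise ValueError("fitted baselines cross inside the data range")
    return upper, lower


def hybridization_yield(
    curve: MeltCurve, baselines: tuple[Baseline, Baseline]
) -> np.ndarray:
    """theta(T) = (F - lower) / (upper - lower), clipped to
    [YIELD_CLIP, 1 - YIELD_CLIP]."""
    upper, lower = baselines
    t = curve.temperatures
    theta = (curve.fluorescence - lower(t)) / (upper(t) - lower(t))
    return np.clip(theta, YIELD_CLIP, 1.0 - YIELD_CLIP)


def keq_from_yield(theta: np.ndarray | float, strand_total: float) -> np.ndarray | float:
    """Bimolecular association constant Keq = theta / (c (1-theta)^2), M^-1,
    for a non-self-complementary duplex at equal per-strand totals c."""
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr <= 0.0) or np.any(theta_arr >= 1.0):
        raise ValueError("hybridization yield must lie strictly inside (0, 1)")
    if not (strand_total > 0):
        raise ValueError(f"strand_total must be > 0, got {strand_total!r}")
    out = theta_arr / (strand_total * (1.0 - theta_arr) ** 2)
    return float(out) if np.isscalar(theta) else out


def melting_temperature(
    temperatures: np.ndarray, theta: np.ndarray
) -> float:
    """Linear-interpolated temperature (degrees C) where theta crosses 0.5."""
    t = np.asarray(temperatures, dtype=float)
    th = np.asarray(theta, dtype=float)
    order = np.argsort(t)
    t, th = t[order], th[order]
    above = th >= 0.5
    crossings = np.nonzero(above[:-1] != above[1:])[0]
    if len(crossings) == 0:
        raise ValueError("yield curve never crosses 0.5; no melting temperature")
    i = crossings[0]
    frac = (0.5 - th[i]) / (th[i + 1] - th[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def two_state_tm(dh: float, ds: float, strand_total: float) -> float:
    """Closed-form two-state melting temperature (degrees C) at equal
    per-strand totals: Tm = dH / (dS + R ln(c/2))."""
    tm_k = dh / (ds + R_KCAL * math.log(strand_total / 2.0))
    return tm_k - 273.15


def vant_hoff_from_curve(
    curve: MeltCurve,
    baselines: tuple[Baseline, Baseline] | None = None,
    theta_window: tuple[float, float] = THETA_FIT_WINDOW,
) -> EnthalpyEntropyFit:
    """Unweighted OLS of ln Keq against 1/T over the transition region.

    Points with yield outside ``theta_window`` are baseline-dominated and
    excluded.  Slope = -dH/R, intercept = dS/R.
    """
    if baselines is None:
        baselines = fit_baselines(curve)
    theta = hybridization_yield(curve, baselines)
    mask = (theta >= theta_window[0]) & (theta <= theta_window[1])
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points fall in the yield window "
            f"{theta_window}; cannot fit van't Hoff line"
        )
    inv_t = 1.0 / (curve.temperatures[mask] + 273.15)
    ln_k = np.log(keq_from_yield(theta[mask], curve.strand_total))
    slope, intercept = np.polyfit(inv_t, ln_k, 1)
    resid = ln_k - (slope * inv_t + intercept)
    return EnthalpyEntropyFit(
        dh=float(-slope * R_KCAL),
        ds=float(intercept * R_KCAL),
        sum_sq_z=float(np.sum(resid**2)),
    )


def motif_dg_from_melt_pair(
    curve_xz: MeltCurve,
    curve_yz: MeltCurve,
    cond: ThermoCondition,
) -> DeltaGEstimate:
    """Motif dG at ``cond`` from one XZ / YZ melt-curve pair.

    dG_motif(T) = (dH_XZ - dH_YZ) - T (dS_XZ - dS_YZ): the difference of
    the two per-duplex van't Hoff fits, i.e. the log-ratio of K_XZ and
    K_YZ extrapolated to the requested temperature.
    """
    fit_xz = vant_hoff_from_curve(curve_xz)
    fit_yz = vant_hoff_from_curve(curve_yz)
    diff = EnthalpyEntropyFit(
        dh=fit_xz.dh - fit_yz.dh,
        ds=fit_xz.ds - fit_yz.ds,
    )
    return DeltaGEstimate(
        value=delta_g_at_temperature(diff, cond),
        sd=0.0,
        n_measurements=1,
        condition=cond,
        label=f"melt:{curve_xz.label}-{curve_yz.label}",
    )


def motif_dg_from_melt_replicates(
    pairs: Sequence[tuple[MeltCurve, MeltCurve]],
    cond: ThermoCondition,
) -> DeltaGEstimate:
    """Aggregate replicate melt-curve pairs into a mean dG with s.d."""
    return aggregate_estimates(
        [motif_dg_from_melt_pair(xz, yz, cond) for xz, yz in pairs]
    )
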