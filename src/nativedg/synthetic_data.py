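"""Seeded generators with known ground truth for every pipeline branch.

Three generators emulate the three kinds of raw data the analysis
consumes:

* :func:`generate_gel_experiment` — a six-lane fluorescent PAGE layout
  (two calibration controls, two 3 h uncatalysed lanes produced by actual
  kinetic integration, two catalysed lanes at the solved equilibrium)
  converted to band intensities through a ssDNA/dsDNA quantum-yield
  factor, a per-lane lognormal loading factor, multiplicative band-
  quantitation noise, and Gaussian stoichiometry error on the true (but
  unreported) initial concentrations;
* :func:`generate_melt_curve` — a two-state bimolecular melt with linear
  upper/lower fluorescence baselines and additive noise;
* :func:`generate_dangle_series` — dangle-length series from the
  saturating length model with replicate Gaussian noise.

Every generator takes a seed, draws all randomness from one
``numpy.random.Generator``, and records its full ground truth in the
output metadata so tests read truth from metadata only.

Default noise magnitudes are a calibration, not a measurement: they are
chosen so that roughly ten replicate lane estimates pool to a mean s.d.
of about 0.05 kcal/mol, the precision scale the catalysed-gel method
achieves in practice.  Temperature error and oligonucleotide synthesis
error are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dangle_model import DangleLengthModel, length_correction
from .equilibrium_network import CONC_1X_MOLAR, SpeciesNetwork, solve_equilibrium
from .gel_pipeline import GelExperiment, GelLane, aggregate_estimates
from .kinetics_sim import RateModel, simulate_timecourse
from .melt_hrm import MeltCurve
from .thermo_core import R_KCAL, DeltaGEstimate, ThermoCondition

__all__ = [
    "NoiseModel",
    "generate_gel_experiment",
    "generate_melt_curve",
    "generate_dangle_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the gel and melt generators.

    ``lane_loading_sd``: sigma of the lognormal per-lane loading factor
    (pipetting); ``band_quant_cv``: multiplicative Gaussian CV per band;
    ``stoichiometry_sd``: relative Gaussian error on each true initial
    concentration; ``melt_fluor_sd``: additive fluorescence noise in units
    of the plateau span.
    """

    lane_loading_sd: float = 0.05
    band_quant_cv: float = 0.02
    stoichiometry_sd: float = 0.03
    melt_fluor_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lane_loading_sd", "band_quant_cv", "stoichiometry_sd", "melt_fluor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, seed)


#: nominal lane compositions of the six-lane layout, in 1x units
_LANE_PLAN = (
    ("lane1", "control_XZ", {"XZ": 1.0}),
    ("lane2", "control_X", {"X": 1.0}),
    ("lane3", "uncatalysed", {"XZ": 1.0, "Y": 1.0}),
    ("lane4", "uncatalysed", {"YZ": 1.0, "X": 1.0}),
    ("lane5", "catalysed", {"XZ": 1.0, "Y": 1.0}),
    ("lane6", "catalysed", {"YZ": 1.0, "X": 1.0}),
)


def generate_gel_experiment(
    truth_dg: float,
    cond: ThermoCondition | None = None,
    noise: NoiseModel | None = None,
    fluor_dg: float | None = None,
    fluorophore: str = "ROX",
    motif_id: str = "motif",
    duplex_dg: float = -30.0,
    cz_dg: float | None = None,
    catalyst_fraction: float = 0.1,
    ssdna_dsdna_yield_ratio: float = 0.8,
    incubation_hours: float = 3.0,
    rates: RateModel | None = None,
) -> GelExperiment:
    """Six-lane gel experiment with reaction dG ``truth_dg`` (kcal/mol).

    The reaction is X + YZ <=> Y + XZ with formation dGs
    dG(YZ) = ``duplex_dg`` and dG(XZ) = ``duplex_dg`` + ``truth_dg``
    (the motif stabilizes XZ).  ``fluor_dg`` optionally records the
    fluorophore component of the truth in the metadata (for subtraction-
    reaction studies); it does not alter the chemistry.  ``cz_dg`` is the
    formation dG of the catalyst-Z intermediate; the default ``None``
    leaves CZ thermodynamically negligible, matching the assumption the
    analysis makes.  Uncatalysed lanes are produced by integrating the
    mass-action kinetics for ``incubation_hours``; catalysed lanes by the
    equilibrium solve.  Band intensities are normalized so the noiseless
    control ssDNA band reads 100 units.
    """
    cond = cond or ThermoCondition(25.0, "TE 12.5 mM Mg2+")
    noise = noise or NoiseModel()
    rates = rates or RateModel()
    rng = np.random.default_rng(noise.seed)

    dg_xz = duplex_dg + truth_dg
    complex_dg = {"XZ": dg_xz, "YZ": duplex_dg}
    if cz_dg is not None:
        complex_dg["CZ"] = cz_dg

    # Fluorescence scale: noiseless ssDNA control band = 100 units.
    global_scale = 100.0 / ssdna_dsdna_yield_ratio
    yields = {"X": ssdna_dsdna_yield_ratio, "XZ": 1.0}

    lanes: list[GelLane] = []
    for lane_id, role, nominal in _LANE_PLAN:
        nominal = dict(nominal)
        if role == "catalysed" and catalyst_fraction > 0:
            nominal["C"] = catalyst_fraction
        true_init = {
            sp: c0 * (1.0 + noise.stoichiometry_sd * rng.standard_normal())
            for sp, c0 in nominal.items()
        }
        true_conc = _lane_true_concentrations(
            role, true_init, complex_dg, cond, rates, incubation_hours
        )
        load = math.exp(noise.lane_loading_sd * rng.standard_normal())
        bands = {}
        for sp in ("X", "XZ"):
            intensity = true_conc.get(sp, 0.0) * yields[sp] * load * global_scale
            intensity *= 1.0 + noise.band_quant_cv * rng.standard_normal()
            bands[sp] = max(intensity, 0.0)
        # analysis sees nominal initials only; catalyst listed for the record
        lanes.append(GelLane(lane_id, role, nominal, bands))

    metadata = {
        "truth_dg": repr(truth_dg),
        "fluor_dg": repr(truth_dg if fluor_dg is None else fluor_dg),
        "duplex_dg": repr(duplex_dg),
        "cz_dg": repr(cz_dg),
        "catalyst_fraction": repr(catalyst_fraction),
        "yield_ratio_true": repr(ssdna_dsdna_yield_ratio),
        "incubation_hours": repr(incubation_hours),
        "seed": repr(noise.seed),
        "noise": (
            f"lane_loading_sd={noise.lane_loading_sd!r},"
            f"band_quant_cv={noise.band_quant_cv!r},"
            f"stoichiometry_sd={noise.stoichiometry_sd!r}"
        ),
    }
    return GelExperiment(
        lanes=lanes,
        condition=cond,
        fluorophore=fluorophore,
        motif_id=motif_id,
        ssdna_dsdna_yield_ratio=ssdna_dsdna_yield_ratio,
        metadata=metadata,
    )


def _lane_true_concentrations(
    role: str,
    initials_x: dict[str, float],
    complex_dg: dict[str, float],
    cond: ThermoCondition,
    rates: RateModel,
    incubation_hours: float,
) -> dict[str, float]:
    """True equilibrium (or 3 h kinetic) concentrations of a lane, 1x units."""
    if role.startswith("control"):
        return dict(initials_x)
    totals = {"X": 0.0, "Y": 0.0, "Z": 0.0, "C": 0.0}
    for sp, c0 in initials_x.items():
        for s in set(sp):
            totals[s] += c0 * sp.count(s)
    totals_m = {s: t * CONC_1X_MOLAR for s, t in totals.items()}
    net = SpeciesNetwork(totals=totals_m, complex_dg=dict(complex_dg), condition=cond)
    if role == "catalysed":
        state = solve_equilibrium(net)
        return {sp: state[sp] / CONC_1X_MOLAR for sp in ("X", "XZ")}
    # uncatalysed: integrate the mass-action kinetics for the incubation
    init_m = {sp: c0 * CONC_1X_MOLAR for sp, c0 in initials_x.items()}
    t_grid = np.array([0.0, incubation_hours * 3600.0])
    traj = simulate_timecourse(net, rates, init_m, t_grid)
    final = traj.iloc[-1]
    return {sp: float(final[sp]) / CONC_1X_MOLAR for sp in ("X", "XZ")}


def generate_melt_curve(
    dh: float,
    ds: float,
    strand_total: float = CONC_1X_MOLAR,
    t_grid: np.ndarray | None = None,
    baselines: tuple[tuple[float, float], tuple[float, float]] = ((120.0, -0.2), (10.0, 0.05)),
    noise: NoiseModel | None = None,
    label: str = "XZ",
) -> MeltCurve:
    """Two-state melt curve for a duplex with formation dH/dS (kcal units).

    theta(T) solves the bimolecular equal-totals quadratic
    Keq(T) c (1-theta)^2 = theta with Keq = exp(-(dH - T dS)/RT);
    fluorescence = lower(T) + theta * (upper(T) - lower(T)) + noise.
    ``baselines`` are ((upper intercept, slope), (lower intercept, slope))
    in signal units per degree C.  Default temperature grid follows the
    ramp convention 95 down to 30 degrees C in 1 degree steps.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed + 1)
    if t_grid is None:
        t_grid = np.arange(95.0, 29.0, -1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    t_k = t_grid + 273.15
    keq = np.exp(-(dh - t_k * ds) / (R_KCAL * t_k))
    kc = keq * strand_total
    theta = (2.0 * kc + 1.0 - np.sqrt((2.0 * kc + 1.0) ** 2 - 4.0 * kc**2)) / (2.0 * kc)
    (u_int, u_slope), (l_int, l_slope) = baselines
    upper = u_int + u_slope * t_grid
    lower = l_int + l_slope * t_grid
    span = np.mean(upper - lower)
    fluor = lower + theta * (upper - lower)
    fluor = fluor + noise.melt_fluor_sd * span * rng.standard_normal(len(t_grid))
    return MeltCurve(
        temperatures=t_grid,
        fluorescence=fluor,
        strand_total=strand_total,
        label=label,
    )


def generate_dangle_series(
    asymptote: float = 0.56,
    length_scale: float = 2.0,
    base_dg: float = -0.3,
    lengths: tuple[int, ...] = tuple(range(1, 22)),
    per_point_sd: float = 0.07,
    n_rep: int = 4,
    seed: int = 0,
) -> list[tuple[int, DeltaGEstimate]]:
    """Dangle-length series (L, aggregated dG estimate) from the saturating
    length model.

    Each length receives ``n_rep`` independent measurements with Gaussian
    noise of ``per_point_sd`` (the single-measurement s.d.), which are
    pooled per length; with the defaults (four repeats, matching typical
    per-dangle replication) the aggregated points carry sd
    per_point_sd / 2.
    """
    if any(l < 1 or l > 21 for l in lengths):
        raise ValueError("dangle lengths must lie in [1, 21]")
    model = DangleLengthModel(asymptote=asymptote, length_scale=length_scale)
    rng = np.random.default_rng(seed)
    cond = ThermoCondition(25.0, "PBS")
    out = []
    for length in lengths:
        truth = base_dg + length_correction(int(length), model)
        draws = truth + per_point_sd * rng.standard_normal(n_rep)
        reps = [
            DeltaGEstimate(float(v), 0.0, 1, cond, label=f"L{length}") for v in draws
        ]
        # Quote the known aggregation sd rather than the n_rep-sample sd:
        # weights stay deterministic and honest for the downstream fit.
        agg = replace(aggregate_estimates(reps), sd=per_point_sd / math.sqrt(n_rep))
        out.append((int(length), agg))
    return out
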