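"""From band-intensity tables to per-lane dG estimates.

A fluorescent PAGE experiment for one motif is six lanes: two calibration
controls (pure XZ, pure X at known concentration), two uncatalysed
reaction lanes (the 3 h kinetic dead-end that motivates catalysis) and two
catalysed lanes run from the two opposite starting compositions.  Only the
fluorophore-bearing species X and XZ are visible as bands.

The analysis chain per catalysed lane:

1. calibrate the ssDNA/dsDNA quantum-yield ratio from the control lanes;
2. rescale the lane so the labelled strand is conserved,
   [X] + [XZ] = [X]0 + [XZ]0, absorbing the per-lane loading
   (pipetting) error — after this step the [X]-derived and [XZ]-derived
   inferences coincide, which is how the two redundant observables are
   reconciled;
3. reconstruct [Y] and [YZ] from strand conservation;
4. dG = -RT ln ([Y][XZ] / [X][YZ]).

Replicate lanes/gels are pooled by a plain mean with the s.d. of the mean
under a Gaussian error model.

Band-table CSV schema (one row per lane x species)::

    lane_id,role,species,initial_conc_x,band_intensity

with ``role`` in {control_XZ, control_X, uncatalysed, catalysed},
concentrations in 1x units (1x = 300 nM) and ``band_intensity`` empty for
species without a fluorophore.  Experiment-level metadata travel in
``# key=value`` comment lines.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .thermo_core import DeltaGEstimate, ThermoCondition, delta_g_from_keq

__all__ = [
    "LANE_ROLES",
    "GelLane",
    "GelExperiment",
    "read_band_table",
    "write_band_table",
    "normalize_lane",
    "infer_concentrations",
    "lane_delta_g",
    "aggregate_estimates",
    "experiment_delta_gs",
]

LANE_ROLES = ("control_XZ", "control_X", "uncatalysed", "catalysed")

#: Observed concentrations may overshoot a mass-balance bound by this
#: fraction of the labelled total (band-quantitation noise) and are
#: clipped; larger violations are errors.
FEASIBILITY_TOL = 0.02

_BANDED = ("X", "XZ")  # only fluorophore-bearing species are visible


@dataclass
class GelLane:
    """One lane: nominal initial mix (1x units) and raw band intensities."""

    lane_id: str
    role: str
    initials: dict[str, float]
    bands: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in LANE_ROLES:
            raise ValueError(
                f"lane {self.lane_id}: unknown role {self.role!r}; "
                f"expected one of {LANE_ROLES}"
            )
        for sp, v in self.bands.items():
            if sp not in _BANDED:
                raise ValueError(
                    f"lane {self.lane_id}: species {sp!r} carries no fluorophore "
                    f"and cannot have a band"
                )
            if not (v >= 0.0):
                raise ValueError(
                    f"lane {self.lane_id}: negative band intensity {v!r} for {sp}"
                )
        for sp, v in self.initials.items():
            if not (v >= 0.0):
                raise ValueError(
                    f"lane {self.lane_id}: negative initial concentration {v!r} for {sp}"
                )


@dataclass
class GelExperiment:
    """A six-lane (or larger) experiment for one motif/fluorophore/condition."""

    lanes: list[GelLane]
    condition: ThermoCondition
    fluorophore: str = "ROX"
    motif_id: str = ""
    ssdna_dsdna_yield_ratio: float = 1.0
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ssdna_dsdna_yield_ratio > 0.0):
            raise ValueError(
                f"ssdna_dsdna_yield_ratio must be > 0, got {self.ssdna_dsdna_yield_ratio!r}"
            )
        roles = {lane.role for lane in self.lanes}
        if self.lanes and not {"control_XZ", "control_X"} <= roles:
            raise ValueError(
                "experiment must contain both calibration lanes "
                "(roles control_XZ and control_X); found roles "
                + ", ".join(sorted(roles))
            )

    def lanes_with_role(self, role: str) -> list[GelLane]:
        return [lane for lane in self.lanes if lane.role == role]

    def calibrate_yield_ratio(self) -> float:
        """Per-state quantum-yield factor y_ss / y_ds estimated from the
        control lanes as (I_X/[X]0) / (I_XZ/[XZ]0)."""
        ctrl_x = self.lanes_with_role("control_X")[0]
        ctrl_xz = self.lanes_with_role("control_XZ")[0]
        y_ss = ctrl_x.bands["X"] / ctrl_x.initials["X"]
        y_ds = ctrl_xz.bands["XZ"] / ctrl_xz.initials["XZ"]
        if y_ss <= 0 or y_ds <= 0:
            raise ValueError("control lanes have zero band intensity")
        return y_ss / y_ds


def write_band_table(exp: GelExperiment, path: str | Path) -> None:
    """Write an experiment as the band-table CSV (with metadata comments)."""
    lines = [
        f"# temperature_C={exp.condition.temperature_celsius!r}",
        f"# buffer={exp.condition.buffer_label}",
        f"# fluorophore={exp.fluorophore}",
        f"# motif_id={exp.motif_id}",
        f"# ssdna_dsdna_yield_ratio={exp.ssdna_dsdna_yield_ratio!r}",
    ]
    for k, v in exp.metadata.items():
        lines.append(f"# meta:{k}={v}")
    rows = []
    for lane in exp.lanes:
        species = sorted(set(lane.initials) | set(lane.bands))
        for sp in species:
            rows.append(
                {
                    "lane_id": lane.lane_id,
                    "role": lane.role,
                    "species": sp,
                    "initial_conc_x": lane.initials.get(sp, 0.0),
                    "band_intensity": lane.bands.get(sp, np.nan),
                }
            )
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_band_table(path: str | Path) -> GelExperiment:
    """Read a band-table CSV back into a :class:`GelExperiment`.

    Malformed rows are reported with their line numbers; missing control
    lanes, duplicate lane x species rows and negative intensities are
    rejected.
    """
    path = Path(path)
    header: dict[str, str] = {}
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition("=")
            if k.startswith("meta:"):
                meta[k[5:]] = v
            else:
                header[k] = v
    df = pd.read_csv(path, comment="#")
    expected = {"lane_id", "role", "species", "initial_conc_x", "band_intensity"}
    if set(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, got {sorted(df.columns)}"
        )
    dup = df.duplicated(subset=["lane_id", "species"])
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup])
        raise ValueError(f"{path}: duplicate lane x species rows at lines {rows}")
    neg = df["band_intensity"] < 0
    if neg.any():
        rows = ", ".join(str(i + 2) for i in df.index[neg])
        raise ValueError(f"{path}: negative band intensity at lines {rows}")

    lanes: list[GelLane] = []
    for lane_id, group in df.groupby("lane_id", sort=False):
        roles = group["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"{path}: lane {lane_id} has conflicting roles {roles}")
        initials, bands = {}, {}
        for _, row in group.iterrows():
            initials[row["species"]] = float(row["initial_conc_x"])
            if not pd.isna(row["band_intensity"]):
                bands[row["species"]] = float(row["band_intensity"])
        lanes.append(GelLane(str(lane_id), roles[0], initials, bands))

    cond = ThermoCondition(
        float(header.get("temperature_C", 25.0)), header.get("buffer", "")
    )
    return GelExperiment(
        lanes=lanes,
        condition=cond,
        fluorophore=header.get("fluorophore", "ROX"),
        motif_id=header.get("motif_id", ""),
        ssdna_dsdna_yield_ratio=float(header.get("ssdna_dsdna_yield_ratio", 1.0)),
        metadata=meta,
    )


def normalize_lane(lane: GelLane, exp: GelExperiment) -> dict[str, float]:
    """Convert a lane's raw band intensities to concentrations (1x units).

    Divides by the per-state quantum yields calibrated from the controls,
    then rescales so the labelled strand is conserved
    ([X] + [XZ] = [X]0 + [XZ]0).  The rescale makes the result invariant
    to any common per-lane loading factor.
    """
    ratio = exp.calibrate_yield_ratio()
    raw_x = lane.bands.get("X", 0.0) / ratio
    raw_xz = lane.bands.get("XZ", 0.0)
    total_raw = raw_x + raw_xz
    if total_raw <= 0.0:
        raise ValueError(f"lane {lane.lane_id}: zero total labelled intensity")
    labelled_total = lane.initials.get("X", 0.0) + lane.initials.get("XZ", 0.0)
    if labelled_total <= 0.0:
        raise ValueError(f"lane {lane.lane_id}: no labelled material in initials")
    scale = labelled_total / total_raw
    return {"X": raw_x * scale, "XZ": raw_xz * scale}


def _feasible_interval(initials: Mapping[str, float]) -> tuple[float, float]:
    x0 = initials.get("X", 0.0)
    y0 = initials.get("Y", 0.0)
    xz0 = initials.get("XZ", 0.0)
    yz0 = initials.get("YZ", 0.0)
    lo = max(0.0, xz0 - y0)
    hi = min(x0 + xz0, xz0 + yz0)
    return lo, hi


def infer_concentrations(
    observed: Mapping[str, float], initials: Mapping[str, float]
) -> dict[str, float]:
    """Reconstruct all four equilibrium concentrations from one observed
    species via the three strand conservation laws.

    ``observed`` is ``{"X": value}`` or ``{"XZ": value}`` (1x units).
    Values that overshoot the feasible interval by at most 2% of the
    labelled total are clipped (band-quantitation noise); larger
    violations raise with the interval in the message.
    """
    if len(observed) != 1 or next(iter(observed)) not in _BANDED:
        raise ValueError("observed must be exactly one of {'X': v} or {'XZ': v}")
    (species, value), = observed.items()
    x0 = initials.get("X", 0.0)
    xz0 = initials.get("XZ", 0.0)
    labelled_total = x0 + xz0
    if labelled_total <= 0.0:
        raise ValueError("initials contain no labelled strand (X + XZ = 0)")
    xz = value if species == "XZ" else labelled_total - value
    lo, hi = _feasible_interval(initials)
    tol = FEASIBILITY_TOL * labelled_total
    if xz < lo - tol or xz > hi + tol:
        raise ValueError(
            f"observed [{species}] = {value:.6g} implies [XZ] = {xz:.6g} outside "
            f"the feasible interval [{lo:.6g}, {hi:.6g}] (tolerance {tol:.2g})"
        )
    xz = min(max(xz, lo), hi)
    yz0 = initials.get("YZ", 0.0)
    y0 = initials.get("Y", 0.0)
    return {
        "X": labelled_total - xz,
        "XZ": xz,
        "YZ": xz0 + yz0 - xz,
        "Y": y0 + yz0 - (xz0 + yz0 - xz),
    }


def lane_delta_g(lane: GelLane, exp: GelExperiment) -> DeltaGEstimate:
    """One dG estimate from one catalysed lane.

    The conservation-enforcing normalization makes the [X]- and
    [XZ]-derived inferences identical, so a single value is emitted with
    ``n_measurements = 1`` (and sd 0, to be filled by aggregation).
    """
    if lane.role != "catalysed":
        raise ValueError(
            f"lane {lane.lane_id} has role {lane.role!r}; dG is only inferred "
            f"from catalysed (equilibrated) lanes"
        )
    norm = normalize_lane(lane, exp)
    conc = infer_concentrations({"XZ": norm["XZ"]}, lane.initials)
    floor = 1e-12 * (lane.initials.get("X", 0.0) + lane.initials.get("XZ", 0.0))
    if min(conc.values()) <= floor:
        raise ValueError(
            f"lane {lane.lane_id}: conversion is complete within quantitation "
            f"noise ({conc}); Keq is unbounded and no dG can be reported"
        )
    keq = (conc["Y"] * conc["XZ"]) / (conc["X"] * conc["YZ"])
    return DeltaGEstimate(
        value=delta_g_from_keq(keq, exp.condition),
        sd=0.0,
        n_measurements=1,
        condition=exp.condition,
        label=f"{exp.motif_id}:{exp.fluorophore}:{lane.lane_id}",
    )


def aggregate_estimates(estimates: Sequence[DeltaGEstimate]) -> DeltaGEstimate:
    """Pool replicate estimates: mean, s.d. of the mean, summed counts.

    All inputs must share a condition.  With a single input the sd is 0
    (no spread information).
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    cond = estimates[0].condition
    for e in estimates[1:]:
        if not cond.same_as(e.condition):
            raise ValueError(
                f"cannot aggregate across conditions: {cond} vs {e.condition}"
            )
    values = np.array([e.value for e in estimates])
    n = len(values)
    mean = float(values.mean())
    sd_mean = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return DeltaGEstimate(
        value=mean,
        sd=sd_mean,
        n_measurements=sum(e.n_measurements for e in estimates),
        condition=cond,
        label=estimates[0].label.rsplit(":", 1)[0],
    )


def experiment_delta_gs(exp: GelExperiment) -> list[DeltaGEstimate]:
    """Per-lane dG estimates from every catalysed lane of an experiment."""
    return [lane_delta_g(lane, exp) for lane in exp.lanes_with_role("catalysed")]
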