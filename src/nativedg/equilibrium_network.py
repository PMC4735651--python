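"""Coupled mass-action equilibrium for the catalysed strand-exchange network.

The network is the exchange reaction

    X + YZ  <=>  Y + XZ

optionally in the presence of a non-covalent catalyst strand C that can
bind the common strand Z (complex CZ, and optionally the three-strand
intermediates CXZ / CYZ).  Complexes are named by concatenating the
single-letter strand ids they contain, e.g. ``"XZ"`` or ``"CXZ"``; the
composition multiset is read directly off the name.

The unique dilute-solution equilibrium is the minimum of the ideal Gibbs
free energy over mass-balanced compositions, which is strictly convex.
We locate it with a damped Newton iteration on the logarithms of the free
strand concentrations: complex concentrations follow from detailed balance
([S1...Sk] = K * prod [Si] with K = exp(-dG_formation/RT)), so the only
equations left are the per-strand mass balances.

Also provided here is the bias analysis for the approximation the gel
pipeline makes: inferring dG while *ignoring* the CZ intermediate
systematically overestimates the reaction dG, and ``bias_scan`` quantifies
that overestimate across motif stabilities and catalyst-complex
stabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .thermo_core import ThermoCondition, delta_g_from_keq

__all__ = [
    "CONC_1X_MOLAR",
    "SpeciesNetwork",
    "EquilibriumState",
    "solve_equilibrium",
    "two_strand_binding_closed_form",
    "apparent_delta_g",
    "bias_scan",
]

#: The reference "1x" lane concentration, 300 nM.
CONC_1X_MOLAR = 300e-9

_GRAD_TOL = 1e-12
_MAX_ITER = 200


@dataclass
class SpeciesNetwork:
    """Strands, complexes with formation free energies, and strand totals.

    Parameters
    ----------
    totals
        Map strand id (``"X"``, ``"Y"``, ``"Z"``, ``"C"``) -> total strand
        concentration in M (free plus bound, counted with multiplicity).
    complex_dg
        Map complex name -> standard free energy of formation from free
        strands, kcal/mol.  Every complex must contain Z.
    condition
        Temperature/buffer context fixing RT.
    """

    totals: dict[str, float]
    complex_dg: dict[str, float]
    condition: ThermoCondition = field(default_factory=lambda: ThermoCondition(25.0))

    def __post_init__(self) -> None:
        for s, t in self.totals.items():
            if len(s) != 1:
                raise ValueError(f"strand ids are single letters, got {s!r}")
            if not (t >= 0.0) or not math.isfinite(t):
                raise ValueError(f"total of strand {s} must be finite and >= 0, got {t!r}")
        for name, dg in self.complex_dg.items():
            if not math.isfinite(dg):
                raise ValueError(f"formation dG of {name} must be finite, got {dg!r}")
            if len(name) < 2:
                raise ValueError(f"complex {name!r} must contain at least two strands")
            for s in name:
                if s not in self.totals:
                    raise ValueError(
                        f"complex {name!r} uses undeclared strand {s!r}"
                    )
            if "Z" not in name:
                raise ValueError(f"complex {name!r} does not contain the common strand Z")

    @property
    def strand_ids(self) -> list[str]:
        return sorted(self.totals)

    def reaction_delta_g(self) -> float:
        """Standard free energy of the net exchange X + YZ <=> Y + XZ."""
        return self.complex_dg["XZ"] - self.complex_dg["YZ"]


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (M) of every free strand and complex."""

    concentrations: dict[str, float]

    def __getitem__(self, species: str) -> float:
        return self.concentrations[species]

    def reaction_quotient(self) -> float:
        """([Y][XZ]) / ([X][YZ]) at the solved state."""
        c = self.concentrations
        return (c["Y"] * c["XZ"]) / (c["X"] * c["YZ"])


def _stoichiometry(net: SpeciesNetwork) -> tuple[list[str], list[str], np.ndarray]:
    """Active strands (total > 0), their complexes, and the count matrix
    (complex x strand)."""
    active = [s for s in net.strand_ids if net.totals[s] > 0.0]
    cnames = [c for c in net.complex_dg if all(s in active for s in c)]
    counts = np.zeros((len(cnames), len(active)))
    for i, cname in enumerate(cnames):
        for j, s in enumerate(active):
            counts[i, j] = cname.count(s)
    return active, cnames, counts


def solve_equilibrium(net: SpeciesNetwork) -> EquilibriumState:
    """Solve the coupled equilibria of ``net`` by damped Newton iteration
    on log free-strand concentrations.

    Returns an :class:`EquilibriumState` whose per-strand mass balances
    hold to better than 1e-9 relative and whose mass-action quotients
    match their equilibrium constants by construction.

    Raises
    ------
    RuntimeError
        If the Newton iteration has not reached a mass-balance residual
        below 1e-12 (log scale) within 200 iterations.
    """
    for need in ("X", "Y", "Z"):
        if need not in net.totals:
            raise ValueError(f"network must declare strand {need}")
    for need in ("XZ", "YZ"):
        if need not in net.complex_dg:
            raise ValueError(f"network must declare complex {need}")

    active, cnames, counts = _stoichiometry(net)
    totals = np.array([net.totals[s] for s in active])
    rt = net.condition.rt
    log_k = np.array([-net.complex_dg[c] / rt for c in cnames])

    def complex_log_conc(u: np.ndarray) -> np.ndarray:
        return log_k + counts @ u

    def computed_totals(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # overshooting trial steps may overflow exp(); the backtracking
        # line search rejects them via the inf residual norm
        with np.errstate(over="ignore"):
            cc = np.exp(complex_log_conc(u))
            return np.exp(u) + counts.T @ cc, cc

    def residual(u: np.ndarray) -> np.ndarray:
        tot, _ = computed_totals(u)
        with np.errstate(over="ignore"):
            return np.log(tot / totals)

    # Start fully dissociated; always feasible (computed totals >= free).
    u = np.log(totals)
    r = residual(u)
    # Far from the solution the complex terms dominate the free terms by
    # more than machine precision and the Newton matrix is numerically
    # rank-deficient, so precondition with a damped log-space fixed point
    # (free *= (totals/computed)^(1/2)) until the residual is O(1).
    for _ in range(500):
        if np.max(np.abs(r)) <= 0.5:
            break
        u = u - 0.5 * r
        r = residual(u)
    converged = False
    for _ in range(_MAX_ITER):
        if np.max(np.abs(r)) < _GRAD_TOL:
            converged = True
            break
        tot, cc = computed_totals(u)
        free = np.exp(u)
        # J_ij = d log(tot_i) / d u_j
        jac = (np.diag(free) + counts.T @ (cc[:, None] * counts)) / tot[:, None]
        step = np.linalg.solve(jac, r)
        # Damped update: backtrack until the residual norm decreases.
        norm0 = np.linalg.norm(r)
        lam = 1.0
        for _ in range(60):
            u_new = u - lam * step
            r_new = residual(u_new)
            if np.linalg.norm(r_new) < norm0:
                break
            lam *= 0.5
        u, r = u_new, r_new
    if not converged and not np.max(np.abs(r)) < _GRAD_TOL:
        raise RuntimeError(
            f"equilibrium solve did not converge: log mass-balance residual "
            f"{np.max(np.abs(r)):.3e} after {_MAX_ITER} iterations "
            f"(tolerance {_GRAD_TOL:.0e})"
        )

    conc: dict[str, float] = {s: 0.0 for s in net.strand_ids}
    conc.update({c: 0.0 for c in net.complex_dg})
    for s, v in zip(active, np.exp(u)):
        conc[s] = float(v)
    for c, v in zip(cnames, np.exp(complex_log_conc(u))):
        conc[c] = float(v)
    return EquilibriumState(conc)


def two_strand_binding_closed_form(
    total_a: float, total_b: float, dg: float, cond: ThermoCondition
) -> float:
    """Closed-form duplex concentration for A + B <=> AB (quadratic root).

    Used as an independent check of :func:`solve_equilibrium` in the
    single-complex limit.
    """
    k = math.exp(-dg / cond.rt)
    s = total_a + total_b + 1.0 / k
    return 0.5 * (s - math.sqrt(s * s - 4.0 * total_a * total_b))


def _cz_ignoring_apparent_keq(
    observed_xz: float, initials: Mapping[str, float]
) -> float:
    """Apply the catalyst-blind mass-balance algebra to an observed [XZ].

    This is exactly what the gel pipeline does: given nominal initial
    concentrations of X, Y, XZ, YZ (catalyst invisible) and the observed
    equilibrium [XZ], reconstruct the other three species from the three
    strand conservation laws and form the reaction quotient.
    """
    x0 = initials.get("X", 0.0)
    y0 = initials.get("Y", 0.0)
    xz0 = initials.get("XZ", 0.0)
    yz0 = initials.get("YZ", 0.0)
    x = x0 + xz0 - observed_xz
    yz = xz0 + yz0 - observed_xz
    y = y0 + yz0 - yz
    if min(x, y, yz, observed_xz) <= 0.0:
        raise ValueError(
            "CZ-ignoring inference produced a non-positive concentration; "
            "lane initials are inconsistent with the observed [XZ]"
        )
    return (y * observed_xz) / (x * yz)


def apparent_delta_g(
    net: SpeciesNetwork, lane_initials: Mapping[str, float]
) -> float:
    """The dG an experimenter would infer from the true equilibrium of
    ``net`` while ignoring catalyst-bound intermediates.

    ``lane_initials`` maps species (free strands and complexes, M) to the
    concentrations mixed into the lane; its implied strand totals must
    match ``net.totals``.  The apparent dG is always >= the true reaction
    dG because bound catalyst inflates the inferred [YZ] and deflates the
    inferred [Y].
    """
    implied: dict[str, float] = {s: 0.0 for s in net.totals}
    for sp, c0 in lane_initials.items():
        for s in set(sp):
            if s not in implied:
                raise ValueError(f"lane species {sp!r} uses undeclared strand {s!r}")
            implied[s] += c0 * sp.count(s)
    for s, t in net.totals.items():
        if not math.isclose(implied.get(s, 0.0), t, rel_tol=1e-9, abs_tol=1e-30):
            raise ValueError(
                f"lane initials imply total [{s}] = {implied.get(s, 0.0):.6e} M "
                f"but the network declares {t:.6e} M"
            )
    state = solve_equilibrium(net)
    keq_app = _cz_ignoring_apparent_keq(state["XZ"], lane_initials)
    return delta_g_from_keq(keq_app, net.condition)


def bias_scan(
    motif_dgs: Iterable[float],
    cz_offsets: Iterable[float],
    catalyst_fraction: float = 0.1,
    duplex_dg: float = -30.0,
    cond: ThermoCondition | None = None,
    conc_1x: float = CONC_1X_MOLAR,
) -> pd.DataFrame:
    """Scan the CZ-ignoring overestimate across motif dG and CZ stability.

    For each true motif dG (the reaction dG, applied to XZ on top of the
    common duplex depth ``duplex_dg``) and each CZ offset (kcal/mol by
    which CZ is *less* stable than the more stable product duplex), the
    standard lane ([XZ]0 = 1x, [Y]0 = 1x, catalyst ``catalyst_fraction``)
    is solved with CZ included and analysed with CZ ignored.

    Returns a DataFrame with columns ``motif_dg``, ``cz_offset``,
    ``cz_dg``, ``apparent_dg``, ``bias`` (apparent - true, kcal/mol).
    The maximum row is ``df.loc[df.bias.idxmax()]``.
    """
    if cond is None:
        cond = ThermoCondition(25.0)
    motif_dgs = list(motif_dgs)
    cz_offsets = list(cz_offsets)
    if not motif_dgs or not cz_offsets:
        raise ValueError("bias_scan requires non-empty motif and offset grids")
    rows = []
    for mdg in motif_dgs:
        dg_xz = duplex_dg + mdg
        dg_yz = duplex_dg
        for off in cz_offsets:
            # CZ is `off` kcal/mol less stable than either product duplex,
            # i.e. offset from the *less* stable of the two.
            cz_dg = max(dg_xz, dg_yz) + off
            totals = {
                "X": conc_1x,
                "Y": conc_1x,
                "Z": conc_1x,
                "C": catalyst_fraction * conc_1x,
            }
            complex_dg = {"XZ": dg_xz, "YZ": dg_yz}
            if catalyst_fraction > 0.0:
                complex_dg["CZ"] = cz_dg
            net = SpeciesNetwork(totals=totals, complex_dg=complex_dg, condition=cond)
            lane = {"XZ": conc_1x, "Y": conc_1x}
            if catalyst_fraction > 0.0:
                lane["C"] = catalyst_fraction * conc_1x
            app = apparent_delta_g(net, lane)
            rows.append(
                {
                    "motif_dg": mdg,
                    "cz_offset": off,
                    "cz_dg": cz_dg,
                    "apparent_dg": app,
                    "bias": app - mdg,
                }
            )
    return pd.DataFrame(rows)
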