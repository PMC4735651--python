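"""Statistical layer: subtraction reactions, consensus scoring, Gaussian
failure expectations and the z-score-weighted van't Hoff fit.

Dangle motifs are measured indirectly: reaction 2 queries fluorophore +
dangle together, reaction 1 queries the fluorophore alone, and the dangle
dG is their difference, with variances adding.  Each dangle is measured
twice — once with a ROX-labelled strand set, once with Alexa532 — and the
two estimates are combined into the inverse-variance (maximum-likelihood)
consensus.  The Consensus Score

    CS = 10 - sum_i z_i^2,    z_i = (mu_i - consensus) / sigma_i

summarises their agreement out of a maximum of 10: CS >= 8 means the
consensus lies within 1 s.d. of both inputs, CS >= 0 within 2.24 s.d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .thermo_core import DeltaGEstimate, EnthalpyEntropyFit, ThermoCondition

__all__ = [
    "ConsensusResult",
    "subtract_fluorophore",
    "consensus_and_cs",
    "consensus_of",
    "expected_cs_failures",
    "simulate_cs_failure_rate",
    "precision_experiment_multiplier",
    "vant_hoff_fit",
]


@dataclass(frozen=True)
class ConsensusResult:
    """Inverse-variance consensus of two estimates plus the Consensus Score."""

    consensus: DeltaGEstimate
    cs: float
    z_rox: float
    z_alexa: float

    def __post_init__(self) -> None:
        if self.cs > 10.0 + 1e-9:
            raise ValueError(f"CS cannot exceed 10, got {self.cs!r}")


def subtract_fluorophore(
    rxn2: DeltaGEstimate, rxn1: DeltaGEstimate
) -> DeltaGEstimate:
    """Dangle dG as reaction2 minus reaction1, with additive variances.

    Both reactions must share a condition (same temperature and buffer);
    the common catalyst-intermediate bias cancels in the difference.
    """
    if not rxn2.condition.same_as(rxn1.condition):
        raise ValueError(
            f"condition mismatch: {rxn2.condition} vs {rxn1.condition}"
        )
    return DeltaGEstimate(
        value=rxn2.value - rxn1.value,
        sd=math.hypot(rxn1.sd, rxn2.sd),
        n_measurements=rxn1.n_measurements + rxn2.n_measurements,
        condition=rxn2.condition,
        label=f"{rxn2.label}-{rxn1.label}",
    )


def consensus_of(estimates: Sequence[DeltaGEstimate]) -> tuple[DeltaGEstimate, float]:
    """Inverse-variance weighted consensus of k >= 2 estimates and its
    sum of squared z scores.

    The weighted mean is the minimizer of sum_i ((c - mu_i)/sigma_i)^2;
    its sd is (sum 1/sigma_i^2)^(-1/2).
    """
    if len(estimates) < 2:
        raise ValueError("consensus requires at least two estimates")
    cond = estimates[0].condition
    for e in estimates:
        if not (e.sd > 0.0):
            raise ValueError(
                f"estimate {e.label!r} has sd {e.sd}; z scores are undefined "
                f"for zero uncertainty"
            )
        if not cond.same_as(e.condition):
            raise ValueError("cannot form a consensus across conditions")
    w = np.array([1.0 / e.sd**2 for e in estimates])
    mu = np.array([e.value for e in estimates])
    c = float(np.sum(w * mu) / np.sum(w))
    sd = float(1.0 / math.sqrt(np.sum(w)))
    ssz = float(np.sum(w * (mu - c) ** 2))
    consensus = DeltaGEstimate(
        value=c,
        sd=sd,
        n_measurements=sum(e.n_measurements for e in estimates),
        condition=cond,
        label="+".join(e.label for e in estimates if e.label) or "consensus",
    )
    return consensus, ssz


def consensus_and_cs(
    e_rox: DeltaGEstimate, e_alexa: DeltaGEstimate
) -> ConsensusResult:
    """Consensus of the ROX- and Alexa532-based estimates with CS.

    For two inputs, CS = 10 - (mu1-mu2)^2/(sigma1^2+sigma2^2) (the sum of
    squared z scores collapses to the normalized squared difference).
    """
    consensus, ssz = consensus_of([e_rox, e_alexa])
    return ConsensusResult(
        consensus=consensus,
        cs=10.0 - ssz,
        z_rox=(e_rox.value - consensus.value) / e_rox.sd,
        z_alexa=(e_alexa.value - consensus.value) / e_alexa.sd,
    )


def expected_cs_failures(n_params: int, cs_threshold: float = 0.0) -> float:
    """Expected number of parameters at or below a CS threshold under the
    Gaussian agreement model.

    The CS boundary at threshold t corresponds (symmetric equal-precision
    case) to each measurement sitting z* = sqrt((10-t)/2) of its own s.d.
    away from the consensus; the expectation applies the two-sided normal
    tail at z* per parameter.  At t = 0 this gives 2*(1-Phi(sqrt(5)))
    ~ 2.5% of parameters.
    """
    if n_params < 1:
        raise ValueError(f"n_params must be >= 1, got {n_params}")
    if cs_threshold > 10.0:
        raise ValueError(f"CS cannot exceed 10; threshold {cs_threshold} is invalid")
    z_star = math.sqrt((10.0 - cs_threshold) / 2.0)
    return n_params * 2.0 * (1.0 - norm.cdf(z_star))


def simulate_cs_failure_rate(
    n_pairs: int,
    cs_threshold: float = 0.0,
    sigma: float = 0.05,
    seed: int = 0,
    independent_errors: bool = False,
) -> float:
    """Monte-Carlo fraction of measurement pairs with CS <= threshold.

    With ``independent_errors=False`` (default) the draw realises the
    Gaussian agreement model behind :func:`expected_cs_failures`: the two
    equal-precision measurements sit symmetrically about their consensus,
    each displaced by its own full s.d. times a standard normal, so the
    fraction converges to 2*(1-Phi(z*)).

    With ``independent_errors=True`` both measurements get independent
    Gaussian errors about a common truth.  The two z scores about the
    *fitted* consensus are then perfectly anti-correlated with variance
    1/2, and the CS <= 0 rate drops to 2*(1-Phi(sqrt(10))) ~ 0.16% — the
    fully propagated counterpart of the 2.5% expectation (see the methods
    note).
    """
    rng = np.random.default_rng(seed)
    cond = ThermoCondition(25.0)
    if independent_errors:
        d1 = sigma * rng.standard_normal(n_pairs)
        d2 = sigma * rng.standard_normal(n_pairs)
    else:
        g = rng.standard_normal(n_pairs)
        d1, d2 = sigma * g, -sigma * g
    failures = 0
    for a, b in zip(d1, d2):
        res = consensus_and_cs(
            DeltaGEstimate(a, sigma, condition=cond, label="rox"),
            DeltaGEstimate(b, sigma, condition=cond, label="alexa"),
        )
        if res.cs <= cs_threshold:
            failures += 1
    return failures / n_pairs


def precision_experiment_multiplier(sd_coarse: float, sd_fine: float) -> tuple[float, float]:
    """(s.d. ratio, repeat-experiment multiplier) for matching a finer
    method's precision by averaging a coarser one.

    The s.d. of a mean falls as 1/sqrt(n), so matching a method whose
    per-parameter s.d. is r-fold smaller requires r^2-fold more repeats.
    """
    if not (sd_coarse > 0 and sd_fine > 0):
        raise ValueError("standard deviations must be positive")
    r = sd_coarse / sd_fine
    return r, r * r


def vant_hoff_fit(estimates: Sequence[DeltaGEstimate]) -> EnthalpyEntropyFit:
    """Weighted linear fit of dG(T) = dH - T*dS across temperatures.

    Minimizes the sum of squared z scores
    sum_i ((dH - T_i dS - mu_i)/sigma_i)^2 by closed-form weighted normal
    equations in the basis (1, -T).  Parameter s.d.'s come from the
    inverse normal matrix (measurement-error propagation, not residual
    rescaling, consistent with z-score weighting).
    """
    if len(estimates) < 2:
        raise ValueError("van't Hoff fit requires estimates at >= 2 temperatures")
    temps = np.array([e.condition.kelvin for e in estimates])
    if len(set(np.round(temps, 9))) < 2:
        raise ValueError("van't Hoff fit requires >= 2 distinct temperatures")
    sds = np.array([e.sd for e in estimates])
    if np.any(sds <= 0):
        raise ValueError("all estimates need sd > 0 for z-score weighting")
    mu = np.array([e.value for e in estimates])
    design = np.column_stack([np.ones_like(temps), -temps])
    w = 1.0 / sds**2
    normal = design.T @ (w[:, None] * design)
    rhs = design.T @ (w * mu)
    beta = np.linalg.solve(normal, rhs)
    cov = np.linalg.inv(normal)
    resid = design @ beta - mu
    return EnthalpyEntropyFit(
        dh=float(beta[0]),
        ds=float(beta[1]),
        dh_sd=float(math.sqrt(cov[0, 0])),
        ds_sd=float(math.sqrt(cov[1, 1])),
        sum_sq_z=float(np.sum(w * resid**2)),
    )
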