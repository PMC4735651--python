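"""Motif-sum duplex dG prediction plus the saturating dangle-length model.

The nearest-neighbour view: the standard free energy of forming a labelled
or dangle-bearing duplex is the sum of independent local motif terms —
helix initiation, one stacking term per base-pair step, a terminal-
fluorophore term per labelled end, and one dangle term per unpaired
overhang, keyed by side (5'/3'), the first dangle base and the closing
pair.

The length model is the package's empirical correction for overhangs
longer than one nucleotide: relative to the single-nucleotide dangle, a
homopolymer dangle of length L is destabilized by

    correction(L) = A * (1 - exp(-(L - 1) / lambda)),

a saturating penalty that vanishes at L = 1 and approaches the asymptote
A (measured at +0.56 kcal/mol for poly-T) with saturation by roughly 8 nt
for the default length scale lambda = 2 nt.

Motif tables are user-supplied TSV files with columns::

    motif_class  side  dangle_base  closing_pair  temperature_C  buffer  dG_kcal_mol  sd

``motif_class`` in {initiation, stack, dangle, fluorophore}.  For stacks
the key is the top-strand dinucleotide (5'->3') in ``closing_pair``; for
dangles ``side`` is 5p/3p, ``dangle_base`` the first overhang base and
``closing_pair`` the adjacent terminal pair (top base then bottom base);
for fluorophores ``dangle_base`` holds the dye name.  Unused key columns
are left as ``-``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.optimize import curve_fit

__all__ = [
    "MotifKey",
    "MotifTable",
    "load_motif_table",
    "DangleLengthModel",
    "length_correction",
    "fit_length_model",
    "duplex_delta_g",
]

_TABLE_COLUMNS = [
    "motif_class",
    "side",
    "dangle_base",
    "closing_pair",
    "temperature_C",
    "buffer",
    "dG_kcal_mol",
    "sd",
]

MotifKey = tuple[str, str, str, str]  # (motif_class, side, dangle_base, closing_pair)


@dataclass
class MotifTable:
    """Additive motif dG terms (kcal/mol) for one temperature/buffer."""

    entries: dict[MotifKey, float]
    condition_label: str = ""

    def __post_init__(self) -> None:
        for key, dg in self.entries.items():
            if not math.isfinite(dg):
                raise ValueError(f"motif {key} has non-finite dG {dg!r}")

    def lookup(self, motif_class: str, side: str = "-", dangle_base: str = "-",
               closing_pair: str = "-") -> float:
        key = (motif_class, side, dangle_base, closing_pair)
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"motif table is missing the entry "
                f"(motif_class={motif_class!r}, side={side!r}, "
                f"dangle_base={dangle_base!r}, closing_pair={closing_pair!r})"
            ) from None


def load_motif_table(
    path: str | Path,
    temperature_c: float | None = None,
    buffer_label: str | None = None,
) -> MotifTable:
    """Read a motif TSV, optionally filtering to one condition.

    Duplicate keys after filtering are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _TABLE_COLUMNS[:4]})
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if temperature_c is not None:
        df = df[np.isclose(df["temperature_C"].astype(float), temperature_c)]
    if buffer_label is not None:
        df = df[df["buffer"] == buffer_label]
    entries: dict[MotifKey, float] = {}
    for _, row in df.iterrows():
        key = (row["motif_class"], row["side"], row["dangle_base"], row["closing_pair"])
        if key in entries:
            raise ValueError(f"{path}: duplicate motif key {key}")
        entries[key] = float(row["dG_kcal_mol"])
    label = ""
    if temperature_c is not None or buffer_label is not None:
        label = f"{temperature_c} C, {buffer_label}"
    return MotifTable(entries, label)


@dataclass
class DangleLengthModel:
    """Saturating destabilization of multinucleotide dangles.

    ``asymptote`` (A, kcal/mol) is the long-dangle penalty relative to the
    single-nucleotide dangle; ``length_scale`` (lambda, nt) sets how fast
    the penalty saturates.  ``saturation_length`` is the smallest integer
    length whose correction reaches 95% of A.
    """

    asymptote: float
    length_scale: float = 2.0
    asymptote_se: float = 0.0
    length_scale_se: float = 0.0
    baseline: float = 0.0
    baseline_se: float = 0.0

    def __post_init__(self) -> None:
        if self.asymptote < 0.0:
            raise ValueError(
                f"asymptote must be >= 0 (a destabilization), got {self.asymptote!r}"
            )
        if not (self.length_scale > 0.0):
            raise ValueError(f"length_scale must be > 0, got {self.length_scale!r}")

    @property
    def saturation_length(self) -> int:
        if self.asymptote == 0.0:
            return 1
        return 1 + math.ceil(-self.length_scale * math.log(0.05))


def length_correction(length: int | np.ndarray, model: DangleLengthModel):
    """Penalty A*(1 - exp(-(L-1)/lambda)) in kcal/mol for a dangle of
    ``length`` nucleotides; zero at L = 1 by definition."""
    arr = np.asarray(length)
    if np.any(arr < 1):
        raise ValueError(f"dangle length must be >= 1 nt, got {length!r}")
    out = model.asymptote * (1.0 - np.exp(-(arr - 1.0) / model.length_scale))
    return float(out) if np.isscalar(length) else out


def fit_length_model(
    data: Sequence[tuple[int, float, float]],
    p0: tuple[float, float, float] | None = None,
) -> DangleLengthModel:
    """Weighted nonlinear least squares of the saturating length model.

    ``data`` rows are (length, dG estimate, sd); the dG values are
    absolute dangle dGs, so a baseline (the single-nucleotide dangle
    value) is co-fitted:  dG(L) = base + A*(1 - exp(-(L-1)/lambda)).
    Requires >= 3 distinct lengths including the L = 1 reference.
    Parameter standard errors come from the Jacobian-based covariance.
    """
    lengths = np.array([d[0] for d in data], dtype=float)
    values = np.array([d[1] for d in data], dtype=float)
    sds = np.array([d[2] for d in data], dtype=float)
    if len(set(lengths)) < 3:
        raise ValueError("fit requires >= 3 distinct dangle lengths")
    if 1 not in lengths:
        raise ValueError("fit requires the L = 1 single-nucleotide reference")
    if np.any(sds < 0):
        raise ValueError("sds must be >= 0")
    sigma = np.where(sds > 0, sds, max(np.max(sds), 1e-9) * 1e-3)

    def model(length, base, a, lam):
        return base + a * (1.0 - np.exp(-(length - 1.0) / lam))

    if p0 is None:
        base0 = float(values[lengths == 1].mean())
        a0 = max(float(values[np.argmax(lengths)] - base0), 1e-3)
        p0 = (base0, a0, 2.0)
    try:
        popt, pcov = curve_fit(
            model,
            lengths,
            values,
            p0=p0,
            sigma=sigma,
            absolute_sigma=True,
            bounds=([-np.inf, 0.0, 1e-3], [np.inf, np.inf, 1e3]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"length-model fit did not converge (last iterate p0={p0}): {err}"
        ) from err
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return DangleLengthModel(
        asymptote=float(popt[1]),
        length_scale=float(popt[2]),
        asymptote_se=float(se[1]),
        length_scale_se=float(se[2]),
        baseline=float(popt[0]),
        baseline_se=float(se[0]),
    )


def _align_duplex(seq_top: str, seq_bottom: str) -> tuple[int, int, int]:
    """Locate the complementary core of two strands (both written 5'->3').

    Slides the reverse complement of the bottom strand along the top
    strand and returns (top_start, bottom-rc_start, length) of the longest
    fully complementary overlap.  Overhangs outside the core are dangles.
    """
    top = seq_top.upper()
    bot_rc = str(Seq(seq_bottom.upper()).reverse_complement())
    best = (0, 0, 0)
    for shift in range(-len(bot_rc) + 1, len(top)):
        i0 = max(0, shift)
        j0 = max(0, -shift)
        n = min(len(top) - i0, len(bot_rc) - j0)
        if n <= 0:
            continue
        if top[i0 : i0 + n] == bot_rc[j0 : j0 + n] and n > best[2]:
            best = (i0, j0, n)
    if best[2] < 2:
        raise ValueError(
            f"strands {seq_top!r} / {seq_bottom!r} share no complementary "
            f"duplex core of >= 2 bp"
        )
    return best


def _homopolymer_first_base(dangle_seq: str, where: str) -> str:
    if len(set(dangle_seq)) != 1:
        raise ValueError(
            f"only homopolymer (secondary-structure-free) dangles are "
            f"supported; got {dangle_seq!r} at {where}"
        )
    return dangle_seq[0]


def duplex_delta_g(
    seq_top: str,
    seq_bottom: str,
    table: MotifTable,
    length_model: DangleLengthModel | None = None,
    fluor_top_5p: str | None = None,
    fluor_top_3p: str | None = None,
) -> float:
    """Motif-sum dG of forming the duplex of two strands (kcal/mol).

    Sums initiation, per-step stacks, terminal-fluorophore terms and
    dangle terms; dangles longer than 1 nt additionally receive the
    saturating length correction (``length_model`` required then).
    Missing table entries raise a KeyError naming the absent key.
    """
    i0, j0, n = _align_duplex(seq_top, seq_bottom)
    top = seq_top.upper()
    bottom = seq_bottom.upper()
    core_top = top[i0 : i0 + n]
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

    total = table.lookup("initiation")
    for k in range(n - 1):
        total += table.lookup("stack", closing_pair=core_top[k : k + 2])

    # dangles: (sequence, side relative to its own strand, closing pair)
    dangles: list[tuple[str, str, str]] = []
    left_top = top[:i0]  # 5' overhang of the top strand
    if left_top:
        dangles.append((left_top[::-1], "5p", core_top[0] + comp[core_top[0]]))
    right_top = top[i0 + n :]  # 3' overhang of the top strand
    if right_top:
        dangles.append((right_top, "3p", core_top[-1] + comp[core_top[-1]]))
    # Bottom-strand overhangs: in reverse-complement coordinates the
    # prefix (left of the core, top 5' side) is the bottom strand's 3'
    # overhang and the suffix is its 5' overhang.  Sequences are read
    # duplex-outward; closing pairs are keyed dangle-strand base first.
    len_b = len(bottom)
    n_3p_b = j0
    n_5p_b = len_b - (j0 + n)
    if n_3p_b:
        dangles.append((bottom[len_b - n_3p_b :], "3p", comp[core_top[0]] + core_top[0]))
    if n_5p_b:
        dangles.append((bottom[:n_5p_b][::-1], "5p", comp[core_top[-1]] + core_top[-1]))

    for seq, side, closing in dangles:
        first = _homopolymer_first_base(seq, f"{side} overhang")
        total += table.lookup("dangle", side=side, dangle_base=first, closing_pair=closing)
        if len(seq) > 1:
            if length_model is None:
                raise ValueError(
                    f"{side} dangle {seq!r} is {len(seq)} nt long; a "
                    f"DangleLengthModel is required for multinucleotide dangles"
                )
            total += length_correction(len(seq), length_model)

    if fluor_top_5p is not None:
        total += table.lookup(
            "fluorophore", side="5p", dangle_base=fluor_top_5p,
            closing_pair=core_top[0] + comp[core_top[0]],
        )
    if fluor_top_3p is not None:
        total += table.lookup(
            "fluorophore", side="3p", dangle_base=fluor_top_3p,
            closing_pair=core_top[-1] + comp[core_top[-1]],
        )
    return total
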