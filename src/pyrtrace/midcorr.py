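"""Natural-abundance correction of measured SIM isotopologue distributions.

A measured channel distribution mixes tracer labelling with the natural
heavy-isotope background of every atom in the derivatized fragment (13C in
derivative carbons, 29/30Si from TBDMS groups, 18O, ...).  The correction
expresses the measurement as a linear combination of theoretical channel
patterns, one per tracer-labelling state: column j of the correction matrix
is the fragment's isotopologue distribution when exactly j of its n
labelable carbons are 13C (those j carbons are removed from the natural
abundance convolution and the pattern is shifted up j channels).  Solving
the resulting linear system under a non-negativity constraint (NNLS) and
renormalising yields the corrected mass isotopomer distribution (MID).

NNLS is used rather than plain matrix inversion because inversion can
produce negative isotopomer fractions on noisy data; the fit residual is
reported so poor fits are visible rather than silently absorbed.

An optional tracer isotopic-purity correction exists but is off by default:
the tracer enrichment in this workflow is a molecule fraction (40 % of
gavage molecules fully labelled), not an atom purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.optimize

from .chem import (
    ElementalFormula,
    FragmentSpec,
    IsotopeTable,
    default_isotope_table,
    fragment_library,
    isotopologue_distribution,
)

__all__ = [
    "MID",
    "CorrectionMatrix",
    "MeasuredDistribution",
    "build_correction_matrix",
    "convolve_mid",
    "correct_mid",
    "correct_area_table",
]


@dataclass(frozen=True)
class MeasuredDistribution:
    """Raw (or normalised) per-channel signal areas for one fragment."""

    fragment: FragmentSpec
    areas: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if areas.ndim != 1 or len(areas) != self.fragment.channel_count:
            raise ValueError(
                f"expected {self.fragment.channel_count} channel areas, "
                f"got shape {areas.shape}"
            )
        if (areas < 0).any():
            raise ValueError("channel areas must be non-negative")
        if not (areas > 0).any():
            raise ValueError("all-zero measurement")


@dataclass(frozen=True)
class CorrectionMatrix:
    """channel_count x (n+1) matrix of labelled-state channel patterns."""

    fragment: FragmentSpec
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        expected = (self.fragment.channel_count, self.fragment.n + 1)
        if m.shape != expected:
            raise ValueError(f"matrix shape {m.shape}, expected {expected}")


@dataclass(frozen=True)
class MID:
    """Corrected mass isotopomer distribution M0..Mn (fractions sum to 1)."""

    fractions: np.ndarray
    n: int
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if len(f) != self.n + 1:
            raise ValueError(f"expected {self.n + 1} fractions, got {len(f)}")
        if (f < -1e-12).any() or (f > 1 + 1e-9).any():
            raise ValueError("MID fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"MID fractions sum to {f.sum()}, expected 1")

    def __getitem__(self, i: int) -> float:
        return float(self.fractions[i])


def build_correction_matrix(frag: FragmentSpec,
                            table: IsotopeTable | None = None) -> CorrectionMatrix:
    """Natural-abundance correction matrix for one fragment.

    Column j: remove j carbons from the natural-abundance convolution (they
    are fixed as 13C) and shift the resulting pattern up j channels, so the
    column has zero mass in channels below j.
    """
    table = table or default_isotope_table()
    k = frag.channel_count
    cols = np.zeros((k, frag.n + 1))
    for j in range(frag.n + 1):
        reduced = frag.formula.remove("C", j)
        pattern = isotopologue_distribution(reduced, table, k - j).probs
        cols[j:, j] = pattern
    return CorrectionMatrix(frag, cols)


def correct_mid(meas: MeasuredDistribution, cm: CorrectionMatrix,
                tracer_purity: float | None = None) -> MID:
    """Invert a measured channel distribution into a corrected MID.

    Solves ``meas ~ cm @ x`` for x >= 0 by non-negative least squares on the
    area-normalised channel vector, then renormalises x to sum 1.  The
    residual 2-norm of the NNLS fit is recorded on the result.

    ``tracer_purity`` (atom fraction 13C of the tracer's labelled positions)
    optionally deconvolves incomplete tracer atom purity; it defaults to
    None (off), as appropriate when tracer enrichment is a molecule fraction.
    """
    if meas.fragment is not cm.fragment and meas.fragment != cm.fragment:
        raise ValueError("measurement and matrix refer to different fragments")
    a = cm.matrix
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient correction matrix for {cm.fragment.metabolite}"
        )
    b = meas.areas / meas.areas.sum()
    x, rnorm = scipy.optimize.nnls(a, b)
    if x.sum() <= 0:
        raise ValueError("degenerate NNLS fit: all-zero solution")
    x = x / x.sum()
    if tracer_purity is not None:
        x = _purity_deconvolve(x, tracer_purity)
    return MID(x, cm.fragment.n, residual_norm=float(rnorm))


def _purity_deconvolve(mid: np.ndarray, purity: float) -> np.ndarray:
    """Remove the binomial smear caused by tracer atom purity < 1."""
    if not 0 < purity <= 1:
        raise ValueError("tracer purity must be in (0, 1]")
    n = len(mid) - 1
    # true state j is observed spread binomially over 0..j labels
    smear = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        for i in range(j + 1):
            smear[i, j] = comb(j, i) * purity**i * (1 - purity) ** (j - i)
    x, _ = scipy.optimize.nnls(smear, mid)
    s = x.sum()
    return x / s if s > 0 else x


def convolve_mid(mid: MID | np.ndarray, cm: CorrectionMatrix) -> MeasuredDistribution:
    """Forward model: project a true MID back onto SIM channels (cm @ mid)."""
    frac = mid.fractions if isinstance(mid, MID) else np.asarray(mid, float)
    if len(frac) != cm.matrix.shape[1]:
        raise ValueError(
            f"MID length {len(frac)} does not match matrix columns "
            f"{cm.matrix.shape[1]}"
        )
    return MeasuredDistribution(cm.fragment, cm.matrix @ frac)


def correct_area_table(areas: pd.DataFrame,
                       fragments: dict[str, FragmentSpec] | None = None,
                       table: IsotopeTable | None = None) -> pd.DataFrame:
    """Correct a tidy SIM area table into a tidy corrected-MID table.

    ``areas`` columns: sample_id, metabolite, channel_index, area.
    Returns columns: sample_id, metabolite, isotopologue (M0..Mn), fraction,
    residual_norm.
    """
    fragments = fragments or fragment_library()
    table = table or default_isotope_table()
    matrices = {}
    rows = []
    for (sample, met), grp in areas.groupby(["sample_id", "metabolite"],
                                            sort=True):
        if met not in fragments:
            raise KeyError(f"metabolite {met!r} not in fragment library")
        frag = fragments[met]
        if met not in matrices:
            matrices[met] = build_correction_matrix(frag, table)
        vec = np.zeros(frag.channel_count)
        idx = grp["channel_index"].to_numpy(dtype=int)
        vec[idx] = grp["area"].to_numpy(dtype=float)
        mid = correct_mid(MeasuredDistribution(frag, vec), matrices[met])
        for i, f in enumerate(mid.fractions):
            rows.append((sample, met, f"M{i}", f, mid.residual_norm))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "metabolite", "isotopologue", "fraction",
                 "residual_norm"],
    )
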