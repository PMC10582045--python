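"""Elemental formulas, monoisotopic masses and natural isotope patterns.

Everything downstream of the GC-MS and MALDI-MSI data reduction rests on
three primitives implemented here:

* parsing/serialising elemental formulas (Hill order),
* monoisotopic (lightest-isotope) masses and deprotonated-ion m/z,
* theoretical isotopologue distributions obtained by convolving per-atom
  natural isotope-shift distributions, binned by nominal mass shift
  (integer Delta-M, matching the 1 m/z spacing of SIM channels).

A packaged isotope table (``data/isotopes.tsv``) provides masses and
abundances; a packaged fragment library (``data/fragments.tsv``) encodes the
SIM fragments monitored for the tracing experiment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping, NamedTuple

import numpy as np

__all__ = [
    "PROTON_MASS",
    "ElementalFormula",
    "FormulaError",
    "FragmentSpec",
    "IsotopePattern",
    "IsotopeTable",
    "default_isotope_table",
    "deprotonated_mz",
    "fragment_library",
    "isotopologue_distribution",
    "monoisotopic_mass",
    "parse_formula",
]

#: Mass of the proton (includes the electron-mass difference from a neutral
#: hydrogen atom), Da.  Deprotonation subtracts this value; at the 3-decimal
#: reporting precision used for lipid ions the distinction from subtracting a
#: hydrogen atom (1.00783 Da) is below the last digit.
PROTON_MASS = 1.007276466


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element-count map for a fragment or lipid ion."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other:
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other:
            merged[el] = merged.get(el, 0) - n
        return ElementalFormula(merged)

    def remove(self, element: str, n: int) -> "ElementalFormula":
        """Return a copy with ``n`` atoms of ``element`` removed."""
        have = self[element]
        if n > have:
            raise FormulaError(
                f"cannot remove {n} {element} from formula with {have}"
            )
        out = dict(self.counts)
        out[element] = have - n
        return ElementalFormula(out)

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Canonical Hill-order serialisation (C, H, then alphabetical)."""
        parts: list[str] = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``"C11H25O3Si2"``-style strings into an :class:`ElementalFormula`.

    Tokens are ``ElementSymbol`` optionally followed by a positive integer
    count (``"C"`` means one carbon).  Unknown symbols and explicit zero
    counts are rejected with an error naming the offending token.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable formula {text!r} at {text[pos:m.start()]!r}"
            )
        pos = m.end()
        el, digits = m.group(1), m.group(2)
        if el not in _KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count token {el}{digits!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at {text[pos:]!r}")
    return ElementalFormula(counts)


# ---------------------------------------------------------------------------
# Isotope table
# ---------------------------------------------------------------------------

class Isotope(NamedTuple):
    mass: float
    abundance: float


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element ordered natural isotopes (mass Da, fractional abundance)."""

    isotopes: Mapping[str, tuple[Isotope, ...]]

    def __post_init__(self) -> None:
        for el, isos in self.isotopes.items():
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"abundances for {el} sum to {total}, expected 1"
                )
            masses = [i.mass for i in isos]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {el} not increasing")

    def __contains__(self, element: str) -> bool:
        return element in self.isotopes

    def __getitem__(self, element: str) -> tuple[Isotope, ...]:
        try:
            return self.isotopes[element]
        except KeyError:
            raise KeyError(f"element {element!r} missing from isotope table")

    def lightest_mass(self, element: str) -> float:
        return self[element][0].mass

    def shift_distribution(self, element: str) -> np.ndarray:
        """Per-atom abundance vector over nominal mass shifts Delta-M.

        Entry k is the probability that one atom of ``element`` is heavier
        than the lightest isotope by k nominal mass units.
        """
        isos = self[element]
        base = isos[0].mass
        shifts = [round(i.mass - base) for i in isos]
        out = np.zeros(max(shifts) + 1)
        for s, iso in zip(shifts, isos):
            out[s] += iso.abundance
        return out

    def with_abundances(self, element: str,
                        abundances: list[float]) -> "IsotopeTable":
        """Copy of the table with one element's abundances replaced."""
        isos = self[element]
        if len(abundances) != len(isos):
            raise ValueError("abundance list length mismatch")
        new = dict(self.isotopes)
        new[element] = tuple(
            Isotope(i.mass, a) for i, a in zip(isos, abundances)
        )
        return IsotopeTable(new)


def _read_isotope_tsv(text: str) -> IsotopeTable:
    isotopes: dict[str, list[Isotope]] = {}
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        el, mass, ab = line.split("\t")
        isotopes.setdefault(el, []).append(Isotope(float(mass), float(ab)))
    return IsotopeTable({el: tuple(v) for el, v in isotopes.items()})


@lru_cache(maxsize=1)
def default_isotope_table() -> IsotopeTable:
    """The packaged natural-abundance isotope table."""
    text = (resources.files("pyrtrace") / "data" / "isotopes.tsv").read_text()
    return _read_isotope_tsv(text)


_KNOWN_ELEMENTS = frozenset({"C", "H", "N", "O", "P", "S", "Si"})


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def monoisotopic_mass(formula: ElementalFormula,
                      table: IsotopeTable | None = None) -> float:
    """Sum of count x lightest-isotope mass over the formula's elements."""
    table = table or default_isotope_table()
    return sum(n * table.lightest_mass(el) for el, n in formula)


def deprotonated_mz(neutral: ElementalFormula,
                    table: IsotopeTable | None = None) -> float:
    """[M-H]- m/z of a neutral molecule (negative-ion MALDI convention)."""
    if neutral["H"] < 1:
        raise FormulaError(
            f"cannot deprotonate {neutral.hill()!r}: no hydrogen"
        )
    return monoisotopic_mass(neutral, table) - PROTON_MASS


# ---------------------------------------------------------------------------
# Isotopologue distributions
# ---------------------------------------------------------------------------

class IsotopePattern(NamedTuple):
    """Truncated nominal-mass-shift distribution and the truncated tail."""

    probs: np.ndarray
    tail: float


def isotopologue_distribution(formula: ElementalFormula,
                              table: IsotopeTable | None = None,
                              channels: int = 5) -> IsotopePattern:
    """Theoretical isotopologue abundances over ``channels`` SIM channels.

    Entry k is the probability that the ion's nominal mass exceeds the
    monoisotopic mass by k, from convolving independent per-atom isotope
    shift distributions.  The vector is truncated to ``channels`` entries;
    the probability mass beyond the last channel is returned as ``tail``.
    Fine mass splitting within a nominal channel is ignored.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    table = table or default_isotope_table()
    dist = np.zeros(channels)
    dist[0] = 1.0
    for el, n in formula:
        atom = table.shift_distribution(el)
        # exponentiate by repeated convolution; truncation to `channels` is
        # exact for the retained entries (entry k never depends on entries
        # >= channels of either factor)
        powed = _convolve_power(atom, n, channels)
        dist = np.convolve(dist, powed)[:channels]
    return IsotopePattern(dist, float(max(0.0, 1.0 - dist.sum())))


def _convolve_power(atom: np.ndarray, n: int, channels: int) -> np.ndarray:
    out = np.zeros(channels)
    out[0] = 1.0
    base = atom[:channels].copy()
    while n:
        if n & 1:
            out = np.convolve(out, base)[:channels]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:channels]
    return out


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSpec:
    """A monitored GC-MS fragment of a metabolite.

    ``n`` is the number of tracer-labelable backbone carbons carried by the
    fragment; ``sim_start_mz`` the first channel of the published SIM window
    (which may differ by 0.1 m/z from the 1-decimal rounding of the computed
    monoisotopic mass for a few fragments; both values are retained).
    """

    metabolite: str
    formula: ElementalFormula
    n: int
    sim_start_mz: float
    channel_count: int
    derivative: str = ""
    sim_window: str = ""

    def __post_init__(self) -> None:
        if self.n > self.formula["C"]:
            raise ValueError(
                f"{self.metabolite}: n={self.n} exceeds carbon count "
                f"{self.formula['C']}"
            )
        if self.channel_count < self.n + 1:
            raise ValueError(
                f"{self.metabolite}: channel_count {self.channel_count} "
                f"< n+1 = {self.n + 1}"
            )

    @property
    def computed_mz(self) -> float:
        return monoisotopic_mass(self.formula)


def _read_fragment_tsv(text: str) -> dict[str, FragmentSpec]:
    out: dict[str, FragmentSpec] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        spec = FragmentSpec(
            metabolite=row["metabolite"],
            formula=parse_formula(row["fragment_formula"]),
            n=int(row["n_labelable"]),
            sim_start_mz=float(row["sim_start_mz"]),
            channel_count=int(row["channel_count"]),
            derivative=row.get("derivative", ""),
            sim_window=row.get("sim_window", ""),
        )
        out[spec.metabolite] = spec
    return out


@lru_cache(maxsize=1)
def fragment_library() -> dict[str, FragmentSpec]:
    """The packaged SIM fragment library, keyed by metabolite name."""
    text = (resources.files("pyrtrace") / "data" / "fragments.tsv").read_text()
    return _read_fragment_tsv(text)
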