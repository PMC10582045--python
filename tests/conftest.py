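"""Shared fixtures and independent oracles."""

from __future__ import annotations

import itertools
from math import comb, factorial, prod

import numpy as np
import pytest

from pyrtrace.chem import (
    ElementalFormula,
    IsotopeTable,
    default_isotope_table,
    fragment_library,
)


@pytest.fixture(scope="session")
def table() -> IsotopeTable:
    return default_isotope_table()


@pytest.fixture(scope="session")
def library():
    return fragment_library()


@pytest.fixture(scope="session")
def zero_abundance_table(table) -> IsotopeTable:
    """Hypothetical table where carbon has no heavy natural isotope."""
    return table.with_abundances("C", [1.0, 0.0])


def enumerate_isotopologue_distribution(formula: ElementalFormula,
                                        table: IsotopeTable,
                                        channels: int) -> np.ndarray:
    """Independent oracle: exhaustive enumeration over isotope assignments.

    For each element, every composition (n_1..n_k) of its atoms over its k
    isotopes is enumerated with its multinomial probability and total
    nominal mass shift; element results are combined by an explicit product
    over the cartesian set.  No convolution code shared with the
    implementation under test.
    """
    per_element: list[dict[int, float]] = []
    for el, n in formula:
        isos = table[el]
        base = isos[0].mass
        shifts = [round(i.mass - base) for i in isos]
        dist: dict[int, float] = {}
        for counts in _compositions(n, len(isos)):
            p = (factorial(n) // prod(factorial(c) for c in counts))
            p *= prod(iso.abundance ** c for iso, c in zip(isos, counts))
            s = sum(c * sh for c, sh in zip(counts, shifts))
            dist[s] = dist.get(s, 0.0) + p
        per_element.append(dist)
    out = np.zeros(channels)
    for combo in itertools.product(*per_element):
        s = sum(combo)
        if s < channels:
            p = prod(d[k] for d, k in zip(per_element, combo))
            out[s] += p
    return out


def _compositions(n: int, k: int):
    """All k-tuples of non-negative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest
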