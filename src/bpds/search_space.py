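"""Algebraic restriction of the model search space.

A coordinate function is only ever asked to interpolate the ``m`` observed
transitions, where ``m`` is the *total length* of the input time series
(sum over series of length minus one).  Any monomial appearing in a minimal
interpolator of ``m`` points must satisfy ``prod(a_i + 1) <= m``; for a
square-free monomial this reads ``2^|supp| <= m``, i.e. the support size is
bounded by ``Phi = floor(log2 m)``.  The search space is therefore the span
of ``M = {x^a : |supp(x^a)| <= Phi}``, of dimension ``sum_{i<=Phi} C(n, i)``
-- dramatically smaller than the ``2^n`` square-free monomials for sparse
data, while provably still containing an exact interpolator of every
consistent data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

from .polynomial import Monomial

__all__ = [
    "SearchSpaceSpec",
    "total_length",
    "support_bound",
    "dimension",
    "enumerate_monomials",
    "is_admissible",
]


def total_length(series_lengths: Sequence[int]) -> int:
    """Total length ``m = sum(alpha_mu - 1)``: the number of prescribed
    transitions.  A fragment of length 1 contributes 0."""
    lengths = list(series_lengths)
    if not lengths:
        raise ValueError("no time series supplied")
    if any(a < 1 for a in lengths):
        raise ValueError("every series length must be >= 1")
    return sum(lengths) - len(lengths)


def support_bound(m: int) -> int:
    """The monomial support bound ``Phi = floor(log2 m)``."""
    if m < 1:
        raise ValueError(f"total length m must be >= 1, got {m}")
    return m.bit_length() - 1  # exact floor(log2 m) for integers


def dimension(n: int, phi: int) -> int:
    """Dimension of the restricted space: ``sum_{i=0}^{Phi} C(n, i)``.

    Exact integer arithmetic; ``phi >= n`` gives the full ``2^n``.
    """
    if n < 0 or phi < 0:
        raise ValueError("n and phi must be non-negative")
    if phi >= n:
        return 1 << n
    return sum(math.comb(n, i) for i in range(phi + 1))


def enumerate_monomials(n: int, phi: int) -> Iterator[Monomial]:
    """All monomials with support size <= ``phi``, in a fixed deterministic
    order: by support size, then lexicographically by variable index."""
    if phi < 0:
        raise ValueError("phi must be non-negative")
    for size in range(min(phi, n) + 1):
        for support in combinations(range(n), size):
            yield Monomial.from_support(support)


def is_admissible(mono: Monomial, m: int) -> bool:
    """Monomial admissibility for data of total length ``m``:
    ``2^|supp| <= m`` (the square-free form of ``prod(a_i + 1) <= m``)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return (1 << mono.degree) <= m


@dataclass
class SearchSpaceSpec:
    """The restricted search space for a given data set.

    ``per_coordinate_phi`` optionally refines the global bound when the
    maximum number of regulators of individual genes is known a priori.
    """

    n: int
    m: int
    phi: int = field(default=-1)
    per_coordinate_phi: list[int] | None = None

    def __post_init__(self) -> None:
        if self.phi < 0:
            self.phi = support_bound(self.m)
        elif self.m >= 1 and self.phi != support_bound(self.m):
            raise ValueError(
                f"phi={self.phi} inconsistent with m={self.m} "
                f"(expected {support_bound(self.m)})"
            )
        if self.per_coordinate_phi is not None:
            if len(self.per_coordinate_phi) != self.n:
                raise ValueError("per_coordinate_phi must have one entry per variable")
            if any(p > self.phi or p < 0 for p in self.per_coordinate_phi):
                raise ValueError("per-coordinate bounds must lie in [0, phi]")

    @classmethod
    def from_lengths(cls, n: int, series_lengths: Sequence[int]) -> "SearchSpaceSpec":
        return cls(n=n, m=total_length(series_lengths))

    def phi_for(self, i: int) -> int:
        if self.per_coordinate_phi is not None:
            return self.per_coordinate_phi[i]
        return self.phi

    @property
    def dimension(self) -> int:
        return dimension(self.n, self.phi)

    def monomials(self, i: int | None = None) -> list[Monomial]:
        phi = self.phi if i is None else self.phi_for(i)
        return list(enumerate_monomials(self.n, phi))
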