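"""Square-free polynomial algebra over GF(2) and Boolean network dynamics.

A Boolean network on ``n`` nodes is a map ``f = (f1, ..., fn)`` from
``{0,1}^n`` to itself.  Over the two-element field every coordinate function
has a unique *square-free* polynomial representative (``x^2 = x``), so a
monomial is fully described by its support -- the set of variables appearing
in it -- and a polynomial by its set of monomials (all coefficients are 0/1,
and monomial pairs cancel modulo 2).

Internally a monomial is a bit-mask of 0-based variable indices and a
polynomial is a frozenset of masks; user-facing text uses the conventional
1-based names ``x1 .. xn``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Monomial",
    "BooleanPolynomial",
    "PolynomialModel",
    "square_free_reduce",
    "from_boolean_expression",
    "pack_state",
    "unpack_state",
]

State = tuple[int, ...]


def pack_state(bits: Sequence[int]) -> int:
    """Pack a 0/1 vector into an integer (bit i = variable i, 0-based)."""
    s = 0
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError(f"state entries must be 0/1, got {b!r}")
        s |= int(b) << i
    return s


def unpack_state(s: int, n: int) -> State:
    return tuple((s >> i) & 1 for i in range(n))


@dataclass(frozen=True)
class Monomial:
    """A square-free monomial, represented by its support bit-mask.

    ``mask == 0`` is the constant monomial 1 (empty support).
    """

    mask: int

    @classmethod
    def from_support(cls, support: Iterable[int]) -> "Monomial":
        m = 0
        for i in support:
            if i < 0:
                raise ValueError("variable indices must be non-negative")
            m |= 1 << i
        return cls(m)

    @property
    def support(self) -> frozenset[int]:
        """0-based indices of the variables in the monomial."""
        return frozenset(i for i in range(self.mask.bit_length()) if (self.mask >> i) & 1)

    @property
    def degree(self) -> int:
        return self.mask.bit_count()

    def evaluate(self, state: int) -> int:
        """Value at a packed state: 1 iff every support variable is 1."""
        return 1 if (state & self.mask) == self.mask else 0

    def __str__(self) -> str:
        if self.mask == 0:
            return "1"
        return "*".join(f"x{i + 1}" for i in sorted(self.support))


def square_free_reduce(exponents: Sequence[int]) -> Monomial:
    """Reduce a raw monomial with integer exponents to its square-free form.

    Over GF(2) ``x^2 = x``, so any variable with exponent >= 1 appears with
    exponent exactly 1; exponent 0 variables drop out (``x^0 = 1``).
    """
    if any(e < 0 for e in exponents):
        raise ValueError("exponents must be non-negative")
    return Monomial.from_support(i for i, e in enumerate(exponents) if e >= 1)


def _mono_sort_key(mask: int) -> tuple[int, tuple[int, ...]]:
    return (mask.bit_count(), tuple(i for i in range(mask.bit_length()) if (mask >> i) & 1))


class BooleanPolynomial:
    """A square-free polynomial over GF(2) in ``n`` variables.

    Stored as a frozenset of monomial masks; the empty set is the zero
    polynomial, ``{0}`` the constant 1.  Addition is symmetric difference
    (mod-2 cancellation); multiplication distributes with parity collapse.
    """

    __slots__ = ("masks", "n")

    def __init__(self, masks: Iterable[int], n: int):
        ms = frozenset(int(m) for m in masks)
        for m in ms:
            if m < 0 or m.bit_length() > n:
                raise ValueError(f"monomial mask {m} references variables beyond n={n}")
        self.masks = ms
        self.n = n

    # -- constructors ------------------------------------------------------
    @classmethod
    def zero(cls, n: int) -> "BooleanPolynomial":
        return cls((), n)

    @classmethod
    def one(cls, n: int) -> "BooleanPolynomial":
        return cls((0,), n)

    @classmethod
    def variable(cls, i: int, n: int) -> "BooleanPolynomial":
        """The polynomial ``x_{i+1}`` (``i`` is a 0-based index)."""
        if not 0 <= i < n:
            raise IndexError(f"variable index {i} out of range for n={n}")
        return cls((1 << i,), n)

    @classmethod
    def from_monomials(cls, monomials: Iterable[Monomial], n: int) -> "BooleanPolynomial":
        masks: set[int] = set()
        for mono in monomials:
            masks.symmetric_difference_update((mono.mask,))
        return cls(masks, n)

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "BooleanPolynomial") -> "BooleanPolynomial":
        self._check(other)
        return BooleanPolynomial(self.masks ^ other.masks, self.n)

    def __mul__(self, other: "BooleanPolynomial") -> "BooleanPolynomial":
        self._check(other)
        out: set[int] = set()
        for a in self.masks:
            for b in other.masks:
                out ^= {a | b}  # x^2 = x: union of supports
        return BooleanPolynomial(out, self.n)

    def _check(self, other: "BooleanPolynomial") -> None:
        if self.n != other.n:
            raise ValueError(f"mixing polynomials on n={self.n} and n={other.n} variables")

    @property
    def is_zero(self) -> bool:
        return not self.masks

    @property
    def monomials(self) -> frozenset[Monomial]:
        return frozenset(Monomial(m) for m in self.masks)

    @property
    def support(self) -> frozenset[int]:
        """0-based indices of all variables appearing in the polynomial."""
        acc = 0
        for m in self.masks:
            acc |= m
        return Monomial(acc).support

    @property
    def total_degree(self) -> int:
        """Maximum monomial support size; 0 for the zero polynomial and 1."""
        return max((m.bit_count() for m in self.masks), default=0)

    # -- evaluation --------------------------------------------------------
    def evaluate_packed(self, state: int) -> int:
        acc = 0
        for m in self.masks:
            if (state & m) == m:
                acc ^= 1
        return acc

    def evaluate(self, state: Sequence[int]) -> int:
        if len(state) != self.n:
            raise ValueError(f"state of length {len(state)} for polynomial on n={self.n}")
        return self.evaluate_packed(pack_state(state))

    # -- text --------------------------------------------------------------
    def __str__(self) -> str:
        if not self.masks:
            return "0"
        terms = sorted(self.masks, key=_mono_sort_key)
        return " + ".join(str(Monomial(m)) for m in terms)

    @classmethod
    def parse(cls, text: str, n: int) -> "BooleanPolynomial":
        """Parse the model text format: ``x1*x2 + x3 + 1`` (or ``0``)."""
        text = text.strip()
        if not text:
            raise ValueError("empty polynomial text")
        masks: set[int] = set()
        for term in text.split("+"):
            term = term.strip()
            if term == "0":
                continue
            mask = 0
            for factor in term.split("*"):
                factor = factor.strip()
                if factor == "1":
                    continue
                m = re.fullmatch(r"x(\d+)", factor)
                if not m:
                    raise ValueError(f"malformed term factor {factor!r}")
                j = int(m.group(1))
                if not 1 <= j <= n:
                    raise ValueError(f"variable x{j} out of range for n={n}")
                mask |= 1 << (j - 1)
            masks ^= {mask}
        return cls(masks, n)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BooleanPolynomial)
            and self.n == other.n
            and self.masks == other.masks
        )

    def __hash__(self) -> int:
        return hash((self.n, self.masks))

    def __repr__(self) -> str:
        return f"BooleanPolynomial({self}, n={self.n})"


# ---------------------------------------------------------------------------
# Boolean expression -> polynomial translation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<var>x\d+)|(?P<const>[01])"
    r"|(?P<op>AND|OR|NOT|XOR|&&?|\|\|?|!|\^)|(?P<bad>\S))",
    re.IGNORECASE,
)

_OP_CANON = {"&": "AND", "&&": "AND", "|": "OR", "||": "OR", "!": "NOT", "^": "XOR"}


def _tokenize(expr: str) -> list[str]:
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(expr):
        if m.group("bad"):
            raise ValueError(f"unexpected character {m.group('bad')!r} in expression")
        if m.group("lpar"):
            tokens.append("(")
        elif m.group("rpar"):
            tokens.append(")")
        elif m.group("var"):
            tokens.append(m.group("var").lower())
        elif m.group("const"):
            tokens.append(m.group("const"))
        else:
            op = m.group("op").upper()
            tokens.append(_OP_CANON.get(op, op))
    return tokens


class _ExprParser:
    """Recursive-descent parser; precedence NOT > AND > XOR > OR.

    Translation into GF(2): AND -> product, OR -> x + y + x*y, NOT -> x + 1,
    XOR -> sum.
    """

    def __init__(self, tokens: list[str], n: int):
        self.tokens = tokens
        self.pos = 0
        self.n = n

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> BooleanPolynomial:
        p = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"trailing token {self.peek()!r}")
        return p

    def parse_or(self) -> BooleanPolynomial:
        p = self.parse_xor()
        while self.peek() == "OR":
            self.next()
            q = self.parse_xor()
            p = p + q + p * q
        return p

    def parse_xor(self) -> BooleanPolynomial:
        p = self.parse_and()
        while self.peek() == "XOR":
            self.next()
            p = p + self.parse_and()
        return p

    def parse_and(self) -> BooleanPolynomial:
        p = self.parse_factor()
        while self.peek() == "AND":
            self.next()
            p = p * self.parse_factor()
        return p

    def parse_factor(self) -> BooleanPolynomial:
        tok = self.next()
        if tok == "NOT":
            return self.parse_factor() + BooleanPolynomial.one(self.n)
        if tok == "(":
            p = self.parse_or()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses")
            return p
        if tok == "0":
            return BooleanPolynomial.zero(self.n)
        if tok == "1":
            return BooleanPolynomial.one(self.n)
        if tok.startswith("x"):
            j = int(tok[1:])
            if not 1 <= j <= self.n:
                raise ValueError(f"unknown variable {tok} for n={self.n}")
            return BooleanPolynomial.variable(j - 1, self.n)
        raise ValueError(f"unexpected token {tok!r}")


def from_boolean_expression(expr: str, n: int) -> BooleanPolynomial:
    """Translate a Boolean logic expression over ``x1..xn`` into its
    square-free GF(2) polynomial.

    Accepts AND/OR/NOT/XOR (words, case-insensitive, or ``& | ! ^``),
    parentheses and the constants 0/1.
    """
    return _ExprParser(_tokenize(expr), n).parse()


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


class PolynomialModel:
    """A Boolean polynomial dynamical system ``f = (f1, ..., fn)``.

    The model is iterated with a synchronous update schedule: every
    coordinate is evaluated on the same current state.  Fixed points
    (steady states) are invariant under any update schedule, which
    :meth:`sequential_step` lets callers verify.
    """

    __slots__ = ("coords", "n")

    def __init__(self, coords: Sequence[BooleanPolynomial]):
        coords = tuple(coords)
        if not coords:
            raise ValueError("a model needs at least one coordinate")
        n = coords[0].n
        if any(p.n != n for p in coords):
            raise ValueError("all coordinate polynomials must share the same n")
        if len(coords) != n:
            raise ValueError(f"expected {n} coordinates, got {len(coords)}")
        self.coords = coords
        self.n = n

    # -- update ------------------------------------------------------------
    def step_packed(self, state: int) -> int:
        out = 0
        for i, p in enumerate(self.coords):
            if p.evaluate_packed(state):
                out |= 1 << i
        return out

    def step(self, state: Sequence[int]) -> State:
        if len(state) != self.n:
            raise ValueError(f"state of length {len(state)} for model on n={self.n}")
        return unpack_state(self.step_packed(pack_state(state)), self.n)

    def simulate(self, s0: Sequence[int], steps: int) -> list[State]:
        """Trajectory of length ``steps`` starting at ``s0`` (inclusive)."""
        if steps < 1:
            raise ValueError("steps must be >= 1")
        s = pack_state(s0) if not isinstance(s0, int) else s0
        traj = [s]
        for _ in range(steps - 1):
            s = self.step_packed(s)
            traj.append(s)
        return [unpack_state(t, self.n) for t in traj]

    def simulate_packed(self, s0: int, steps: int) -> list[int]:
        if steps < 1:
            raise ValueError("steps must be >= 1")
        traj = [s0]
        s = s0
        for _ in range(steps - 1):
            s = self.step_packed(s)
            traj.append(s)
        return traj

    def sequential_step(self, state: Sequence[int], order: Sequence[int]) -> State:
        """Apply the coordinates one at a time in ``order`` (0-based), each
        update seeing the effect of the previous ones."""
        if sorted(order) != list(range(self.n)):
            raise ValueError("order must be a permutation of 0..n-1")
        s = pack_state(state)
        for i in order:
            bit = self.coords[i].evaluate_packed(s)
            s = (s & ~(1 << i)) | (bit << i)
        return unpack_state(s, self.n)

    # -- perturbation ------------------------------------------------------
    def knockout(self, r: int) -> "PolynomialModel":
        """The knock-out model ``f* = (f1, ..., 0, ..., fn)``: the silenced
        node's coordinate is the zero function (0-based index ``r``)."""
        if not 0 <= r < self.n:
            raise IndexError(f"knockout index {r} out of range for n={self.n}")
        coords = list(self.coords)
        coords[r] = BooleanPolynomial.zero(self.n)
        return PolynomialModel(coords)

    # -- attractors --------------------------------------------------------
    def steady_states(
        self,
        exhaustive_limit: int = 20,
        sample: bool = False,
        n_samples: int = 1000,
        max_steps: int = 200,
        rng=None,
    ) -> tuple[set[State], bool]:
        """Fixed points of ``f`` (states with ``f(s) = s``).

        Exhaustive over all ``2^n`` states for ``n <= exhaustive_limit``;
        above that, a trajectory-sampling mode must be requested explicitly
        and the second return value flags the result as non-exhaustive.

        Returns ``(states, exhaustive)``.
        """
        if self.n <= exhaustive_limit and not sample:
            found = {
                s for s in range(1 << self.n) if self.step_packed(s) == s
            }
            return ({unpack_state(s, self.n) for s in found}, True)
        if not sample:
            raise ValueError(
                f"n={self.n} exceeds the exhaustive limit {exhaustive_limit}; "
                "pass sample=True for (non-exhaustive) trajectory sampling"
            )
        import numpy as np

        rng = np.random.default_rng(rng)
        found = set()
        for _ in range(n_samples):
            s = pack_state(rng.integers(0, 2, size=self.n))
            for _ in range(max_steps):
                t = self.step_packed(s)
                if t == s:
                    found.add(s)
                    break
                s = t
        return ({unpack_state(s, self.n) for s in found}, False)

    # -- topology ----------------------------------------------------------
    def adjacency(self):
        """The wiring diagram ``V``: ``V[i][j] = 1`` iff variable ``x_{j+1}``
        appears in coordinate function ``f_{i+1}``.  Constants contribute no
        edges (their support is empty)."""
        import numpy as np

        V = np.zeros((self.n, self.n), dtype=np.int8)
        for i, p in enumerate(self.coords):
            for j in p.support:
                V[i, j] = 1
        return V

    # -- text format -------------------------------------------------------
    def to_text(self) -> str:
        return "\n".join(f"f{i + 1} = {p}" for i, p in enumerate(self.coords)) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PolynomialModel":
        """Parse the model text format: one ``f<i> = <polynomial>`` per line."""
        lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")]
        if not lines:
            raise ValueError("empty model text")
        n = len(lines)
        coords: list[BooleanPolynomial | None] = [None] * n
        for ln in lines:
            m = re.fullmatch(r"f(\d+)\s*=\s*(.+)", ln)
            if not m:
                raise ValueError(f"malformed model line {ln!r}")
            i = int(m.group(1))
            if not 1 <= i <= n or coords[i - 1] is not None:
                raise ValueError(f"bad or duplicate coordinate index f{i}")
            coords[i - 1] = BooleanPolynomial.parse(m.group(2), n)
        return cls([c for c in coords if c is not None])

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path) -> "PolynomialModel":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def key(self) -> str:
        """Canonical text key (deterministic tie-breaking and caching)."""
        return self.to_text()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PolynomialModel) and self.coords == other.coords

    def __hash__(self) -> int:
        return hash(self.coords)

    def __repr__(self) -> str:
        return f"PolynomialModel(n={self.n}, {'; '.join(str(p) for p in self.coords)})"


def all_update_orders(n: int) -> Iterator[tuple[int, ...]]:
    """All sequential update orders (for small-n schedule-invariance checks)."""
    return permutations(range(n))
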