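"""Coordinate model and combinatorics of the spliced/non-spliced peptide sequence space.

A substrate protein of length ``L`` can give rise to

* **non-spliced** peptides — contiguous substrings ``[i, j]``;
* **forward cis-spliced** peptides — two fragments (splice-reactants)
  ``[i, j]`` and ``[k, n]`` of the *same* molecule ligated in substrate
  order with at least one intervening residue (``k >= j + 2``);
* **reverse cis-spliced** peptides — two disjoint fragments ligated in
  inverted order (the first product reactant lies downstream:
  ``i >= n + 1``);
* **homologous trans-spliced** peptides — fragments whose substrate
  intervals overlap, so a single molecule cannot supply both and the
  product must arise from two copies of the same protein.

All coordinates are 1-based inclusive residue indices, and splice-reactant
lengths are bounded below by ``l_ext`` (default 1).  The closed-form counts
implemented here are exact and are cross-checked against the brute-force
enumerator :func:`brute_force_counts` in the test-suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterator, Mapping

__all__ = [
    "AA_ALPHABET",
    "ProductType",
    "ResolvedType",
    "Substrate",
    "SpaceParams",
    "ProductLocation",
    "PeptideProduct",
    "classify_tuple",
    "count_nonspliced",
    "count_forward_cis",
    "count_reverse_cis",
    "count_trans",
    "count_products",
    "enumerate_products",
    "brute_force_counts",
    "map_peptide",
    "canonical_sequence",
    "DEFAULT_RESIDUE_EQUIVALENCE",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_RE = re.compile(f"^[{AA_ALPHABET}]+$")

#: Leucine and isoleucine are isobaric and indistinguishable by MS2 mass
#: alone; mapping therefore treats them as equivalent by default.
DEFAULT_RESIDUE_EQUIVALENCE: Mapping[str, str] = {"I": "L"}


class ProductType(str, Enum):
    """Coordinate-level product classes."""

    NON_SPLICED = "non_spliced"
    CIS_FORWARD = "cis_forward"
    CIS_REVERSE = "cis_reverse"
    TRANS = "trans"


class ResolvedType(str, Enum):
    """Sequence-level class after multi-location arbitration."""

    NON_SPLICED = "non_spliced"
    CIS = "cis"
    TRANS = "trans"
    CIS_MULTI_MAPPER = "cis_multi_mapper"


@dataclass(frozen=True)
class Substrate:
    """A protein substrate over the canonical 20-letter alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("substrate sequence must be non-empty")
        if not _AA_RE.match(self.sequence):
            raise ValueError(
                f"substrate {self.id!r} contains characters outside the "
                f"canonical alphabet {AA_ALPHABET}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpaceParams:
    """Sequence-space parameters: product length ``n`` and minimal
    splice-reactant length ``l_ext``."""

    n: int
    l_ext: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("product length n must be >= 1")
        if self.l_ext < 1:
            raise ValueError("l_ext must be >= 1")

    def require_spliceable(self) -> None:
        if self.n < 2 * self.l_ext:
            raise ValueError(
                f"spliced products need n >= 2*l_ext (n={self.n}, l_ext={self.l_ext})"
            )


@dataclass(frozen=True)
class ProductLocation:
    """One substrate origin of a peptide product.

    ``sr1`` is the first splice-reactant *in product order*; for
    non-spliced products the ``sr2`` fields are ``None``.
    """

    product_type: ProductType
    sr1_start: int
    sr1_end: int
    sr2_start: int | None = None
    sr2_end: int | None = None

    def __post_init__(self) -> None:
        i, j, k, n = self.sr1_start, self.sr1_end, self.sr2_start, self.sr2_end
        if not (1 <= i <= j):
            raise ValueError(f"invalid sr1 interval ({i}, {j})")
        if self.product_type is ProductType.NON_SPLICED:
            if k is not None or n is not None:
                raise ValueError("non-spliced locations carry no second reactant")
            return
        if k is None or n is None:
            raise ValueError("spliced locations need a second reactant")
        if not (1 <= k <= n):
            raise ValueError(f"invalid sr2 interval ({k}, {n})")
        expected = classify_tuple(i, j, k, n)
        if expected is not self.product_type:
            raise ValueError(
                f"coordinates ({i},{j},{k},{n}) classify as {expected}, "
                f"not {self.product_type}"
            )

    @property
    def length(self) -> int:
        length = self.sr1_end - self.sr1_start + 1
        if self.sr2_start is not None:
            length += self.sr2_end - self.sr2_start + 1
        return length

    @property
    def splice_site(self) -> tuple[int, int] | None:
        """The (j, k) junction coordinate pair; ``None`` for non-spliced."""
        if self.product_type is ProductType.NON_SPLICED:
            return None
        return (self.sr1_end, self.sr2_start)

    def extract(self, substrate: Substrate | str) -> str:
        seq = substrate.sequence if isinstance(substrate, Substrate) else substrate
        out = seq[self.sr1_start - 1 : self.sr1_end]
        if self.sr2_start is not None:
            out += seq[self.sr2_start - 1 : self.sr2_end]
        return out


@dataclass(frozen=True)
class PeptideProduct:
    """A peptide sequence with all its substrate origins."""

    sequence: str
    locations: tuple[ProductLocation, ...]
    resolved_type: ResolvedType
    intensity: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.locations:
            raise ValueError("a peptide product needs at least one location")

    @property
    def n_origins(self) -> int:
        return len(self.locations)

    @property
    def is_spliced(self) -> bool:
        return self.resolved_type is not ResolvedType.NON_SPLICED


def classify_tuple(i: int, j: int, k: int, n: int) -> ProductType | None:
    """Classify a coordinate tuple (1-based, ``i<=j``, ``k<=n``).

    Returns ``None`` for forward-adjacent tuples (``k == j + 1``), whose
    product sequence equals a non-spliced peptide and which are therefore
    never counted or emitted as spliced.
    """
    if k >= j + 2:
        return ProductType.CIS_FORWARD
    if k == j + 1:
        return None
    if i >= n + 1:
        return ProductType.CIS_REVERSE
    # k <= j and i <= n here, hence the intervals overlap.
    return ProductType.TRANS


def _check_ln(length: int, n: int) -> None:
    if length < 1:
        raise ValueError("substrate length must be >= 1")
    if n < 1:
        raise ValueError("product length must be >= 1")


def count_nonspliced(length: int, n: int) -> int:
    """Number of non-spliced peptides of length ``n``: ``L - N + 1``."""
    _check_ln(length, n)
    return max(length - n + 1, 0)


def count_forward_cis(length: int, n: int, l_ext: int = 1) -> int:
    """Closed-form count of forward cis-spliced products of length ``n``."""
    _check_ln(length, n)
    SpaceParams(n, l_ext).require_spliceable()
    if length <= n:
        return 0
    return (n - 2 * l_ext + 1) * (length - n) * (length - n + 1) // 2


def count_reverse_cis(length: int, n: int, l_ext: int = 1) -> int:
    """Closed-form count of reverse cis-spliced products of length ``n``."""
    _check_ln(length, n)
    SpaceParams(n, l_ext).require_spliceable()
    if length < n:
        return 0
    return (n - 2 * l_ext + 1) * (length - n + 1) * (length - n + 2) // 2


def count_trans(length: int, n: int, l_ext: int = 1) -> int:
    """Closed-form count of homologous trans-spliced products of length ``n``.

    Equals the number of reactant coordinate pairs whose substrate
    intervals overlap (the two-molecule requirement).
    """
    _check_ln(length, n)
    SpaceParams(n, l_ext).require_spliceable()
    L, N, E = length, n, l_ext
    value = (
        Fraction(-1)
        + Fraction(2, 3) * E**3
        + E**2 * (-1 - N)
        + Fraction(5, 6) * N
        + N**2
        - Fraction(5, 6) * N**3
        + L * (-1 + E * (2 - 2 * N) + N**2)
        + E * (Fraction(7, 3) - 3 * N + 2 * N**2)
    )
    if value.denominator != 1:
        raise AssertionError("trans-count polynomial did not reduce to an integer")
    return max(int(value), 0)


_COUNTERS = {
    ProductType.NON_SPLICED: lambda L, n, e: count_nonspliced(L, n),
    ProductType.CIS_FORWARD: count_forward_cis,
    ProductType.CIS_REVERSE: count_reverse_cis,
    ProductType.TRANS: count_trans,
}


def count_products(length: int, params: SpaceParams, product_type: ProductType) -> int:
    """Closed-form count for one product type."""
    return _COUNTERS[ProductType(product_type)](length, params.n, params.l_ext)


def _reactant_lengths(params: SpaceParams) -> Iterator[tuple[int, int]]:
    for len1 in range(params.l_ext, params.n - params.l_ext + 1):
        yield len1, params.n - len1


def enumerate_products(
    substrate: Substrate,
    params: SpaceParams,
    product_type: ProductType | str,
) -> Iterator[tuple[ProductLocation, str]]:
    """Yield every valid coordinate tuple of one product type exactly once,
    with its product sequence.

    Only two-fragment ligation is modelled; three-fragment splicing is
    outside the coordinate system.
    """
    product_type = ProductType(product_type)
    L, N = substrate.length, params.n
    if product_type is ProductType.NON_SPLICED:
        for i in range(1, L - N + 2):
            loc = ProductLocation(product_type, i, i + N - 1)
            yield loc, loc.extract(substrate)
        return

    params.require_spliceable()
    for len1, len2 in _reactant_lengths(params):
        for i in range(1, L - len1 + 2):
            j = i + len1 - 1
            if product_type is ProductType.CIS_FORWARD:
                ks = range(j + 2, L - len2 + 2)
            elif product_type is ProductType.CIS_REVERSE:
                ks = range(1, i - len2 + 1)
            elif product_type is ProductType.TRANS:
                # overlap: k <= j and k + len2 - 1 >= i
                ks = range(max(1, i - len2 + 1), min(j, L - len2 + 1) + 1)
            else:  # pragma: no cover - enum is exhaustive
                raise ValueError(f"unknown product type {product_type}")
            for k in ks:
                loc = ProductLocation(product_type, i, j, k, k + len2 - 1)
                yield loc, loc.extract(substrate)


def brute_force_counts(
    length: int, n: int, l_ext: int = 1, cap: int = 50
) -> dict[ProductType, int]:
    """Exhaustively count coordinate tuples per product type.

    Loops over all (i, j, k, n) tuples with reactant lengths summing to the
    product length and classifies each by :func:`classify_tuple`; this is
    the independent oracle for the closed forms and deliberately shares no
    arithmetic with them.
    """
    _check_ln(length, n)
    if length > cap:
        raise ValueError(
            f"substrate length {length} exceeds the brute-force cap {cap}"
        )
    params = SpaceParams(n, l_ext)
    params.require_spliceable()
    counts = {t: 0 for t in ProductType}
    counts[ProductType.NON_SPLICED] = count_nonspliced(length, n)
    for len1, len2 in _reactant_lengths(params):
        for i in range(1, length - len1 + 2):
            j = i + len1 - 1
            for k in range(1, length - len2 + 2):
                kind = classify_tuple(i, j, k, k + len2 - 1)
                if kind is not None:
                    counts[kind] += 1
    return counts


def canonical_sequence(
    sequence: str,
    residue_equivalence: Mapping[str, str] = DEFAULT_RESIDUE_EQUIVALENCE,
) -> str:
    """Collapse mass-equivalent residues (by default I -> L)."""
    return sequence.translate(str.maketrans(dict(residue_equivalence)))


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of needle."""
    out = []
    start = haystack.find(needle)
    while start != -1:
        out.append(start + 1)
        start = haystack.find(needle, start + 1)
    return out


def map_peptide(
    sequence: str,
    substrate: Substrate,
    params: SpaceParams | None = None,
    residue_equivalence: Mapping[str, str] = DEFAULT_RESIDUE_EQUIVALENCE,
) -> PeptideProduct | None:
    """Map a peptide sequence onto a substrate.

    The full sequence is first matched exactly (under the residue
    equivalence); only if no contiguous occurrence exists is the sequence
    split into two splice-reactants at every internal position and each
    fragment pair located.  All valid locations are reported; the resolved
    type follows the precedence non-spliced > cis > trans, and a sequence
    explainable by both forward and reverse cis-splicing is flagged as a
    cis multi-mapper.  Returns ``None`` if the sequence cannot be explained
    by at most two fragments.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    if not _AA_RE.match(sequence):
        raise ValueError(f"invalid residues in peptide {sequence!r}")
    l_ext = params.l_ext if params is not None else 1

    pep = canonical_sequence(sequence, residue_equivalence)
    sub = canonical_sequence(substrate.sequence, residue_equivalence)

    exact = _find_all(sub, pep)
    if exact:
        locs = tuple(
            ProductLocation(ProductType.NON_SPLICED, s, s + len(pep) - 1)
            for s in exact
        )
        return PeptideProduct(sequence, locs, ResolvedType.NON_SPLICED)

    locations: list[ProductLocation] = []
    for split in range(l_ext, len(pep) - l_ext + 1):
        sr1, sr2 = pep[:split], pep[split:]
        starts1 = _find_all(sub, sr1)
        if not starts1:
            continue
        starts2 = _find_all(sub, sr2)
        for i in starts1:
            j = i + len(sr1) - 1
            for k in starts2:
                kind = classify_tuple(i, j, k, k + len(sr2) - 1)
                if kind is not None:
                    locations.append(
                        ProductLocation(kind, i, j, k, k + len(sr2) - 1)
                    )
    if not locations:
        return None
    locations = sorted(
        set(locations),
        key=lambda l: (l.sr1_start, l.sr1_end, l.sr2_start, l.sr2_end),
    )
    types = {loc.product_type for loc in locations}
    has_fwd = ProductType.CIS_FORWARD in types
    has_rev = ProductType.CIS_REVERSE in types
    if has_fwd and has_rev:
        resolved = ResolvedType.CIS_MULTI_MAPPER
    elif has_fwd or has_rev:
        resolved = ResolvedType.CIS
    else:
        resolved = ResolvedType.TRANS
    return PeptideProduct(sequence, tuple(locations), resolved)
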