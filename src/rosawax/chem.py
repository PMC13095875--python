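"""Chemical bookkeeping for cuticular wax analytes.

Compound identities (class, chain length, hydroxyl locants), nominal
masses, and the alpha-cleavage fragmentation model for trimethylsilyl
(TMS) ethers of mid-chain secondary alcohols.

Mid-chain secondary alcohols are analysed by GC-MS as their TMS ethers
(BSTFA derivatization). Electron-impact ionization cleaves the C-C bonds
on either side of the carbinol carbon ("alpha cleavage"), producing a
characteristic pair of even-electron cations, each retaining the
carbinol carbon and the OTMS group. For a chain of n carbons with the
hydroxyl at carbon k (lowest-locant convention), the nominal masses are

    low  = 14*k + 89        (short alkyl side, C_{k+3} H_{2k+9} O Si)
    high = 14*(n-k) + 103   (long alkyl side,  C_{n-k+4} H_{2(n-k)+11} O Si)

so that low + high = 14*n + 192 = tms_ether_mass(n) + 102. Because each
locant of one chain maps to a unique pair, the pair identifies the
hydroxyl position; e.g. nonacosan-10-ol (C29, k=10) gives m/z 229/369.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "CompoundClass",
    "CompoundIdentity",
    "FragmentPair",
    "NOMINAL_ATOMIC_MASS",
    "nominal_mass",
    "tms_ether_mass",
    "alpha_fragments",
    "position_from_fragments",
    "candidate_fragment_table",
    "CHAIN_PROFILE_CLASSES",
]

#: Nominal (integer) atomic masses. Printed GC-MS m/z values for TMS
#: derivatives are nominal, so monoisotopic masses are deliberately not used.
NOMINAL_ATOMIC_MASS: dict[str, int] = {"C": 12, "H": 1, "O": 16, "Si": 28}


class CompoundClass(str, enum.Enum):
    """The eight wax compound classes resolved by GC-FID/GC-MS."""

    ALDEHYDE = "aldehyde"
    ALKANE = "alkane"
    SECONDARY_ALCOHOL = "secondary_alcohol"
    DIOL = "diol"
    FATTY_ACID = "fatty_acid"
    PRIMARY_ALCOHOL = "primary_alcohol"
    ALKYL_ESTER = "alkyl_ester"
    TRITERPENOID = "triterpenoid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes included in overall chain-length profiles. Alkyl esters (two
#: moieties, reported only by total carbon count) and triterpenoids (no
#: aliphatic chain) are excluded.
CHAIN_PROFILE_CLASSES: frozenset[CompoundClass] = frozenset(
    {
        CompoundClass.ALDEHYDE,
        CompoundClass.ALKANE,
        CompoundClass.SECONDARY_ALCOHOL,
        CompoundClass.DIOL,
        CompoundClass.FATTY_ACID,
        CompoundClass.PRIMARY_ALCOHOL,
    }
)

_COMPOUND_RE = re.compile(
    r"^(?P<cls>[a-z_]+):(?:C(?P<chain>\d+))?(?::(?P<rest>.+))?$"
)


@dataclass(frozen=True, order=True)
class CompoundIdentity:
    """One wax analyte: class, carbon chain length, hydroxyl locants.

    Parameters
    ----------
    compound_class
        One of the eight wax classes.
    chain_length
        Carbon count. For alkyl esters this is the total ester carbon
        count (acid + alcohol moieties). Unset (``None``) for
        triterpenoids, which are identified by ``name`` instead.
    hydroxyl_positions
        Locants of mid-chain hydroxyl groups, lowest-locant convention;
        non-empty only for secondary alcohols and diols (and optional
        even there, when the isomer is unresolved).
    name
        Free-text identifier for triterpenoids, e.g. ``"ursolic_acid"``.
    """

    compound_class: CompoundClass
    chain_length: int | None = None
    hydroxyl_positions: tuple[int, ...] = field(default=())
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "compound_class", CompoundClass(self.compound_class)
        )
        object.__setattr__(
            self, "hydroxyl_positions", tuple(self.hydroxyl_positions)
        )
        cls = self.compound_class
        n = self.chain_length
        if cls is CompoundClass.TRITERPENOID:
            if not self.name:
                raise ValueError("triterpenoids require a name")
        elif n is None:
            raise ValueError(f"{cls.value} requires a chain length")
        if n is not None and n < 1:
            raise ValueError(f"chain length must be >= 1, got {n}")
        if self.hydroxyl_positions and cls not in (
            CompoundClass.SECONDARY_ALCOHOL,
            CompoundClass.DIOL,
        ):
            raise ValueError(
                f"hydroxyl positions not allowed on {cls.value}"
            )
        for p in self.hydroxyl_positions:
            assert n is not None
            if not 2 <= p <= n - 1:
                raise ValueError(
                    f"hydroxyl locant {p} outside [2, {n - 1}] for C{n}"
                )
        if cls is CompoundClass.SECONDARY_ALCOHOL:
            for p in self.hydroxyl_positions:
                if p > n + 1 - p:
                    raise ValueError(
                        f"locant {p} of C{n} violates the lowest-locant "
                        f"convention (use {n + 1 - p})"
                    )

    def to_string(self) -> str:
        """Canonical string, grammar ``CLASS:Cnn[:OH=k[,k2]]``.

        Triterpenoids serialize as ``triterpenoid::name``.
        """
        if self.compound_class is CompoundClass.TRITERPENOID:
            return f"triterpenoid::{self.name}"
        s = f"{self.compound_class.value}:C{self.chain_length}"
        if self.hydroxyl_positions:
            s += ":OH=" + ",".join(str(p) for p in self.hydroxyl_positions)
        return s

    @classmethod
    def from_string(cls, text: str) -> "CompoundIdentity":
        """Parse the canonical grammar back into an identity."""
        m = _COMPOUND_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse compound string {text!r}")
        try:
            ccls = CompoundClass(m.group("cls"))
        except ValueError:
            raise ValueError(
                f"unknown compound class {m.group('cls')!r} in {text!r}"
            ) from None
        chain = m.group("chain")
        rest = m.group("rest")
        positions: tuple[int, ...] = ()
        name = ""
        if rest:
            if rest.startswith("OH="):
                positions = tuple(int(p) for p in rest[3:].split(","))
            else:
                name = rest
        return cls(
            compound_class=ccls,
            chain_length=int(chain) if chain else None,
            hydroxyl_positions=positions,
            name=name,
        )

    def __str__(self) -> str:
        return self.to_string()


@dataclass(frozen=True)
class FragmentPair:
    """The two alpha-cleavage ions diagnostic for one positional isomer."""

    low_mz: int
    high_mz: int
    position: int
    chain_length: int

    def __post_init__(self) -> None:
        if self.low_mz > self.high_mz:
            raise ValueError("low_mz must be <= high_mz")
        if self.low_mz + self.high_mz != 14 * self.chain_length + 192:
            raise ValueError(
                f"fragment pair ({self.low_mz}, {self.high_mz}) violates the "
                f"conservation identity for C{self.chain_length}"
            )

    def __iter__(self):
        return iter((self.low_mz, self.high_mz))


def nominal_mass(formula: dict[str, int]) -> int:
    """Nominal mass of a formula given as an element -> count map.

    Only C, H, O and Si are supported (the elements occurring in TMS
    derivatives of aliphatic wax compounds).
    """
    total = 0
    for element, count in formula.items():
        if element not in NOMINAL_ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        total += NOMINAL_ATOMIC_MASS[element] * count
    return total


def tms_ether_mass(n: int) -> int:
    """Nominal molecular mass of the TMS ether of a C_n secondary alcohol.

    Equal to ``nominal_mass`` of C_{n}H_{2n+1}-O-Si(CH3)3, i.e. 14n + 90.
    """
    if n < 3:
        raise ValueError(
            f"chain length {n} has no mid-chain hydroxyl position"
        )
    return 14 * n + 90


def alpha_fragments(n: int, k: int) -> FragmentPair:
    """Diagnostic alpha-cleavage ion pair for a C_n secondary alcohol, OH at C_k.

    Both ions retain the carbinol carbon and the OTMS group; masses are
    14k + 89 (short side) and 14(n-k) + 103 (long side), returned sorted
    ascending. ``k`` must be given in the lowest-locant convention.

    >>> tuple(alpha_fragments(29, 10))
    (229, 369)
    """
    if not 2 <= k <= n - 1:
        raise ValueError(f"hydroxyl locant {k} outside [2, {n - 1}] for C{n}")
    if k > (n + 1) / 2:
        raise ValueError(
            f"locant {k} of C{n} is not the lowest locant; use {n + 1 - k}"
        )
    a = 14 * k + 89
    b = 14 * (n - k) + 103
    return FragmentPair(
        low_mz=min(a, b), high_mz=max(a, b), position=k, chain_length=n
    )


def position_from_fragments(n: int, observed) -> int:
    """Infer the hydroxyl locant from an observed alpha-fragment pair.

    Inverse of :func:`alpha_fragments`. ``observed`` is any pair of
    integer m/z values (order irrelevant).
    """
    mzs = sorted(observed)
    if len(mzs) != 2:
        raise ValueError("expected exactly two m/z values")
    low, high = mzs
    if low + high != 14 * n + 192:
        raise ValueError(
            f"({low}, {high}) is not an alpha-fragment pair for chain "
            f"length {n} (sum {low + high} != {14 * n + 192})"
        )
    # One of the two ions is the short-side fragment 14k + 89.
    for candidate in (low, high):
        if (candidate - 89) % 14 == 0:
            k = (candidate - 89) // 14
            if 2 <= k <= (n + 1) / 2:
                pair = alpha_fragments(n, k)
                if (pair.low_mz, pair.high_mz) == (low, high):
                    return k
    raise ValueError(
        f"no valid hydroxyl locant of C{n} matches fragments ({low}, {high})"
    )


def candidate_fragment_table(n: int, positions: list[int]) -> list[FragmentPair]:
    """Fragment pairs for several candidate locants of one homologue.

    Used to precompute extraction targets for isomer quantification.
    Distinct locants of one chain never share a fragment m/z (the low
    series 14k+89 and high series 14(n-k)+103 are strictly monotonic in
    k), which is asserted defensively.
    """
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate hydroxyl positions requested")
    pairs = [alpha_fragments(n, k) for k in positions]
    seen: dict[int, int] = {}
    for pair in pairs:
        for mz in (pair.low_mz, pair.high_mz):
            if mz in seen and seen[mz] != pair.position:
                raise ValueError(
                    f"fragment m/z {mz} shared between locants"
                )  # pragma: no cover - impossible for one chain
            seen[mz] = pair.position
    return pairs
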