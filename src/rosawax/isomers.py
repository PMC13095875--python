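"""Positional-isomer quantification for wax secondary alcohols.

Relative amounts of positional isomers within one GC peak are obtained
from the peak's electron-impact mass spectrum: each isomer contributes a
characteristic pair of alpha-cleavage fragments, and its score is the
average abundance of those two ions. Scores are normalized across the
candidate isomers to yield fractions.

Spectra are handled at unit (nominal) mass resolution; fragment lookup
is exact on integer m/z. Homologues are assumed chromatographically
separated, so isobaric fragment overlap between homologues (e.g. m/z 369
from C29 k=10 and from C27 k=8) is not deconvolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .chem import alpha_fragments, candidate_fragment_table

__all__ = [
    "MassSpectrum",
    "IsomerProfile",
    "fragment_intensity",
    "quantify_isomers",
    "scan_positions",
    "parity_summary",
    "asymmetry_ratio",
]


@dataclass(frozen=True)
class MassSpectrum:
    """Unit-resolution mass spectrum of one GC peak.

    ``peaks`` is a sequence of (integer m/z, non-negative intensity)
    pairs; m/z values must be unique. ``chain_length`` records the
    homologue the peak was assigned to.
    """

    peaks: tuple[tuple[int, float], ...]
    peak_id: str = ""
    chain_length: int | None = None

    def __post_init__(self) -> None:
        pk = tuple((int(mz), float(i)) for mz, i in self.peaks)
        object.__setattr__(self, "peaks", pk)
        mzs = [mz for mz, _ in pk]
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"duplicate m/z values in spectrum {self.peak_id!r}")
        for mz, intensity in pk:
            if intensity < 0:
                raise ValueError(
                    f"negative intensity at m/z {mz} in {self.peak_id!r}"
                )

    def intensity_map(self) -> dict[int, float]:
        return dict(self.peaks)


@dataclass(frozen=True)
class IsomerProfile:
    """Relative amounts of hydroxyl-position isomers of one homologue."""

    chain_length: int
    fractions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fractions:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"isomer fractions sum to {total}, expected 1"
                )
        for k in self.fractions:
            alpha_fragments(self.chain_length, k)  # validates the locant

    def dominant_position(self) -> int:
        """Locant with the largest fraction (smallest locant on ties)."""
        return min(self.fractions, key=lambda k: (-self.fractions[k], k))


def fragment_intensity(spectrum: MassSpectrum, mz: int) -> float:
    """Intensity at exactly the given nominal m/z; 0 if the ion is absent."""
    return spectrum.intensity_map().get(int(mz), 0.0)


def quantify_isomers(
    spectrum: MassSpectrum, positions: list[int]
) -> IsomerProfile:
    """Relative isomer fractions from the two alpha-fragments per isomer.

    For each candidate locant ``k`` the score is the mean intensity of
    its low- and high-mass alpha fragments; fractions are scores
    normalized to sum to 1. Candidates with zero score keep fraction 0.

    Raises ``ValueError`` if no candidate has any fragment signal. A
    strong disagreement between the two fragments of one isomer
    (intensity ratio > 5) triggers a warning but the mean is kept.
    """
    if spectrum.chain_length is None:
        raise ValueError("spectrum has no assigned chain length")
    n = spectrum.chain_length
    pairs = candidate_fragment_table(n, positions)
    intensities = spectrum.intensity_map()
    scores: dict[int, float] = {}
    for pair in pairs:
        lo = intensities.get(pair.low_mz, 0.0)
        hi = intensities.get(pair.high_mz, 0.0)
        if lo > 0 and hi > 0 and max(lo, hi) / min(lo, hi) > 5:
            warnings.warn(
                f"alpha-fragments {pair.low_mz}/{pair.high_mz} of C{n} "
                f"k={pair.position} disagree by more than 5-fold "
                f"({lo:g} vs {hi:g}); using their mean",
                stacklevel=2,
            )
        scores[pair.position] = (lo + hi) / 2.0
    total = sum(scores.values())
    if total == 0:
        raise ValueError(
            f"no candidate isomer fragments detected in spectrum "
            f"{spectrum.peak_id!r} (C{n}, positions {sorted(positions)})"
        )
    return IsomerProfile(
        chain_length=n,
        fractions={k: s / total for k, s in scores.items()},
    )


def scan_positions(
    spectrum: MassSpectrum,
    k_range: tuple[int, int] | None = None,
    floor: float = 0.0,
) -> list[int]:
    """Locants whose BOTH alpha-fragments exceed ``floor`` in the spectrum.

    Single-ion evidence is treated as absence (conservative
    identification). ``k_range`` defaults to all lowest locants of the
    spectrum's chain length.
    """
    if spectrum.chain_length is None:
        raise ValueError("spectrum has no assigned chain length")
    n = spectrum.chain_length
    k_max_valid = (n + 1) // 2
    if k_range is None:
        k_range = (2, k_max_valid)
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi > (n + 1) / 2:
        raise ValueError(
            f"locant range [{k_lo}, {k_hi}] outside [2, {(n + 1) / 2:g}] "
            f"for C{n}"
        )
    intensities = spectrum.intensity_map()
    found = []
    for k in range(k_lo, k_hi + 1):
        pair = alpha_fragments(n, k)
        if (
            intensities.get(pair.low_mz, 0.0) > floor
            and intensities.get(pair.high_mz, 0.0) > floor
        ):
            found.append(k)
    return found


def parity_summary(profiles: list[IsomerProfile]) -> dict[str, float]:
    """Summed even- vs odd-locant fractions, renormalized over all profiles.

    Used to test whether hydroxyls occur on both even- and odd-numbered
    carbons (the signature of alkane mid-chain hydroxylation, as opposed
    to head-to-head condensation which yields even locants only).
    """
    if not profiles:
        raise ValueError("no isomer profiles given")
    even = sum(
        f for p in profiles for k, f in p.fractions.items() if k % 2 == 0
    )
    odd = sum(
        f for p in profiles for k, f in p.fractions.items() if k % 2 == 1
    )
    total = even + odd
    if total == 0:
        return {"even": 0.0, "odd": 0.0}
    return {"even": even / total, "odd": odd / total}


def asymmetry_ratio(n: int, k: int) -> float:
    """Ratio of alkyl carbons on the short vs long side of the hydroxyl.

    ``(k - 1) / (n - k)``: carbons C1..C(k-1) against C(k+1)..Cn. The
    1:2 asymmetry characteristic of Rosaceae secondary alcohols gives
    values near 0.5 (e.g. 11-hentriacontanol: 10/20 exactly); a
    mid-chain hydroxyl (15-nonacosanol) gives 1.0. Any mid-chain locant
    2 <= k <= n-1 is accepted, not only the lowest locant.
    """
    if not 2 <= k <= n - 1:
        raise ValueError(f"hydroxyl locant {k} outside [2, {n - 1}] for C{n}")
    return (k - 1) / (n - k)
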