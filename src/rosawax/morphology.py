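"""Rule-based prediction of epicuticular wax crystal morphology.

Epicuticular wax crystals (EWCs) self-assemble when specific
crystallizing compounds accumulate beyond a phase-separation threshold
(~15 % of the wax mixture). Two chemistry-structure relationships are
encoded as an ordered rule cascade (first match wins):

R1 tubules
    Secondary alcohols at or above the threshold, dominated by the C29
    homologue with hydroxyl at/near C-10 (nonacosan-10-ol); alkanediols
    present in the mixture co-crystallize and are recorded as
    supporting evidence.
R2 irregular platelets
    Combined C31 + C33 alkanes at or above the threshold together with
    any C31/C33 secondary alcohols of the same chain lengths, which are
    thought to co-crystallize on the alkane scaffold.
R3 film or crust (default)
    No crystallizer reaches the threshold; when a non-crystallizing
    class (triterpenoids, which partition intracuticularly, or alkyl
    esters) dominates at >= 25 %, it is recorded in the trace.

The thresholds apply to total-wax shares; epicuticular concentrations
are expected to be equal or higher, so the calls are conservative.
Calls are whole-leaf: per-surface (abaxial/adaxial) differences such as
upright adaxial platelets have no known compositional rule and are not
modelled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .chem import CompoundClass
from .isomers import IsomerProfile
from .quantify import SampleProfile, class_relative, total_load

__all__ = [
    "Morphology",
    "MorphologyCall",
    "crystallizer_share",
    "predict_morphology",
]

#: Phase-separation threshold (percent of total wax) above which a
#: crystallizing compound class can form epicuticular crystals.
DEFAULT_THETA = 15.0

#: Share above which a dominant non-crystallizing class is reported in
#: the film/crust trace.
NONCRYSTALLIZER_REPORT_SHARE = 25.0


class Morphology(str, enum.Enum):
    TUBULES = "tubules"
    IRREGULAR_PLATELETS = "irregular_platelets"
    FILM_OR_CRUST = "film_or_crust"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MorphologyCall:
    """Categorical morphology prediction with the rule trace that fired."""

    call: Morphology
    fired_rules: tuple[tuple[str, dict], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.fired_rules:
            raise ValueError("a morphology call must carry a rule trace")


def crystallizer_share(profile: SampleProfile) -> dict[str, float]:
    """Percent shares tested by the morphology rules.

    Keys: ``R1`` (secondary alcohols), ``R2`` (C31 + C33 alkanes),
    ``diol``, ``triterpenoid``, ``alkyl_ester``.
    """
    total = total_load(profile)
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id!r} has zero total load")
    rel = class_relative(profile)
    c31_c33_alkane = 100.0 * sum(
        load
        for c, load in profile.loads.items()
        if c.compound_class is CompoundClass.ALKANE
        and c.chain_length in (31, 33)
    ) / total
    return {
        "R1": rel[CompoundClass.SECONDARY_ALCOHOL],
        "R2": c31_c33_alkane,
        "diol": rel[CompoundClass.DIOL],
        "triterpenoid": rel[CompoundClass.TRITERPENOID],
        "alkyl_ester": rel[CompoundClass.ALKYL_ESTER],
    }


def _dominant_secondary_alcohol_chain(profile: SampleProfile) -> int | None:
    by_chain: dict[int, float] = {}
    for c, load in profile.loads.items():
        if c.compound_class is CompoundClass.SECONDARY_ALCOHOL and load > 0:
            by_chain[c.chain_length] = by_chain.get(c.chain_length, 0.0) + load
    if not by_chain:
        return None
    return min(by_chain, key=lambda n: (-by_chain[n], n))


def predict_morphology(
    profile: SampleProfile,
    isomers: dict[int, IsomerProfile] | None = None,
    theta: float = DEFAULT_THETA,
) -> MorphologyCall:
    """Predict the epicuticular wax crystal morphology of one profile.

    ``isomers`` optionally maps secondary-alcohol chain length to its
    positional-isomer profile; when given, the tubule rule additionally
    requires the dominant C29 hydroxyl locant to lie in {9, 10, 11}.
    ``theta`` is the crystallizer threshold in percent of total wax.
    """
    shares = crystallizer_share(profile)
    trace: list[tuple[str, dict]] = []

    # R1: tubules from nonacosan-10-ol (+/- adjacent locants)
    if shares["R1"] >= theta:
        dom_chain = _dominant_secondary_alcohol_chain(profile)
        locant_ok = True
        dom_locant = None
        if isomers is not None and dom_chain is not None:
            prof = isomers.get(dom_chain)
            if prof is not None and prof.fractions:
                dom_locant = prof.dominant_position()
                locant_ok = dom_locant in (9, 10, 11)
        if dom_chain == 29 and locant_ok:
            evidence = {
                "secondary_alcohol_pct": shares["R1"],
                "dominant_chain": dom_chain,
                "theta": theta,
            }
            if dom_locant is not None:
                evidence["dominant_locant"] = dom_locant
            if shares["diol"] > 0:
                evidence["diol_pct"] = shares["diol"]
            trace.append(("R1", evidence))
            return MorphologyCall(Morphology.TUBULES, tuple(trace))

    # R2: irregular platelets from C31/C33 alkanes + same-chain sec-OHs
    if shares["R2"] >= theta:
        sec_31_33 = sum(
            load
            for c, load in profile.loads.items()
            if c.compound_class is CompoundClass.SECONDARY_ALCOHOL
            and c.chain_length in (31, 33)
            and load > 0
        )
        if sec_31_33 > 0:
            trace.append(
                (
                    "R2",
                    {
                        "c31_c33_alkane_pct": shares["R2"],
                        "c31_c33_secondary_alcohol_load": sec_31_33,
                        "theta": theta,
                    },
                )
            )
            return MorphologyCall(Morphology.IRREGULAR_PLATELETS, tuple(trace))

    # R3: default film or crust
    evidence = {"theta": theta, **shares}
    dominant_nc = max(
        ("triterpenoid", "alkyl_ester"), key=lambda k: shares[k]
    )
    if shares[dominant_nc] >= NONCRYSTALLIZER_REPORT_SHARE:
        evidence["dominant_noncrystallizer"] = dominant_nc
    trace.append(("R3", evidence))
    return MorphologyCall(Morphology.FILM_OR_CRUST, tuple(trace))
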