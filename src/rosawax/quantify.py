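"""Internal-standard quantification of wax loads and profile aggregation.

Each compound's wax load (ug cm^-2) is obtained by comparing its GC peak
area with the internal-standard (tetracosane) peak area, scaling by the
spiked IS mass, and dividing by the extracted leaf surface area. An FID
response factor of 1 is assumed for all analytes relative to the
internal standard.

Loads aggregate into per-sample totals, compound-class percentages,
chain-length percentages (over the six aliphatic chain classes:
aldehydes, alkanes, secondary alcohols, diols, fatty acids, primary
alcohols — alkyl esters and triterpenoids excluded), load-weighted
average chain lengths, and per-species mean / standard-error summaries.
Compounds absent from a replicate are measured zeros, not missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .chem import CHAIN_PROFILE_CLASSES, CompoundClass, CompoundIdentity

__all__ = [
    "PeakRecord",
    "SampleMeta",
    "SampleProfile",
    "compound_load",
    "build_profiles",
    "total_load",
    "class_relative",
    "chain_length_relative",
    "average_chain_length",
    "species_summary",
    "trait_total_load",
    "trait_class_percent",
    "trait_chain_percent",
]


@dataclass(frozen=True)
class PeakRecord:
    """One integrated GC peak of one sample."""

    sample_id: str
    compound: CompoundIdentity | None
    area: float
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(
                f"negative peak area in sample {self.sample_id!r}"
            )
        if not self.is_internal_standard and self.compound is None:
            raise ValueError(
                f"analyte peak without compound identity in sample "
                f"{self.sample_id!r}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata needed for quantification."""

    sample_id: str
    species: str
    subfamily: str
    replicate: int
    leaf_area_cm2: float
    is_mass_ug: float

    def __post_init__(self) -> None:
        if self.leaf_area_cm2 <= 0:
            raise ValueError(f"leaf_area_cm2 must be > 0 for {self.sample_id!r}")
        if self.is_mass_ug <= 0:
            raise ValueError(f"is_mass_ug must be > 0 for {self.sample_id!r}")


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample wax loads (ug cm^-2) by compound, with metadata."""

    sample_id: str
    loads: dict[CompoundIdentity, float] = field(default_factory=dict)
    meta: SampleMeta | None = None


def compound_load(
    area: float, is_area: float, is_mass_ug: float, leaf_area_cm2: float
) -> float:
    """Wax load (ug cm^-2) from a peak area via the internal standard.

    ``(area / is_area) * is_mass_ug / leaf_area_cm2``, response factor 1.
    """
    if is_area <= 0:
        raise ValueError("internal standard missing/zero")
    if leaf_area_cm2 <= 0:
        raise ValueError("leaf area must be positive")
    return (area / is_area) * is_mass_ug / leaf_area_cm2


def build_profiles(
    records: Iterable[PeakRecord], metas: Iterable[SampleMeta]
) -> list[SampleProfile]:
    """Convert peak records into per-sample load profiles.

    Every sample must have metadata and exactly one internal-standard
    record. Profiles are ordered by sample id; loads within a profile
    by the canonical compound string.
    """
    meta_by_id = {m.sample_id: m for m in metas}
    by_sample: dict[str, list[PeakRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)

    profiles = []
    for sample_id in sorted(by_sample):
        if sample_id not in meta_by_id:
            raise ValueError(f"no metadata for sample {sample_id!r}")
        meta = meta_by_id[sample_id]
        is_recs = [r for r in by_sample[sample_id] if r.is_internal_standard]
        if not is_recs:
            raise ValueError(
                f"sample {sample_id!r} has no internal-standard record"
            )
        if len(is_recs) > 1:
            raise ValueError(
                f"sample {sample_id!r} has {len(is_recs)} internal-standard "
                f"records, expected exactly 1"
            )
        is_area = is_recs[0].area
        analytes = sorted(
            (r for r in by_sample[sample_id] if not r.is_internal_standard),
            key=lambda r: r.compound.to_string(),
        )
        loads: dict[CompoundIdentity, float] = {}
        for rec in analytes:
            load = compound_load(
                rec.area, is_area, meta.is_mass_ug, meta.leaf_area_cm2
            )
            loads[rec.compound] = loads.get(rec.compound, 0.0) + load
        profiles.append(
            SampleProfile(sample_id=sample_id, loads=loads, meta=meta)
        )
    return profiles


def total_load(profile: SampleProfile) -> float:
    """Total wax load over all compounds, triterpenoids and esters included."""
    return sum(profile.loads.values())


def class_relative(profile: SampleProfile) -> dict[CompoundClass, float]:
    """Per-class percentage of the total wax load; sums to 100."""
    total = total_load(profile)
    if total <= 0:
        raise ValueError(
            f"sample {profile.sample_id!r} has zero total load"
        )
    out = {cls: 0.0 for cls in CompoundClass}
    for compound, load in profile.loads.items():
        out[compound.compound_class] += load
    return {cls: 100.0 * v / total for cls, v in out.items()}


def chain_length_relative(profile: SampleProfile) -> dict[int, float]:
    """Chain-length percentages over the six aliphatic chain classes.

    Loads are summed per carbon number across aldehydes, alkanes,
    secondary alcohols, diols, fatty acids and primary alcohols, then
    normalized to 100. Alkyl esters (total-carbon chain of two moieties)
    and triterpenoids are excluded.
    """
    sums: dict[int, float] = {}
    for compound, load in profile.loads.items():
        if compound.compound_class in CHAIN_PROFILE_CLASSES:
            n = compound.chain_length
            sums[n] = sums.get(n, 0.0) + load
    total = sum(sums.values())
    if total <= 0:
        raise ValueError(
            f"sample {profile.sample_id!r} has no compounds in the "
            f"chain-length profile classes"
        )
    return {n: 100.0 * v / total for n, v in sorted(sums.items())}


def average_chain_length(
    profile: SampleProfile, class_filter: CompoundClass | None = None
) -> float:
    """Load-weighted mean carbon number, optionally within one class."""
    pairs = [
        (c.chain_length, w)
        for c, w in profile.loads.items()
        if c.chain_length is not None
        and (class_filter is None or c.compound_class == class_filter)
        and w > 0
    ]
    if not pairs:
        raise ValueError(
            f"no compounds with chain lengths after filtering "
            f"({class_filter})"
        )
    weight = sum(w for _, w in pairs)
    return sum(n * w for n, w in pairs) / weight


# --- per-species summaries ------------------------------------------------

def trait_total_load(profile: SampleProfile) -> dict[str, float]:
    return {"total_load": total_load(profile)}


def trait_class_percent(profile: SampleProfile) -> dict[str, float]:
    return {cls.value: pct for cls, pct in class_relative(profile).items()}


def trait_chain_percent(profile: SampleProfile) -> dict[str, float]:
    return {f"C{n}": pct for n, pct in chain_length_relative(profile).items()}


def species_summary(
    profiles: Iterable[SampleProfile],
    statistic: Callable[[SampleProfile], Mapping[str, float]] = trait_total_load,
) -> pd.DataFrame:
    """Mean, standard error and n of a trait set per species.

    ``statistic`` maps a profile to ``{trait: value}``; traits missing
    in a replicate (e.g. a compound class not detected there) count as
    measured zeros. SE = sd / sqrt(n) with the sample sd (ddof=1); a
    species with a single replicate gets SE = NaN.

    Returns a tidy frame with columns species, trait, mean, se, n.
    """
    rows = []
    for p in profiles:
        if p.meta is None:
            raise ValueError(f"profile {p.sample_id!r} lacks metadata")
        for trait, value in statistic(p).items():
            rows.append((p.meta.species, p.sample_id, trait, value))
    if not rows:
        raise ValueError("no profiles given")
    long = pd.DataFrame(rows, columns=["species", "sample_id", "trait", "value"])
    # absent trait in a replicate = measured zero
    wide = (
        long.pivot_table(
            index=["species", "sample_id"],
            columns="trait",
            values="value",
            fill_value=0.0,
        )
        .reset_index()
    )
    out = []
    for species, grp in wide.groupby("species", sort=True):
        n = len(grp)
        for trait in wide.columns:
            if trait in ("species", "sample_id"):
                continue
            vals = grp[trait].to_numpy(dtype=float)
            mean = float(vals.mean())
            se = (
                float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            )
            out.append((species, trait, mean, se, n))
    return pd.DataFrame(out, columns=["species", "trait", "mean", "se", "n"])
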