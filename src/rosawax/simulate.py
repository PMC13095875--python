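"""Synthetic GC peak tables, metadata and mass spectra with known truth.

The generator emulates the study design of a comparative leaf-wax
survey: species from two subfamilies, five biological replicates each,
eight compound classes over chain lengths roughly C20-C46 (C20-C33 for
the aliphatic chain classes), secondary-alcohol isomer mixtures with
hydroxyls at C-8..C-12, and multiplicative (lognormal) replicate noise.

Every quantity is generated by inverting the analysis equations: true
compound loads follow from the configured totals, class percentages and
chain weights; peak areas are the loads pushed back through the
internal-standard equation; secondary-alcohol spectra carry
alpha-fragment intensities exactly proportional to the configured
isomer fractions (plus non-diagnostic background ions). At zero noise
the full analysis chain therefore recovers the configuration exactly.
All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import CompoundClass, CompoundIdentity, alpha_fragments, tms_ether_mass
from .isomers import MassSpectrum
from .quantify import PeakRecord, SampleMeta

__all__ = [
    "SpeciesSpec",
    "SyntheticDataset",
    "default_panel",
    "generate",
    "perturb_isomers",
    "true_loads",
]

#: Fixed internal-standard peak area (detector counts). The IS area
#: carries no noise so that quantification noise is attributable to the
#: analytes; configurable through :func:`generate`.
DEFAULT_IS_AREA = 1.0e6


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground-truth wax profile of one synthetic species.

    ``class_percent`` must sum to 100. ``chain_distribution`` maps each
    class to relative weights per carbon number (per compound name for
    triterpenoids); weights are normalized within the class.
    ``isomer_spec`` maps secondary-alcohol chain lengths to hydroxyl
    locant fractions (each summing to 1). ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal replicate
    noise applied per compound (and per spectrum fragment).
    """

    name: str
    subfamily: str
    total_load_ug_cm2: float
    class_percent: dict[CompoundClass, float]
    chain_distribution: dict[CompoundClass, dict] = field(default_factory=dict)
    isomer_spec: dict[int, dict[int, float]] = field(default_factory=dict)
    n_replicates: int = 5
    noise_cv: float = 0.15

    def __post_init__(self) -> None:
        cp = {CompoundClass(c): float(v) for c, v in self.class_percent.items()}
        object.__setattr__(self, "class_percent", cp)
        cd = {
            CompoundClass(c): dict(w)
            for c, w in self.chain_distribution.items()
        }
        object.__setattr__(self, "chain_distribution", cd)
        if self.total_load_ug_cm2 <= 0:
            raise ValueError(f"{self.name}: total_load_ug_cm2 must be > 0")
        if self.n_replicates < 1:
            raise ValueError(f"{self.name}: n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError(f"{self.name}: noise_cv must be >= 0")
        total = sum(cp.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(
                f"{self.name}: class_percent sums to {total}, expected 100"
            )
        for cls, pct in cp.items():
            if pct < 0:
                raise ValueError(f"{self.name}: negative percent for {cls}")
            if pct > 0 and not cd.get(cls):
                raise ValueError(
                    f"{self.name}: class {cls.value} has {pct}% but no "
                    f"chain_distribution entry"
                )
        for cls, weights in cd.items():
            for key, w in weights.items():
                if w < 0:
                    raise ValueError(
                        f"{self.name}: negative chain weight {cls.value}:{key}"
                    )
        for n, fracs in self.isomer_spec.items():
            s = sum(fracs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: isomer fractions for C{n} sum to {s}"
                )
            for k in fracs:
                alpha_fragments(n, k)  # validates locants


def true_loads(spec: SpeciesSpec) -> dict[CompoundIdentity, float]:
    """Noise-free per-compound loads (ug cm^-2) implied by a spec."""
    loads: dict[CompoundIdentity, float] = {}
    for cls, pct in spec.class_percent.items():
        if pct == 0:
            continue
        weights = spec.chain_distribution[cls]
        total_w = sum(weights.values())
        if total_w <= 0:
            raise ValueError(
                f"{spec.name}: class {cls.value} has no positive chain weight"
            )
        class_load = spec.total_load_ug_cm2 * pct / 100.0
        for key, w in sorted(weights.items(), key=lambda kv: str(kv[0])):
            if w == 0:
                continue
            if cls is CompoundClass.TRITERPENOID:
                compound = CompoundIdentity(cls, name=str(key))
            else:
                compound = CompoundIdentity(cls, chain_length=int(key))
            loads[compound] = class_load * w / total_w
    return loads


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated peak records, metadata, spectra and their ground truth."""

    records: tuple[PeakRecord, ...]
    metas: tuple[SampleMeta, ...]
    spectra: dict[str, dict[int, MassSpectrum]]  # sample -> chain -> spectrum
    specs: tuple[SpeciesSpec, ...]
    seed: int
    is_area: float


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise factor with unit mean and the given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _background_ions(
    rng: np.random.Generator,
    n: int,
    diagnostic: set[int],
    max_intensity: float,
    count: int = 8,
) -> list[tuple[int, float]]:
    """Non-diagnostic background ions at 10-20 % of the strongest fragment."""
    upper = tms_ether_mass(n)
    candidates = [
        mz for mz in range(60, upper + 1) if mz not in diagnostic
    ]
    chosen = rng.choice(len(candidates), size=min(count, len(candidates)),
                        replace=False)
    return [
        (candidates[i], float(rng.uniform(0.10, 0.20)) * max_intensity)
        for i in sorted(chosen)
    ]


def generate(
    specs: list[SpeciesSpec],
    seed: int,
    is_mass_ug: float = 10.0,
    leaf_area_cm2: float = 5.0,
    is_area: float = DEFAULT_IS_AREA,
    background_ion_count: int = 8,
) -> SyntheticDataset:
    """Generate a reproducible synthetic dataset from species specs.

    For each species x replicate, per-compound true loads are perturbed
    by lognormal noise (unit-mean, CV = ``spec.noise_cv``) and inverted
    through the internal-standard equation into peak areas; one
    noise-free internal-standard record per sample uses ``is_area``.
    Secondary-alcohol homologues listed in ``isomer_spec`` also get a
    mass spectrum whose two alpha-fragments per isomer are proportional
    to the isomer fraction (same per-fragment noise model) on top of
    background ions at non-diagnostic m/z.
    """
    rng = np.random.default_rng(seed)
    records: list[PeakRecord] = []
    metas: list[SampleMeta] = []
    spectra: dict[str, dict[int, MassSpectrum]] = {}

    for spec in specs:
        loads = true_loads(spec)
        for rep in range(1, spec.n_replicates + 1):
            sample_id = f"{spec.name}_r{rep}"
            metas.append(
                SampleMeta(
                    sample_id=sample_id,
                    species=spec.name,
                    subfamily=spec.subfamily,
                    replicate=rep,
                    leaf_area_cm2=leaf_area_cm2,
                    is_mass_ug=is_mass_ug,
                )
            )
            records.append(
                PeakRecord(
                    sample_id=sample_id,
                    compound=None,
                    area=is_area,
                    is_internal_standard=True,
                )
            )
            for compound, load in loads.items():
                noisy = load * _lognormal_factor(rng, spec.noise_cv)
                area = noisy * leaf_area_cm2 * is_area / is_mass_ug
                records.append(
                    PeakRecord(
                        sample_id=sample_id, compound=compound, area=area
                    )
                )
            sec_pct = spec.class_percent.get(
                CompoundClass.SECONDARY_ALCOHOL, 0.0
            )
            if sec_pct > 0 and spec.isomer_spec:
                spectra[sample_id] = {}
                for n, fracs in sorted(spec.isomer_spec.items()):
                    peaks: list[tuple[int, float]] = []
                    diagnostic: set[int] = set()
                    for k, frac in sorted(fracs.items()):
                        pair = alpha_fragments(n, k)
                        diagnostic.update((pair.low_mz, pair.high_mz))
                        base = 1000.0 * frac
                        for mz in (pair.low_mz, pair.high_mz):
                            peaks.append(
                                (mz, base * _lognormal_factor(rng, spec.noise_cv))
                            )
                    max_diag = max((i for _, i in peaks), default=0.0)
                    peaks.extend(
                        _background_ions(
                            rng, n, diagnostic, max_diag, background_ion_count
                        )
                    )
                    spectra[sample_id][n] = MassSpectrum(
                        peaks=tuple(peaks),
                        peak_id=f"{sample_id}:secondary_alcohol:C{n}",
                        chain_length=n,
                    )
    return SyntheticDataset(
        records=tuple(records),
        metas=tuple(metas),
        spectra=spectra,
        specs=tuple(specs),
        seed=seed,
        is_area=is_area,
    )


def perturb_isomers(
    spec: SpeciesSpec, shift: dict[int, dict[int, float]]
) -> SpeciesSpec:
    """Shift and renormalize a spec's isomer fractions.

    ``shift`` maps chain length to additive locant deltas. The shifted
    fractions must remain non-negative with a positive sum (they are
    renormalized to 1). Useful for power and robustness studies of
    isomer recovery.
    """
    new_spec: dict[int, dict[int, float]] = {}
    for n, fracs in spec.isomer_spec.items():
        deltas = shift.get(n, {})
        unknown = set(deltas) - set(fracs)
        shifted = {k: f + deltas.get(k, 0.0) for k, f in fracs.items()}
        for k in sorted(unknown):
            alpha_fragments(n, k)
            shifted[k] = deltas[k]
        if any(v < -1e-12 for v in shifted.values()):
            raise ValueError(
                f"shift drives C{n} isomer fractions negative"
            )
        total = sum(shifted.values())
        if total <= 0:
            raise ValueError(f"shift empties the C{n} isomer simplex")
        new_spec[n] = {
            k: max(v, 0.0) / total for k, v in shifted.items() if v > 0
        }
    return replace(spec, isomer_spec=new_spec)


def default_panel() -> list[SpeciesSpec]:
    """Three archetype species spanning the observed morphology space.

    The archetypes carry the hallmark compositions of a tubule-bearing
    species (secondary alcohols 53 % of total wax, C29-dominant with
    hydroxyl mainly at C-10), a platelet-bearing species (C31 and C33
    alkanes at 15 and 21 % with same-chain secondary alcohols present)
    and a film-covered species (triterpenoids 38 %, no crystallizer at
    threshold); the remaining classes fill each profile to 100 % as
    documented constants.
    """
    SA = CompoundClass.SECONDARY_ALCOHOL
    return [
        SpeciesSpec(
            name="tubule_former",
            subfamily="Amygdaloideae",
            total_load_ug_cm2=35.0,
            class_percent={
                CompoundClass.SECONDARY_ALCOHOL: 53.0,
                CompoundClass.ALDEHYDE: 6.0,
                CompoundClass.ALKANE: 9.0,
                CompoundClass.DIOL: 1.0,
                CompoundClass.FATTY_ACID: 7.0,
                CompoundClass.PRIMARY_ALCOHOL: 8.0,
                CompoundClass.ALKYL_ESTER: 12.0,
                CompoundClass.TRITERPENOID: 4.0,
            },
            chain_distribution={
                SA: {27: 2.0, 28: 0.5, 29: 49.0, 30: 0.5, 31: 1.0},
                CompoundClass.ALDEHYDE: {28: 2.0, 30: 4.0},
                CompoundClass.ALKANE: {29: 6.0, 31: 3.0},
                CompoundClass.DIOL: {29: 1.0},
                CompoundClass.FATTY_ACID: {24: 2.0, 26: 3.0, 28: 2.0},
                CompoundClass.PRIMARY_ALCOHOL: {26: 5.0, 28: 3.0},
                CompoundClass.ALKYL_ESTER: {42: 4.0, 44: 5.0, 46: 3.0},
                CompoundClass.TRITERPENOID: {
                    "ursolic_acid": 3.0,
                    "oleanolic_acid": 1.0,
                },
            },
            isomer_spec={
                27: {8: 0.40, 9: 0.40, 10: 0.20},
                28: {9: 0.55, 10: 0.30, 11: 0.15},
                29: {9: 0.20, 10: 0.60, 11: 0.20},
                30: {9: 0.15, 10: 0.60, 11: 0.25},
                31: {9: 0.15, 10: 0.35, 11: 0.35, 12: 0.15},
            },
        ),
        SpeciesSpec(
            name="platelet_former",
            subfamily="Rosoideae",
            total_load_ug_cm2=30.0,
            class_percent={
                CompoundClass.ALKANE: 39.0,
                CompoundClass.SECONDARY_ALCOHOL: 10.0,
                CompoundClass.ALDEHYDE: 10.0,
                CompoundClass.DIOL: 1.0,
                CompoundClass.FATTY_ACID: 8.0,
                CompoundClass.PRIMARY_ALCOHOL: 8.0,
                CompoundClass.ALKYL_ESTER: 10.0,
                CompoundClass.TRITERPENOID: 14.0,
            },
            chain_distribution={
                CompoundClass.ALKANE: {29: 3.0, 31: 15.0, 33: 21.0},
                SA: {31: 6.0, 33: 4.0},
                CompoundClass.ALDEHYDE: {28: 7.0, 30: 3.0},
                CompoundClass.DIOL: {29: 1.0},
                CompoundClass.FATTY_ACID: {24: 3.0, 26: 3.0, 28: 2.0},
                CompoundClass.PRIMARY_ALCOHOL: {26: 5.0, 28: 3.0},
                CompoundClass.ALKYL_ESTER: {42: 3.0, 44: 4.0, 46: 3.0},
                CompoundClass.TRITERPENOID: {"uvaol": 10.0, "beta_amyrin": 4.0},
            },
            isomer_spec={
                31: {9: 0.10, 10: 0.10, 11: 0.45, 12: 0.35},
                33: {10: 0.20, 11: 0.40, 12: 0.40},
            },
        ),
        SpeciesSpec(
            name="film_former",
            subfamily="Amygdaloideae",
            total_load_ug_cm2=20.0,
            class_percent={
                CompoundClass.TRITERPENOID: 38.0,
                CompoundClass.ALKYL_ESTER: 12.0,
                CompoundClass.SECONDARY_ALCOHOL: 5.0,
                CompoundClass.ALKANE: 10.0,
                CompoundClass.PRIMARY_ALCOHOL: 12.0,
                CompoundClass.ALDEHYDE: 9.0,
                CompoundClass.FATTY_ACID: 14.0,
                CompoundClass.DIOL: 0.0,
            },
            chain_distribution={
                CompoundClass.TRITERPENOID: {
                    "ursolic_acid": 30.0,
                    "oleanolic_acid": 8.0,
                },
                CompoundClass.ALKYL_ESTER: {42: 4.0, 44: 5.0, 46: 3.0},
                SA: {29: 5.0},
                CompoundClass.ALKANE: {27: 3.0, 29: 5.0, 31: 2.0},
                CompoundClass.PRIMARY_ALCOHOL: {26: 7.0, 28: 5.0},
                CompoundClass.ALDEHYDE: {28: 6.0, 30: 3.0},
                CompoundClass.FATTY_ACID: {24: 4.0, 26: 6.0, 28: 4.0},
            },
            isomer_spec={29: {9: 0.25, 10: 0.50, 11: 0.25}},
        ),
    ]
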