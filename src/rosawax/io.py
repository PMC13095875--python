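"""Readers and writers for the plain-text interchange formats.

Peak tables and sample metadata travel as CSV; mass spectra as either a
two-column (mz, intensity) CSV per peak or a multi-spectrum JSON
document; analysis outputs as tidy CSV. Compound identities use the
canonical grammar ``CLASS:Cnn[:OH=k[,k2]]`` (``triterpenoid::name``)
from :mod:`rosawax.chem` everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .chem import CompoundIdentity
from .isomers import IsomerProfile, MassSpectrum
from .quantify import PeakRecord, SampleMeta, SampleProfile
from .simulate import SyntheticDataset, true_loads

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_metadata",
    "write_metadata",
    "read_spectrum_csv",
    "read_spectra_json",
    "write_spectra_json",
    "write_profiles",
    "write_isomer_fractions",
    "write_dataset",
]

PEAK_COLUMNS = ["sample_id", "compound", "area", "is_internal_standard"]
META_COLUMNS = [
    "sample_id",
    "species",
    "subfamily",
    "replicate",
    "leaf_area_cm2",
    "is_mass_ug",
]


def write_peak_table(records, path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "compound": r.compound.to_string() if r.compound else "",
            "area": r.area,
            "is_internal_standard": int(r.is_internal_standard),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


def read_peak_table(path) -> list[PeakRecord]:
    df = pd.read_csv(path, dtype={"compound": str}, keep_default_na=False)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        is_std = bool(int(row.is_internal_standard))
        compound = (
            CompoundIdentity.from_string(row.compound)
            if row.compound and not is_std
            else None
        )
        records.append(
            PeakRecord(
                sample_id=str(row.sample_id),
                compound=compound,
                area=float(row.area),
                is_internal_standard=is_std,
            )
        )
    return records


def write_metadata(metas, path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "species": m.species,
            "subfamily": m.subfamily,
            "replicate": m.replicate,
            "leaf_area_cm2": m.leaf_area_cm2,
            "is_mass_ug": m.is_mass_ug,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


def read_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks columns {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            species=str(r.species),
            subfamily=str(r.subfamily),
            replicate=int(r.replicate),
            leaf_area_cm2=float(r.leaf_area_cm2),
            is_mass_ug=float(r.is_mass_ug),
        )
        for r in df.itertuples(index=False)
    ]


def read_spectrum_csv(path, peak_id: str = "", chain_length=None) -> MassSpectrum:
    """Read a single spectrum from a two-column (mz, intensity) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"spectrum CSV {path} needs mz and intensity columns")
    mz_col, int_col = df.columns[:2]
    return MassSpectrum(
        peaks=tuple(
            (int(mz), float(i)) for mz, i in zip(df[mz_col], df[int_col])
        ),
        peak_id=peak_id or Path(path).stem,
        chain_length=chain_length,
    )


def write_spectra_json(spectra: dict[str, dict[int, MassSpectrum]], path) -> None:
    """Write sample -> chain -> spectrum as a multi-spectrum JSON document."""
    doc = [
        {
            "sample_id": sample_id,
            "peak_id": sp.peak_id,
            "chain_length": sp.chain_length,
            "peaks": [[mz, intensity] for mz, intensity in sp.peaks],
        }
        for sample_id in sorted(spectra)
        for _, sp in sorted(spectra[sample_id].items())
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_spectra_json(path) -> dict[str, dict[int, MassSpectrum]]:
    doc = json.loads(Path(path).read_text())
    out: dict[str, dict[int, MassSpectrum]] = {}
    for entry in doc:
        sp = MassSpectrum(
            peaks=tuple((int(mz), float(i)) for mz, i in entry["peaks"]),
            peak_id=entry.get("peak_id", ""),
            chain_length=entry.get("chain_length"),
        )
        if sp.chain_length is None:
            raise ValueError(
                f"spectrum {sp.peak_id!r} in {path} lacks a chain_length"
            )
        out.setdefault(entry["sample_id"], {})[sp.chain_length] = sp
    return out


def write_profiles(profiles: list[SampleProfile], path) -> None:
    """Tidy CSV of per-sample compound loads (ug cm^-2)."""
    rows = [
        {
            "sample_id": p.sample_id,
            "compound": c.to_string(),
            "load_ug_cm2": load,
        }
        for p in profiles
        for c, load in sorted(p.loads.items(), key=lambda kv: kv[0].to_string())
    ]
    pd.DataFrame(rows, columns=["sample_id", "compound", "load_ug_cm2"]).to_csv(
        path, index=False
    )


def write_isomer_fractions(
    fractions: dict[str, dict[int, IsomerProfile]], path
) -> None:
    """Tidy CSV: sample, peak_id, chain_length, position, fraction."""
    rows = []
    for sample_id in sorted(fractions):
        for n, prof in sorted(fractions[sample_id].items()):
            for k, f in sorted(prof.fractions.items()):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "chain_length": n,
                        "position": k,
                        "fraction": f,
                    }
                )
    pd.DataFrame(
        rows, columns=["sample_id", "chain_length", "position", "fraction"]
    ).to_csv(path, index=False)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write a synthetic dataset plus its ground truth to a directory.

    Emits ``peaks.csv``, ``metadata.csv``, ``spectra.json`` and
    ``truth.json`` (per-species true compound loads, class percentages
    and isomer fractions). Returns the mapping of logical name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": str(out / "peaks.csv"),
        "metadata": str(out / "metadata.csv"),
        "spectra": str(out / "spectra.json"),
        "truth": str(out / "truth.json"),
    }
    write_peak_table(dataset.records, paths["peaks"])
    write_metadata(dataset.metas, paths["metadata"])
    write_spectra_json(dataset.spectra, paths["spectra"])
    truth = {
        "seed": dataset.seed,
        "species": {
            spec.name: {
                "subfamily": spec.subfamily,
                "total_load_ug_cm2": spec.total_load_ug_cm2,
                "class_percent": {
                    cls.value: pct for cls, pct in spec.class_percent.items()
                },
                "compound_loads": {
                    c.to_string(): load
                    for c, load in sorted(
                        true_loads(spec).items(),
                        key=lambda kv: kv[0].to_string(),
                    )
                },
                "isomer_fractions": {
                    str(n): {str(k): f for k, f in sorted(fr.items())}
                    for n, fr in sorted(spec.isomer_spec.items())
                },
                "n_replicates": spec.n_replicates,
                "noise_cv": spec.noise_cv,
            }
            for spec in dataset.specs
        },
    }
    Path(paths["truth"]).write_text(json.dumps(truth, indent=1))
    return paths
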