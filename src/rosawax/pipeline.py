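"""End-to-end orchestration: quantification -> summaries -> isomers ->
compositional statistics -> morphology, with a versioned run manifest.

Stages are isolated: absence of the optional spectra input skips the
isomer stage (and the isomer evidence in morphology calls) with a
warning, leaving every other output intact. Given identical inputs and
options the run is fully deterministic, so re-running a config yields
byte-identical outputs and manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .isomers import IsomerProfile, quantify_isomers, scan_positions
from .morphology import predict_morphology
from .quantify import (
    SampleProfile,
    build_profiles,
    species_summary,
    trait_chain_percent,
    trait_class_percent,
    trait_total_load,
    total_load,
)
from .stats import anova_tukey, clr_transform, hca, pca

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("rosawax")


@dataclass
class RunConfig:
    """Options and input/output paths for a full analysis run."""

    peaks: str
    metadata: str
    out_dir: str
    spectra: str | None = None
    theta: float = 15.0
    alpha: float = 0.05
    clr_zero_scale: float = 0.65
    distance: str = "euclidean"
    linkage: str = "ward"
    standardize: bool = True
    isomer_floor_frac: float = 0.01
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _species_mean_profiles(
    profiles: list[SampleProfile],
) -> dict[str, SampleProfile]:
    """Average replicate loads per species (absent compound = 0)."""
    by_species: dict[str, list[SampleProfile]] = {}
    for p in profiles:
        by_species.setdefault(p.meta.species, []).append(p)
    out = {}
    for species in sorted(by_species):
        reps = by_species[species]
        compounds = sorted(
            {c for p in reps for c in p.loads}, key=lambda c: c.to_string()
        )
        loads = {
            c: sum(p.loads.get(c, 0.0) for p in reps) / len(reps)
            for c in compounds
        }
        out[species] = SampleProfile(sample_id=species, loads=loads, meta=None)
    return out


def _isomer_stage(
    spectra, floor_frac: float
) -> dict[str, dict[int, IsomerProfile]]:
    fractions: dict[str, dict[int, IsomerProfile]] = {}
    for sample_id, by_chain in spectra.items():
        for n, spectrum in by_chain.items():
            peak_max = max((i for _, i in spectrum.peaks), default=0.0)
            positions = scan_positions(spectrum, floor=floor_frac * peak_max)
            if not positions:
                warnings.warn(
                    f"no isomer fragments found in {spectrum.peak_id!r}; "
                    f"skipping",
                    stacklevel=2,
                )
                continue
            fractions.setdefault(sample_id, {})[n] = quantify_isomers(
                spectrum, positions
            )
    return fractions


def _species_mean_isomers(
    fractions: dict[str, dict[int, IsomerProfile]],
    sample_species: dict[str, str],
) -> dict[str, dict[int, IsomerProfile]]:
    acc: dict[str, dict[int, list[IsomerProfile]]] = {}
    for sample_id, by_chain in fractions.items():
        species = sample_species[sample_id]
        for n, prof in by_chain.items():
            acc.setdefault(species, {}).setdefault(n, []).append(prof)
    out: dict[str, dict[int, IsomerProfile]] = {}
    for species, by_chain in acc.items():
        out[species] = {}
        for n, profs in by_chain.items():
            keys = sorted({k for p in profs for k in p.fractions})
            mean = {
                k: sum(p.fractions.get(k, 0.0) for p in profs) / len(profs)
                for k in keys
            }
            total = sum(mean.values())
            out[species][n] = IsomerProfile(
                chain_length=n, fractions={k: v / total for k, v in mean.items()}
            )
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the run manifest.

    Writes, under ``config.out_dir``: per-sample loads, species
    summaries (total load, class %, chain-length %), isomer fractions
    (when spectra are given), the CLR/HCA dendrogram in Newick form,
    PCA scores/loadings/variance, ANOVA + Tukey compact letters, the
    per-species morphology calls, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def stage(name):
        log.info("stage: %s", name)

    # -- quantification ----------------------------------------------------
    stage("quantification")
    try:
        records = rio.read_peak_table(config.peaks)
        metas = rio.read_metadata(config.metadata)
        profiles = build_profiles(records, metas)
    except Exception as exc:
        raise RuntimeError(f"stage quantification failed: {exc}") from exc
    rio.write_profiles(profiles, out / "loads.csv")
    outputs["loads"] = str(out / "loads.csv")

    # -- species summaries -------------------------------------------------
    stage("summaries")
    try:
        for label, fn in [
            ("total_load", trait_total_load),
            ("class_percent", trait_class_percent),
            ("chain_percent", trait_chain_percent),
        ]:
            path = out / f"species_{label}.csv"
            species_summary(profiles, fn).to_csv(path, index=False)
            outputs[f"species_{label}"] = str(path)
    except Exception as exc:
        raise RuntimeError(f"stage summaries failed: {exc}") from exc

    # -- isomer quantification (optional input) ----------------------------
    isomer_fractions: dict[str, dict[int, IsomerProfile]] = {}
    if config.spectra and Path(config.spectra).exists():
        stage("isomers")
        try:
            spectra = rio.read_spectra_json(config.spectra)
            isomer_fractions = _isomer_stage(spectra, config.isomer_floor_frac)
        except Exception as exc:
            raise RuntimeError(f"stage isomers failed: {exc}") from exc
        rio.write_isomer_fractions(isomer_fractions, out / "isomer_fractions.csv")
        outputs["isomer_fractions"] = str(out / "isomer_fractions.csv")
    else:
        if config.spectra:
            warnings.warn(
                f"spectra input {config.spectra!r} not found; "
                f"isomer stage skipped",
                stacklevel=2,
            )
        else:
            log.warning("no spectra input; isomer stage skipped")

    # -- compositional statistics ------------------------------------------
    stage("stats")
    try:
        mean_profiles = _species_mean_profiles(profiles)
        # species x compound relative amounts for CLR + HCA
        comp = pd.DataFrame(
            {
                sp: {
                    c.to_string(): load for c, load in prof.loads.items()
                }
                for sp, prof in mean_profiles.items()
            }
        ).T.fillna(0.0)
        comp = comp.div(comp.sum(axis=1), axis=0) * 100.0
        if len(comp) >= 2:
            clr = clr_transform(comp, zero_scale=config.clr_zero_scale)
            tree = hca(clr, distance=config.distance, linkage=config.linkage)
            (out / "hca.nwk").write_text(tree.to_newick() + "\n")
            outputs["hca"] = str(out / "hca.nwk")
        # species x (class %, total load) for PCA
        class_summary = species_summary(profiles, trait_class_percent)
        totals = species_summary(profiles, trait_total_load)
        pca_input = (
            pd.concat([class_summary, totals])
            .pivot_table(index="species", columns="trait", values="mean")
            .fillna(0.0)
        )
        if pca_input.shape[0] >= 2 and pca_input.shape[1] >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = pca(pca_input, standardize=config.standardize)
            res.scores.to_csv(out / "pca_scores.csv")
            res.loadings.to_csv(out / "pca_loadings.csv")
            pd.DataFrame(
                {
                    "component": res.scores.columns,
                    "variance_pct": res.variance_explained,
                }
            ).to_csv(out / "pca_variance.csv", index=False)
            outputs["pca_scores"] = str(out / "pca_scores.csv")
            outputs["pca_loadings"] = str(out / "pca_loadings.csv")
            outputs["pca_variance"] = str(out / "pca_variance.csv")
        # ANOVA + Tukey letters on total load per species
        groups = {}
        for p in profiles:
            groups.setdefault(p.meta.species, []).append(total_load(p))
        if len(groups) >= 2 and any(len(v) >= 2 for v in groups.values()):
            res = anova_tukey(groups, alpha=config.alpha)
            pd.DataFrame(
                sorted(res.letters.items()), columns=["species", "letters"]
            ).to_csv(out / "total_load_letters.csv", index=False)
            outputs["total_load_letters"] = str(out / "total_load_letters.csv")
    except Exception as exc:
        raise RuntimeError(f"stage stats failed: {exc}") from exc

    # -- morphology --------------------------------------------------------
    stage("morphology")
    try:
        sample_species = {p.sample_id: p.meta.species for p in profiles}
        species_isomers = _species_mean_isomers(isomer_fractions, sample_species)
        calls = {}
        for species, prof in mean_profiles.items():
            call = predict_morphology(
                prof,
                isomers=species_isomers.get(species),
                theta=config.theta,
            )
            calls[species] = {
                "call": call.call.value,
                "fired_rules": [
                    {"rule": rid, "evidence": ev} for rid, ev in call.fired_rules
                ],
            }
        (out / "morphology.json").write_text(json.dumps(calls, indent=1))
        outputs["morphology"] = str(out / "morphology.json")
    except Exception as exc:
        raise RuntimeError(f"stage morphology failed: {exc}") from exc

    # -- manifest ----------------------------------------------------------
    inputs = {"peaks": config.peaks, "metadata": config.metadata}
    if config.spectra and Path(config.spectra).exists():
        inputs["spectra"] = config.spectra
    manifest = {
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "options": asdict(config),
        "seed": config.seed,
        "outputs": {
            k: {"path": v, "sha256": _sha256(v)} for k, v in sorted(outputs.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
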