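"""Synthetic data generation: ground-truth round trips and determinism."""

import dataclasses
import math

import numpy as np
import pytest

from rosawax.chem import CompoundClass
from rosawax.isomers import quantify_isomers, scan_positions
from rosawax.quantify import (
    average_chain_length,
    build_profiles,
    chain_length_relative,
    class_relative,
    total_load,
)
from rosawax.simulate import (
    SpeciesSpec,
    default_panel,
    generate,
    perturb_isomers,
    true_loads,
)
from rosawax import io as rio


class TestDefaultPanel:
    def test_three_archetypes_with_printed_shares(self):
        panel = {s.name: s for s in default_panel()}
        assert len(panel) >= 3
        assert panel["tubule_former"].class_percent[
            CompoundClass.SECONDARY_ALCOHOL
        ] == pytest.approx(53.0)
        alkanes = panel["platelet_former"].chain_distribution[
            CompoundClass.ALKANE
        ]
        total = panel["platelet_former"].total_load_ug_cm2
        cls_pct = panel["platelet_former"].class_percent[CompoundClass.ALKANE]
        w = sum(alkanes.values())
        assert cls_pct * alkanes[31] / w == pytest.approx(15.0)
        assert cls_pct * alkanes[33] / w == pytest.approx(21.0)
        assert panel["film_former"].class_percent[
            CompoundClass.TRITERPENOID
        ] == pytest.approx(38.0)

    def test_class_percent_sums_to_100(self):
        for spec in default_panel():
            assert sum(spec.class_percent.values()) == pytest.approx(
                100.0, abs=1e-9
            )

    def test_invalid_spec_names_the_field(self):
        with pytest.raises(ValueError, match="class_percent"):
            SpeciesSpec(
                name="bad",
                subfamily="Rosoideae",
                total_load_ug_cm2=10.0,
                class_percent={CompoundClass.ALKANE: 50.0},
                chain_distribution={CompoundClass.ALKANE: {29: 1.0}},
            )


class TestZeroNoiseRoundTrip:
    def test_full_pipeline_recovers_configuration(
        self, noise_free_panel, noise_free_profiles
    ):
        specs = {s.name: s for s in noise_free_panel}
        for profile in noise_free_profiles:
            spec = specs[profile.meta.species]
            assert total_load(profile) == pytest.approx(
                spec.total_load_ug_cm2, abs=1e-9
            )
            rel = class_relative(profile)
            for cls, pct in spec.class_percent.items():
                assert rel[cls] == pytest.approx(pct, abs=1e-9)
            # chain-length percentages from the configured weights
            expected: dict[int, float] = {}
            for cls, weights in spec.chain_distribution.items():
                if cls not in (
                    CompoundClass.ALKYL_ESTER,
                    CompoundClass.TRITERPENOID,
                ):
                    w_total = sum(weights.values())
                    load = spec.class_percent[cls]
                    for n, w in weights.items():
                        expected[n] = expected.get(n, 0.0) + load * w / w_total
            scale = 100.0 / sum(expected.values())
            observed = chain_length_relative(profile)
            for n, v in expected.items():
                assert observed[n] == pytest.approx(v * scale, abs=1e-9)
            # load-weighted average chain length, per class, from the spec
            for cls, weights in spec.chain_distribution.items():
                if cls is CompoundClass.TRITERPENOID:
                    continue
                w_total = sum(weights.values())
                acl_expected = (
                    sum(n * w for n, w in weights.items()) / w_total
                )
                assert average_chain_length(profile, cls) == pytest.approx(
                    acl_expected, abs=1e-9
                )

    def test_spectra_recover_isomer_fractions_exactly(
        self, noise_free_panel, noise_free_dataset
    ):
        specs = {s.name: s for s in noise_free_panel}
        for sample_id, by_chain in noise_free_dataset.spectra.items():
            species = sample_id.rsplit("_r", 1)[0]
            for n, spectrum in by_chain.items():
                truth = specs[species].isomer_spec[n]
                prof = quantify_isomers(spectrum, sorted(truth))
                for k, f in truth.items():
                    assert prof.fractions[k] == pytest.approx(f, abs=1e-12)

    def test_scan_finds_exactly_the_configured_positions(
        self, noise_free_panel, noise_free_dataset
    ):
        specs = {s.name: s for s in noise_free_panel}
        sample_id = "tubule_former_r1"
        spectrum = noise_free_dataset.spectra[sample_id][29]
        peak_max = max(i for _, i in spectrum.peaks)
        found = scan_positions(spectrum, floor=0.05 * peak_max)
        assert found == sorted(specs["tubule_former"].isomer_spec[29])


class TestDeterminismAndNoise:
    def test_same_seed_is_byte_identical(self, tmp_path):
        panel = default_panel()
        for sub in ("a", "b"):
            rio.write_dataset(generate(panel, seed=42), tmp_path / sub)
        for name in ("peaks.csv", "metadata.csv", "spectra.json", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = generate(default_panel(), seed=1)
        b = generate(default_panel(), seed=2)
        areas_a = [r.area for r in a.records if not r.is_internal_standard]
        areas_b = [r.area for r in b.records if not r.is_internal_standard]
        assert areas_a != areas_b

    def test_replicate_se_tracks_the_configured_cv(self):
        # SE of the total load across n replicates should be near
        # total * cv / sqrt(n); allow a factor-3 band per run and require
        # most runs inside it.
        panel = [
            dataclasses.replace(default_panel()[0], noise_cv=0.1)
        ]
        expected_se = panel[0].total_load_ug_cm2 * 0.1 / math.sqrt(5)
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            ds = generate(panel, seed=seed)
            profiles = build_profiles(ds.records, ds.metas)
            totals = np.array([total_load(p) for p in profiles])
            se = totals.std(ddof=1) / math.sqrt(len(totals))
            if expected_se / 3 <= se <= expected_se * 3:
                hits += 1
        assert hits >= int(0.75 * n_runs)


class TestPerturbIsomers:
    def test_zero_shift_is_identity(self):
        spec = default_panel()[0]
        assert perturb_isomers(spec, {}).isomer_spec == spec.isomer_spec

    def test_all_mass_to_one_position_recovers_unity(self):
        spec = dataclasses.replace(default_panel()[2], noise_cv=0.0)
        frac = spec.isomer_spec[29]
        shift = {29: {k: (1e6 if k == 10 else -frac[k]) for k in frac}}
        moved = perturb_isomers(spec, shift)
        assert moved.isomer_spec[29] == pytest.approx({10: 1.0})
        ds = generate([moved], seed=5)
        spectrum = ds.spectra[f"{moved.name}_r1"][29]
        prof = quantify_isomers(spectrum, [9, 10, 11])
        assert prof.fractions[10] == pytest.approx(1.0)

    def test_invalid_simplex_rejected(self):
        spec = default_panel()[0]
        with pytest.raises(ValueError, match="negative"):
            perturb_isomers(spec, {29: {10: -0.9}})

    def test_shifted_fractions_distinguishable_at_low_noise(self):
        # 60/20/20 vs 40/30/30 must separate at cv=0.05 with n=5 replicates
        base = dataclasses.replace(
            default_panel()[2],
            noise_cv=0.05,
            isomer_spec={29: {9: 0.2, 10: 0.6, 11: 0.2}},
        )
        alt = dataclasses.replace(
            base, isomer_spec={29: {9: 0.3, 10: 0.4, 11: 0.3}}
        )

        def recovered_mean(spec, seed):
            ds = generate([spec], seed=seed)
            fracs = [
                quantify_isomers(sp[29], [9, 10, 11]).fractions[10]
                for sp in ds.spectra.values()
            ]
            return float(np.mean(fracs))

        a = [recovered_mean(base, s) for s in range(10)]
        b = [recovered_mean(alt, s) for s in range(10, 20)]
        assert min(a) > max(b)

    def test_true_loads_sum_to_total(self):
        for spec in default_panel():
            assert sum(true_loads(spec).values()) == pytest.approx(
                spec.total_load_ug_cm2, abs=1e-9
            )
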