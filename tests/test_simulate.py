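"""Synthetic-fixture generators: determinism, parseability, planted structure."""

import filecmp

import numpy as np
import pytest

from turf.asb import asb_positives, call_asb
from turf.genomic import read_bed, read_bedgraph, read_organ_map, read_variants
from turf.organs import ld_expand
from turf.simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_asb_counts,
    simulate_cell_lines,
    simulate_gwas,
    simulate_training_variants,
    substream,
    write_annotations,
    write_asb_counts,
    write_gwas,
)


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=500_000,
        organs=("liver", "heart"),
        biosamples_per_organ=2,
        regions_per_biosample=10,
        n_variants=100,
        asb_n_sites=120,
        asb_n_planted=20,
        gwas_n_snvs=60,
        gwas_trait_size=10,
        gwas_n_null_traits=1,
    )


class TestConfig:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, positive_fraction=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, asb_rho=1.0)

    def test_yaml_round_trip(self, small_config, tmp_path):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == small_config

    def test_substreams_are_independent(self):
        a = substream(3, "x").integers(0, 1_000_000, 5)
        b = substream(3, "y").integers(0, 1_000_000, 5)
        a2 = substream(3, "x").integers(0, 1_000_000, 5)
        assert np.array_equal(a, a2) and not np.array_equal(a, b)


class TestAnnotations:
    def test_bundle_and_map_counts(self, small_config):
        sim = simulate_annotations(small_config)
        assert len(sim.bundles) == 4  # 2 organs x 2 biosamples
        assert len([(b, o) for b, os in sim.organ_map.mapping.items() for o in os]) == 4

    def test_zero_peak_density_still_runs(self):
        cfg = SimulationConfig(
            seed=5, n_chroms=2, chrom_length=200_000, background_peak_density=0.0,
            assay_active_prob=0.0, regions_per_biosample=5,
        )
        sim = simulate_annotations(cfg)
        assert all(len(b.dnase_peaks) == 0 for b in sim.bundles.values())

    def test_same_seed_byte_identical_files(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_annotations(simulate_annotations(small_config), d1)
        write_annotations(simulate_annotations(small_config), d2)
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert filecmp.cmp(p1, p2, shallow=False), p1.name

    def test_written_files_parse_cleanly(self, small_config, tmp_path):
        sim = simulate_annotations(small_config)
        write_annotations(sim, tmp_path)
        m = read_organ_map(tmp_path / "organ_map.tsv")
        assert m.organs() == {"liver", "heart"}
        sample_dir = tmp_path / sorted(sim.bundles)[0]
        peaks = read_bed(sample_dir / "dnase_peaks.bed")
        assert all(iv.start < iv.end for iv in peaks)
        track = read_bedgraph(next(iter(sample_dir.glob("*_chip.bedgraph"))))
        assert all(np.isfinite(v) for _, _, _, v in track.steps())

    def test_disjoint_regions_do_not_overlap(self, small_config):
        sim = simulate_annotations(
            small_config, biosamples=["a", "b", "c"], disjoint_regions=True
        )
        seen = set()
        for regs in sim.active_regions.values():
            for iv in regs:
                span = (iv.chrom, iv.start, iv.end)
                assert span not in seen
                seen.add(span)


class TestAsbCounts:
    def test_planted_sites_recovered_null_sites_mostly_not(self, small_config):
        cfg = SimulationConfig(seed=13, asb_n_sites=1000, asb_n_planted=100)
        sites, truth = simulate_asb_counts(cfg)
        res = call_asb(sites, fdr=0.05)
        called = {v.key for v in asb_positives(res)}
        planted = set(truth[truth.planted]["variant"])
        assert len(called & planted) / len(planted) >= 0.9
        fdp = len(called - planted) / max(1, len(called))
        assert fdp <= 0.1

    def test_no_effect_ratio_means_no_signal(self):
        cfg = SimulationConfig(seed=17, asb_n_sites=600, asb_n_planted=100,
                               asb_effect_ratio=0.5)
        sites, truth = simulate_asb_counts(cfg)
        res = call_asb(sites, fdr=0.05)
        called = {v.key for v in asb_positives(res)}
        planted = set(truth[truth.planted]["variant"])
        # planted and null sites are indistinguishable at ratio 0.5
        assert len(called & planted) / len(planted) <= 0.10

    def test_counts_table_round_trips(self, small_config, tmp_path):
        sites, truth = simulate_asb_counts(small_config)
        write_asb_counts(sites, truth, tmp_path)
        from turf.genomic import read_allelic_counts

        df = read_allelic_counts(tmp_path / "allelic_counts.tsv")
        assert len(df) == len(sites)
        assert (df["ref_count"] + df["alt_count"] >= 1).all()


class TestTrainingVariants:
    def test_positives_inside_active_regions(self, small_config):
        sim = simulate_annotations(small_config)
        training = simulate_training_variants(small_config, sim)
        active = sim.all_active_index()
        pos = [v for v, l in zip(training.variants, training.labels) if l == 1]
        neg = [v for v, l in zip(training.variants, training.labels) if l == 0]
        assert all(active.contains_variant(v) for v in pos)
        assert not any(active.contains_variant(v) for v in neg)

    def test_eqtl_enrichment_in_positives(self):
        cfg = SimulationConfig(seed=23, n_chroms=2, chrom_length=500_000,
                               n_variants=2000, regions_per_biosample=10)
        sim = simulate_annotations(cfg)
        training = simulate_training_variants(cfg, sim)
        pos_rate = np.mean([v.key in training.eqtl_ids
                            for v, l in zip(training.variants, training.labels) if l])
        neg_rate = np.mean([v.key in training.eqtl_ids
                            for v, l in zip(training.variants, training.labels) if not l])
        assert pos_rate > 2 * neg_rate


class TestGwas:
    def test_ld_block_size_one_is_identity(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, ld_block_size=1)
        sim = simulate_annotations(cfg)
        gwas = simulate_gwas(cfg, sim)
        assert gwas.ld_table.empty
        ids = set(gwas.catalog["variant_id"])
        assert ld_expand(ids, gwas.ld_table, 0.8) == ids

    def test_planted_trait_sits_in_planted_organ_regions(self, small_config):
        sim = simulate_annotations(small_config)
        gwas = simulate_gwas(small_config, sim)
        liver_regions = sim.active_index("liver_bs1")
        planted = gwas.catalog[gwas.catalog.trait == "planted_trait"]
        from turf.genomic import Variant

        frac = np.mean(
            [
                any(
                    sim.active_index(b).contains_variant(
                        Variant(r.chrom, int(r.pos), "A", "G")
                    )
                    for b in sim.organ_map.biosamples_for("liver")
                )
                for r in planted.itertuples()
            ]
        )
        assert frac == 1.0

    def test_written_vcf_parses_with_zero_skips(self, small_config, tmp_path):
        sim = simulate_annotations(small_config)
        gwas = simulate_gwas(small_config, sim)
        write_gwas(gwas, tmp_path)
        back = read_variants(tmp_path / "snvs.vcf", "vcf")
        assert len(back) == len(gwas.positions)

    def test_cell_line_asb_sets_are_disjoint(self, small_config):
        cells = simulate_cell_lines(small_config)
        keys = [v.key for line in small_config.cell_lines
                for v in cells.asb_by_cell_line[line]]
        assert len(keys) == len(set(keys))
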