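import numpy as np
import pytest

from radvar.io_tables import write_occurrence_chart, read_occurrence_chart
from radvar.primer_v4 import extract_v4
from radvar.pdistance import group_mean_within
from radvar.richness_metrics import rank_abundance_profiles, order_summary
from radvar.sharing_classify import Category, classify_all
from radvar.synthetic_data import (
    MorphospeciesSpec,
    SyntheticConfig,
    build_truth,
    generate_dataset,
    paper_like_config,
    sample_reads_table,
)
from radvar.vetting import vet_dataset


def tiny_config(seed=0, **overrides):
    """Small, fast config: one species per category."""
    species = (
        MorphospeciesSpec("Alpha one", "Collodaria", "Collosphaeridae", 3,
                          Category.SHARED_DOMINANT.value, haplotypes_per_genome=4),
        MorphospeciesSpec("Beta two", "Collodaria", "Collosphaeridae", 3,
                          Category.SHARED_ASV_DIFFERENT_DOMINANTS.value,
                          haplotypes_per_genome=4),
        MorphospeciesSpec("Gamma three", "Nassellaria", "Pterocorythidae", 4,
                          Category.NO_UNIVERSAL_ASV.value, n_subgroups=2,
                          haplotypes_per_genome=3),
    )
    defaults = dict(species=species, seed=seed, template_length=700, v4_offset=80,
                    v4_insert_length=440, depth_mean=5000.0)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_infeasible_target_hierarchy_rejected(self):
        with pytest.raises(ValueError, match="target_p"):
            tiny_config(target_p={"intragenomic": 0.1, "intraspecies": 0.05, "interspecies": 0.2})

    def test_no_universal_requires_subgroups(self):
        with pytest.raises(ValueError, match="subgroups"):
            MorphospeciesSpec("X y", "Collodaria", "F", 4, Category.NO_UNIVERSAL_ASV.value)

    def test_template_too_short_rejected(self):
        with pytest.raises(ValueError, match="template"):
            tiny_config(template_length=300)


class TestBuildTruth:
    def test_forced_categories_recorded(self):
        truth = build_truth(tiny_config())
        assert truth.species_category["Alpha one"] == "SHARED_DOMINANT"
        assert truth.species_category["Gamma three"] == "NO_UNIVERSAL_ASV"

    def test_disjoint_subgroup_asv_sets(self):
        truth = build_truth(tiny_config())
        pools = {}
        for s, sub in truth.specimen_subgroup.items():
            if truth.specimen_species[s] == "Gamma three":
                pools.setdefault(sub, set()).update(truth.specimen_haplotypes[s])
        assert len(pools) == 2
        assert pools[0].isdisjoint(pools[1])

    def test_shared_dominant_by_construction(self):
        truth = build_truth(tiny_config())
        tops = []
        for s, haps in truth.specimen_haplotypes.items():
            if truth.specimen_species[s] == "Alpha one":
                tops.append(max(haps, key=haps.get))
        assert len(set(tops)) == 1

    def test_determinism_same_seed(self):
        t1, t2 = build_truth(tiny_config(seed=5)), build_truth(tiny_config(seed=5))
        assert t1.haplotype_sequences == t2.haplotype_sequences
        assert t1.specimen_haplotypes == t2.specimen_haplotypes

    def test_primer_sites_survive_mutation(self):
        truth = build_truth(tiny_config())
        for seq in truth.haplotype_sequences.values():
            assert extract_v4(seq) is not None


class TestSampleReads:
    def test_bit_identical_charts_same_seed(self):
        c1, _, _ = generate_dataset(tiny_config(seed=3))
        c2, _, _ = generate_dataset(tiny_config(seed=3))
        assert c1 == c2

    def test_different_seed_differs(self):
        c1, _, _ = generate_dataset(tiny_config(seed=3))
        c2, _, _ = generate_dataset(tiny_config(seed=4))
        assert c1 != c2

    def test_clean_config_vetting_removes_nothing(self):
        cfg = tiny_config(noise_variants_per_specimen=0.0, contaminants_per_specimen=0.0,
                          depth_mean=20000.0)
        chart, meta, _ = generate_dataset(cfg)
        vetted, rep = vet_dataset(chart, meta)
        assert rep.removed_by_taxonomy == []
        assert rep.removed_specimens == []
        assert set(vetted.asv_ids) == set(chart.asv_ids)

    def test_contaminant_recall_and_precision(self):
        cfg = tiny_config(contaminants_per_specimen=2.0)
        chart, meta, truth = generate_dataset(cfg)
        vetted, rep = vet_dataset(chart, meta)
        removed_tax = {a for a, *_ in rep.removed_by_taxonomy}
        present_contams = set(truth.contaminant_asvs) & set(chart.asv_ids)
        assert removed_tax == present_contams  # recall and precision both 1.0
        assert set(vetted.asv_ids).isdisjoint(truth.contaminant_asvs)

    def test_noise_variants_removed_by_presence_rule(self):
        cfg = tiny_config(noise_variants_per_specimen=3.0)
        chart, meta, truth = generate_dataset(cfg)
        vetted, _ = vet_dataset(chart, meta)
        assert set(vetted.asv_ids).isdisjoint(truth.noise_asvs)

    def test_multinomial_rank1_share_near_frequency(self):
        # DERIVED: freq 0.9 at depth 10,000 -> SE = sqrt(.9*.1/10000) = 0.003
        rng = np.random.default_rng(77)
        shares = []
        for _ in range(100):
            draws = rng.multinomial(10_000, [0.9, 0.1])
            shares.append(draws[0] / 10_000)
        assert abs(np.mean(shares) - 0.9) < 3 * 0.003 / np.sqrt(100) + 1e-3

    def test_depth_scale_matches_config(self):
        cfg = tiny_config(depth_mean=22617.0, noise_variants_per_specimen=0.0,
                          contaminants_per_specimen=0.0)
        chart, _, _ = generate_dataset(cfg)
        depths = chart.counts.sum(axis=0)
        assert 0.5 * 22617 < depths.mean() < 2.0 * 22617

    def test_zero_species_config_empty(self):
        cfg = SyntheticConfig(species=(), seed=0)
        chart, meta, truth = generate_dataset(cfg)
        assert chart.asv_ids == [] and meta == {} and truth.specimen_haplotypes == {}


class TestRecovery:
    def test_category_recovery_noise_free_50_replicates(self):
        hits = total = 0
        for seed in range(50):
            cfg = tiny_config(seed=seed, noise_variants_per_specimen=0.0,
                              contaminants_per_specimen=0.0)
            chart, meta, truth = generate_dataset(cfg)
            vetted, _ = vet_dataset(chart, meta)
            for cat in classify_all(vetted, meta):
                total += 1
                hits += cat.category.value == truth.species_category[cat.morphospecies]
        assert total == 150
        assert hits == total  # 100% noise-free

    def test_category_recovery_default_noise_50_replicates(self):
        hits = total = 0
        for seed in range(50):
            chart, meta, truth = generate_dataset(tiny_config(seed=1000 + seed))
            vetted, _ = vet_dataset(chart, meta)
            for cat in classify_all(vetted, meta):
                total += 1
                hits += cat.category.value == truth.species_category[cat.morphospecies]
        assert hits / total >= 0.90

    def test_intragenomic_p_recovery_within_20pct(self):
        rel_errors = []
        for seed in range(50):
            cfg = tiny_config(seed=2000 + seed, noise_variants_per_specimen=0.0,
                              contaminants_per_specimen=0.0)
            chart, meta, truth = generate_dataset(cfg)
            vetted, _ = vet_dataset(chart, meta)
            target = cfg.target_p["intragenomic"]
            means = []
            for s in vetted.specimen_ids:
                col = vetted.counts[s]
                members = {a: vetted.sequences[a] for a in col.index[col > 0]}
                summ = group_mean_within(members)
                if summ.mean_p is not None:
                    means.append(summ.mean_p)
            rel_errors.append(abs(np.mean(means) - target) / target)
        assert np.mean(rel_errors) < 0.20

    def test_rank1_share_ordering_over_20_seeds(self):
        wins = 0
        for seed in range(20):
            cfg = paper_like_config(seed=3000 + seed, scale=0.35)
            chart, meta, _ = generate_dataset(cfg)
            vetted, _ = vet_dataset(chart, meta)
            profiles = rank_abundance_profiles(vetted, meta)
            df = order_summary(profiles, "median", "rank1").set_index("order")
            nas = df.loc["Nassellaria", "value"]
            col = df.loc["Collodaria", "value"]
            spu = df.loc["Spumellaria", "value"]
            wins += nas > col > spu
        assert wins >= 18  # ordering holds by construction; allow sampling slack


class TestBundleRoundTrip:
    def test_chart_passes_io_round_trip(self, tmp_path, paper_like_bundle):
        chart, meta, _ = paper_like_bundle
        path = tmp_path / "chart.tsv"
        write_occurrence_chart(chart, path)
        assert read_occurrence_chart(path) == chart

    def test_truth_json_round_trip(self, paper_like_bundle):
        from radvar.synthetic_data import SyntheticTruth

        _, _, truth = paper_like_bundle
        back = SyntheticTruth.from_json(truth.to_json())
        assert back.specimen_haplotypes == truth.specimen_haplotypes
        assert back.species_category == truth.species_category
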