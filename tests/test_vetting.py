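import numpy as np
import pytest

from radvar.io_tables import parse_lineage
from radvar.vetting import (
    VettingConfig,
    apply_count_thresholds,
    filter_taxonomy_consistency,
    vet_dataset,
)
from conftest import make_chart, make_meta


class TestTaxonomyConsistency:
    def test_matching_family_retained(self):
        chart = make_chart({"A": {"s1": 10}}, families={"A": "Collosphaeridae"})
        meta = make_meta(["s1"], family="Collosphaeridae")
        out, rep = filter_taxonomy_consistency(chart, meta)
        assert out.counts.at["A", "s1"] == 10
        assert rep.removed_by_taxonomy == []

    def test_off_family_zeroed_and_logged(self):
        chart = make_chart({"A": {"s1": 10}}, families={"A": "Sphaerozoidae"})
        meta = make_meta(["s1"], family="Pterocorythidae")
        out, rep = filter_taxonomy_consistency(chart, meta)
        assert out.counts.at["A", "s1"] == 0
        assert rep.removed_by_taxonomy == [("A", "s1", "Sphaerozoidae", "Pterocorythidae")]

    def test_relaxed_specimen_accepts_any_polycystine_family(self):
        chart = make_chart({"A": {"s1": 10}}, families={"A": "Sphaerozoidae"})
        meta = make_meta(["s1"], relaxed={"s1": True})
        out, rep = filter_taxonomy_consistency(chart, meta)
        assert out.counts.at["A", "s1"] == 10
        assert rep.removed_by_taxonomy == []

    def test_relaxed_specimen_rejects_non_polycystine(self):
        chart = make_chart({"A": {"s1": 10}})
        # overwrite with a non-polycystine order
        chart.lineage["A"] = parse_lineage("Eukaryota;TSAR;Alveolata;Dinophyceae;Gymnodiniales;Gymnodiniaceae;G;S")
        meta = make_meta(["s1"], relaxed={"s1": True})
        out, _ = filter_taxonomy_consistency(chart, meta)
        assert out.counts.at["A", "s1"] == 0

    def test_family_match_case_insensitive(self):
        chart = make_chart({"A": {"s1": 10}}, families={"A": "Collosphaeridae"})
        meta = make_meta(["s1"], family="collosphaeridae ")
        out, _ = filter_taxonomy_consistency(chart, meta)
        assert out.counts.at["A", "s1"] == 10

    def test_low_confidence_removed_everywhere(self):
        chart = make_chart(
            {"A": {"s1": 10, "s2": 20}, "B": {"s1": 5}}, confidence={"A": 0.1}
        )
        meta = make_meta(["s1", "s2"])
        out, rep = filter_taxonomy_consistency(chart, meta)
        assert "A" not in out.asv_ids
        assert rep.removed_by_confidence == [("A", 0.1)]

    def test_specimen_without_metadata_errors(self):
        chart = make_chart({"A": {"s1": 10}})
        with pytest.raises(KeyError, match="s1"):
            filter_taxonomy_consistency(chart, {})


class TestCountThresholds:
    def test_cell_below_presence_zeroed(self):
        chart = make_chart({"A": {"s1": 2, "s2": 3}, "B": {"s1": 50, "s2": 50}})
        out, rep = apply_count_thresholds(chart)
        assert out.counts.at["A", "s1"] == 0
        assert out.counts.at["A", "s2"] == 3
        assert ("A", "s1", 2) in rep.removed_by_presence

    def test_asv_below_everywhere_removed_globally(self):
        # DERIVED: counts {2,2,2} -> all cells zeroed -> no specimen reaches 3
        chart = make_chart({"A": {"s1": 2, "s2": 2, "s3": 2}, "B": {"s1": 9, "s2": 9, "s3": 9}})
        out, rep = apply_count_thresholds(chart)
        assert "A" not in out.asv_ids
        assert "A" in rep.removed_asvs_global

    def test_weak_specimen_dropped_and_logged(self):
        chart = make_chart({"A": {"s1": 4, "s2": 100}})
        out, rep = apply_count_thresholds(chart)
        assert "s1" not in out.specimen_ids
        assert ("s1", 4) in rep.removed_specimens

    def test_specimen_with_five_reads_kept(self):
        chart = make_chart({"A": {"s1": 5}})
        out, _ = apply_count_thresholds(chart)
        assert out.specimen_ids == ["s1"]


class TestVetDataset:
    def test_planted_contaminants_and_noise_removed_exactly(self):
        counts = {}
        families = {}
        # 4 genuine ASVs
        for i in range(4):
            counts[f"real{i}"] = {"s1": 100 + i, "s2": 50}
            families[f"real{i}"] = "Collosphaeridae"
        # 3 contaminants: off-family, healthy counts
        for i in range(3):
            counts[f"cont{i}"] = {"s1": 30}
            families[f"cont{i}"] = "Pterocorythidae"
        # 2 noise ASVs: <3 reads everywhere
        for i in range(2):
            counts[f"noise{i}"] = {"s1": 2, "s2": 1}
            families[f"noise{i}"] = "Collosphaeridae"
        chart = make_chart(counts, families=families)
        meta = make_meta(["s1", "s2"], family="Collosphaeridae")
        out, rep = vet_dataset(chart, meta)
        assert sorted(out.asv_ids) == [f"real{i}" for i in range(4)]
        removed_tax = {a for a, *_ in rep.removed_by_taxonomy}
        assert removed_tax == {"cont0", "cont1", "cont2"}
        assert set(rep.removed_asvs_global) >= {"noise0", "noise1"}

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        counts = {
            f"a{i}": {f"s{j}": int(rng.integers(0, 30)) for j in range(5)}
            for i in range(12)
        }
        chart = make_chart(counts)
        meta = make_meta([f"s{j}" for j in range(5)])
        once, _ = vet_dataset(chart, meta)
        twice, rep2 = vet_dataset(once, meta)
        assert twice == once
        assert rep2.removed_by_taxonomy == []
        assert rep2.removed_by_presence == []
        assert rep2.removed_specimens == []

    def test_idempotence_with_stranding_specimen_removal(self):
        # ASV 'x' is present >=3 only in the weak specimen that gets dropped
        chart = make_chart({"x": {"s1": 4, "s2": 0}, "y": {"s1": 0, "s2": 60}})
        meta = make_meta(["s1", "s2"])
        once, _ = vet_dataset(chart, meta)
        assert "x" not in once.asv_ids  # stranded ASV cleaned up
        twice, _ = vet_dataset(once, meta)
        assert twice == once

    @pytest.mark.parametrize("knob,delta", [
        ("min_reads_presence", 2),
        ("min_specimen_reads", 10),
        ("min_asv_reads_somewhere", 4),
        ("min_confidence", 0.4),
    ])
    def test_monotonicity_raising_thresholds(self, knob, delta):
        rng = np.random.default_rng(11)
        counts = {
            f"a{i}": {f"s{j}": int(rng.integers(0, 25)) for j in range(6)}
            for i in range(15)
        }
        conf = {f"a{i}": float(rng.uniform(0.2, 1.0)) for i in range(15)}
        chart = make_chart(counts, confidence=conf)
        meta = make_meta([f"s{j}" for j in range(6)])
        base, _ = vet_dataset(chart, meta, VettingConfig())
        kwargs = {knob: getattr(VettingConfig(), knob) + delta}
        tighter, _ = vet_dataset(chart, meta, VettingConfig(**kwargs))
        assert set(tighter.asv_ids) <= set(base.asv_ids)
        assert set(tighter.specimen_ids) <= set(base.specimen_ids)

    def test_partition_property_read_mass(self):
        rng = np.random.default_rng(3)
        counts = {
            f"a{i}": {f"s{j}": int(rng.integers(0, 40)) for j in range(4)}
            for i in range(10)
        }
        families = {f"a{i}": ("Collosphaeridae" if i % 3 else "Pterocorythidae") for i in range(10)}
        chart = make_chart(counts, families=families)
        meta = make_meta([f"s{j}" for j in range(4)], family="Collosphaeridae")
        vetted, rep = vet_dataset(chart, meta)
        assert rep.input_total_reads == chart.total_reads
        assert rep.retained_total_reads == vetted.total_reads
        assert rep.removed_total_reads == chart.total_reads - vetted.total_reads
        assert rep.removed_total_reads >= 0

    def test_report_summary_by_order(self, paper_like_bundle):
        chart, meta, truth = paper_like_bundle
        vetted, rep = vet_dataset(chart, meta)
        for order, stats in rep.retained_summary.items():
            assert stats["n_specimens"] >= 0 and stats["n_asvs"] >= 0
        total_specs = sum(s["n_specimens"] for s in rep.retained_summary.values())
        assert total_specs == len(vetted.specimen_ids)

    def test_strict_mode_never_retains_more(self):
        rng = np.random.default_rng(5)
        counts = {
            f"a{i}": {f"s{j}": int(rng.integers(0, 8)) for j in range(5)}
            for i in range(12)
        }
        chart = make_chart(counts)
        meta = make_meta([f"s{j}" for j in range(5)])
        default, _ = vet_dataset(chart, meta, VettingConfig())
        strict, _ = vet_dataset(chart, meta, VettingConfig(strict_global_rule=True))
        assert set(strict.asv_ids) <= set(default.asv_ids)


class TestConfigValidation:
    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            VettingConfig(min_reads_presence=-1)

    def test_bad_confidence_rejected(self):
        with pytest.raises(ValueError):
            VettingConfig(min_confidence=1.5)
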