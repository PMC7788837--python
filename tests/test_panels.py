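import numpy as np
import pytest

from mixindep import (
    PanelDesign,
    allele_freq,
    build_panel,
    genotype_freq,
    hwe_test,
    power_study,
    sample_marker_model,
    simulate_linked_block,
    simulate_unlinked,
    test_independence as run_test,
)
from mixindep.panels import MarkerModel, _linked_count


class TestDesignRules:
    @pytest.mark.parametrize(
        "size,linkage,bias,expected",
        [
            (20, "Unlinked", "Both", (0, 0, 0)),
            (20, "OnePair", "SNP", (2, 2, 0)),
            (20, "OnePair", "STR", (2, 0, 2)),
            (16, "HalfQuarter", "SNP", (2, 2, 0)),
            (16, "HalfQuarter", "Both", (2, 1, 1)),
            (20, "Quarter", "STR", (5, 0, 5)),
            (20, "Half", "SNP", (10, 10, 0)),
            (20, "Half", "Both", (10, 5, 5)),
            (20, "ThreeQuarter", "SNP", (15, 10, 5)),
            (20, "ThreeQuarter", "STR", (15, 5, 10)),
            (20, "Almost", "SNP", (18, 10, 8)),
            (20, "Almost", "STR", (18, 8, 10)),
            (20, "Fully", "Both", (20, 10, 10)),
        ],
    )
    def test_grid_rules(self, size, linkage, bias, expected):
        d = PanelDesign.from_rules(size, linkage, bias)
        assert (d.n_linked, d.n_linked_snps, d.n_linked_strs) == expected

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            PanelDesign.from_rules(20, "OnePair", "Both")
        with pytest.raises(ValueError):
            PanelDesign.from_rules(20, "Almost", "Both")
        with pytest.raises(ValueError):
            PanelDesign.from_rules(20, "HalfQuarter", "SNP")  # 2.5 markers
        with pytest.raises(ValueError):
            PanelDesign.from_rules(15, "Unlinked", "Both")  # odd size
        with pytest.raises(ValueError):
            PanelDesign(20, 4, 3, 1, "Quarter", "Both")  # unequal Both split

    def test_direct_construction_checks_counts(self):
        with pytest.raises(ValueError, match="requires"):
            PanelDesign(20, 4, 2, 2, "Half", "Both")  # Half at 20 means 10

    def test_linked_count_helper(self):
        assert _linked_count("Fully", 32) == 32
        assert _linked_count("Almost", 32) == 30
        with pytest.raises(ValueError):
            _linked_count("Quarter", 10)  # 2.5 markers


class TestMarkerModels:
    def test_snp_model_contract(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = sample_marker_model("SNP", rng)
            assert len(m.labels) == 2 and len(set(m.labels)) == 2
            assert 0.1 <= m.freqs.min() <= 0.5
            assert m.freqs.sum() == pytest.approx(1.0)

    def test_str_model_contract_and_min_heterozygosity(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            m = sample_marker_model("STR", rng)
            assert 5 <= len(m.labels) <= 10
            assert m.freqs.sum() == pytest.approx(1.0)
            assert m.heterozygosity >= 0.5


class TestUnlinkedSimulation:
    def test_shape(self):
        models = [sample_marker_model("STR", np.random.default_rng(3)) for _ in range(20)]
        models += [sample_marker_model("SNP", np.random.default_rng(4)) for _ in range(10)]
        table = simulate_unlinked(models, 500, seed=5)
        assert (table.n_samples, table.n_markers) == (500, 30)

    def test_empirical_frequencies_match_models(self):
        model = MarkerModel("STR", ["1", "2", "3", "4", "5"], np.array([0.4, 0.3, 0.15, 0.1, 0.05]))
        table = simulate_unlinked([model], 100_000, seed=6)
        freqs = allele_freq(table).freqs[table.marker_ids[0]]
        for label, p in zip(model.labels, model.freqs):
            assert freqs[label] == pytest.approx(p, abs=0.01)

    def test_loci_are_uncorrelated(self):
        models = [
            MarkerModel("SNP", ["A", "T"], np.array([0.5, 0.5])),
            MarkerModel("SNP", ["C", "G"], np.array([0.5, 0.5])),
        ]
        table = simulate_unlinked(models, 100_000, seed=7)
        dosage = np.stack(
            [
                (table.alleles[:, j, :] == models[j].labels[1]).sum(axis=1)
                for j in range(2)
            ]
        ).astype(float)
        r2 = np.corrcoef(dosage)[0, 1] ** 2
        assert r2 < 0.001


class TestLinkedBlock:
    def test_two_class_block_gives_perfect_correlation(self):
        # with two haplotype classes every SNP map is a bijection, so any
        # two block SNPs are deterministic relabelings of each other: r^2 = 1
        models = [
            MarkerModel("SNP", ["A", "T"], np.array([0.5, 0.5]), block=0),
            MarkerModel("SNP", ["C", "G"], np.array([0.5, 0.5]), block=0),
        ]
        cols = simulate_linked_block(models, 2000, n_hap_classes=2, rng=8)
        dosage = np.stack(
            [(cols[:, j, :] == models[j].labels[1]).sum(axis=1) for j in range(2)]
        ).astype(float)
        assert np.corrcoef(dosage)[0, 1] ** 2 == pytest.approx(1.0)

    def test_block_panel_is_detected_as_dependent(self):
        panel = build_panel(PanelDesign.from_rules(10, "Fully", "Both"), 500, seed=9)
        result = run_test(panel, "K", B=300, seed=10)
        assert result.reject

    def test_block_marginals_stay_in_hwe(self):
        # the two latent classes of an individual are drawn i.i.d., so each
        # locus alone should not show HWE departure more often than alpha
        rng = np.random.default_rng(11)
        low_p = 0
        for rep in range(40):
            panel = build_panel(
                PanelDesign.from_rules(4, "Fully", "Both"), 400, seed=rng
            )
            pvals = hwe_test(
                genotype_freq(panel),
                genotype_freq(panel, expected=True),
                simulate_p=True,
                B=400,
                seed=rng,
            )
            low_p += int((pvals < 0.05).sum())
        # 160 marker-tests at alpha 0.05 -> expect ~8 rejections
        assert low_p <= 20

    def test_too_small_block_rejected(self):
        models = [MarkerModel("SNP", ["A", "T"], np.array([0.5, 0.5]))]
        with pytest.raises(ValueError):
            simulate_linked_block(models, 100, rng=1)
        with pytest.raises(ValueError):
            simulate_linked_block(models * 2, 100, n_hap_classes=1, rng=1)


class TestBuildPanel:
    def test_composition_and_determinism(self):
        design = PanelDesign.from_rules(20, "Half", "SNP")
        panel = build_panel(design, 100, seed=12)
        assert panel.n_markers == 20
        assert panel.marker_types.count("SNP") == 10
        assert panel.marker_types.count("STR") == 10
        again = build_panel(design, 100, seed=12)
        assert panel.equals(again)
        assert not panel.equals(build_panel(design, 100, seed=13))

    def test_power_study_schema_and_monotone_power_in_linked_markers(self):
        designs = [
            PanelDesign.from_rules(size, "Fully", "Both") for size in (10, 20, 50)
        ]
        df = power_study(designs, n=100, trials=40, B=150, seed=14, statistics=("K",))
        assert list(df["panel_size"]) == [10, 20, 50]
        assert {"panel_size", "n_linked", "linkage", "bias", "power_K"} <= set(df.columns)
        powers = df["power_K"].to_numpy()
        assert (np.diff(powers) >= -0.05).all()  # non-decreasing up to MC noise
        assert powers[-1] >= 0.95

    def test_power_study_reproducible(self):
        designs = [PanelDesign.from_rules(10, "Unlinked", "Both")]
        a = power_study(designs, n=80, trials=10, B=100, seed=15)
        b = power_study(designs, n=80, trials=10, B=100, seed=15)
        assert a.equals(b)
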