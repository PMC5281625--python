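"""The RN odd-mass statistic, system sums, differential features, ratio
distribution, identified ratios, and PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from corrosomics.metabolome_stats import (
    differential_features,
    id_ratio_top_n,
    parse_system_map,
    pca_features,
    ratio_distribution,
    rn_statistic,
    system_sums,
)
from corrosomics.synthetic_data import GeneratorConfig, simulate_metabolome
from conftest import make_table

SAMPLES = ("LC3", "LC11", "HC3", "HC11")


class TestRN:
    def test_hand_arithmetic(self):
        # one odd-nominal-mass feature (75 Da) at 300 i.u., one even (146) at 700
        table = make_table([75.032, 146.0579], [1, 2], ["negative"] * 2,
                           [{"HC11": 300.0}, {"HC11": 700.0}])
        rn = rn_statistic(table, "HC11")
        assert rn.rn_percent == pytest.approx(30.0)
        assert rn.odd_abundance_iu == pytest.approx(300.0)

    def test_all_even_gives_zero_and_zero_total_errors(self):
        table = make_table([146.0579, 174.0892], [1, 2], ["negative"] * 2,
                           [{"HC11": 100.0}, {"HC11": 100.0}])
        assert rn_statistic(table, "HC11").rn_percent == 0.0
        with pytest.raises(ValueError, match="undefined"):
            rn_statistic(table, "LC3")

    def test_invariant_to_uniform_rescaling_and_bounded(self):
        rng = np.random.default_rng(4)
        means = [{s: float(rng.uniform(10, 1000)) for s in SAMPLES} for _ in range(30)]
        table = make_table(rng.uniform(80, 400, 30), rng.uniform(0, 30, 30), ["positive"] * 30, means)
        rn1 = rn_statistic(table, "LC3").rn_percent
        scaled = make_table(
            table.features["neutral_mass_da"], table.features["rt_min"], table.features["ion_mode"],
            [{s: 7.5 * m[s] for s in SAMPLES} for m in means],
        )
        assert rn_statistic(scaled, "LC3").rn_percent == pytest.approx(rn1, abs=1e-9)
        assert 0.0 <= rn1 <= 100.0

    def test_formula_parity_overrides_mass_rounding(self):
        table = make_table([146.0579], [1], ["negative"], [{"HC11": 100.0}])
        fid = table.features.index[0]
        assert rn_statistic(table, "HC11").rn_percent == 0.0
        assert rn_statistic(table, "HC11", parity_overrides={fid: True}).rn_percent == 100.0

    def test_recovers_generator_ground_truth_within_shot_noise(self, bundle):
        for sample, truth in bundle.truth.true_rn.items():
            est = rn_statistic(bundle.table, sample).rn_percent
            assert est == pytest.approx(truth, abs=1.0)


def test_system_sums_examples_and_oracle():
    table = make_table([100.0], [1], ["positive"],
                       [{"LC3": 100.0, "LC11": 200.0, "HC3": 0.0, "HC11": 50.0}])
    sums = system_sums(table)
    fid = table.features.index[0]
    assert sums.loc[fid, "LC"] == 300.0 and sums.loc[fid, "HC"] == 50.0
    rng = np.random.default_rng(6)
    means = [{s: float(rng.uniform(0, 100)) for s in SAMPLES} for _ in range(5)]
    t5 = make_table(rng.uniform(80, 200, 5), rng.uniform(0, 10, 5), ["positive"] * 5, means)
    s5 = system_sums(t5)
    for i, fid in enumerate(t5.features.index):
        assert s5.loc[fid, "LC"] == pytest.approx(means[i]["LC3"] + means[i]["LC11"])
        assert s5.loc[fid, "HC"] == pytest.approx(means[i]["HC3"] + means[i]["HC11"])
    with pytest.raises(KeyError):
        system_sums(t5, {"LC3": "LC"})  # unmapped samples


class TestDifferential:
    def _sums(self, pairs):
        return pd.DataFrame(pairs, columns=["HC", "LC"])

    def test_rule_arithmetic(self):
        res = differential_features(self._sums([(60_000.0, 5_000.0)]))
        assert res.hc_enriched_count == 1 and res.lc_enriched_count == 0
        res = differential_features(self._sums([(9_000.0, 1_000.0)]))
        assert res.hc_enriched_count == res.lc_enriched_count == 0  # abundance gate
        res = differential_features(self._sums([(50_000.0, 10_000.0)]))
        assert res.hc_enriched_count == 1  # ratio exactly 5 is inclusive
        res = differential_features(self._sums([(50_000.0, 0.0)]))
        assert res.hc_enriched_count == 1  # infinite ratio counts
        assert math.isinf(res.per_feature["hc_lc_ratio"].iloc[0])

    def test_sets_disjoint_and_gates_monotone(self):
        rng = np.random.default_rng(9)
        sums = self._sums(list(zip(10 ** rng.uniform(2, 6, 300), 10 ** rng.uniform(2, 6, 300))))
        base = differential_features(sums)
        assert not (base.per_feature["hc_enriched"] & base.per_feature["lc_enriched"]).any()
        tighter_ab = differential_features(sums, min_abundance_iu=50_000.0)
        tighter_ratio = differential_features(sums, min_ratio=10.0)
        assert tighter_ab.hc_enriched_count <= base.hc_enriched_count
        assert tighter_ab.lc_enriched_count <= base.lc_enriched_count
        assert tighter_ratio.hc_enriched_count <= base.hc_enriched_count
        assert tighter_ratio.lc_enriched_count <= base.lc_enriched_count

    def test_noiseless_generator_labels_recovered_exactly(self):
        config = GeneratorConfig(seed=5, shot_noise=False, n_true_metabolites=150, n_exochemicals=100)
        b = simulate_metabolome(config)
        res = differential_features(system_sums(b.table))
        assert res.hc_enriched_count == len(b.truth.hc_enriched_ids)
        assert res.lc_enriched_count == len(b.truth.lc_enriched_ids)
        pf = res.per_feature
        assert set(pf.index[pf["hc_enriched"]]) == set(b.truth.hc_enriched_ids)
        assert set(pf.index[pf["lc_enriched"]]) == set(b.truth.lc_enriched_ids)


def test_ratio_distribution_counting_and_one_sided_handling():
    sums = pd.DataFrame(
        {"HC": [100, 100, 100, 100, 100, 100, 100, 100, 100, 100, 0.0],
         "LC": [50, 60, 70, 80, 90, 110, 400, 500, 600, 700, 100.0]})
    out = ratio_distribution(sums)
    assert out.fraction_similar == pytest.approx(0.6)
    assert out.n_both_nonzero == 10 and out.n_one_sided == 1
    same = pd.DataFrame({"HC": [5.0, 6.0], "LC": [5.0, 6.0]})
    assert ratio_distribution(same).fraction_similar == 1.0


def test_id_ratio_top_n():
    rng = np.random.default_rng(10)
    means = [{"HC11": 1000.0 - i} for i in range(300)]
    table = make_table(rng.uniform(80, 400, 300), rng.uniform(0, 30, 300), ["positive"] * 300, means)
    top = table.sample_means()["HC11"].sort_values(ascending=False).index[:200]
    assert id_ratio_top_n(table, set(top[:120]), "HC11") == pytest.approx(1.5)
    assert id_ratio_top_n(table, set(top[:100]), "HC11") == pytest.approx(1.0)
    assert id_ratio_top_n(table, set(), "HC11") == 0.0
    assert math.isinf(id_ratio_top_n(table, set(top), "HC11"))
    with pytest.raises(ValueError):
        id_ratio_top_n(table, set(), "HC11", n=301)


@pytest.fixture(scope="module")
def clustered():
    config = GeneratorConfig(
        seed=11, n_true_metabolites=150, n_exochemicals=50,
        frac_hc_enriched=0.3, frac_lc_enriched=0.3, spikes=(), rn_targets=None,
    )
    return simulate_metabolome(config).table


class TestPCA:
    @pytest.mark.filterwarnings("ignore:invalid value")
    def test_identical_replicates_coincide(self):
        table = make_table([100.0, 200.0, 300.0], [1, 2, 3], ["positive"] * 3,
                           [{s: 20000.0 for s in SAMPLES},
                            {s: 15000.0 for s in SAMPLES},
                            {s: 11000.0 for s in SAMPLES}])
        res = pca_features(table)
        assert np.allclose(res.scores[["PC1", "PC2"]].to_numpy().std(axis=0), 0.0, atol=1e-9)

    def test_pc1_separates_the_two_systems(self, clustered):
        res = pca_features(clustered, scale="log")
        pc1 = res.scores["PC1"]
        systems = ["HC" if s.startswith("HC") else "LC" for s in pc1.index.get_level_values(0)]
        hc = pc1.to_numpy()[np.array(systems) == "HC"]
        lc = pc1.to_numpy()[np.array(systems) == "LC"]
        assert max(hc.max(), lc.max()) > min(hc.min(), lc.min())  # sanity
        assert hc.min() > lc.max() or lc.min() > hc.max()  # no overlap

    def test_linear_and_log_scalings_agree_on_pc1(self, clustered):
        lin = pca_features(clustered, scale="linear").scores["PC1"].to_numpy()
        log = pca_features(clustered, scale="log").scores["PC1"].to_numpy()
        assert abs(np.corrcoef(lin, log)[0, 1]) > 0.9

    def test_explained_variance_fractions_well_formed(self, clustered):
        evr = pca_features(clustered).explained_variance_ratio
        assert evr.sum() <= 1.0 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_gate_and_degenerate_inputs(self):
        table = make_table([100.0, 200.0], [1, 2], ["positive"] * 2,
                           [{s: 500.0 for s in SAMPLES}, {s: 600.0 for s in SAMPLES}])
        with pytest.raises(ValueError):
            pca_features(table)  # nothing passes the 10,000 i.u. gate


def test_statistics_match_brute_force_on_small_table(bundle):
    """RN / sums / differential agree with direct numpy recomputation."""
    small = bundle.table.subset(bundle.table.features.index[:20])
    means = small.abundances.T.groupby(level=0).mean().T
    parity = np.array([
        int(np.floor(m + 0.5)) % 2 == 1 for m in small.features["neutral_mass_da"]
    ])
    for sample in small.sample_names:
        expected = 100 * means[sample].to_numpy()[parity].sum() / means[sample].sum()
        assert rn_statistic(small, sample).rn_percent == pytest.approx(expected)
    sums = system_sums(small)
    assert np.allclose(sums["HC"], means[["HC3", "HC11"]].sum(axis=1))
    res = differential_features(sums)
    hand = ((sums.max(axis=1) > 10_000) & ((sums["LC"] == 0) | (sums["HC"] / sums["LC"] >= 5))).sum()
    assert res.hc_enriched_count == hand


def test_parse_system_map():
    assert parse_system_map("HC=HC3,HC11;LC=LC3,LC11") == {
        "HC3": "HC", "HC11": "HC", "LC3": "LC", "LC11": "LC"
    }
    with pytest.raises(ValueError):
        parse_system_map("HC:HC3")
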