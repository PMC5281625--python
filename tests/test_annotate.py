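"""Exact-mass library matching, the QSRR retention-time model, confidence
scoring, best-match selection, and pathway roll-up."""

import itertools

import numpy as np
import pytest

from corrosomics.annotate import (
    Annotation,
    CompoundRecord,
    RTModel,
    annotate_table,
    confidence_score,
    fit_rt_model,
    map_pathways,
    match_features,
    predict_rt,
    read_compound_library,
    select_best,
    write_compound_library,
)
from corrosomics.chem_mass import parse_formula
from conftest import make_table


def _compound(cid="C1", formula="C6H10O4", priority=1, descriptors=None, pathways=(), rt=None):
    return CompoundRecord(
        compound_id=cid,
        name=cid,
        formula=parse_formula(formula),
        source_db="KEGG",
        db_priority=priority,
        pathway_ids=tuple(pathways),
        descriptors=descriptors,
        reference_rt=rt,
    )


class TestRTModel:
    def test_noiseless_system_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))
        beta = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.25])
        y = 2.0 + X @ beta
        model = fit_rt_model(X, y)
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(model.coefficients, beta, atol=1e-9)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-6)
        # prediction interpolates the calibration points exactly
        assert model.predict(X[3]) == pytest.approx(y[3], abs=1e-9)

    def test_underdetermined_and_rank_deficient_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="at least"):
            fit_rt_model(rng.normal(size=(6, 6)), rng.normal(size=6))
        X = rng.normal(size=(20, 6))
        X[:, 5] = X[:, 0]  # collinear
        with pytest.raises(ValueError, match="rank"):
            fit_rt_model(X, rng.normal(size=20))

    def test_coefficient_recovery_within_three_se(self):
        """At the calibration design of the study (n=33 standards, 0.5 min
        residual noise) each coefficient lands within 3 standard errors of
        truth in at least 99% of seeded replicates."""
        rng = np.random.default_rng(2024)
        beta = np.array([1.2, -0.8, 0.5, 2.0, -1.5, 0.9])
        reps = 500
        hits = np.zeros(6)
        for _ in range(reps):
            X = rng.normal(size=(33, 6))
            y = 14.0 + X @ beta + rng.normal(0.0, 0.5, size=33)
            model = fit_rt_model(X, y)
            within = np.abs(np.array(model.coefficients) - beta) <= 3 * np.array(model.stderr)
            hits += within
        # coverage of 3-SE intervals is ~99.4% nominal under t(26)
        assert hits.sum() / (6 * reps) >= 0.99
        assert (hits / reps >= 0.985).all()

    def test_predict_rt_zero_descriptors_and_dot_product(self):
        model = RTModel(intercept=2.0, coefficients=(1.0,) * 6, n_calibration=10, residual_sd=0.1)
        assert model.predict(np.zeros(6)) == 2.0
        assert model.predict(np.full(6, 0.5)) == pytest.approx(5.0)
        assert predict_rt(model, _compound(descriptors=None)) is None


class TestMatching:
    def test_mass_gate_at_six_ppm(self):
        table = make_table([146.0580, 146.0590], [1.2, 1.2], ["negative", "negative"],
                           [{"HC11": 5000.0}, {"HC11": 5000.0}])
        matches = match_features(table, [_compound()])
        f1, f2 = table.features.index
        assert f1 in matches and matches[f1][0].mass_error_ppm == pytest.approx(0.62, abs=0.05)
        assert f2 not in matches  # 7.5 ppm off

    def test_rt_gate_applies_to_positive_mode_only(self):
        model = RTModel(intercept=5.0, coefficients=(0.0,) * 6, n_calibration=10, residual_sd=0.1)
        compound = _compound(descriptors=np.zeros(6))
        pos = make_table([146.0579], [10.0], ["positive"], [{"HC11": 5000.0}])
        neg = make_table([146.0579], [10.0], ["negative"], [{"HC11": 5000.0}])
        assert match_features(pos, [compound], rt_model=model) == {}  # deviation 1.0 > 0.45
        neg_matches = match_features(neg, [compound], rt_model=model)
        assert len(neg_matches) == 1  # negative mode skips the gate

    def test_accepted_candidates_respect_both_gates(self):
        rng = np.random.default_rng(5)
        model = RTModel(intercept=10.0, coefficients=(1.0,) * 6, n_calibration=10, residual_sd=0.1)
        library = [
            _compound(f"C{k}", "C6H10O4", descriptors=rng.normal(size=6) * 0.3) for k in range(5)
        ]
        table = make_table(
            rng.uniform(146.0570, 146.0588, 10),
            rng.uniform(1, 30, 10),
            ["positive"] * 10,
            [{"HC11": 5000.0}] * 10,
        )
        for cands in match_features(table, library, rt_model=model).values():
            for a in cands:
                assert abs(a.mass_error_ppm) <= 6.0
                if a.rt_deviation_fraction is not None:
                    assert a.rt_deviation_fraction <= 0.45


class TestConfidence:
    def test_rubric_extremes(self):
        assert confidence_score(0.0, 0.0, 1) == 10
        assert confidence_score(6.0, 0.45, 4) == 1
        assert confidence_score(6.0, 0.45, 9) == 1  # floor
        assert confidence_score(0.0, None, 1, matched_standard=True) == 10

    def test_rubric_intermediate_rounds_half_up(self):
        # 10 - 1.5 (mass) - 1 (no RT) - 0 (rank 1) = 7.5 -> 8
        assert confidence_score(3.0, None, 1) == 8

    def test_rubric_monotone_in_each_penalty(self):
        for ppm_lo, ppm_hi in [(0, 3), (3, 6)]:
            assert confidence_score(ppm_lo, 0.1, 2) >= confidence_score(ppm_hi, 0.1, 2)
        assert confidence_score(1.0, 0.0, 1) >= confidence_score(1.0, 0.4, 1)
        assert confidence_score(1.0, 0.1, 1) >= confidence_score(1.0, 0.1, 3)


class TestSelection:
    def test_single_and_empty(self):
        a = Annotation("F1", "C1", 1.0, confidence=5, accepted=True)
        assert select_best([a]) is a
        assert select_best([]) is None

    def test_tie_broken_by_database_priority(self):
        lib = {f"C{k}": _compound(f"C{k}", priority=p) for k, p in enumerate((1, 2, 1))}
        anns = [
            Annotation("F1", "C0", 1.0, confidence=7, accepted=True),
            Annotation("F1", "C1", 0.5, confidence=9, accepted=True),
            Annotation("F1", "C2", 2.0, confidence=9, accepted=True),
        ]
        assert select_best(anns, lib).compound_id == "C2"  # the 9 with rank 1

    def test_winner_invariant_under_input_permutation(self):
        lib = {f"C{k}": _compound(f"C{k}", priority=1 + k % 3) for k in range(4)}
        anns = [
            Annotation("F1", f"C{k}", ppm, confidence=c, accepted=True)
            for k, (ppm, c) in enumerate([(1.0, 8), (0.5, 8), (2.0, 8), (0.1, 7)])
        ]
        winners = {select_best(list(p), lib).compound_id for p in itertools.permutations(anns)}
        assert len(winners) == 1


def test_map_pathways_counts_and_unassigned():
    library = [
        _compound("C1", pathways=("P",)),
        _compound("C2", "C7H12O4", pathways=("P", "Q")),
        _compound("C3", "C8H14O4", pathways=()),
    ]
    anns = {
        "F1": Annotation("F1", "C1", 0.0, confidence=9, accepted=True),
        "F2": Annotation("F2", "C2", 0.0, confidence=9, accepted=True),
        "F3": Annotation("F3", "C3", 0.0, confidence=9, accepted=True),
    }
    out = map_pathways(anns, library)
    assert out.loc["P", "n_metabolites"] == 2
    assert out.loc["Q", "n_metabolites"] == 1
    assert out.loc["unassigned", "n_metabolites"] == 1
    # all pathway-free library -> everything unassigned
    bare = [_compound("C1"), _compound("C2", "C7H12O4")]
    out2 = map_pathways({k: v for k, v in anns.items() if k != "F3"}, bare)
    assert list(out2.index) == ["unassigned"] and out2["n_metabolites"].sum() == 2


def test_library_tsv_roundtrip(tmp_path, bundle):
    path = tmp_path / "library.tsv"
    write_compound_library(bundle.library[:25], path)
    back = read_compound_library(path)
    assert len(back) == 25
    for a, b in zip(bundle.library[:25], back):
        assert a.compound_id == b.compound_id and a.formula == b.formula
        assert a.pathway_ids == b.pathway_ids
        assert np.allclose(a.descriptors, b.descriptors)


def test_full_recall_on_synthetic_metabolites(bundle, filtered_table, rt_model):
    """With well-separated library masses, every retained true metabolite is
    identified at 6 ppm (the RT gate included), no exochemical is, and
    tightening the tolerance never adds annotations."""
    annotations = annotate_table(filtered_table, bundle.library, rt_model=rt_model)
    identified = set(annotations)
    kinds = bundle.truth.per_feature.loc[filtered_table.features.index, "kind"]
    metabolites = set(kinds.index[kinds == "metabolite"])
    exochemicals = set(kinds.index[kinds == "exochemical"])
    assert metabolites <= identified
    assert not (identified & exochemicals)
    # correct identities, not just any match
    compound_truth = bundle.truth.per_feature["compound_id"]
    for fid in metabolites:
        assert annotations[fid].compound_id == compound_truth[fid]
    counts = []
    for tol in (6.0, 3.0, 1.0):
        counts.append(len(annotate_table(filtered_table, bundle.library, rt_model=rt_model, mass_tol_ppm=tol)))
    assert counts[0] >= counts[1] >= counts[2]
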