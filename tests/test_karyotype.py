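"""Fold estimation, grid classification, nuclear composition, cohort screens."""

import itertools

import numpy as np
import pytest

from karyoscope import presets
from karyoscope.depth import ChromosomeDepth, summarize_chromosome_depth
from karyoscope.karyotype import (
    CompositionInfeasible,
    KaryotypeCall,
    KaryotypeModel,
    NucleusMixture,
    classify_folds,
    enumerate_splits,
    estimate_folds,
    infer_nuclear_composition,
    screen_cohort,
)
from karyoscope.synthetic import StrainConfig, build_cohort, simulate_depth

from conftest import make_strain


def _summaries(depths):
    return [ChromosomeDepth(f"chr{i + 1:02d}", 100, d, 1.0, 0.0)
            for i, d in enumerate(depths)]


class TestEstimateFolds:
    def test_median_baseline_and_folds(self):
        folds = estimate_folds(_summaries([50, 50, 50, 100]))
        assert folds[0].baseline == 50
        assert [f.raw_fold for f in folds] == [1, 1, 1, 2]

    def test_all_equal_gives_unit_folds(self):
        folds = estimate_folds(_summaries([70] * 6))
        assert all(f.raw_fold == 1.0 for f in folds)

    def test_scale_invariance(self):
        a = estimate_folds(_summaries([40, 44, 38, 80]))
        b = estimate_folds(_summaries([120, 132, 114, 240]))
        assert [f.raw_fold for f in a] == pytest.approx([f.raw_fold for f in b])

    def test_noiseless_mixture_fold_exact(self):
        # 3 nuclei-weighted copies over baseline 2 -> fold exactly 1.5
        strain = StrainConfig.dikaryon("d", presets.cv(), presets.cv(chr14=2),
                                       dispersion=0.0, outlier_fraction=0.0)
        bins, _ = simulate_depth([100_000] * 15, strain)
        folds = estimate_folds(summarize_chromosome_depth(bins))
        assert folds[13].raw_fold == pytest.approx(1.5)

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_folds(_summaries([50]))


class TestClassifyFolds:
    def test_near_unity_assigned_euploid(self):
        call = classify_folds(estimate_folds(_summaries([50, 51, 49.5, 51.0 * 1.0])))
        assert call.verdict == "euploid"
        assert all(e.multiple == 1.0 for e in call.estimates)

    def test_duplicated_chromosome_aneuploid(self):
        call = classify_folds(estimate_folds(_summaries([50] * 14 + [50 * 2.03])))
        assert call.verdict == "aneuploid"
        assert call.duplicated == {"chr15": 2.0}

    def test_gap_fold_unassigned_ambiguous(self):
        folds = estimate_folds(_summaries([50, 50, 50, 50 * 1.25]))
        call = classify_folds(folds, grid=(1.0, 1.5, 2.0), tolerance=0.1)
        assert call.verdict == "ambiguous"
        assert call.estimates[-1].multiple is None

    def test_grid_must_contain_one(self):
        with pytest.raises(ValueError, match="1.0"):
            classify_folds(estimate_folds(_summaries([50, 50])), grid=(1.5, 2.0))

    def test_s10_fixture_duplicated_set(self):
        strain = presets.strain_S10(seed=3)
        bins, _ = simulate_depth(presets.CHROMOSOME_LENGTHS, strain)
        res = KaryotypeModel(bins, "S10").fit(seed=3, bootstrap_reps=50)
        assert res.verdict == "aneuploid"
        assert res.duplicated == {"chr14": 1.5, "chr15": 2.0}


class TestKaryotypeModel:
    def test_fit_recovers_planted_multiples(self):
        strain = make_strain("L7", presets.cv(chr15=2), seed=7)
        bins, _ = simulate_depth(presets.CHROMOSOME_LENGTHS, strain)
        res = KaryotypeModel(bins, "L7").fit(seed=1, bootstrap_reps=50)
        assert res.duplicated == {"chr15": 2.0}
        assert res.estimates[14].confidence >= 0.95

    def test_scale_invariance_of_calls(self):
        strain = make_strain("s", presets.cv(chr15=2), seed=19)
        bins, _ = simulate_depth([500_000] * 15, strain)
        r1 = KaryotypeModel(bins, "s").fit(seed=2, bootstrap_reps=0)
        r2 = KaryotypeModel(bins.scaled(2.5), "s").fit(seed=2, bootstrap_reps=0)
        assert [e.multiple for e in r1.estimates] == [e.multiple for e in r2.estimates]
        assert [e.raw_fold for e in r1.estimates] == pytest.approx(
            [e.raw_fold for e in r2.estimates])

    def test_confidence_not_increasing_with_dispersion(self):
        confs = []
        for disp in (0.05, 1.5):
            strain = make_strain("s", presets.cv(chr15=2), base_depth=20.0,
                                 dispersion=disp, outlier_fraction=0.0, seed=23)
            bins, _ = simulate_depth([400_000] * 15, strain)
            res = KaryotypeModel(bins, "s").fit(seed=5, bootstrap_reps=100)
            confs.append(res.estimates[14].confidence)
        assert confs[1] <= confs[0] + 1e-9

    def test_summary_contains_verdict_and_folds(self):
        strain = make_strain("L7", presets.cv(chr15=2), seed=7)
        bins, _ = simulate_depth([1_000_000] * 15, strain)
        res = KaryotypeModel(bins, "L7").fit(bootstrap_reps=0)
        text = res.summary()
        assert "aneuploid" in text and "chr15" in text

    def test_mode_baseline_option(self):
        strain = make_strain("s", presets.cv(chr15=2), seed=29)
        bins, _ = simulate_depth([500_000] * 15, strain)
        res = KaryotypeModel(bins, "s").fit(baseline_method="mode",
                                            bootstrap_reps=0)
        assert res.duplicated == {"chr15": 2.0}


def brute_force_splits(total, nuclei):
    """Oracle: all unordered splits of `total` copies into `nuclei` >= 1."""
    out = set()
    for combo in itertools.product(range(1, total + 1), repeat=nuclei):
        if sum(combo) == total:
            out.add(tuple(sorted(combo, reverse=True)))
    return out


class TestNuclearComposition:
    def test_homokaryon_duplication(self):
        mixtures = infer_nuclear_composition({"chr15": 2.0}, nucleus_count=1)
        assert len(mixtures) == 1
        assert mixtures[0].components == [((2,), 1.0)]

    def test_dikaryon_1_5_fold_parsimony_split(self):
        mixtures = infer_nuclear_composition({"chr15": 1.5}, nucleus_count=2)
        # total 3 copies over two nuclei: only split is (1, 2)
        assert len(mixtures) == 1
        assert sorted(v[0] for v, _ in mixtures[0].components) == [1, 2]

    def test_dikaryon_multiple_3_complete_enumeration(self):
        mixtures = infer_nuclear_composition({"chr15": 3.0}, nucleus_count=2)
        splits = {tuple(sorted((v[0] for v, _ in m.components), reverse=True))
                  for m in mixtures}
        assert splits == {(3, 3), (4, 2), (5, 1)}
        # parsimony: the balanced single-genotype split ranks first
        first = mixtures[0]
        assert first.n_distinct == 1

    @pytest.mark.parametrize("nuclei", [1, 2, 3, 4])
    @pytest.mark.parametrize("multiple", [1.0, 2.0, 3.0, 4.0])
    def test_enumeration_matches_brute_force(self, nuclei, multiple):
        total = int(multiple * nuclei)
        assert set(enumerate_splits(total, nuclei)) == brute_force_splits(total, nuclei)

    def test_homokaryon_half_fold_needs_mixture(self):
        with pytest.raises(CompositionInfeasible):
            infer_nuclear_composition({"chr15": 1.5}, nucleus_count=1)
        mixtures = infer_nuclear_composition({"chr15": 1.5}, nucleus_count=1,
                                             allow_mixture=True)
        assert len(mixtures) == 1
        comp = dict(mixtures[0].components)
        assert comp == {(1,): 0.5, (2,): 0.5}
        assert mixtures[0].effective_copies()[0] == pytest.approx(1.5)

    def test_mixture_effective_copies_match_targets(self):
        mixtures = infer_nuclear_composition({"chr14": 1.5, "chr15": 2.0},
                                             nucleus_count=1, allow_mixture=True)
        eff = mixtures[0].effective_copies()
        assert eff == pytest.approx([1.5, 2.0])

    def test_unassigned_folds_rejected(self):
        call = KaryotypeCall("s", estimates=[], verdict="ambiguous", duplicated={})
        from karyoscope.karyotype import FoldEstimate

        call.estimates = [FoldEstimate("chr01", 1.25, multiple=None)]
        with pytest.raises(ValueError, match="assigned"):
            infer_nuclear_composition(call, 1)


class TestScreenCohort:
    def _calls_from(self, mixtures, seed=0, lengths=None):
        lengths = lengths or [1_000_000] * 15
        parent = presets.strain_L12(seed)
        truth, bins = build_cohort(parent, mixtures, lengths, seed=seed)
        return [KaryotypeModel(b, sid).fit(bootstrap_reps=0)
                for sid, b in bins.items()]

    def test_heterokaryon_screen_three_aneuploid(self):
        calls = []
        for strain in presets.heterokaryon_screen_strains(seed=31):
            bins, _ = simulate_depth([1_000_000] * 15, strain)
            calls.append(KaryotypeModel(bins, strain.strain_id).fit(bootstrap_reps=0))
        screen = screen_cohort(calls)
        assert screen.n_strains == 6
        assert screen.n_aneuploid == 3 and screen.n_euploid == 3
        assert screen.per_chromosome == {"chr15": 3}
        assert screen.per_multiple[("chr15", 1.5)] == 2
        assert screen.per_multiple[("chr15", 3.0)] == 1

    def test_offspring_screen_three_of_eight(self):
        calls = self._calls_from(presets.l12_offspring_mixtures(), seed=33)
        screen = screen_cohort(calls)
        assert screen.n_aneuploid == 3 and screen.n_euploid == 5

    def test_all_euploid_summary(self):
        calls = self._calls_from([[(presets.cv(), 1.0)]] * 4, seed=35)
        screen = screen_cohort(calls)
        assert screen.n_aneuploid == 0
        assert screen.per_chromosome == {}

    def test_duplicate_strain_ids_rejected(self):
        calls = self._calls_from([[(presets.cv(), 1.0)]] * 2, seed=37)
        calls[1].call.strain_id = calls[0].call.strain_id
        with pytest.raises(ValueError, match="duplicate"):
            screen_cohort(calls)


def test_results_plot_renders(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    strain = make_strain("L7", presets.cv(chr15=2), seed=7)
    bins, _ = simulate_depth([1_000_000] * 15, strain)
    res = KaryotypeModel(bins, "L7").fit(bootstrap_reps=0)
    ax = res.plot()
    assert len(ax.patches) == 15
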