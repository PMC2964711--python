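"""Mutation classification, rho/sigma and calibrated ages."""

import numpy as np
import pandas as pd
import pytest

from mtn1a.dating import (
    Calibration,
    MutationClassifier,
    ages_report,
    estimate_ages,
    load_calibrations,
    make_class_filter,
    rho,
    sigma_saillard,
)
from mtn1a.hvs_io import MutationCall, parse_token
from mtn1a.network import MutationTree, TreeNode
from mtn1a.reference import TRANSITION_PARTNER, translate_codon
from mtn1a.simulate import SimulationConfig, simulate_genealogy

from oracles import brute_rho_sigma


def _dummy_call(ref, pos=16093):
    return parse_token(str(pos - 16000), "hvs1", ref)


def make_star(ref, per_tip_counts):
    """Star tree; each tip i carries per_tip_counts[i] control transitions."""
    root = TreeNode("root")
    pool = [p for p in ref.control_sites()]
    k = 0
    for i, c in enumerate(per_tip_counts):
        calls = []
        for _ in range(c):
            calls.append(_dummy_call(ref, pool[k]))
            k += 1
        tip = TreeNode(f"t{i}", multiplicity=1)
        root.add_child(tip, calls)
    return MutationTree(root)


class TestClassifyMutation:
    def test_control_site(self, ref, classifier):
        assert classifier.classify(parse_token("147A", "hvs1", ref)) == "control"

    def test_known_coding_site_agrees_with_direct_translation(self, ref, classifier):
        """Oracle: translate the ND1 codon around 3336 directly."""
        call = parse_token("3336", "coding", ref)
        # ND1 spans 3307..4262 on the heavy strand
        off = 3336 - 3307
        c0 = 3307 + 3 * (off // 3)
        codon = ref.sequence[c0 - 1 : c0 + 2]
        k = off % 3
        mutated = codon[:k] + call.derived + codon[k + 1 :]
        syn = translate_codon(codon) == translate_codon(mutated)
        got = classifier.classify(call)
        assert got == ("synonymous_transition" if syn else "nonsynonymous")

    def test_enumerated_synonymous_sites_classify_synonymous(self, ref, classifier):
        from mtn1a.reference import synonymous_transition_sites

        sites = synonymous_transition_sites(ref)
        rng = np.random.default_rng(3)
        for pos in rng.choice(sites, size=25, replace=False):
            pos = int(pos)
            alt = TRANSITION_PARTNER[ref.base(pos)]
            call = MutationCall(pos, ref.base(pos), "transition", alt)
            assert classifier.classify(call) == "synonymous_transition"

    def test_overlap_requires_synonymy_in_all_frames(self, ref, classifier):
        """In the ATP8/ATP6 overlap a change must leave both proteins
        unchanged to count as synonymous."""
        for pos in range(8527, 8573):
            alt = TRANSITION_PARTNER[ref.base(pos)]
            call = MutationCall(pos, ref.base(pos), "transition", alt)
            label = classifier.classify(call)
            each = [classifier._codon(f, pos) for f in classifier.proteins
                    if f[1] <= pos <= f[2]]
            assert len(each) == 2
            syn_each = []
            for f in [f for f in classifier.proteins if f[1] <= pos <= f[2]]:
                codon, k = classifier._codon(f, pos)
                base = alt if f[3] == 1 else {"A": "T", "T": "A",
                                              "C": "G", "G": "C"}[alt]
                mutated = codon[:k] + base + codon[k + 1 :]
                syn_each.append(translate_codon(codon) == translate_codon(mutated))
            if all(syn_each):
                assert label == "synonymous_transition"
            else:
                assert label == "nonsynonymous"

    def test_rna_and_indel(self, ref, classifier):
        call = MutationCall(700, ref.base(700),
                            "transition", TRANSITION_PARTNER[ref.base(700)])
        assert classifier.classify(call) == "rna"  # inside the small rRNA
        ins = MutationCall(5740, ref.base(5740), "insertion", "A")
        assert classifier.classify(ins) == "indel"


ALL = lambda m: True


class TestRho:
    def test_all_tips_identical_to_root(self, ref):
        tree = make_star(ref, [0, 0, 0])
        assert rho(tree, ALL) == (0.0, 3)

    def test_star_one_mutation_each(self, ref):
        tree = make_star(ref, [1, 1, 1, 1])
        assert rho(tree, ALL) == (1.0, 4)

    def test_five_edge_tree(self, ref):
        """root-A (1 mut; A subtends tips 1,2), A-tip1 (1), A-tip2 (0),
        root-tip3 (2), root-tip4 (0) -> rho = (2+1+2+0)/4 = 1.25."""
        pool = iter(ref.control_sites())
        call = lambda: _dummy_call(ref, next(pool))
        root = TreeNode("root")
        a = root.add_child(TreeNode("A"), [call()])
        a.add_child(TreeNode("t1", multiplicity=1), [call()])
        a.add_child(TreeNode("t2", multiplicity=1), [])
        root.add_child(TreeNode("t3", multiplicity=1), [call(), call()])
        root.add_child(TreeNode("t4", multiplicity=1), [])
        tree = MutationTree(root)
        assert rho(tree, ALL) == (1.25, 4)
        assert sigma_saillard(tree, ALL) == pytest.approx(np.sqrt(0.4375))

    def test_multiplicity_weighting(self, ref):
        root = TreeNode("root")
        root.add_child(TreeNode("t1", multiplicity=3), [_dummy_call(ref)])
        root.add_child(TreeNode("t2", multiplicity=1), [])
        tree = MutationTree(root)
        assert rho(tree, ALL) == (0.75, 4)

    def test_empty_tree_errors(self):
        tree = MutationTree(TreeNode("root"))
        with pytest.raises(ValueError):
            rho(tree, ALL)


class TestSigma:
    def test_star_formula(self, ref):
        tree = make_star(ref, [1, 1, 1, 1])
        assert sigma_saillard(tree, ALL) == 0.5

    def test_no_qualifying_mutations(self, ref):
        tree = make_star(ref, [0, 0, 0, 0])
        assert sigma_saillard(tree, ALL) == 0.0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_simulated_genealogies(self, ref, classifier,
                                                          seed):
        cfg = SimulationConfig(seed=seed, topology="yule", n_tips=8,
                               tmrca_years=12000)
        gt = simulate_genealogy(cfg, ref)
        for cls in ("all", "coding_substitution", "synonymous_transition",
                    "control"):
            flt = make_class_filter(cls, classifier)
            r, n = rho(gt.tree, flt)
            s = sigma_saillard(gt.tree, flt)
            r2, s2, n2 = brute_rho_sigma(gt.tree, flt)
            assert (r, n) == pytest.approx((r2, n2))
            assert s == pytest.approx(s2)


class TestEstimateAges:
    def test_age_arithmetic(self, ref, classifier):
        """rho=1.0, sigma=0.5 under a 5,140 y/mutation clock -> 5,140 +/- 2,570."""
        tree = make_star(ref, [1, 1, 1, 1])
        cal = Calibration("a", "all", 5140.0)
        ages = estimate_ages(tree, {"clade": tree.root}, [cal], classifier)
        row = ages.iloc[0]
        assert row.age_years == 5140.0 and row.age_se_years == 2570.0

    def test_synonymous_rate_arithmetic(self, ref, classifier):
        cal = Calibration("c", "all", 6764.0)
        tree = make_star(ref, [1, 1, 1, 1])
        ages = estimate_ages(tree, {"x": tree.root}, [cal], classifier)
        assert ages.iloc[0].age_years == 6764.0

    def test_zero_mutation_clade(self, ref, classifier):
        tree = make_star(ref, [0, 0, 0])
        ages = estimate_ages(tree, {"x": tree.root},
                             load_calibrations(), classifier)
        assert (ages.age_years == 0).all() and (ages.age_se_years == 0).all()

    def test_age_scales_linearly_in_rate(self, ref, classifier):
        tree = make_star(ref, [2, 1, 0, 3])
        cals = [Calibration("r1", "all", 1000.0), Calibration("r2", "all", 3000.0)]
        ages = estimate_ages(tree, {"x": tree.root}, cals, classifier)
        a1, a2 = ages.age_years
        assert a2 == pytest.approx(3 * a1)

    def test_packaged_calibration_table(self):
        cals = load_calibrations()
        assert len(cals) == 6
        by = {c.label: c for c in cals}
        assert by["a"].years_per_mutation == 5140
        assert by["a"].mutation_class == "coding_substitution"
        assert by["c"].years_per_mutation == 6764
        assert by["c"].mutation_class == "synonymous_transition"

    def test_report_rounding(self, ref, classifier):
        tree = make_star(ref, [1, 1, 1, 1])
        ages = estimate_ages(tree, {"x": tree.root},
                             [Calibration("a", "all", 5140.0)], classifier)
        wide = ages_report(ages)
        assert wide.iloc[0]["a"] == "5,140 ± 2,570"


class TestCoverage:
    def test_interval_covers_truth_on_star_genealogies(self, ref, classifier):
        """rho +/- 2 sigma covers the true expected mutation count per
        lineage in >= 93% of 1,000 star simulations at study scale."""
        flt = make_class_filter("coding_substitution", classifier)
        rng = np.random.default_rng(2026)
        cfg = SimulationConfig(seed=0, topology="star", n_tips=19,
                               tmrca_years=10000)
        expected = cfg.tmrca_years / cfg.rates["coding_substitution"]
        covered = 0
        for _ in range(1000):
            gt = simulate_genealogy(cfg, ref, rng)
            r, _ = rho(gt.tree, flt)
            s = sigma_saillard(gt.tree, flt)
            if r - 2 * s <= expected <= r + 2 * s:
                covered += 1
        assert covered / 1000 >= 0.93
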