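import numpy as np
import pytest

from causalmr import (
    LDMatrix,
    harmonize_pair,
    harmonize_sets,
    is_palindromic,
    select_instruments,
)
from causalmr.harmonize import AnalysisError
from causalmr.simulate import SimConfig, simulate_two_sample

from conftest import make_record


class TestSelectInstruments:
    def test_independent_significant_all_retained(self):
        records = [make_record(f"rs{i}", pval=1e-10) for i in range(3)]
        ld = LDMatrix([f"rs{i}" for i in range(3)], np.eye(3))
        assert len(select_instruments(records, ld)) == 3

    def test_greedy_keeps_lowest_p_of_correlated_pair(self):
        a = make_record("rsA", pval=1e-20)
        b = make_record("rsB", pval=1e-9)
        r = np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]])
        ld = LDMatrix(["rsA", "rsB"], r)
        kept = select_instruments([b, a], ld)
        assert [k.variant_id for k in kept] == ["rsA"]

    def test_subthreshold_p_dropped_regardless_of_ld(self):
        records = [make_record("rs1", pval=1e-6)]
        assert select_instruments(records) == []

    def test_no_ld_matrix_means_p_filter_only(self):
        records = [make_record("rs1", pval=1e-10), make_record("rs2", pval=1e-6)]
        kept = select_instruments(records, None)
        assert [k.variant_id for k in kept] == ["rs1"]

    def test_variant_missing_from_ld_is_error(self):
        records = [make_record("rs1", pval=1e-10)]
        ld = LDMatrix(["rsX"], np.eye(1))
        with pytest.raises(KeyError):
            select_instruments(records, ld)


@pytest.mark.parametrize(
    "a1,a2,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("A", "C", False)],
)
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


class TestHarmonizePair:
    def test_identical_coding_kept_unchanged(self):
        exp = make_record("rs1", "A", "G", beta=0.1)
        out = make_record("rs1", "A", "G", beta=0.2, trait_id="OA")
        action, _, adj = harmonize_pair(exp, out)
        assert action == "kept"
        assert adj.beta == 0.2

    def test_swapped_alleles_flip_sign_and_frequency(self):
        exp = make_record("rs1", "A", "G", beta=0.1)
        out = make_record("rs1", "G", "A", eaf=0.8, beta=0.2)
        action, _, adj = harmonize_pair(exp, out)
        assert action == "flipped"
        assert adj.beta == -0.2
        assert adj.eaf == pytest.approx(0.2)

    def test_strand_complement_keeps_magnitude(self):
        exp = make_record("rs1", "A", "G", beta=0.1)
        out = make_record("rs1", "T", "C", beta=0.2)  # same variant, other strand
        action, _, adj = harmonize_pair(exp, out)
        assert action == "kept"
        assert adj.beta == 0.2

    def test_strand_complement_plus_swap_flips(self):
        exp = make_record("rs1", "A", "G", beta=0.1)
        out = make_record("rs1", "C", "T", eaf=0.7, beta=0.2)
        action, _, adj = harmonize_pair(exp, out)
        assert action == "flipped"
        assert adj.beta == -0.2

    def test_palindromic_intermediate_frequency_dropped(self):
        exp = make_record("rs1", "A", "T", eaf=0.50)
        out = make_record("rs1", "A", "T", eaf=0.50, beta=0.2)
        action, reason, adj = harmonize_pair(exp, out)
        assert action == "dropped"
        assert "intermediate" in reason
        assert adj is None

    def test_maf_limit_is_strict(self):
        exp = make_record("rs1", "A", "T", eaf=0.30)
        out = make_record("rs1", "A", "T", eaf=0.30, beta=0.2)
        assert harmonize_pair(exp, out)[0] == "dropped"
        exp = make_record("rs1", "A", "T", eaf=0.29)
        out = make_record("rs1", "A", "T", eaf=0.29, beta=0.2)
        assert harmonize_pair(exp, out)[0] == "kept"

    def test_palindromic_missing_eaf_dropped(self):
        exp = make_record("rs1", "A", "T", eaf=None)
        out = make_record("rs1", "A", "T", eaf=0.2, beta=0.2)
        action, reason, _ = harmonize_pair(exp, out)
        assert action == "dropped"
        assert "missing" in reason

    def test_palindromic_discordant_frequency_flips(self):
        # outcome coded on the other strand: frequency identifies the flip
        exp = make_record("rs1", "A", "T", eaf=0.2, beta=0.1)
        out = make_record("rs1", "A", "T", eaf=0.8, beta=0.2)
        action, _, adj = harmonize_pair(exp, out)
        assert action == "flipped"
        assert adj.beta == -0.2

    def test_irreconcilable_alleles_dropped(self):
        exp = make_record("rs1", "A", "G", beta=0.1)
        out = make_record("rs1", "A", "C", beta=0.2)
        action, reason, _ = harmonize_pair(exp, out)
        assert action == "dropped"
        assert reason == "allele mismatch"


class TestHarmonizeSets:
    def test_counts_sum_to_intersection(self):
        exposure = [
            make_record("rs1", "A", "G", beta=0.1),
            make_record("rs2", "A", "T", eaf=0.5, beta=0.1),  # will drop
            make_record("rs3", "C", "T", beta=0.1),
            make_record("rs4", "A", "G", beta=0.1),  # not in outcome
        ]
        outcome = [
            make_record("rs1", "G", "A", beta=0.2),
            make_record("rs2", "A", "T", eaf=0.5, beta=0.2),
            make_record("rs3", "C", "T", beta=0.2),
        ]
        h = harmonize_sets(exposure, outcome)
        audit = h.audit_frame()
        assert len(audit) == 4  # every input variant audited exactly once
        counts = audit["action"].value_counts().to_dict()
        assert counts == {"kept": 1, "flipped": 1, "dropped": 2}
        assert h.n_snps == 2

    def test_disjoint_sets_error(self):
        with pytest.raises(AnalysisError):
            harmonize_sets([make_record("rs1")], [make_record("rs2")])

    def test_idempotent(self):
        sim = simulate_two_sample(SimConfig(seed=4, J=40, palindromic_fraction=0.3))
        h1 = harmonize_sets(sim.exposure, sim.outcome)
        # rebuild record lists from the harmonized set and harmonize again
        exp2 = [
            make_record(v, "A", "G", eaf=float(e), beta=float(g), se=float(sg))
            for v, g, sg, e in zip(h1.variant_ids, h1.gamma, h1.se_gamma, h1.eaf_exposure)
        ]
        out2 = [
            make_record(v, "A", "G", eaf=float(e), beta=float(G), se=float(sG))
            for v, G, sG, e in zip(h1.variant_ids, h1.Gamma, h1.se_Gamma, h1.eaf_exposure)
        ]
        h2 = harmonize_sets(exp2, out2)
        np.testing.assert_array_equal(h2.gamma, h1.gamma)
        np.testing.assert_array_equal(h2.Gamma, h1.Gamma)
        assert all(a == "kept" for _, a, _ in h2.audit)

    def test_flipping_entire_outcome_file_is_invariant(self):
        sim = simulate_two_sample(SimConfig(seed=9, J=50, palindromic_fraction=0.3))
        h1 = harmonize_sets(sim.exposure, sim.outcome)
        flipped_outcome = [r.flipped() for r in sim.outcome]
        h2 = harmonize_sets(sim.exposure, flipped_outcome)
        assert h1.variant_ids == h2.variant_ids
        np.testing.assert_allclose(h1.Gamma, h2.Gamma)
        np.testing.assert_allclose(h1.gamma, h2.gamma)

    def test_recovers_true_effect_orientation(self):
        # harmonized Γ/γ must estimate θ, not −θ, despite randomized coding
        sim = simulate_two_sample(
            SimConfig(seed=12, J=60, theta=-0.3, palindromic_fraction=0.4,
                      se_exposure=0.001, se_outcome=0.001)
        )
        h = harmonize_sets(sim.exposure, sim.outcome)
        ratios = h.Gamma / h.gamma
        assert np.median(ratios) == pytest.approx(-0.3, abs=0.05)
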