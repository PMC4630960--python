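"""Sparse non-negative decomposition and genotype calling."""

import numpy as np
import pytest

from pyromux import (
    AdviserGenotyper,
    GenotypeState,
    build_dictionary,
    decompose,
    enumerate_combination_signals,
    genotype_signal,
    relative_contribution_summary,
    suggest_primer_adjustment,
)
from conftest import make_panel, make_snp


@pytest.fixture(scope="module")
def quad_est(quad_panel):
    return AdviserGenotyper(panel=quad_panel).fit()


class TestDecompose:
    def test_single_atom_identity(self, quad_est):
        D = quad_est.matrix_
        for k in range(D.shape[1]):
            dec = quad_est.decompose(D[:, k])
            expected = np.zeros(D.shape[1])
            expected[k] = 1.0
            np.testing.assert_allclose(dec.coefficients, expected, atol=1e-6)
            assert dec.confidence_r == pytest.approx(1.0)

    def test_het_mixture_recovered_exactly(self, quad_est):
        D = quad_est.matrix_
        y = 0.5 * D[:, 0] + 0.5 * D[:, 1]
        dec = quad_est.decompose(y)
        np.testing.assert_allclose(dec.coefficients[:2], [0.5, 0.5], atol=1e-8)
        np.testing.assert_allclose(dec.coefficients[2:], 0.0, atol=1e-8)

    def test_reference_patient1_support(self, quad_panel, quad_est):
        """A noiseless quadruplex well for genotypes C/C, T/T, C/C, T loads
        exactly the four generating atoms."""
        truth = {"rs1016343": "hom_ref", "rs10993994": "hom_alt",
                 "rs16901979": "hom_alt", "rs5945619": "hemi_alt"}
        d = quad_est.dictionary_
        y = np.sum([genotype_signal(d, GenotypeState(s, st)).heights
                    for s, st in truth.items()], axis=0)
        dec = quad_est.decompose(y)
        support = {lab for lab, c in zip(dec.atom_labels, dec.coefficients)
                   if c > 1e-8}
        assert support == {"rs1016343:C", "rs10993994:T",
                           "rs16901979:C", "rs5945619:T"}

    def test_confidence_r_is_one_inside_cone(self, quad_est):
        rng = np.random.default_rng(42)
        D = quad_est.matrix_
        for _ in range(20):
            y = D @ rng.uniform(0, 2, size=D.shape[1])
            assert quad_est.decompose(y).confidence_r == pytest.approx(1.0)

    def test_scale_invariance(self, quad_panel, quad_est):
        combos = enumerate_combination_signals(quad_panel)
        y = combos[17][1]
        a = quad_est.decompose(y)
        b = quad_est.decompose(4.2 * y)
        np.testing.assert_allclose(b.coefficients, 4.2 * a.coefficients, atol=1e-8)
        assert b.confidence_r == pytest.approx(a.confidence_r)
        ca = quad_est.call_genotypes(a)
        cb = quad_est.call_genotypes(b)
        for x, z in zip(ca, cb):
            assert x.genotype == z.genotype
            assert x.allele_fraction_alt == pytest.approx(z.allele_fraction_alt)
            assert x.contribution_rel == pytest.approx(z.contribution_rel)

    def test_lasso_penalty_shrinks_toward_nnls(self, quad_est):
        y = quad_est.matrix_ @ np.array([1, 0, 1, 0, 0.5, 0.5, 0, 1.0])
        est = AdviserGenotyper(panel=quad_est.panel, penalty_lambda=1e-4).fit()
        dec0 = quad_est.decompose(y)
        dec1 = est.decompose(y)
        assert dec1.penalty_lambda > 0
        np.testing.assert_allclose(dec1.coefficients, dec0.coefficients, atol=1e-2)

    def test_auto_lambda_runs(self, quad_est):
        est = AdviserGenotyper(panel=quad_est.panel, penalty_lambda="auto").fit()
        y = quad_est.matrix_ @ np.array([1, 0, 0, 1, 1, 0, 1, 0.0])
        dec = est.decompose(y)
        assert dec.confidence_r > 0.99

    def test_errors(self, quad_est):
        with pytest.raises(ValueError, match="length"):
            quad_est.decompose(np.ones(3))
        with pytest.raises(ValueError, match="zero"):
            quad_est.decompose(np.zeros(14))


class TestCallGenotypes:
    def _well(self, est, assignment):
        d = est.dictionary_
        return np.sum([genotype_signal(d, GenotypeState(s, st)).heights
                       for s, st in assignment.items()], axis=0)

    def test_hom_het_hemi_calls(self, quad_panel, quad_est):
        truth = {"rs1016343": "het", "rs10993994": "hom_ref",
                 "rs16901979": "hom_alt", "rs5945619": "hemi_ref"}
        calls = quad_est.call_genotypes(quad_est.decompose(self._well(quad_est, truth)))
        by_id = {c.snp_id: c for c in calls}
        assert by_id["rs1016343"].genotype == "C/T"
        assert by_id["rs1016343"].allele_fraction_alt == pytest.approx(0.5, abs=1e-6)
        assert by_id["rs10993994"].genotype == "C/C"
        assert by_id["rs10993994"].allele_fraction_alt == pytest.approx(0.0, abs=1e-6)
        assert by_id["rs16901979"].genotype == "C/C"  # alt allele is C
        assert by_id["rs5945619"].genotype == "C"

    def test_ambiguous_fraction_gives_no_call(self, quad_panel, quad_est):
        d = quad_est.dictionary_
        snp = quad_panel.snp("rs10993994")
        y = self._well(quad_est, {"rs1016343": "hom_ref",
                                  "rs16901979": "hom_ref",
                                  "rs5945619": "hemi_ref"})
        ref = d.atoms_for("rs10993994", snp.allele_ref)[0].signal.heights
        alt = d.atoms_for("rs10993994", snp.allele_alt)[0].signal.heights
        y = y + 0.75 * ref + 0.25 * alt  # fraction 0.25: neither hom nor het
        calls = {c.snp_id: c for c in
                 quad_est.call_genotypes(quad_est.decompose(y))}
        assert calls["rs10993994"].genotype == "no_call"
        assert "ambiguous_fraction" in calls["rs10993994"].flags

    def test_relative_contributions_sum_to_100(self, quad_est):
        truth = {"rs1016343": "het", "rs10993994": "het",
                 "rs16901979": "hom_ref", "rs5945619": "hemi_alt"}
        calls = quad_est.call_genotypes(quad_est.decompose(self._well(quad_est, truth)))
        assert sum(c.contribution_rel for c in calls) == pytest.approx(100.0)

    def test_low_confidence_flag(self, quad_panel):
        est = AdviserGenotyper(panel=quad_panel, min_confidence_r=1.1).fit()
        y = est.matrix_ @ np.ones(8)
        calls = est.call_genotypes(est.decompose(y))
        assert all("low_confidence" in c.flags for c in calls)

    def test_predict_shape_and_labels(self, quad_panel, quad_est):
        combos = enumerate_combination_signals(quad_panel)
        X = np.array([combos[0][1], combos[10][1]])
        labels = quad_est.predict(X)
        assert labels.shape == (2, 4)
        truth0 = [g.label(quad_panel.snp(g.snp_id)) for g in combos[0][0]]
        assert list(labels[0]) == truth0

    def test_sklearn_get_set_params(self, quad_panel):
        est = AdviserGenotyper(panel=quad_panel)
        params = est.get_params()
        assert params["hom_fraction_max"] == 0.2
        est.set_params(hom_fraction_max=0.1).fit()
        assert est.hom_fraction_max == 0.1

    def test_invalid_threshold_ordering_rejected(self, quad_panel):
        est = AdviserGenotyper(panel=quad_panel, hom_fraction_max=0.5,
                               het_fraction_lo=0.3)
        with pytest.raises(ValueError):
            est.fit()


class TestNoiselessIdentifiability:
    @pytest.mark.parametrize("group", ["quadruplex", "quintuplex"])
    def test_every_combination_recovered(self, group, quad_panel, quint_panel):
        panel = quad_panel if group == "quadruplex" else quint_panel
        est = AdviserGenotyper(panel=panel).fit()
        for combo, sig in enumerate_combination_signals(panel):
            calls = est.call_genotypes(est.decompose(sig))
            got = {c.snp_id: c.call.state if c.call else None for c in calls}
            assert got == {g.snp_id: g.state for g in combo}


class TestContributionSummary:
    def test_single_well_equals_its_shares(self, quad_est):
        y = quad_est.matrix_ @ np.array([1, 0, 1, 0, 1, 0, 1, 0.0])
        calls = quad_est.call_genotypes(quad_est.decompose(y))
        summary = relative_contribution_summary([calls])
        for c in calls:
            assert summary[c.snp_id] == pytest.approx(c.contribution_rel)

    def test_balanced_wells_near_equal_shares(self, quad_panel):
        """Unit efficiencies and symmetric noise give ~25% per SNP in a 4-plex."""
        from pyromux import NoiseModel, sample_cohort, simulate_multiplex_well
        rng = np.random.default_rng(11)
        est = AdviserGenotyper(panel=quad_panel).fit()
        cohort = sample_cohort(quad_panel, 100, seed=5)
        wells = []
        for geno in cohort.patients:
            sig = simulate_multiplex_well(geno, quad_panel, est.dictionary_,
                                          noise=NoiseModel(), rng=rng)
            wells.append(est.call_genotypes(est.decompose(sig.heights)))
        summary = relative_contribution_summary(wells)
        for share in summary.values():
            assert share == pytest.approx(25.0, abs=3.0)

    def test_light_mode_shares_proportional_to_atom_light(self, quad_panel):
        est = AdviserGenotyper(panel=quad_panel, contribution_mode="light").fit()
        truth = {s.snp_id: GenotypeState(s.snp_id, s.states[0]) for s in quad_panel}
        d = est.dictionary_
        y = np.sum([genotype_signal(d, g).heights for g in truth.values()], axis=0)
        calls = est.call_genotypes(est.decompose(y))
        lights = {s.snp_id: d.atoms_for(s.snp_id, s.allele_ref)[0].signal.heights.sum()
                  for s in quad_panel}
        total = sum(lights.values())
        for c in calls:
            assert c.contribution_rel == pytest.approx(
                100.0 * lights[c.snp_id] / total, abs=1e-6)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            relative_contribution_summary([])


class TestParameterRecovery:
    def test_weight_error_shrinks_with_noise(self, quad_panel):
        """Mean absolute error of recovered per-SNP weights decreases
        monotonically as peak noise goes to zero."""
        from pyromux import NoiseModel, sample_cohort, simulate_multiplex_well
        est = AdviserGenotyper(panel=quad_panel).fit()
        cohort = sample_cohort(quad_panel, 25, seed=3)
        maes = []
        for sd in (2.0, 0.5, 0.0):
            rng = np.random.default_rng(9)
            errs = []
            noise = NoiseModel(sd_base=sd, sd_prop=0.0, fuph_scale=1.0)
            for geno in cohort.patients:
                sig = simulate_multiplex_well(geno, quad_panel, est.dictionary_,
                                              noise=noise, rng=rng)
                dec = est.decompose(sig.heights)
                w = est._snp_weights(dec.coefficients)
                for snp in quad_panel:
                    tw = geno[snp.snp_id].weights
                    errs.append(abs(w[snp.snp_id][0] - tw[0])
                                + abs(w[snp.snp_id][1] - tw[1]))
            maes.append(float(np.mean(errs)))
        assert maes[0] >= maes[1] >= maes[2]
        assert maes[2] == pytest.approx(0.0, abs=1e-8)


class TestPrimerAdjustment:
    def test_scaling_examples(self):
        adj, flagged = suggest_primer_adjustment(
            {"a": 50.0, "b": 12.5}, {"a": 0.1, "b": 0.1},
            {"a": 25.0, "b": 25.0})
        assert adj["a"] == pytest.approx(0.05)
        assert adj["b"] == pytest.approx(0.2)
        assert flagged == []

    def test_direction_on_unbalanced_quadruplex_shares(self):
        """The over-represented X SNP is decreased, matching the reported
        manual adjustment (0.1 -> 0.05)."""
        shares = {"rs1016343": 15.9, "rs10993994": 27.4,
                  "rs16901979": 21.4, "rs5945619": 35.3}
        conc = {k: 0.1 for k in shares}
        adj, _ = suggest_primer_adjustment(shares, conc)
        assert adj["rs5945619"] < 0.1
        assert adj["rs1016343"] > 0.1

    def test_zero_share_flagged(self):
        adj, flagged = suggest_primer_adjustment(
            {"a": 0.0, "b": 100.0}, {"a": 0.1, "b": 0.1})
        assert adj["a"] == 0.1 and flagged == ["a"]

    def test_grid_snapping(self):
        adj, _ = suggest_primer_adjustment(
            {"a": 40.0, "b": 60.0}, {"a": 0.1, "b": 0.1},
            {"a": 50.0, "b": 50.0}, conc_grid=[0.05, 0.075, 0.1, 0.15, 0.3])
        assert adj["a"] in (0.1, 0.15) and adj["b"] == 0.075


def test_functional_wrapper(quad_panel):
    d = build_dictionary(quad_panel)
    y = d.matrix @ np.array([1, 0, 0, 1, 0.5, 0.5, 1, 0.0])
    dec = decompose(y, quad_panel)
    assert dec.confidence_r == pytest.approx(1.0)
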