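"""Variance-component estimation: empirical and closed-form paths."""

import numpy as np
import pandas as pd
import pytest

from gma import (ClassTable, GMAModel, LocusSpec, build_design, fit_ls,
                 hwe_weights, joint_classes, varcomp_empirical,
                 varcomp_equilibrium_multilocus, varcomp_hwe_one_locus_phased,
                 varcomp_hwe_one_locus_unphased)

from conftest import (random_class_values, random_phased_locus,
                      random_unphased_locus)


# --- literal transcriptions of the published closed forms (test oracle) ----

def printed_va_vd_unphased(alpha, delta, p_nb):
    """V_A = 2 sum p a^2 - 2 (sum p a)^2 ;
    V_D = sum p p d^2 - 2 sum_j p_j (sum_i p_i d_ij)^2 + (sum p p d)^2,
    sums over non-baseline alleles with the symmetric delta extension.
    Valid when the full frequency vector sums to exactly 1."""
    p = np.asarray(p_nb)
    a = np.asarray(alpha)
    D = np.asarray(delta)
    va = 2 * (p @ a ** 2) - 2 * (p @ a) ** 2
    vd = (np.einsum("i,j,ij->", p, p, D ** 2)
          - 2 * np.sum(p * (D @ p) ** 2)
          + (p @ D @ p) ** 2)
    return va, vd


def printed_vap_vam_vd_phased(aP, aM, delta, pP_nb, pM_nb):
    pP, pM = np.asarray(pP_nb), np.asarray(pM_nb)
    vap = pP @ np.asarray(aP) ** 2 - (pP @ aP) ** 2
    vam = pM @ np.asarray(aM) ** 2 - (pM @ aM) ** 2
    D = np.asarray(delta)
    vd = (np.einsum("i,j,ij->", pP, pM, D ** 2)
          - np.sum(pP * (D @ pM) ** 2)
          - np.sum(pM * (pP @ D) ** 2)
          + (pP @ D @ pM) ** 2)
    return vap, vam, vd


def fit_random_saturated(rng, loci, phased=False):
    gdf = joint_classes(loci, phased)
    y = rng.normal(0, 10, size=len(gdf))
    dm = build_design(gdf, loci, phased=phased)
    return fit_ls(dm, y)


# --- empirical path ---------------------------------------------------------

class TestEmpirical:
    def test_acp1_observed_weights(self, acp1):
        table, locus = acp1
        for trait, va, vd, cov, tot, ratio in [
                ("activity", 658.868, 0.973, -0.356, 659.129, 99.96),
                ("inhibition", 44.920, 0.146, -0.217, 44.632, 100.65)]:
            res = GMAModel.from_class_table(table, [locus], trait).fit()
            vc = res.varcomp()
            assert vc.variance("A(acp1)") == pytest.approx(va, abs=5e-3)
            assert vc.variance("D(acp1)") == pytest.approx(vd, abs=5e-3)
            assert vc.covariance("A(acp1)", "D(acp1)") == pytest.approx(
                cov, abs=5e-3)
            assert vc.total == pytest.approx(tot, abs=5e-2)
            assert 100 * vc.ratios["A(acp1)"] == pytest.approx(ratio, abs=0.05)

    def test_hwd_breaks_orthogonality(self, acp1):
        """With the observed (out-of-HWE) class frequencies the additive and
        dominance components covary; the inhibition additive share exceeds
        100% because V_D + 2 Cov(A, D) < 0."""
        table, locus = acp1
        act = GMAModel.from_class_table(table, [locus], "activity").fit()
        assert abs(act.varcomp().covariance("A(acp1)", "D(acp1)")) > 0.1
        inh = GMAModel.from_class_table(table, [locus], "inhibition").fit()
        assert inh.varcomp().ratios["A(acp1)"] > 1.0

    def test_decomposition_identity_and_total(self):
        rng = np.random.default_rng(0)
        loci = [random_unphased_locus(rng, 3, "L1"),
                random_unphased_locus(rng, 2, "L2")]
        table = random_class_values(rng, loci)
        w = rng.random(table.n_classes) + 0.05
        res = GMAModel.from_class_table(table, loci, "y", weights=w).fit()
        vc = res.varcomp(weights=w)
        assert vc.total == sum(vc.variances.values()) + \
            2 * sum(vc.covariances.values())
        # total equals the weighted variance of the fitted genotypic values
        W = w / w.sum()
        g = res.fitted_genotypic_values
        direct = W @ (g - W @ g) ** 2
        assert vc.total == pytest.approx(direct, rel=1e-12)

    def test_zero_coefficients_give_zero_components(self):
        rng = np.random.default_rng(1)
        locus = random_unphased_locus(rng, 3)
        table = random_class_values(rng, [locus])
        res = fit_ls(build_design(table, [locus]), np.zeros(table.n_classes))
        vc = res.varcomp()
        assert all(v == pytest.approx(0.0, abs=1e-20)
                   for v in vc.variances.values())

    def test_degenerate_single_row_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="gma.varcomp"):
            vc = varcomp_empirical(pd.DataFrame({"A(L)": [3.0]}), [1.0])
        assert vc.variances["A(L)"] == 0.0
        assert any("single row" in r.message for r in caplog.records)


# --- one-locus closed forms -------------------------------------------------

class TestClosedFormsOneLocus:
    def test_acp1_hwe_values(self, acp1):
        table, locus = acp1
        for trait, va, vd in [("activity", 660.588, 0.971),
                              ("inhibition", 46.422, 0.152)]:
            res = GMAModel.from_class_table(table, [locus], trait).fit()
            got_va, got_vd = varcomp_hwe_one_locus_unphased(res, locus)
            assert got_va == pytest.approx(va, abs=5e-3)
            assert got_vd == pytest.approx(vd, abs=5e-3)

    @pytest.mark.parametrize("m,seed", [(2, 0), (3, 1), (4, 2), (3, 3),
                                        (4, 4)])
    def test_unphased_closed_form_equals_hwe_enumeration(self, m, seed):
        rng = np.random.default_rng(seed)
        locus = random_unphased_locus(rng, m)
        res = fit_random_saturated(rng, [locus])
        va, vd = varcomp_hwe_one_locus_unphased(res, locus)
        w = hwe_weights(res.design.genotypes, [locus])
        vc = res.varcomp(weights=w)
        assert va == pytest.approx(vc.variance(f"A({locus.locus_id})"),
                                   rel=1e-10)
        assert vd == pytest.approx(vc.variance(f"D({locus.locus_id})"),
                                   rel=1e-10)
        # orthogonality under exact-HWE weights
        assert abs(vc.covariance(f"A({locus.locus_id})",
                                 f"D({locus.locus_id})")) < 1e-10

    @pytest.mark.parametrize("m,seed", [(2, 5), (3, 6), (4, 7)])
    def test_unphased_closed_form_matches_printed_formula(self, m, seed):
        """When frequencies sum to exactly 1 the moment-based closed form
        reduces to the published expressions."""
        rng = np.random.default_rng(seed)
        locus = random_unphased_locus(rng, m)
        res = fit_random_saturated(rng, [locus])
        from gma.varcomp import _one_locus_params
        alpha, D = _one_locus_params(res, locus, phased=False)
        p_nb = np.array([locus.freq(a) for a in locus.nonbaseline])
        want_va, want_vd = printed_va_vd_unphased(alpha, D, p_nb)
        got_va, got_vd = varcomp_hwe_one_locus_unphased(res, locus)
        assert got_va == pytest.approx(want_va, rel=1e-10)
        assert got_vd == pytest.approx(want_vd, rel=1e-10)

    def test_phased_symmetric_biallelic(self):
        """p = 0.5, additive effect a, no dominance:
        V_AP = V_AM = a^2 / 4, V_D = 0."""
        locus = LocusSpec("L", ["A", "B"], [0.5, 0.5], [0.5, 0.5])
        gdf = joint_classes([locus], phased=True)
        dm = build_design(gdf, [locus], phased=True)
        a = 3.0
        y = dm.X @ np.array([0.0, a, a, 0.0])  # mu, aP, aM, d
        res = fit_ls(dm, y)
        vap, vam, vd = varcomp_hwe_one_locus_phased(res, locus)
        assert vap == pytest.approx(a ** 2 / 4)
        assert vam == pytest.approx(a ** 2 / 4)
        assert vd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m,seed", [(2, 8), (3, 9), (4, 10)])
    def test_phased_closed_form_equals_enumeration(self, m, seed):
        rng = np.random.default_rng(seed)
        locus = random_phased_locus(rng, m)
        res = fit_random_saturated(rng, [locus], phased=True)
        vap, vam, vd = varcomp_hwe_one_locus_phased(res, locus)
        w = hwe_weights(res.design.genotypes, [locus], phased=True)
        vc = res.varcomp(weights=w)
        lid = locus.locus_id
        assert vap == pytest.approx(vc.variance(f"A_P({lid})"), rel=1e-10)
        assert vam == pytest.approx(vc.variance(f"A_M({lid})"), rel=1e-10)
        assert vd == pytest.approx(vc.variance(f"D({lid})"), rel=1e-10)
        from gma.varcomp import _one_locus_params
        aP, aM, D = _one_locus_params(res, locus, phased=True)
        pP = np.array([locus.p_pat[locus.index(a)] for a in locus.nonbaseline])
        pM = np.array([locus.p_mat[locus.index(a)] for a in locus.nonbaseline])
        want = printed_vap_vam_vd_phased(aP, aM, D, pP, pM)
        assert np.allclose((vap, vam, vd), want, rtol=1e-10)


# --- multi-locus equilibrium product forms ----------------------------------

class TestEquilibriumMultilocus:
    @pytest.mark.parametrize("ms,seed", [((2, 3), 0), ((3, 3), 1),
                                         ((2, 2), 2), ((4, 2), 3)])
    def test_unphased_matches_full_enumeration(self, ms, seed):
        rng = np.random.default_rng(seed)
        loci = [random_unphased_locus(rng, m, f"L{k + 1}")
                for k, m in enumerate(ms)]
        res = fit_random_saturated(rng, loci)
        analytic = varcomp_equilibrium_multilocus(res)
        w = hwe_weights(res.design.genotypes, loci)
        empirical = res.varcomp(weights=w)
        for name, v in analytic.variances.items():
            assert v == pytest.approx(empirical.variance(name), rel=1e-8,
                                      abs=1e-10), name
        for pair, c in empirical.covariances.items():
            assert abs(c) < 1e-8 * max(1.0, empirical.total), pair
        assert analytic.total == pytest.approx(empirical.total, rel=1e-8)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_phased_two_locus_matches_16_class_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        loci = [random_phased_locus(rng, 2, "L1"),
                random_phased_locus(rng, 2, "L2")]
        res = fit_random_saturated(rng, loci, phased=True)
        assert res.design.n_rows == 16
        analytic = varcomp_equilibrium_multilocus(res)
        w = hwe_weights(res.design.genotypes, loci, phased=True)
        empirical = res.varcomp(weights=w)
        for name, v in analytic.variances.items():
            assert v == pytest.approx(empirical.variance(name), rel=1e-8,
                                      abs=1e-10), name

    def test_reduces_to_one_locus_when_interactions_vanish(self):
        rng = np.random.default_rng(6)
        loci = [random_unphased_locus(rng, 3, "L1"),
                random_unphased_locus(rng, 2, "L2")]
        # build a two-locus response with no epistasis: sum of per-locus parts
        gdf = joint_classes(loci, False)
        dm = build_design(gdf, loci)
        beta = np.zeros(dm.n_cols)
        one_locus_truth = {}
        for k, loc in enumerate(loci):
            sub = fit_random_saturated(np.random.default_rng(100 + k), [loc])
            one_locus_truth[loc.locus_id] = sub
            for c, lab in enumerate(sub.design.labels):
                if lab.is_intercept:
                    continue
                name = lab.name([loc])
                j = dm.column_names.index(name)
                beta[j] = sub.params.iloc[c]
        res = fit_ls(dm, dm.X @ beta)
        vc = varcomp_equilibrium_multilocus(res)
        for loc in loci:
            va, vd = varcomp_hwe_one_locus_unphased(
                one_locus_truth[loc.locus_id], loc)
            assert vc.variance(f"A({loc.locus_id})") == pytest.approx(
                va, rel=1e-8, abs=1e-12)
            assert vc.variance(f"D({loc.locus_id})") == pytest.approx(
                vd, rel=1e-8, abs=1e-12)
        # interaction components are exactly zero
        for name, v in vc.variances.items():
            if "x" in name:
                assert v == pytest.approx(0.0, abs=1e-16)


class TestBaselineInvariance:
    @pytest.mark.parametrize("phased", [False, True])
    def test_all_components_invariant_to_baseline(self, phased):
        rng = np.random.default_rng(11)
        m = 3
        locus = (random_phased_locus if phased else random_unphased_locus)(
            rng, m, "L")
        gdf = joint_classes([locus], phased)
        y = rng.normal(0, 5, size=len(gdf))
        w = rng.random(len(gdf)) + 0.05   # arbitrary (disequilibrium) weights
        results = {}
        for base in locus.alleles:
            dm = build_design(gdf, [locus.with_baseline(base)], phased=phased)
            vc = fit_ls(dm, y).varcomp(weights=w)
            results[base] = vc
        ref = results[locus.alleles[0]]
        for base, vc in results.items():
            for name, v in vc.variances.items():
                assert v == pytest.approx(ref.variances[name], rel=1e-8), \
                    (base, name)
            for pair, c in vc.covariances.items():
                assert c == pytest.approx(ref.covariances[pair], rel=1e-8,
                                          abs=1e-10)
            assert vc.total == pytest.approx(ref.total, rel=1e-10)
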