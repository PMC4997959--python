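"""Inverse-variance pooling, genomic control, thresholds, replication."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import nagwas as ng
from nagwas.meta import CHI2_1_MEDIAN
from nagwas.types import ValidationError


def _variant(i=1, a0="A", a1="G"):
    return ng.Variant(f"rs{i}", "6", 107_500_000 + i, a0, a1)


def _assoc(i, beta, se, model="recessive", cohort="c", a0="A", a1="G"):
    p = 2 * stats.norm.sf(abs(beta / se))
    return ng.AssocResult(_variant(i, a0, a1), model, beta, se,
                          max(p, 5e-324), 500, 0.3, cohort=cohort)


class TestInverseVariance:
    def test_single_study_identity(self):
        b, s, p = ng.inverse_variance_meta([(0.08, 0.02)])
        assert (b, s) == (0.08, 0.02)
        assert p == pytest.approx(2 * stats.norm.sf(4), rel=1e-9)

    def test_equal_se_closed_form(self):
        b, s, _ = ng.inverse_variance_meta([(0.1, 0.02), (0.06, 0.02)])
        assert b == pytest.approx(0.08, rel=1e-12)
        assert s == pytest.approx(0.02 / np.sqrt(2), rel=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            ng.inverse_variance_meta([(0.1, 0.0)])
        with pytest.raises(ValidationError):
            ng.inverse_variance_meta([])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.floats(-1, 1),
                              st.floats(0.001, 1)), min_size=1, max_size=8))
    def test_pooled_variance_never_exceeds_smallest(self, inputs):
        b, s, p = ng.inverse_variance_meta(inputs)
        assert s <= min(se for _, se in inputs) + 1e-12

    def test_concordant_equal_effects_improve_p(self):
        """With identical effects the pooled p is <= every input p."""
        inputs = [(0.05, 0.02), (0.05, 0.03), (0.05, 0.01)]
        _, _, p = ng.inverse_variance_meta(inputs)
        for b, s in inputs:
            assert p <= 2 * stats.norm.sf(abs(b / s)) + 1e-15


class TestGenomicControl:
    def test_null_chi2_lambda_near_one(self):
        """lambda on 10k null chi-square statistics lands in [0.95, 1.05]."""
        rng = np.random.default_rng(3)
        z = rng.standard_normal(10_000)
        results = [_assoc(i, float(zi) * 0.01, 0.01) for i, zi in enumerate(z)]
        lam, corrected = ng.genomic_control(results)
        assert 0.95 < lam < 1.05

    def test_doubling_statistics_doubles_lambda(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(500) * 1.3  # inflated set, lambda > 1
        base = [_assoc(i, float(zi) * 0.01, 0.01) for i, zi in enumerate(z)]
        doubled = [dataclasses.replace(r, beta=r.beta * np.sqrt(2))
                   for r in base]
        lam1, corr1 = ng.genomic_control(base)
        lam2, corr2 = ng.genomic_control(doubled)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)
        assert lam1 > 1
        # corrected chi-squares coincide: (2 chi2) / (2 lambda) = chi2 / lambda
        for a, b in zip(corr1, corr2):
            assert (b.beta / b.se) ** 2 == pytest.approx(
                (a.beta / a.se) ** 2, rel=1e-9)

    def test_lambda_exactly_one_is_noop(self):
        z = np.sqrt(CHI2_1_MEDIAN)
        results = [_assoc(i, z * 0.01, 0.01) for i in range(101)]
        lam, corrected = ng.genomic_control(results)
        assert lam == pytest.approx(1.0, rel=1e-12)
        assert corrected == results

    def test_deflation_never_applied(self):
        results = [_assoc(i, 0.001 * (i + 1) / 100, 0.01) for i in range(100)]
        lam, corrected = ng.genomic_control(results)
        assert lam < 1
        assert corrected == results

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ng.genomic_control([])


class TestThreshold:
    def test_effective_models_threshold(self):
        """5e-8 over 2.2 effective model tests gives 2.27e-8."""
        spec = ng.significance_threshold(5e-8, 2.2)
        assert spec.threshold == pytest.approx(2.27e-8, rel=5e-3)
        assert spec.threshold == 5e-8 / 2.2

    @pytest.mark.parametrize("alpha,neff,expected", [
        (5e-8, 1.0, 5e-8),
        (0.05, 2.2, 0.05 / 2.2),
    ])
    def test_arithmetic(self, alpha, neff, expected):
        assert ng.significance_threshold(alpha, neff).threshold == expected

    @pytest.mark.parametrize("alpha,neff", [(0, 2.2), (5e-8, -1)])
    def test_nonpositive_rejected(self, alpha, neff):
        with pytest.raises(ValidationError):
            ng.significance_threshold(alpha, neff)


def _table_fixture_results(pdss2_table):
    """Discovery MetaResults and replication AssocResults from the bundled
    PDSS2-locus table."""
    disc, rep = [], []
    for r in pdss2_table.itertuples():
        v = ng.Variant(r.SNP, str(r.CHR), int(r.POS), r.A0, r.A1)
        disc.append(ng.MetaResult(
            v, "recessive", (("discovery_meta", r.BETA, r.SE, r.P),),
            r.BETA, r.SE, r.P))
        rep.append(ng.AssocResult(
            v, "recessive", r.BETA_REP, r.SE_REP, r.P_REP, 1731, 0.3,
            cohort="replication"))
    return disc, rep


class TestReplication:
    def test_locus_table_yields_five_replicated(self, pdss2_table):
        """Exactly 5 of the 28 locus variants replicate at p < 0.05 with a
        concordant (positive, attenuated) effect."""
        disc, rep = _table_fixture_results(pdss2_table)
        annotated, report = ng.replication_filter(disc, rep, alpha=0.05)
        hits = [m for m in annotated if m.replicated]
        assert len(hits) == 5
        assert report["replicated"] == 5
        for m in hits:
            assert m.direction_concordant
        ids = {m.variant.id for m in hits}
        assert ids == {"rs2216084", "rs6942255", "rs7745311", "rs7754744",
                       "rs9386630"}

    def test_boundary_p_is_strict(self):
        d = ng.MetaResult(_variant(1), "recessive",
                          (("m", 0.08, 0.014, 1e-9),), 0.08, 0.014, 1e-9)
        r = ng.AssocResult(_variant(1), "recessive", 0.03, 0.014, 0.05,
                           1731, 0.3)
        annotated, _ = ng.replication_filter([d], [r])
        assert annotated[0].replicated is False

    def test_discordant_sign_never_replicates(self):
        d = ng.MetaResult(_variant(1), "recessive",
                          (("m", 0.08, 0.014, 1e-9),), 0.08, 0.014, 1e-9)
        r = ng.AssocResult(_variant(1), "recessive", -0.08, 0.014, 0.001,
                           1731, 0.3)
        annotated, _ = ng.replication_filter([d], [r])
        assert annotated[0].replicated is False
        assert annotated[0].direction_concordant is False

    def test_unmatched_reported_not_fatal(self):
        d = ng.MetaResult(_variant(1), "recessive",
                          (("m", 0.08, 0.014, 1e-9),), 0.08, 0.014, 1e-9)
        annotated, report = ng.replication_filter([d], [])
        assert report["unmatched"] == 1
        assert annotated[0].replicated is None

    def test_swapped_alleles_flip_replication_sign(self):
        d = ng.MetaResult(_variant(1, "A", "G"), "recessive",
                          (("m", 0.08, 0.014, 1e-9),), 0.08, 0.014, 1e-9)
        r = ng.AssocResult(_variant(1, "G", "A"), "recessive", -0.08, 0.014,
                           0.001, 1731, 0.3)
        annotated, _ = ng.replication_filter([d], [r])
        assert annotated[0].replicated is True


class TestPooling:
    def test_three_identical_cohorts(self):
        cohorts = {c: [_assoc(1, 0.06, 0.015, cohort=c)]
                   for c in ("a", "b", "c")}
        pooled, _ = ng.pool_all_cohorts(cohorts)
        assert pooled[0].se_pooled == pytest.approx(0.015 / np.sqrt(3))
        assert pooled[0].beta_pooled == pytest.approx(0.06)

    def test_order_invariant(self):
        a = {"x": [_assoc(1, 0.05, 0.02, cohort="x")],
             "y": [_assoc(1, 0.03, 0.01, cohort="y")]}
        b = {k: a[k] for k in reversed(list(a))}
        pa, _ = ng.pool_all_cohorts(a)
        pb, _ = ng.pool_all_cohorts(b)
        assert pa[0].beta_pooled == pytest.approx(pb[0].beta_pooled, rel=1e-12)
        assert pa[0].p_pooled == pytest.approx(pb[0].p_pooled, rel=1e-12)

    def test_allele_flip_harmonized_in_meta(self):
        cohorts = {
            "a": [_assoc(1, 0.05, 0.02, cohort="a", a0="A", a1="G")],
            "b": [_assoc(1, -0.05, 0.02, cohort="b", a0="G", a1="A")],
        }
        pooled = ng.meta_analyze(cohorts)
        assert pooled[0].beta_pooled == pytest.approx(0.05)

    def test_replicated_rows_gain_significance_when_pooled(self, pdss2_table):
        """For each replicated locus variant, pooling discovery + replication
        gives a p below the discovery p."""
        disc, rep = _table_fixture_results(pdss2_table)
        annotated, _ = ng.replication_filter(disc, rep)
        rep_by_id = {r.variant.id: r for r in rep}
        for m in annotated:
            if not m.replicated:
                continue
            r = rep_by_id[m.variant.id]
            _, _, p_all = ng.inverse_variance_meta(
                [(m.beta_pooled, m.se_pooled), (r.beta, r.se)])
            assert p_all < m.p_pooled

    def test_two_cohort_meta_beats_either_cohort(self):
        """Synthetic discovery pair sharing a recessive causal variant: the
        meta p at the causal variant beats both per-cohort p-values in >=
        90% of replicates."""
        from nagwas.phenotype import transform_cups

        wins = 0
        n_rep = 20
        for rep_i in range(n_rep):
            per_cohort = {}
            for name, fams in (("disc1", 82), ("disc2", 187)):
                cfg = ng.SimConfig(n_families=fams, n_variants=60,
                                   med_fraction=0.0,
                                   seed=7000 + 13 * rep_i + (name == "disc2"))
                causal = [ng.CausalSpec("v000001", "recessive", 0.086, 0.548)]
                co = ng.simulate_cohort(cfg, causal=causal, store_gp=False)
                pheno = co.phenotypes.copy()
                pheno["y_transformed"] = transform_cups(
                    pheno.cups_per_day.to_numpy())
                kin = ng.estimate_kinship(co.genotypes)
                res = ng.run_scan(co.genotypes, pheno, kin,
                                  ng.ScanConfig(models=("recessive",),
                                                cohort=name))
                per_cohort[name] = res
            pooled = ng.meta_analyze(per_cohort)
            m = next(x for x in pooled if x.variant.id == "v000001")
            if m.p_pooled < min(p for _, _, _, p in m.per_cohort):
                wins += 1
        assert wins >= 0.9 * n_rep
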