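"""Hardy-Weinberg carrier/affected rates and inclusion scenarios."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierprev import (
    NEVER,
    AlleleFrequencyRecord,
    VariantKey,
    combined_q,
    hwe_rates,
    observed_carrier_rate,
    one_in,
    one_in_exact,
    sensitivity_scenarios,
)
from carrierprev.catalog import IntersectionResult
from carrierprev.errors import UndefinedFrequencyError, UsageError

K1 = VariantKey("chr17", 3550800, "G", "A")
K2 = VariantKey("chr17", 3559792, "T", "C")


def afr(key, ac, an=2184, stratum="ALL"):
    n_het = ac  # all-heterozygous convention for these fixtures
    return AlleleFrequencyRecord(key=key, stratum=stratum, ac=ac, an=an,
                                 n_het=n_het, n_hom_alt=0)


class TestCombinedQ:
    def test_two_variant_pool(self):
        assert combined_q([afr(K1, 35), afr(K2, 1)]) == Fraction(36, 2184)

    def test_single_variant(self):
        assert combined_q([afr(K2, 1)]) == Fraction(1, 2184)

    def test_empty_inclusion_set_is_zero(self):
        assert combined_q([]) == 0

    def test_mixed_strata_rejected(self):
        with pytest.raises(UsageError):
            combined_q([afr(K1, 35), afr(K2, 1, stratum="AFR")])

    def test_zero_allele_number_undefined(self):
        rec = AlleleFrequencyRecord(key=K1, stratum="ALL", ac=0, an=0, n_het=0, n_hom_alt=0)
        with pytest.raises(UndefinedFrequencyError):
            combined_q([rec])


class TestHweRates:
    def test_rare_allele_exact_fractions(self):
        carrier, affected = hwe_rates(Fraction(1, 2184))
        assert carrier == Fraction(4366, 4769856)
        assert affected == Fraction(1, 4769856)

    def test_pooled_allele_affected_reciprocal(self):
        _, affected = hwe_rates(Fraction(36, 2184))
        assert affected == Fraction(1296, 4769856)
        assert one_in(affected) == 3680  # reciprocal 3680.44 rounds down

    @pytest.mark.parametrize("q,expected", [(0, (0, 0)), (1, (0, 1))])
    def test_boundary_identities(self, q, expected):
        assert hwe_rates(Fraction(q)) == expected

    @given(q=st.fractions(min_value=0, max_value=1))
    @settings(max_examples=100, derandomize=True)
    def test_exact_rational_identities(self, q):
        carrier, affected = hwe_rates(q)
        assert affected == q * q
        assert carrier == 2 * q * (1 - q)
        if q <= Fraction(2, 3):
            assert affected <= carrier

    def test_limit_agreement_as_q_vanishes(self):
        for exp in (3, 6, 9):
            q = Fraction(1, 10**exp)
            carrier, affected = hwe_rates(q)
            assert abs(affected / (q * q) - 1) == 0
            assert abs(carrier / (2 * q) - 1) == q  # 2q(1-q)/2q = 1-q -> 1


class TestOneIn:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (Fraction(1296, 4769856), 3680),
            (Fraction(1, 4769856), 4769856),
            (Fraction(4366, 4769856), 1093),  # reciprocal 1092.5002... rounds half-up
            (Fraction(36, 1092), 30),  # 30.33
            (Fraction(1, 1092), 1092),
            (Fraction(2, 5), 3),  # 2.5 rounds half-up, not banker's
        ],
    )
    def test_half_up_rounding(self, rate, expected):
        assert one_in(rate) == expected

    def test_zero_rate_is_never(self):
        assert one_in(Fraction(0)) is NEVER
        assert one_in_exact(Fraction(0)) is NEVER

    def test_exact_reciprocal_retained(self):
        assert one_in_exact(Fraction(4366, 4769856)) == Fraction(4769856, 4366)


def fake_intersection(carriers_by_key):
    from carrierprev.catalog import CatalogVariant

    matched = [
        (CatalogVariant(key=k), {s: 1 for s in samples})
        for k, samples in carriers_by_key.items()
    ]
    union = set().union(*carriers_by_key.values()) if carriers_by_key else set()
    return IntersectionResult(
        matched=matched,
        carrier_samples=union,
        per_variant_het_count={k: len(v) for k, v in carriers_by_key.items()},
        per_variant_hom_count={k: 0 for k in carriers_by_key},
    )


class TestObservedCarrierRate:
    def test_study_cohort_rate(self):
        res = fake_intersection({K1: {f"s{i}" for i in range(35)}, K2: {"x"}})
        rate = observed_carrier_rate(res, 1092)
        assert rate == Fraction(36, 1092)
        assert one_in(rate) == 30

    def test_single_carrier_differs_from_hwe_convention(self):
        res = fake_intersection({K2: {"x"}})
        assert one_in(observed_carrier_rate(res, 1092)) == 1092
        assert one_in(hwe_rates(Fraction(1, 2184))[0]) == 1093

    def test_no_carriers(self):
        assert observed_carrier_rate(fake_intersection({}), 10) == 0

    def test_zero_cohort_rejected(self):
        with pytest.raises(UsageError):
            observed_carrier_rate(fake_intersection({}), 0)


class TestSensitivityScenarios:
    RECORDS = [afr(K1, 35), afr(K2, 1)]

    def intersection(self):
        return fake_intersection({K1: {f"s{i}" for i in range(35)}, K2: {"x"}})

    def test_all_and_filtered_policies(self, bundle):
        from carrierprev import assign_evidence, reconcile

        freqs = {"AFR": Fraction("6.26") / 100, "NFE": 0, "FIN": 0, "Asian": 0}
        recs = []
        for cv, _ in bundle.result.matched:
            a = assign_evidence(freqs if cv.key == K1 else {"AFR": Fraction(1, 2184)}, key=cv.key)
            recs.append(reconcile(a, cv))
        all_ = sensitivity_scenarios(
            bundle.records, bundle.result, recs, policy="all", cohort_size=1092
        )
        assert all_[0].q == Fraction(36, 2184)
        assert all_[0].carrier_rate_observed == Fraction(36, 1092)
        filtered = sensitivity_scenarios(
            bundle.records, bundle.result, recs, policy="acmg_filtered", cohort_size=1092
        )
        assert filtered[0].q == Fraction(1, 2184)
        assert filtered[0].included_keys == [K2]

    def test_leave_one_out_combinatorics(self):
        out = sensitivity_scenarios(self.RECORDS, self.intersection(), policy="leave_one_out")
        assert len(out) == 2
        assert {tuple(e.included_keys) for e in out} == {(K1,), (K2,)}

    def test_explicit_empty_list_gives_zero_q(self):
        (est,) = sensitivity_scenarios(
            self.RECORDS, self.intersection(), policy="explicit", explicit_keys=[]
        )
        assert est.q == 0
        assert est.one_in_affected is NEVER

    def test_explicit_unknown_key_rejected(self):
        with pytest.raises(UsageError):
            sensitivity_scenarios(
                self.RECORDS, self.intersection(), policy="explicit",
                explicit_keys=[VariantKey("chr9", 1, "G", "A")],
            )

    def test_q_is_monotone_under_exclusion(self):
        inter = self.intersection()
        (q_all,) = sensitivity_scenarios(self.RECORDS, inter, policy="all")
        loo = sensitivity_scenarios(self.RECORDS, inter, policy="leave_one_out")
        (q_none,) = sensitivity_scenarios(
            self.RECORDS, inter, policy="explicit", explicit_keys=[]
        )
        for est in loo:
            assert q_none.q <= est.q <= q_all.q
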