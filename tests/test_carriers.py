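"""Carrier calling, couple screening and residual risk."""

import pytest

from carrierscreen import (
    Classification,
    GenotypeRecord,
    Individual,
    PanelGene,
    ValidationError,
    call_carriers,
    couple_screen,
    multiplicity_histogram,
    residual_risk,
)
from carrierscreen.panel import Inheritance

P = Classification.PATHOGENIC
LP = Classification.LIKELY_PATHOGENIC
VUS = Classification.VUS

PANEL = [
    PanelGene("CFTR", "T1", "Cystic fibrosis", "219700", Inheritance.AR),
    PanelGene("GJB2", "T2", "Deafness, AR 1A", "220290", Inheritance.AR),
    PanelGene("SLC26A4", "T3", "Deafness, AR 4", "274600", Inheritance.AR),
    PanelGene("GLA", "T4", "Fabry disease", "301500", Inheritance.XL),
    PanelGene("LDLR", "T5", "Familial hypercholesterolemia", "143890", Inheritance.AD_AR),
]
GENE_OF = {"v1": "CFTR", "v2": "GJB2", "v3": "GLA", "v4": "LDLR", "v5": "CFTR", "v6": "SLC26A4"}
CLS = {"v1": LP, "v2": P, "v3": P, "v4": P, "v5": P, "v6": P}


def inds(*people):
    return list(people)


class TestCallCarriers:
    def test_het_lp_on_ar_gene_is_carrier(self):
        cohort = inds(Individual("A", "female"))
        calls = call_carriers(cohort, [GenotypeRecord("A", "v1")], CLS, PANEL, GENE_OF)
        assert len(calls) == 1
        assert calls[0].category == "carrier"
        assert calls[0].disorder_name == "Cystic fibrosis"

    def test_hemi_male_on_xl_gene_is_affected_risk(self):
        cohort = inds(Individual("A", "male"))
        calls = call_carriers(cohort, [GenotypeRecord("A", "v3", "hemi")], CLS, PANEL, GENE_OF)
        assert calls[0].category == "affected_risk"

    def test_het_female_on_xl_gene_is_carrier(self):
        cohort = inds(Individual("A", "female"))
        calls = call_carriers(cohort, [GenotypeRecord("A", "v3", "het")], CLS, PANEL, GENE_OF)
        assert calls[0].category == "carrier"

    def test_het_male_on_xl_gene_is_a_data_error(self):
        cohort = inds(Individual("A", "male"))
        with pytest.raises(ValidationError, match="X-linked"):
            call_carriers(cohort, [GenotypeRecord("A", "v3", "het")], CLS, PANEL, GENE_OF)

    def test_het_on_ad_ar_gene_is_affected_risk_not_carrier(self):
        cohort = inds(Individual("A", "female"))
        calls = call_carriers(cohort, [GenotypeRecord("A", "v4")], CLS, PANEL, GENE_OF)
        assert calls[0].category == "affected_risk"

    def test_two_genes_give_two_calls(self):
        cohort = inds(Individual("A", "female"))
        gts = [GenotypeRecord("A", "v1"), GenotypeRecord("A", "v2")]
        calls = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        assert len(calls) == 2
        assert multiplicity_histogram(calls) == {2: 1}

    def test_two_het_variants_same_ar_gene_flags_affected_risk(self):
        cohort = inds(Individual("A", "female"))
        gts = [GenotypeRecord("A", "v1"), GenotypeRecord("A", "v5")]
        [call] = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        assert call.category == "affected_risk"
        assert call.variant_ids == ("v1", "v5")

    def test_hom_on_ar_gene_flags_affected_risk(self):
        cohort = inds(Individual("A", "female"))
        [call] = call_carriers(cohort, [GenotypeRecord("A", "v1", "hom")], CLS, PANEL, GENE_OF)
        assert call.category == "affected_risk"

    def test_vus_generates_no_call(self):
        cohort = inds(Individual("A", "female"))
        cls = dict(CLS, v1=VUS)
        assert call_carriers(cohort, [GenotypeRecord("A", "v1")], cls, PANEL, GENE_OF) == []

    def test_vus_inertness(self):
        """Removing a non-reportable genotype never changes the output."""
        cohort = inds(Individual("A", "female"), Individual("B", "male"))
        cls = dict(CLS, v2=VUS)
        with_vus = call_carriers(
            cohort, [GenotypeRecord("A", "v1"), GenotypeRecord("A", "v2")], cls, PANEL, GENE_OF
        )
        without = call_carriers(cohort, [GenotypeRecord("A", "v1")], cls, PANEL, GENE_OF)
        assert with_vus == without

    def test_unknown_individual_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            call_carriers(inds(Individual("A", "female")), [GenotypeRecord("ghost", "v1")], CLS, PANEL, GENE_OF)

    def test_duplicate_genotype_rejected(self):
        cohort = inds(Individual("A", "female"))
        gts = [GenotypeRecord("A", "v1"), GenotypeRecord("A", "v1")]
        with pytest.raises(ValidationError, match="duplicate"):
            call_carriers(cohort, gts, CLS, PANEL, GENE_OF)


class TestCoupleScreen:
    def couple(self):
        return inds(
            Individual("H", "male", couple_id="C1"),
            Individual("W", "female", couple_id="C1"),
            Individual("S", "female"),
        )

    def test_both_partners_same_gene_at_risk(self):
        cohort = self.couple()
        gts = [GenotypeRecord("H", "v2"), GenotypeRecord("W", "v2")]
        calls = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        [risk] = couple_screen(cohort, calls)
        assert risk.couple_id == "C1" and risk.gene == "GJB2"
        assert risk.member_ids == ("H", "W")

    def test_different_deafness_genes_not_at_risk_at_gene_level(self):
        cohort = self.couple()
        gts = [GenotypeRecord("H", "v2"), GenotypeRecord("W", "v6")]
        calls = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        assert couple_screen(cohort, calls) == []

    def test_disorder_level_matching_optional(self):
        # GJB2 and SLC26A4 deafness carry different disorder labels here, so
        # even disorder-level matching keeps them distinct; same-disorder
        # matching triggers on the shared label
        cohort = self.couple()
        gts = [GenotypeRecord("H", "v2"), GenotypeRecord("W", "v6")]
        calls = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        assert couple_screen(cohort, calls, level="disorder") == []

    def test_symmetric_in_partner_order(self):
        cohort = self.couple()
        gts = [GenotypeRecord("W", "v2"), GenotypeRecord("H", "v2")]
        calls = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        [risk] = couple_screen(cohort, calls)
        assert risk.member_ids == ("H", "W")

    def test_singletons_ignored(self):
        cohort = self.couple()
        gts = [GenotypeRecord("S", "v2"), GenotypeRecord("W", "v2")]
        calls = call_carriers(cohort, gts, CLS, PANEL, GENE_OF)
        assert couple_screen(cohort, calls) == []

    def test_couple_id_must_pair_two(self):
        bad = inds(Individual("A", "male", couple_id="C9"))
        with pytest.raises(ValidationError, match="C9"):
            couple_screen(bad, [])


class TestResidualRisk:
    def test_uninformative_test_keeps_prior(self):
        assert residual_risk(0.05, 0.0) == pytest.approx(0.05)

    def test_perfect_test_clears_risk(self):
        assert residual_risk(0.05, 1.0) == 0.0
        assert residual_risk(1.0, 1.0) == 0.0  # limit handled

    def test_bayes_value(self):
        # prior 1 in 22, 90% detection -> about 1 in 211
        assert residual_risk(1 / 22, 0.9) == pytest.approx(0.0047393, abs=1e-6)

    def test_matches_enumeration_over_synthetic_population(self):
        """Direct count over a finite population of 22,000: 1,000 carriers,
        a 90%-sensitive screen; among screen-negatives the carrier fraction
        equals the Bayes formula."""
        n, carriers = 22_000, 1_000
        detected = int(carriers * 0.9)
        negatives = n - detected
        missed = carriers - detected
        assert residual_risk(carriers / n, 0.9) == pytest.approx(missed / negatives)

    def test_monotone_decreasing_in_detection_rate(self):
        risks = [residual_risk(0.05, d / 10) for d in range(11)]
        assert risks == sorted(risks, reverse=True)
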