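"""Annotation, filtering, inheritance-model and trio logic, two-pass search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paneldx import (
    Case,
    ConfigurationError,
    DiseaseGeneMap,
    SimulationSpec,
    ValidationError,
    VariantCall,
    annotate,
    frequency_filter,
    model_consistency,
    prioritize,
    segregation_check,
    simulate_case,
)
from paneldx.prioritize import (
    CARRIER_ONLY,
    CONSISTENT,
    DE_NOVO,
    INCONSISTENT,
    INHERITED_BIPARENTAL,
    INHERITED_MATERNAL,
    MENDELIAN_ERROR,
)


def _call(pos=100, gene="GENE1", zygosity="heterozygous", chrom="chr1", **kw):
    return VariantCall(chrom, pos, "G", "A", gene=gene, zygosity=zygosity, **kw)


def _ann(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "local_freq", "pop_freq", "known_pathogenic", "deleterious_votes",
        ],
    )


class TestAnnotate:
    def test_known_pathogenic_flag_joined(self):
        table = _ann([("chr1", 100, "G", "A", 0.001, 0.0005, True, 2)])
        (rec,) = annotate([_call()], table)
        assert rec.known_pathogenic
        assert not rec.novel_flag
        assert rec.pop_freq == 0.0005

    def test_absent_call_is_novel_with_missing_frequencies(self):
        (rec,) = annotate([_call()], _ann([]))
        assert rec.novel_flag
        assert rec.local_freq is None and rec.pop_freq is None

    def test_empty_call_set_empty_output(self):
        assert annotate([], _ann([])) == []


class TestFrequencyFilter:
    def test_common_non_pathogenic_removed_with_reason(self):
        (rec,) = annotate([_call()], _ann([("chr1", 100, "G", "A", 0.3, 0.30, False, 0)]))
        log = []
        assert frequency_filter([rec], removal_log=log) == []
        assert log and "pop_freq" in log[0][1]

    def test_no_frequency_data_retained(self):
        (rec,) = annotate([_call()], None)
        assert frequency_filter([rec]) == [rec]

    def test_known_pathogenic_overrides_frequency(self):
        (rec,) = annotate([_call()], _ann([("chr1", 100, "G", "A", 0.3, 0.3, True, 0)]))
        assert frequency_filter([rec]) == [rec]

    @given(
        freqs=st.lists(
            st.one_of(st.none(), st.floats(0, 1)), min_size=1, max_size=20
        ),
        lo=st.floats(0, 0.5),
        delta=st.floats(0, 0.5),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_max_freq(self, freqs, lo, delta):
        records = annotate(
            [_call(pos=100 + i) for i in range(len(freqs))],
            _ann(
                [
                    ("chr1", 100 + i, "G", "A", f, f, False, 0)
                    for i, f in enumerate(freqs)
                ]
            ),
        )
        small = {r.key for r in frequency_filter(records, max_freq=lo)}
        large = {r.key for r in frequency_filter(records, max_freq=lo + delta)}
        assert small <= large


class TestModelConsistency:
    def test_ar_single_homozygote_consistent(self):
        recs = annotate([_call(zygosity="homozygous")], None)
        assert model_consistency(recs, "AR") == CONSISTENT

    def test_ar_two_heterozygotes_consistent_compound(self):
        recs = annotate([_call(pos=100), _call(pos=200)], None)
        assert model_consistency(recs, "AR") == CONSISTENT

    def test_ar_single_heterozygote_carrier_only(self):
        recs = annotate([_call()], None)
        assert model_consistency(recs, "AR") == CARRIER_ONLY

    def test_xl_hemizygous_male_consistent(self):
        recs = annotate([_call(chrom="chrX", zygosity="hemizygous")], None)
        assert model_consistency(recs, "XL", sex="male") == CONSISTENT

    def test_xl_het_female_carrier_only(self):
        recs = annotate([_call(chrom="chrX")], None)
        assert model_consistency(recs, "XL", sex="female") == CARRIER_ONLY

    def test_ad_any_record_consistent(self):
        assert model_consistency(annotate([_call()], None), "AD") == CONSISTENT
        assert model_consistency([], "AD") == INCONSISTENT

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            model_consistency([], "mitochondrial")

    def test_mixed_genes_rejected(self):
        recs = annotate([_call(gene="A"), _call(pos=200, gene="B")], None)
        with pytest.raises(ValidationError):
            model_consistency(recs, "AR")


class TestSegregationCheck:
    def test_maternal_x_transmission_to_hemizygous_son(self):
        v = _call(chrom="chrX", zygosity="hemizygous")
        labels = segregation_check(
            [v], [], [_call(chrom="chrX")], proband_sex="male"
        )
        assert labels[v.key] == INHERITED_MATERNAL

    def test_paternal_x_in_hemizygous_son_is_mendelian_error(self):
        v = _call(chrom="chrX", zygosity="hemizygous")
        labels = segregation_check([v], [_call(chrom="chrX")], [], proband_sex="male")
        assert labels[v.key] == MENDELIAN_ERROR

    def test_absent_from_both_parents_is_de_novo(self):
        v = _call()
        assert segregation_check([v], [], [])[v.key] == DE_NOVO

    def test_homozygote_with_het_parents_inherited_from_both(self):
        v = _call(zygosity="homozygous")
        labels = segregation_check([v], [_call()], [_call()])
        assert labels[v.key] == INHERITED_BIPARENTAL

    def test_homozygote_missing_in_one_parent_is_mendelian_error(self):
        v = _call(zygosity="homozygous")
        assert segregation_check([v], [_call()], [])[v.key] == MENDELIAN_ERROR

    def test_duplicated_locus_in_one_individual_rejected(self):
        with pytest.raises(ValidationError):
            segregation_check([_call(), _call()], [], [])


@pytest.fixture()
def simple_map():
    return DiseaseGeneMap(
        genes_by_disease={"DIS_A": ["GENE1"], "DIS_B": ["GENE2"], "DIS_X": ["XG1"]},
        models_by_gene={"GENE1": ("AR",), "GENE2": ("AR",), "XG1": ("XL",)},
    )


class TestPrioritize:
    def test_hom_known_pathogenic_in_candidate_ar_gene_is_tier1_causal(self, simple_map):
        table = _ann([("chr1", 100, "G", "A", 0.0001, np.nan, True, 2)])
        case = Case("C1", "DIS_A", [_call(zygosity="homozygous")], sex="female")
        rep = prioritize(case, simple_map, table)
        assert rep.verdict == "causal_found"
        assert rep.consistency == "yes"
        assert len(rep.tier1) == 1 and not rep.tier2 and not rep.tier3

    def test_off_candidate_compound_het_reassigns_diagnosis(self, simple_map):
        calls = [
            _call(pos=100, gene="GENE2"),
            _call(pos=200, gene="GENE2"),
        ]
        table = _ann(
            [
                ("chr1", 100, "G", "A", np.nan, np.nan, True, 2),
                ("chr1", 200, "G", "A", np.nan, np.nan, False, 2),
            ]
        )
        rep = prioritize(Case("C2", "DIS_A", calls, sex="female"), simple_map, table)
        assert rep.verdict == "causal_found"
        assert rep.consistency == "reassigned:DIS_B"
        assert len(rep.tier3) == 2
        assert any("compound_het_phase_unknown" in h["flags"] for h in rep.tier3)

    def test_no_passing_variants_negative_verdict(self, simple_map):
        table = _ann([("chr1", 100, "G", "A", 0.4, 0.4, False, 0)])
        rep = prioritize(Case("C3", "DIS_A", [_call()], sex="female"), simple_map, table)
        assert rep.verdict == "negative"
        assert rep.consistency == "no"
        assert not rep.all_hits()

    def test_single_ar_het_known_pathogenic_is_suspected(self, simple_map):
        # synonymous-style single hit: model satisfied only as carrier
        table = _ann([("chr1", 100, "G", "A", np.nan, np.nan, True, 0)])
        case = Case("C4", "DIS_A", [_call(cdna="c.1620A>G", protein="p.Q540Q")])
        rep = prioritize(case, simple_map, table)
        assert rep.verdict == "suspected"
        assert rep.consistency == "yes"
        assert any("possible missed second allele" in n for n in rep.notes)

    def test_ad_variant_from_asymptomatic_parent_downgraded(self):
        dmap = DiseaseGeneMap(
            genes_by_disease={"DIS_D": ["GENE3"]}, models_by_gene={"GENE3": ("AD",)}
        )
        v = _call(gene="GENE3")
        table = _ann([("chr1", 100, "G", "A", np.nan, np.nan, True, 2)])
        case = Case(
            "C5", "DIS_D", [v], sex="female",
            father_calls=[], mother_calls=[_call(gene="GENE3")],
        )
        rep = prioritize(case, dmap, table)
        assert rep.verdict == "suspected"
        assert any("incomplete penetrance" in f for h in rep.all_hits() for f in h["flags"])

    def test_unknown_diagnosis_without_flag_rejected(self, simple_map):
        with pytest.raises(ConfigurationError):
            prioritize(Case("C6", "NOT_A_CODE", []), simple_map, None)

    def test_hemizygous_autosomal_call_rejected(self, simple_map):
        case = Case("C7", "DIS_A", [_call(zygosity="hemizygous")], sex="male")
        with pytest.raises(ValidationError):
            prioritize(case, simple_map, None)

    def test_verdict_is_total_over_simulated_cases(self, panel, dmap):
        verdicts = set()
        for seed in range(12):
            spec = SimulationSpec(seed=seed, background_rate=15)
            disease = sorted(dmap.genes_by_disease)[seed % len(dmap.genes_by_disease)]
            try:
                sim = simulate_case(spec, disease, dmap, panel, mode="AR")
            except ConfigurationError:
                continue
            case = Case(
                f"S{seed}", disease, sim.calls["proband"], sex=sim.proband_sex,
                father_calls=sim.calls["father"], mother_calls=sim.calls["mother"],
            )
            rep = prioritize(case, dmap, sim.annotations)
            verdicts.add(rep.verdict)
        assert verdicts <= {"causal_found", "suspected", "negative"}

    def test_trio_carrier_parents_hom_proband(self, panel, dmap):
        """Parents of an AR homozygote report as carriers, proband as causal."""
        spec = SimulationSpec(seed=21, noise_free=True, background_rate=0)
        disease = next(
            d for d, genes in dmap.genes_by_disease.items()
            if any("AR" in dmap.models_by_gene[g] for g in genes)
        )
        sim = simulate_case(spec, disease, dmap, panel, mode="AR")
        proband = Case(
            "kid", disease, sim.calls["proband"], sex=sim.proband_sex,
            father_calls=sim.calls["father"], mother_calls=sim.calls["mother"],
        )
        assert prioritize(proband, dmap, sim.annotations).verdict == "causal_found"
        for parent in ("father", "mother"):
            rep = prioritize(
                Case(parent, disease, sim.calls[parent], sex="female" if parent == "mother" else "male"),
                dmap, sim.annotations,
            )
            assert rep.verdict == "suspected"
            assert any("carrier_only" in h["flags"] for h in rep.all_hits())
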