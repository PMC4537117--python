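"""Dosage-ratio normalization and CNV/aneuploidy calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paneldx import (
    ChromCounts,
    ConfigurationError,
    DosageEvent,
    Karyotype,
    SimulationSpec,
    ValidationError,
    call_exon_cnv,
    chrom_dosage,
    expected_copy_ratio,
    infer_sex,
    normalize_exon_ratios,
    segment_dosage,
    simulate_binned_counts,
    simulate_chrom_counts,
    simulate_depths,
)

REF_NAMES = [f"R{i}" for i in range(4)]
REFS = {r: Karyotype("female") for r in REF_NAMES}


def _ratio_series(values_by_gene):
    idx, vals = [], []
    for gene, values in values_by_gene.items():
        for i, v in enumerate(values, start=1):
            idx.append((gene, f"CDS{i}"))
            vals.append(v)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["gene", "exon"]))


class TestNormalizeExonRatios:
    def test_test_identical_to_controls_gives_unit_ratios(self, panel):
        spec = SimulationSpec(seed=1, n_controls=4, noise_free=True)
        dm = simulate_depths(panel, spec, {"T1": []})
        ratios = normalize_exon_ratios(dm, "T1")
        assert np.allclose(ratios, 1.0)

    def test_noise_free_het_duplication_ratio_is_exactly_1_5(self, panel):
        spec = SimulationSpec(seed=1, n_controls=4, noise_free=True)
        exons = ("CDS1", "CDS2", "CDS3", "CDS4")
        ev = [DosageEvent("exon_run", 3, gene="G0003", exons=exons)]
        ratios = normalize_exon_ratios(simulate_depths(panel, spec, {"T1": ev}), "T1")
        for e in exons:
            assert ratios.loc[("G0003", e)] == pytest.approx(1.5)
        others = ratios.drop(index=[("G0003", e) for e in exons])
        assert np.allclose(others, 1.0)

    def test_noise_free_hemizygous_deletion_ratio_is_exactly_0_5(self, panel):
        spec = SimulationSpec(seed=1, n_controls=4, noise_free=True)
        ev = [DosageEvent("exon_run", 1, gene="G0003", exons=("CDS2",))]
        ratios = normalize_exon_ratios(simulate_depths(panel, spec, {"T1": ev}), "T1")
        assert ratios.loc[("G0003", "CDS2")] == pytest.approx(0.5)

    @given(k=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_per_sample_scaling(self, panel, k):
        spec = SimulationSpec(seed=2, n_controls=4)
        dm = simulate_depths(panel, spec, {"T1": []})
        before = normalize_exon_ratios(dm, "T1")
        dm.depths["T1"] *= k
        dm.depths["C02"] *= 3.7
        after = normalize_exon_ratios(dm, "T1")
        assert np.allclose(before.fillna(-1), after.fillna(-1))

    def test_no_in_batch_controls_is_configuration_error(self, panel):
        spec = SimulationSpec(seed=1, n_controls=1, noise_free=True)
        dm = simulate_depths(panel, spec, {"T1": []})
        dm.batches["T1"] = "batch_other"
        with pytest.raises(ConfigurationError, match="batch_other"):
            normalize_exon_ratios(dm, "T1")

    def test_zero_control_median_flagged_nan(self, panel):
        spec = SimulationSpec(seed=1, n_controls=3, noise_free=True)
        dm = simulate_depths(panel, spec, {"T1": []})
        dm.depths.loc[("G0001", "CDS1"), ["C01", "C02", "C03"]] = 0.0
        ratios = normalize_exon_ratios(dm, "T1")
        assert np.isnan(ratios.loc[("G0001", "CDS1")])


class TestCallExonCnv:
    def test_fig_profile_one_gain_call_copy_3(self):
        ratios = _ratio_series({"PMP22": [1.4965, 1.5674, 1.5513, 1.5306]})
        (call,) = call_exon_cnv(ratios)
        assert call.classification == "gain"
        assert call.n_units == 4
        assert call.expected_copies == 3
        assert call.exons == ("CDS1", "CDS2", "CDS3", "CDS4")

    def test_all_unit_ratios_no_calls(self):
        ratios = _ratio_series({"G1": [1.0] * 6, "G2": [1.0] * 3})
        assert call_exon_cnv(ratios) == []

    def test_empty_vector_no_calls(self):
        assert call_exon_cnv(_ratio_series({})) == []

    def test_runs_do_not_cross_gene_boundaries(self):
        ratios = _ratio_series({"G1": [1.5, 1.5], "G2": [1.5, 1.5]})
        calls = call_exon_cnv(ratios)
        assert sorted(c.gene for c in calls) == ["G1", "G2"]

    def test_single_exon_call_flagged(self):
        (call,) = call_exon_cnv(_ratio_series({"G1": [1.0, 0.5, 1.0]}))
        assert call.classification == "loss"
        assert "single_unit_call" in call.flags

    def test_matches_brute_force_run_finder_exhaustively(self):
        """Every ratio vector of length <= 8 over {0.5, 1.0, 1.5} gives the
        same calls as a brute-force maximal-run enumerator."""

        def brute_force(vals, lo=0.65, hi=1.35):
            out = []
            n = len(vals)
            for kind, ok in (("gain", lambda v: v >= hi), ("loss", lambda v: v <= lo)):
                i = 0
                while i < n:
                    if ok(vals[i]):
                        j = i
                        while j < n and ok(vals[j]):
                            j += 1
                        out.append((kind, i, j, float(np.median(vals[i:j]))))
                        i = j
                    else:
                        i += 1
            return sorted(out)

        for n in range(1, 9):
            for vals in itertools.product((0.5, 1.0, 1.5), repeat=n):
                calls = call_exon_cnv(_ratio_series({"G": list(vals)}))
                got = sorted(
                    (
                        c.classification,
                        int(c.exons[0][3:]) - 1,
                        int(c.exons[-1][3:]),
                        c.observed_ratio,
                    )
                    for c in calls
                )
                assert got == brute_force(vals), vals

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            call_exon_cnv(_ratio_series({"G": [1.0]}), gain_threshold=0.9)


class TestChromDosage:
    def test_noise_free_trisomy_ratio_exactly_1_5_elsewhere_1(self, panel):
        spec = SimulationSpec(seed=4, noise_free=True)
        cc = simulate_chrom_counts(
            panel, spec, {"T1": Karyotype("female", copies={"chr2": 3}), **REFS}
        )
        calls = {c.location: c for c in chrom_dosage(cc, "T1", REF_NAMES)}
        assert calls["chr2"].observed_ratio == pytest.approx(1.5)
        assert calls["chr2"].classification == "gain"
        assert calls["chr2"].expected_copies == 3
        for chrom in ("chr1", "chr3", "chr17", "chrX"):
            assert calls[chrom].observed_ratio == pytest.approx(1.0)
            assert calls[chrom].classification == "normal"

    def test_identical_to_references_all_unit(self, panel):
        spec = SimulationSpec(seed=4, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, {"T1": Karyotype("female"), **REFS})
        for c in chrom_dosage(cc, "T1", REF_NAMES):
            if c.location != "chrY":  # all-female cohort: no Y signal to compare
                assert c.observed_ratio == pytest.approx(1.0)

    def test_reference_vs_remaining_references_unit_in_noise_free(self, panel):
        spec = SimulationSpec(seed=4, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, REFS)
        for c in chrom_dosage(cc, "R0", REF_NAMES[1:]):
            if c.location != "chrY":
                assert c.observed_ratio == pytest.approx(1.0)

    def test_multinomial_trisomy_replicates_land_in_gain_band(self, panel):
        kts = {"T1": Karyotype("female", copies={"chr2": 3}), **REFS}
        for seed in range(20):
            spec = SimulationSpec(seed=seed)
            cc = simulate_chrom_counts(panel, spec, kts, total_reads=7_000_000)
            (call,) = [c for c in chrom_dosage(cc, "T1", REF_NAMES) if c.location == "chr2"]
            assert 1.35 <= call.observed_ratio <= 1.65
            assert call.classification == "gain"

    def test_no_references_rejected(self, panel):
        spec = SimulationSpec(seed=4, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, REFS)
        with pytest.raises(ConfigurationError):
            chrom_dosage(cc, "R0", [])


class TestSegmentDosage:
    def _setup(self, panel, spec, segments=()):
        kts = {"T1": Karyotype("female", segments=segments), **REFS}
        return simulate_binned_counts(panel, spec, "chr17", 20_000, kts)

    def test_noise_free_het_deletion_exact_half_over_event_bins(self, panel):
        regs = [r for r in panel.regions if r.chrom == "chr17"]
        lo = min(r.start for r in regs)
        hi = max(r.end for r in regs)
        seg = ("chr17", lo + (hi - lo) // 4, lo + (hi - lo) // 2, 1)
        spec = SimulationSpec(seed=5, noise_free=True)
        binned = self._setup(panel, spec, segments=(seg,))
        (call,) = segment_dosage(binned, "T1", REF_NAMES)
        assert call.classification == "loss"
        assert call.observed_ratio == pytest.approx(0.5)
        # called interval covers the event to bin resolution
        assert call.interval[0] <= seg[1] and call.interval[1] >= seg[2] - 20_000

    def test_no_event_empty_list(self, panel):
        spec = SimulationSpec(seed=5, noise_free=True)
        binned = self._setup(panel, spec)
        assert segment_dosage(binned, "T1", REF_NAMES) == []

    def test_megabase_deletion_recovered_with_high_jaccard(self):
        # gene-dense chromosome-17-like footprint: 3.4 Mb het deletion in ~24 Mb
        from paneldx import build_panel

        panel = build_panel(
            n_genes=300, exons_per_gene=6, exon_length=150, gap=5_000,
            chromosomes=("chr17", "chrX", "chrY"), x_genes=2, y_genes=1, seed=0,
        )
        regs = [r for r in panel.regions if r.chrom == "chr17"]
        start = min(r.start for r in regs) + 5_037_000  # not bin-aligned
        seg = ("chr17", start, start + 3_400_000, 1)
        kts = {"T1": Karyotype("female", segments=(seg,)), **REFS}
        jaccards = []
        for seed in range(5):
            spec = SimulationSpec(seed=seed)
            binned = simulate_binned_counts(panel, spec, "chr17", 100_000, kts)
            losses = [
                c for c in segment_dosage(binned, "T1", REF_NAMES)
                if c.classification == "loss"
            ]
            best = 0.0
            for c in losses:
                inter = max(
                    0, min(c.interval[1], seg[2]) - max(c.interval[0], seg[1])
                )
                union = max(c.interval[1], seg[2]) - min(c.interval[0], seg[1])
                best = max(best, inter / union)
            jaccards.append(best)
        assert min(jaccards) >= 0.9


class TestSexInference:
    def _profiles(self, panel):
        spec = SimulationSpec(seed=6, noise_free=True)
        cc = simulate_chrom_counts(
            panel, spec, {"F": Karyotype("female"), "M": Karyotype("male")}
        )
        f = cc.counts.at["chrX", "F"] / cc.autosomal_total("F")
        m = cc.counts.at["chrX", "M"] / cc.autosomal_total("M")
        return f, m

    def test_xx_profile_female(self, panel):
        f, m = self._profiles(panel)
        spec = SimulationSpec(seed=7, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, {"S": Karyotype("female")})
        assert infer_sex(cc, "S", f, m) == "female"

    def test_xy_profile_male(self, panel):
        f, m = self._profiles(panel)
        spec = SimulationSpec(seed=7, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, {"S": Karyotype("male")})
        assert infer_sex(cc, "S", f, m) == "male"

    def test_midway_dosage_undetermined(self, panel):
        f, m = self._profiles(panel)
        spec = SimulationSpec(seed=7, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, {"S": Karyotype("female")})
        # force X dosage midway between the profiles
        mid_target = (f + m) / 2 * cc.autosomal_total("S")
        cc.counts.at["chrX", "S"] = mid_target
        assert infer_sex(cc, "S", f, m) == "undetermined"

    def test_no_x_targets_is_configuration_error(self, panel):
        spec = SimulationSpec(seed=7, noise_free=True)
        cc = simulate_chrom_counts(panel, spec, {"S": Karyotype("female")})
        trimmed = ChromCounts(cc.counts.drop(index=["chrX", "chrY"]))
        with pytest.raises(ConfigurationError):
            infer_sex(trimmed, "S", 0.1, 0.05)


class TestExpectedCopyRatio:
    @pytest.mark.parametrize("copies,ratio", [(3, 1.5), (2, 1.0), (1, 0.5), (0, 0.0)])
    def test_values(self, copies, ratio):
        assert expected_copy_ratio(copies) == ratio

    def test_negative_copies_rejected(self):
        with pytest.raises(ValidationError):
            expected_copy_ratio(-1)


class TestMatrixIO:
    def test_depth_matrix_tsv_round_trip(self, panel, tmp_path):
        spec = SimulationSpec(seed=8, n_controls=3)
        dm = simulate_depths(panel, spec, {"T1": []})
        p = tmp_path / "depths.tsv"
        dm.write_tsv(p)
        back = type(dm).read_tsv(p)
        assert back.batches == dm.batches
        assert np.allclose(back.depths, dm.depths)
        assert back.regions == dm.regions

    def test_chrom_counts_tsv_round_trip(self, panel, tmp_path):
        spec = SimulationSpec(seed=8)
        cc = simulate_chrom_counts(panel, spec, REFS)
        p = tmp_path / "counts.tsv"
        cc.write_tsv(p)
        back = type(cc).read_tsv(p)
        assert np.allclose(back.counts, cc.counts)
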