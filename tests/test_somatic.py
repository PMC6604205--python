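"""The tumor-only filter-and-rescue engine."""

import numpy as np
import pandas as pd
import pytest

from pdxsoma import simulate, somatic
from pdxsoma.somatic import (
    ClinicalKB,
    FilterTrace,
    GermlineResource,
    PipelineConfig,
    RecurrenceTable,
    apply_quality_filters,
    build_germline_resource,
    compute_recurrence,
    flag_germline,
    flag_recurrent_fp,
    run_somatic_pipeline,
    variant_frame,
)

from conftest import make_call


class TestQualityFilters:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(QD=1.5), "fail_hard"),                      # SNV QD < 2.0
            (dict(FS=61.0), "fail_hard"),
            (dict(MQ=39.9), "fail_hard"),
            (dict(MQRankSum=-13.0), "fail_hard"),
            (dict(ReadPosRankSum=-8.5), "fail_hard"),
            (dict(DP=139), "fail_depth"),                     # DP >= 140 inclusive
            (dict(DP=140, ALT_AF=0.049), "fail_af"),
            (dict(DP=500, ALT_AF=0.05), "pass"),              # AF boundary inclusive
            (dict(), "pass"),
        ],
    )
    def test_snv_thresholds(self, kwargs, expected):
        assert apply_quality_filters(make_call(**kwargs)) == expected

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(ReadPosRankSum=-25.0), "fail_hard"),        # indel RPRS < -20
            (dict(FS=100.0), "pass"),                         # indel FS cut is 200
            (dict(FS=201.0), "fail_hard"),
            (dict(MQ=10.0), "pass"),                          # MQ not in the indel set
        ],
    )
    def test_indel_thresholds(self, kwargs, expected):
        call = make_call(vtype="indel", alt="AT", **kwargs)
        assert apply_quality_filters(call) == expected

    def test_missing_annotations_do_not_fail(self):
        call = make_call(QD=None, FS=None, MQ=None, MQRankSum=None, ReadPosRankSum=None)
        assert apply_quality_filters(call) == "pass"

    def test_unknown_vtype_rejected(self):
        call = make_call()
        call.vtype = "sv"
        with pytest.raises(ValueError):
            apply_quality_filters(call)


KEY = ("chr1", 100, "A", "T")


class TestGermlineResource:
    def _normals(self, n_carrying, total=20):
        return {f"N{i}": ([KEY] if i < n_carrying else []) for i in range(total)}

    def _pdx(self, n_carrying, total=20):
        return {f"P{i}": ([KEY] if i < n_carrying else []) for i in range(total)}

    def test_two_of_twenty_normals_admitted(self):
        res = build_germline_resource({}, self._normals(2), self._pdx(0))
        assert KEY in res

    def test_one_normal_plus_two_pdx_admitted(self):
        res = build_germline_resource({}, self._normals(1), self._pdx(2))
        assert KEY in res

    def test_one_normal_plus_one_pdx_not_admitted(self):
        res = build_germline_resource({}, self._normals(1), self._pdx(1))
        assert KEY not in res

    def test_public_sources_union(self):
        res = build_germline_resource(
            {"dbsnp": [KEY], "exac": [(("chr2", 5, "G", "C"), 0.02)]}
        )
        assert KEY in res and ("chr2", 5, "G", "C") in res

    def test_exac_below_one_percent_maf_rejected(self):
        with pytest.raises(ValueError):
            build_germline_resource({"exac": [(KEY, 0.005)]})

    def test_zero_normals_with_compendium_is_an_error(self):
        with pytest.raises(ValueError):
            build_germline_resource({}, {}, self._pdx(2))


class TestFlagGermline:
    def _resource(self):
        res = GermlineResource()
        res.add(KEY, "dbsnp")
        return res

    @pytest.mark.parametrize(
        "af,expected",
        [
            (0.50, True),    # heterozygous window
            (0.40, True),    # window closed at 40%
            (0.60, True),
            (0.75, False),   # between the windows
            (0.90, False),   # "> 90%" strict
            (0.95, True),
            (1.00, True),
            (0.39, False),
        ],
    )
    def test_af_windows(self, af, expected):
        assert flag_germline(make_call(ALT_AF=af), self._resource()) is expected

    def test_absent_from_resource_never_germline(self):
        assert not flag_germline(make_call(pos=999, ALT_AF=0.5), self._resource())


class TestRecurrence:
    def _table(self, carriers, n, pos=100):
        rows = [{"sample_id": f"S{i}", "chrom": "chr1", "pos": pos,
                 "germline_flag": False} for i in range(carriers)]
        return compute_recurrence(pd.DataFrame(rows), cohort_size=n)

    def test_59_of_236_is_a_quarter(self):
        table = self._table(59, 236)
        assert table.fractions[("chr1", 100)] == pytest.approx(0.25)

    def test_1_of_20(self):
        assert self._table(1, 20).fractions[("chr1", 100)] == pytest.approx(0.05)

    def test_germline_occurrences_excluded_from_numerator(self):
        rows = [
            {"sample_id": "S1", "chrom": "chr1", "pos": 100, "germline_flag": True},
            {"sample_id": "S2", "chrom": "chr1", "pos": 100, "germline_flag": False},
        ]
        table = compute_recurrence(pd.DataFrame(rows), cohort_size=4)
        assert table.fractions[("chr1", 100)] == pytest.approx(0.25)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            compute_recurrence(
                pd.DataFrame(columns=["sample_id", "chrom", "pos", "germline_flag"]),
                cohort_size=0,
            )

    @pytest.mark.parametrize(
        "fraction,n,germline,expected",
        [
            (0.30, 20, False, True),
            (0.24, 20, False, False),    # below the 25% threshold
            (0.25, 20, False, True),     # inclusive boundary
            (0.30, 20, True, False),     # germline-flagged: disjoint filter path
            (1.00, 1, False, False),     # one carrier is not recurrent
        ],
    )
    def test_flagging(self, fraction, n, germline, expected):
        table = RecurrenceTable(fractions={("chr1", 100): fraction}, cohort_size=n)
        got = flag_recurrent_fp(make_call(), table, germline_flag=germline)
        assert got is expected

    def test_position_missing_from_table_is_an_error(self):
        table = RecurrenceTable(fractions={}, cohort_size=10)
        with pytest.raises(KeyError):
            flag_recurrent_fp(make_call(), table)


class TestRescue:
    def _kb(self):
        kb = ClinicalKB()
        kb.add_site(KEY, ["treatment_approach"])
        kb.add_gene_change("BRAF", "V600E", ["gain_or_loss_of_function"])
        return kb

    def test_gatk_germline_with_kb_hit_is_rescued(self):
        trace = FilterTrace(germline_flag=True, final="filtered_germline")
        out = somatic.rescue_clinical(trace, make_call(), self._kb())
        assert out.final == "rescued_clinical" and out.rescued

    def test_gene_protein_change_match_rescues(self):
        trace = FilterTrace(germline_flag=True, final="filtered_germline")
        call = make_call(pos=55, gene="BRAF", protein_change="V600E")
        assert somatic.rescue_clinical(trace, call, self._kb()).final == "rescued_clinical"

    def test_pindel_with_kb_hit_retained(self):
        trace = FilterTrace(recurrent_fp_flag=True, final="filtered_fp")
        call = make_call(caller="pindel", vtype="indel", alt="AT",
                         gene="BRAF", protein_change="V600E")
        assert somatic.rescue_clinical(trace, call, self._kb()).final == "rescued_clinical"

    def test_pindel_without_kb_hit_dropped(self):
        trace = FilterTrace(final="somatic_pass")
        call = make_call(pos=999, caller="pindel", vtype="indel", alt="AT")
        assert somatic.rescue_clinical(trace, call, self._kb()).final == "filtered_pindel_no_kb"

    def test_quality_failed_variants_are_not_rescued(self):
        trace = FilterTrace(quality_status="fail_hard", germline_flag=True,
                            final="filtered_quality")
        out = somatic.rescue_clinical(trace, make_call(), self._kb())
        assert out.final == "filtered_quality" and not out.rescued

    def test_clinical_entries_require_tags(self):
        with pytest.raises(ValueError):
            ClinicalKB().add_site(KEY, [])


class TestPipeline:
    def test_clean_somatic_variants_all_pass(self):
        calls = variant_frame([make_call(pos=p, sample_id="S1") for p in (10, 20, 30)])
        result = run_somatic_pipeline(calls, GermlineResource())
        assert (result.calls["final"] == "somatic_pass").all()

    def test_status_partition_and_conservation(self, default_pipeline):
        vc, result = default_pipeline
        assert result.calls["final"].isin(somatic.FINAL_STATUSES).all()
        assert result.summary.values.sum() == len(vc.calls)
        assert len(result.calls) == len(vc.calls)

    def test_rescue_containment(self, default_pipeline):
        _, result = default_pipeline
        rescued = result.calls[result.calls["rescued"]]
        assert (
            rescued["germline_flag"] | rescued["recurrent_fp_flag"]
            | (rescued["caller"] == "pindel")
        ).all()
        # no quality-failed variant is ever emitted
        emitted = result.passing()
        assert (emitted["quality_status"] == "pass").all()

    def test_row_order_independence(self, default_cohort):
        _, vc = default_cohort
        shuffled = vc.calls.sample(frac=1.0, random_state=3)
        a = run_somatic_pipeline(vc.calls, vc.resource)
        b = run_somatic_pipeline(shuffled, vc.resource)
        key = ["sample_id", "chrom", "pos", "alt"]
        merged = a.calls[key + ["final"]].merge(b.calls[key + ["final"]], on=key)
        assert (merged["final_x"] == merged["final_y"]).all()

    def test_rerun_is_deterministic(self, default_cohort):
        _, vc = default_cohort
        a = run_somatic_pipeline(vc.calls, vc.resource)
        b = run_somatic_pipeline(vc.calls, vc.resource)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_planted_artifacts_filtered_in_every_sample(self, default_pipeline):
        vc, result = default_pipeline
        artifact_keys = set(
            (r.sample_id, r.chrom, r.pos)
            for r in vc.truth[vc.truth["label"] == "artifact"].itertuples(index=False)
        )
        called = result.calls[
            result.calls.apply(
                lambda r: (r["sample_id"], r["chrom"], r["pos"]) in artifact_keys, axis=1
            )
        ]
        assert not called.empty
        assert (called["final"] == "filtered_fp").all()

    def test_planted_germline_removed(self, default_pipeline):
        vc, result = default_pipeline
        germ_keys = set(
            (r.sample_id, r.chrom, r.pos, r.alt)
            for r in vc.truth[vc.truth["label"] == "germline"].itertuples(index=False)
        )
        called = result.calls[
            result.calls.apply(
                lambda r: (r["sample_id"], r["chrom"], r["pos"], r["alt"]) in germ_keys,
                axis=1,
            )
        ]
        removed = called["final"].isin(["filtered_germline", "rescued_clinical"])
        assert removed.mean() >= 0.95

    def test_kb_rescue_reinstates_known_germline_lookalike(self):
        resource = GermlineResource()
        resource.add(KEY, "dbsnp")
        kb = ClinicalKB()
        kb.add_site(KEY, ["gain_or_loss_of_function"])
        calls = variant_frame([make_call(ALT_AF=0.48, sample_id="S1")])
        result = run_somatic_pipeline(calls, resource, kb)
        assert result.calls.loc[0, "germline_flag"]
        assert result.calls.loc[0, "final"] == "rescued_clinical"

    def test_full_filters_beat_disabled_filters_on_precision(self, default_cohort):
        """Germline+recurrence filtering raises precision at little recall cost."""
        from pdxsoma import cohort as cohortstats
        from conftest import truth_universe

        _, vc = default_cohort
        truth = vc.truth[vc.truth["label"] == "somatic"]

        def bench(config):
            result = run_somatic_pipeline(vc.calls, vc.resource, config=config)
            pred = result.passing()
            return cohortstats.benchmark(pred, truth, truth_universe(vc, pred))

        full = bench(PipelineConfig())
        bare = bench(PipelineConfig(enable_germline_filter=False, enable_fp_filter=False))
        assert full.precision >= bare.precision
        assert full.precision > 0.9
        assert full.recall >= bare.recall - 0.05
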