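import dataclasses

import pytest

from netprio.data import load_toy_blacklist, load_toy_variants
from netprio.exceptions import ValidationError
from netprio.variant_filter import (
    FilterConfig,
    VariantRecord,
    aggregate_to_genes,
    filter_variants,
    passes_blacklist_filter,
    passes_consequence_filter,
    passes_cosegregation_filter,
    passes_deleteriousness_filter,
    passes_inhouse_filter,
    passes_population_filter,
    passes_qc_filter,
    read_variants_tsv,
    write_variants_tsv,
)


def make_record(**overrides) -> VariantRecord:
    base = dict(
        family_id="F1",
        gene="GENE1",
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        consequence="missense",
        maf_1kg=None,
        maf_esp=None,
        maf_exac=None,
        inhouse_family_count=0,
        carriers_in_family=3,
        cases_sequenced=5,
        metasvm="D",
        metalr="D",
        cadd=25.0,
        qc_flagged=False,
        depth=40,
        abhet=0.5,
        caller_count=3,
    )
    base.update(overrides)
    return VariantRecord(**base)


class TestRecordValidation:
    def test_carriers_cannot_exceed_cases(self):
        with pytest.raises(ValidationError):
            make_record(carriers_in_family=6, cases_sequenced=5)

    def test_unknown_consequence_rejected(self):
        with pytest.raises(ValidationError):
            make_record(consequence="synonymous")


class TestPredicates:
    @pytest.mark.parametrize(
        "mafs,expected",
        [
            ((0.0005, 0.0002, None), True),
            ((0.001, 0.0, 0.0), False),  # strict inequality at the bound
            ((None, None, None), True),  # absence implies rarity
        ],
    )
    def test_population(self, mafs, expected):
        rec = make_record(maf_1kg=mafs[0], maf_esp=mafs[1], maf_exac=mafs[2])
        assert passes_population_filter(rec, 0.001) is expected

    @pytest.mark.parametrize("count,expected", [(0, True), (2, True), (3, False)])
    def test_inhouse(self, count, expected):
        assert passes_inhouse_filter(make_record(inhouse_family_count=count), 2) is expected

    @pytest.mark.parametrize(
        "carriers,cases,expected", [(3, 5, True), (2, 3, False), (4, 4, True)]
    )
    def test_cosegregation(self, carriers, cases, expected):
        rec = make_record(carriers_in_family=carriers, cases_sequenced=cases)
        assert passes_cosegregation_filter(rec, 3) is expected

    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("stop_gain", True),
            ("splicing", True),
            ("frameshift", True),
            ("inframe_indel", True),
            ("missense", True),
            ("other", False),
        ],
    )
    def test_consequence(self, consequence, expected):
        assert passes_consequence_filter(make_record(consequence=consequence)) is expected

    def test_blacklist(self):
        assert not passes_blacklist_filter(make_record(gene="MUC16"), {"MUC16"})
        assert passes_blacklist_filter(make_record(gene="ATR"), {"MUC16"})
        assert passes_blacklist_filter(make_record(gene="MUC16"), set())

    @pytest.mark.parametrize(
        "metasvm,metalr,cadd,expected",
        [
            ("T", "T", 24.6, False),  # one vote (the contentious tolerated/high-CADD case)
            ("D", "D", 5.0, True),  # two predictor votes, CADD abstains
            ("D", None, 21.0, True),  # missing predictor is a non-vote
            (None, None, None, False),
        ],
    )
    def test_deleteriousness_missense(self, metasvm, metalr, cadd, expected):
        rec = make_record(metasvm=metasvm, metalr=metalr, cadd=cadd)
        assert passes_deleteriousness_filter(rec, 20.0, 2) is expected

    def test_deleteriousness_single_vote_config(self):
        rec = make_record(metasvm="T", metalr="T", cadd=24.6)
        assert passes_deleteriousness_filter(rec, 20.0, 1)

    def test_non_missense_passes_unconditionally(self):
        rec = make_record(consequence="stop_gain", metasvm=None, metalr=None, cadd=None)
        assert passes_deleteriousness_filter(rec)

    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"depth": 9}, False),
            ({"abhet": 0.85}, False),
            ({"abhet": 0.15}, False),
            ({"abhet": None}, True),  # ABHet undefined for homozygous calls
            ({"caller_count": 1}, False),
            ({"qc_flagged": True}, False),
            ({"depth": 30, "abhet": 0.5, "caller_count": 3}, True),
        ],
    )
    def test_qc(self, overrides, expected):
        assert passes_qc_filter(make_record(**overrides)) is expected


@pytest.fixture(scope="module")
def toy():
    return load_toy_variants(), FilterConfig(blacklist=load_toy_blacklist())


class TestFilterVariants:
    def test_toy_fixture_survivor_set(self, toy):
        records, config = toy
        survivors, attrition = filter_variants(records, config)
        assert len(survivors) == 7
        assert sorted({r.gene for r in survivors}) == [
            "GENEA", "GENEB", "GENEC", "GENED", "GENEE", "GENEF",
        ]
        # every filter rejects at least one record of the fixture
        assert all(count >= 1 for count in attrition.values())
        # hand-derived per-filter attrition
        assert attrition == {
            "population": 2,
            "inhouse": 3,
            "cosegregation": 3,
            "consequence": 2,
            "blacklist": 1,
            "deleteriousness": 2,
            "qc": 4,
        }

    def test_empty_input(self):
        survivors, attrition = filter_variants([], FilterConfig())
        assert survivors == [] and all(v == 0 for v in attrition.values())

    def test_all_passing_is_identity(self):
        records = [make_record(gene=f"G{i}") for i in range(5)]
        survivors, _ = filter_variants(records, FilterConfig())
        assert survivors == records

    def test_order_invariance(self, toy):
        records, config = toy
        forward, _ = filter_variants(records, config)
        backward, _ = filter_variants(list(reversed(records)), config)
        assert sorted(forward, key=str) == sorted(backward, key=str)

    def test_survivors_repass_each_predicate(self, toy):
        records, config = toy
        survivors, _ = filter_variants(records, config)
        for rec in survivors:
            assert passes_population_filter(rec, config.maf_max)
            assert passes_inhouse_filter(rec, config.inhouse_max)
            assert passes_cosegregation_filter(rec, config.min_carriers)
            assert passes_consequence_filter(rec)
            assert passes_blacklist_filter(rec, config.blacklist)
            assert passes_deleteriousness_filter(rec, config.cadd_min, config.min_votes)
            assert passes_qc_filter(
                rec, config.min_depth, config.abhet_lo, config.abhet_hi,
                config.min_callers,
            )

    @pytest.mark.parametrize(
        "relaxed",
        [
            {"maf_max": 0.01},
            {"inhouse_max": 10},
            {"min_carriers": 1},
            {"cadd_min": 5.0},
            {"min_votes": 1},
            {"min_depth": 0},
            {"abhet_lo": 0.0, "abhet_hi": 1.0},
            {"min_callers": 0},
            {"blacklist": frozenset()},
        ],
    )
    def test_relaxing_any_threshold_never_loses_survivors(self, toy, relaxed):
        records, config = toy
        baseline, _ = filter_variants(records, config)
        relaxed_config = dataclasses.replace(config, **relaxed)
        more, _ = filter_variants(records, relaxed_config)
        assert set(id(r) for r in baseline) <= set(id(r) for r in more)


class TestAggregate:
    def test_same_gene_two_families(self):
        recs = [
            make_record(gene="G", family_id="F1"),
            make_record(gene="G", family_id="F2"),
        ]
        (cand,) = aggregate_to_genes(recs, 20)
        assert cand.n_families == 2 and cand.families == frozenset({"F1", "F2"})

    def test_three_genes_three_candidates(self):
        recs = [make_record(gene=g) for g in ("A", "B", "C")]
        assert len(aggregate_to_genes(recs, 10)) == 3

    def test_pooled_carrier_fraction(self):
        recs = [
            make_record(gene="G", family_id="F1", carriers_in_family=3),
            make_record(gene="G", family_id="F2", carriers_in_family=4, cases_sequenced=6),
        ]
        (cand,) = aggregate_to_genes(recs, 98)
        assert cand.patient_carrier_fraction == pytest.approx(7 / 98)

    def test_toy_fixture_fractions(self, toy):
        records, config = toy
        survivors, _ = filter_variants(records, config)
        by_gene = {c.gene: c for c in aggregate_to_genes(survivors, 29)}
        assert by_gene["GENEA"].n_families == 2
        assert by_gene["GENEA"].patient_carrier_fraction == pytest.approx(6 / 29)

    def test_total_cases_too_small_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_to_genes([make_record()], 3)


def test_variants_tsv_round_trip(tmp_path, toy):
    records, _ = toy
    write_variants_tsv(records, tmp_path / "v.tsv")
    assert read_variants_tsv(tmp_path / "v.tsv") == records
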