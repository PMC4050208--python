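"""Per-site verdicts, aggregation, and the decoding pipeline's semantics."""

import pytest
from hypothesis import given, strategies as st

from cugscribe.cug_classifier import (
    AggregateVerdict,
    CugSiteReport,
    ReferenceFamily,
    aggregate,
    annotate_cug_sites,
    build_site_report,
    composition_verdict,
    conservation_counts,
    conservation_verdict,
)
from cugscribe.homolog_finder import PredictedGene
from cugscribe.profile_mapping import ColumnMap


def make_family(rows, species, complete, cug_columns, decoding):
    return ReferenceFamily(
        family_id="fam",
        rows=rows,
        species=species,
        complete=complete,
        cug_columns={sid: frozenset(cols) for sid, cols in cug_columns.items()},
        decoding=decoding,
    )


@pytest.fixture
def mixed_family():
    """Three aycu rows, two standard rows; CUG annotations at column 1."""
    rows = {f"a{i}": "MSKV" for i in range(3)}
    rows.update({f"s{i}": "MLKV" for i in range(2)})
    species = {sid: f"sp_{sid}" for sid in rows}
    complete = {sid: True for sid in rows}
    decoding = {f"sp_a{i}": "aycu" for i in range(3)}
    decoding.update({f"sp_s{i}": "standard" for i in range(2)})
    cug = {f"a{i}": [1] for i in range(3)}
    return make_family(rows, species, complete, cug, decoding)


class TestCompositionVerdict:
    @pytest.mark.parametrize(
        "composition, expected",
        [
            ({"L": 30, "I": 5, "S": 2}, "standard"),
            ({"S": 20, "T": 5, "L": 3}, "aycu"),
            ({"G": 10, "P": 8, "L": 2}, "ambiguous"),  # majority in neither class
            ({"L": 5, "S": 5}, "ambiguous"),  # tie
            ({"L": 2, "S": 1}, "ambiguous"),  # below minimum occupancy
        ],
    )
    def test_examples(self, composition, expected):
        assert composition_verdict(composition) == expected

    def test_minimum_occupancy_is_configurable(self):
        assert composition_verdict({"L": 2, "S": 1}, min_occupancy=1) == "standard"

    @given(
        st.dictionaries(
            st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
            st.integers(min_value=0, max_value=50),
            max_size=8,
        ),
        st.integers(min_value=2, max_value=9),
    )
    def test_scale_invariance(self, composition, factor):
        scaled = {aa: n * factor for aa, n in composition.items()}
        assert composition_verdict(composition, min_occupancy=0) == composition_verdict(
            scaled, min_occupancy=0
        )


class TestConservationVerdict:
    def test_majority_of_complete_annotated_rows(self, mixed_family):
        assert conservation_counts(mixed_family, 1) == (0, 3)
        assert conservation_verdict(mixed_family, 1) == "aycu"

    def test_no_reference_cug_is_ambiguous(self, mixed_family):
        assert conservation_verdict(mixed_family, 2) == "ambiguous"

    def test_incomplete_rows_are_excluded(self, mixed_family):
        mixed_family.complete.update({f"a{i}": False for i in range(3)})
        assert conservation_counts(mixed_family, 1) == (0, 0)
        assert conservation_verdict(mixed_family, 1) == "ambiguous"

    def test_mixed_annotations_majority_wins(self, mixed_family):
        mixed_family.cug_columns["s0"] = frozenset([1])
        assert conservation_counts(mixed_family, 1) == (1, 3)
        assert conservation_verdict(mixed_family, 1) == "aycu"

    def test_tie_is_ambiguous(self, mixed_family):
        mixed_family.cug_columns["s0"] = frozenset([1])
        mixed_family.complete["a1"] = False
        mixed_family.complete["a2"] = False
        assert conservation_counts(mixed_family, 1) == (1, 1)
        assert conservation_verdict(mixed_family, 1) == "ambiguous"

    def test_label_swap_flips_every_verdict(self, small_bundle):
        bundle, _ = small_bundle
        flip = {"standard": "aycu", "aycu": "standard"}
        for fam in bundle.families:
            swapped = ReferenceFamily(
                fam.family_id,
                fam.rows,
                fam.species,
                fam.complete,
                fam.cug_columns,
                {sp: flip[lab] for sp, lab in fam.decoding.items()},
            )
            for col in range(fam.n_columns):
                v = conservation_verdict(fam, col)
                w = conservation_verdict(swapped, col)
                assert w == (flip[v] if v in flip else v)


class TestBuildSiteReport:
    def test_composition_uses_all_rows_conservation_only_complete(self, mixed_family):
        mixed_family.complete["a0"] = False  # still counts for composition
        report = build_site_report(mixed_family, 2, 1)
        assert report.composition == {"L": 2, "S": 3}
        assert report.polar_small_count == 3
        assert report.hydrophobic_count == 2
        assert report.cug_as_ser_count == 2  # a0 excluded
        assert report.column == 2  # 1-based in reports

    def test_null_column_site_is_ambiguous_both_ways(self, mixed_family):
        report = build_site_report(mixed_family, 5, None)
        assert report.column is None
        assert report.composition_verdict == "ambiguous"
        assert report.conservation_verdict == "ambiguous"


class TestAnnotateCugSites:
    def _gene(self, codons):
        protein = "".join("L" if c == "CTG" else "K" for c in codons)
        return PredictedGene(
            family_id="fam",
            contig_id="c",
            strand="+",
            start=0,
            end=3 * len(codons),
            protein=protein,
            codons=tuple(codons),
            codon_starts=tuple(range(0, 3 * len(codons), 3)),
            score=100,
        )

    def test_no_ctg_yields_empty(self):
        gene = self._gene(["AAA", "AAG"])
        assert annotate_cug_sites(gene, ColumnMap((0, 1), 2)) == []

    def test_ctg_sites_carry_their_columns(self):
        gene = self._gene(["AAA", "CTG", "AAA", "CTG"])
        cm = ColumnMap((0, 24, 25, None), 30)
        assert annotate_cug_sites(gene, cm) == [(2, 24), (4, None)]

    def test_length_mismatch_rejected(self):
        gene = self._gene(["AAA"])
        with pytest.raises(ValueError):
            annotate_cug_sites(gene, ColumnMap((0, 1), 2))


def site(comp, cons):
    return CugSiteReport(1, 1, {}, 0, 0, 0, 0, comp, cons)


class TestAggregate:
    def test_majority_per_feature(self):
        reports = [site("aycu", "aycu")] * 35 + [site("standard", "standard")] * 4
        v = aggregate(reports)
        assert v.composition == "aycu" and v.conservation == "aycu"
        assert v.combined == "aycu"
        assert v.composition_tally.aycu == 35 and v.composition_tally.standard == 4

    def test_no_sites_is_no_evidence(self):
        v = aggregate([])
        assert v.composition == v.conservation == v.combined == "no-evidence"
        assert v.n_sites == 0

    def test_disagreeing_features_combine_to_ambiguous(self):
        reports = [site("standard", "aycu")] * 10
        v = aggregate(reports)
        assert v.composition == "standard"
        assert v.conservation == "aycu"
        assert v.combined == "ambiguous"

    def test_tallies_sum_to_site_count(self):
        reports = [site("aycu", "ambiguous"), site("standard", "aycu"), site("ambiguous", "aycu")]
        v = aggregate(reports)
        assert v.composition_tally.total == v.conservation_tally.total == 3
        assert v.n_sites == 3

    def test_feature_tie_is_ambiguous(self):
        reports = [site("aycu", "aycu"), site("standard", "standard")]
        assert aggregate(reports).combined == "ambiguous"


class TestPipeline:
    def test_recovers_both_decodings(self, small_bundle, small_config, small_genomes):
        from cugscribe.cug_classifier import predict_decoding

        bundle, _ = small_bundle
        for label in ("standard", "aycu"):
            contigs, truth = small_genomes[label]
            verdict = predict_decoding(contigs, bundle, flank=small_config.flank)
            assert verdict.overall.combined == label
            assert verdict.overall.n_sites > 0

    def test_single_reference_aligners_also_recover(self, small_bundle, small_config, small_genomes):
        from cugscribe.cug_classifier import predict_decoding

        bundle, _ = small_bundle
        contigs, _ = small_genomes["aycu"]
        for aligner in ("nw", "gotoh"):
            verdict = predict_decoding(
                contigs, bundle, aligner=aligner, flank=small_config.flank
            )
            assert verdict.overall.combined == "aycu"

    def test_genome_without_homologs_is_no_evidence(self, small_bundle):
        from cugscribe.cug_classifier import predict_decoding

        bundle, _ = small_bundle
        verdict = predict_decoding({"c": "ACGT" * 500}, bundle)
        assert verdict.n_genes == 0
        assert verdict.overall.combined == "no-evidence"
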