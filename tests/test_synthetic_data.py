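"""Determinism and ground-truth consistency of the data generator."""

from dataclasses import replace

import pytest

from cugscribe.genetic_codes import AYCU, STANDARD, translate
from cugscribe.homolog_finder import reverse_complement
from cugscribe.synthetic_data import (
    SimulationConfig,
    annotated_columns_by_type,
    simulate_query_genome,
    simulate_reference_bundle,
    simulate_trna_refs,
)
from cugscribe.trna_classifier import find_cag_anticodon


class TestSimulateReferenceBundle:
    def test_same_seed_gives_identical_bundles(self, small_config):
        b1, t1 = simulate_reference_bundle(small_config)
        b2, t2 = simulate_reference_bundle(small_config)
        for f1, f2 in zip(b1.families, b2.families):
            assert f1.rows == f2.rows
            assert f1.cug_columns == f2.cug_columns
            assert f1.complete == f2.complete
        assert t1 == t2

    def test_emitted_bundles_pass_validation(self, small_bundle):
        bundle, _ = small_bundle
        assert bundle.validate() == []

    def test_full_purity_forces_serine_in_aycu_rows(self, small_config):
        cfg = replace(small_config, purity=1.0)
        bundle, truth = simulate_reference_bundle(cfg)
        for fam in bundle.families:
            for col in truth.ser_columns[fam.family_id]:
                for sid, row in fam.rows.items():
                    if fam.decoding[fam.species[sid]] == "aycu" and row[col] != "-":
                        assert row[col] == "S"

    def test_zero_incomplete_fraction_marks_all_complete(self, small_config):
        cfg = replace(small_config, fraction_incomplete=0.0)
        bundle, _ = simulate_reference_bundle(cfg)
        for fam in bundle.families:
            assert all(fam.complete.values())

    def test_incomplete_rows_exist_and_are_truncated(self, small_config):
        cfg = replace(cfg_seed(small_config, 31), fraction_incomplete=0.5)
        bundle, _ = simulate_reference_bundle(cfg)
        incomplete = [
            (fam, sid)
            for fam in bundle.families
            for sid, ok in fam.complete.items()
            if not ok
        ]
        assert incomplete
        for fam, sid in incomplete:
            row = fam.rows[sid]
            assert row.startswith("-") or row.endswith("-")

    def test_annotation_types_match_clades(self, small_bundle):
        bundle, truth = small_bundle
        for fam in bundle.families:
            ser, leu = annotated_columns_by_type(fam)
            assert ser <= set(truth.ser_columns[fam.family_id])
            assert leu <= set(truth.leu_columns[fam.family_id])


def cfg_seed(cfg, seed):
    return replace(cfg, seed=seed)


class TestSimulateQueryGenome:
    def test_every_recorded_cug_site_is_a_ctg_codon(self, small_bundle, small_config):
        bundle, _ = small_bundle
        for label, code in (("aycu", AYCU), ("standard", STANDARD)):
            contigs, truth = simulate_query_genome(bundle, label, small_config, seed=3)
            assert truth.decoding == label
            for gene in truth.genes:
                cds = gene.cds
                placed = contigs[gene.contig_id][gene.start : gene.end]
                if gene.strand == "-":
                    placed = reverse_complement(placed)
                assert placed == cds
                assert translate(cds, code) == gene.protein
                ctg_residues = {
                    i // 3 + 1 for i in range(0, len(cds), 3) if cds[i : i + 3] == "CTG"
                }
                assert ctg_residues == {r for r, _ in gene.cug_sites}

    def test_full_purity_aycu_encodes_every_annotated_serine_as_ctg(
        self, small_config
    ):
        cfg = replace(small_config, purity=1.0, query_identity=1.0, indel_rate=0.0)
        bundle, truth = simulate_reference_bundle(cfg)
        contigs, qt = simulate_query_genome(bundle, "aycu", cfg, seed=4)
        fams = {f.family_id: f for f in bundle.families}
        for gene in qt.genes:
            ser_cols, _ = annotated_columns_by_type(fams[gene.family_id])
            planted_cols = {c for _, c in gene.cug_sites}
            # at purity 1 every annotated ser column of the source row is CUG
            assert planted_cols
            assert planted_cols <= {c + 1 for c in ser_cols}
            for r, c in gene.cug_sites:
                assert gene.protein[r - 1] == "S"
                assert gene.protein_cug_as_leu[r - 1] == "L"

    def test_determinism(self, small_bundle, small_config):
        bundle, _ = small_bundle
        g1 = simulate_query_genome(bundle, "standard", small_config, seed=9)
        g2 = simulate_query_genome(bundle, "standard", small_config, seed=9)
        assert g1[0] == g2[0]
        assert g1[1] == g2[1]

    def test_intergenic_spacing_at_least_twice_flank(self, small_bundle, small_config):
        bundle, _ = small_bundle
        contigs, truth = simulate_query_genome(bundle, "standard", small_config, seed=10)
        by_contig = {}
        for g in truth.genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for genes in by_contig.values():
            genes.sort(key=lambda g: g.start)
            assert genes[0].start >= 2 * small_config.flank
            for a, b in zip(genes, genes[1:]):
                assert b.start - a.end >= 2 * small_config.flank

    def test_unknown_decoding_rejected(self, small_bundle, small_config):
        bundle, _ = small_bundle
        with pytest.raises(ValueError):
            simulate_query_genome(bundle, "mitochondrial", small_config)


class TestSimulateTrnaRefs:
    def test_default_set_sizes(self):
        cfg = SimulationConfig(seed=2)
        refs, labels = simulate_trna_refs(cfg)
        assert (len(refs.leu_cag), len(refs.ser_cag), len(refs.other)) == (51, 22, 34)
        assert len(labels) == 107

    def test_zero_noise_makes_class_members_identical(self):
        cfg = SimulationConfig(seed=2, trna_noise=0.0)
        refs, _ = simulate_trna_refs(cfg)
        assert len(set(refs.leu_cag.values())) == 1
        assert len(set(refs.ser_cag.values())) == 1

    def test_class_consensuses_diverge(self):
        cfg = SimulationConfig(seed=2, trna_noise=0.0)
        refs, _ = simulate_trna_refs(cfg)
        leu = next(iter(refs.leu_cag.values()))
        ser = next(iter(refs.ser_cag.values()))
        diffs = sum(1 for x, y in zip(leu, ser) if x != y)
        assert diffs / len(leu) >= 0.25

    def test_cag_classes_pass_anticodon_check_others_do_not(self):
        cfg = SimulationConfig(seed=3)
        refs, _ = simulate_trna_refs(cfg)
        for pool in (refs.leu_cag, refs.ser_cag):
            for seq in pool.values():
                assert find_cag_anticodon(seq) is not None
        for seq in refs.other.values():
            assert find_cag_anticodon(seq) != 33

    def test_determinism(self):
        cfg = SimulationConfig(seed=4)
        r1, l1 = simulate_trna_refs(cfg)
        r2, l2 = simulate_trna_refs(cfg)
        assert r1.leu_cag == r2.leu_cag and r1.ser_cag == r2.ser_cag and r1.other == r2.other
        assert l1 == l2
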