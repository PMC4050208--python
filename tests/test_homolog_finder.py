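"""Six-frame translation, seeded region finding, and gene extraction."""

import random

import pytest

from cugscribe.genetic_codes import STANDARD, translate
from cugscribe.homolog_finder import (
    extract_best_gene,
    find_candidate_regions,
    reverse_complement,
    six_frame_translate,
)
from cugscribe.synthetic_data import simulate_query_genome

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(protein, rng, forbid_ctg=True):
    codons = []
    for aa in protein:
        options = [c for c in STANDARD.codons_for(aa) if not (forbid_ctg and c == "CTG")]
        codons.append(rng.choice(options))
    return "".join(codons)


def random_protein(n, rng):
    return "".join(rng.choice(AA20) for _ in range(n))


def random_dna(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestSixFrameTranslate:
    def test_forward_frame_one(self):
        frames = {f.frame: f.protein for f in six_frame_translate("ATGAAA")}
        assert frames[1] == "MK"

    def test_reverse_frame_equals_forward_of_revcomp(self):
        rng = random.Random(1)
        seq = random_dna(50, rng)
        fwd_of_rc = {f.frame: f.protein for f in six_frame_translate(reverse_complement(seq))}
        rev = {f.frame: f.protein for f in six_frame_translate(seq)}
        for f in (1, 2, 3):
            assert rev[-f] == fwd_of_rc[f]

    def test_ctg_on_reverse_strand_reads_cag(self):
        frames = {f.frame: f.protein for f in six_frame_translate("CTG")}
        assert frames[-1] == "Q"  # reverse complement of CTG is CAG -> Gln
        assert frames[1] == "L"

    def test_coordinate_maps_trace_codons(self):
        rng = random.Random(2)
        seq = random_dna(61, rng)
        for ft in six_frame_translate(seq):
            for i, aa in enumerate(ft.protein):
                s = int(ft.codon_starts[i])
                codon = seq[s : s + 3]
                if ft.strand == "-":
                    codon = reverse_complement(codon)
                assert translate(codon, STANDARD) == aa


class TestFindCandidateRegions:
    def test_exact_planted_copy_yields_one_region(self):
        rng = random.Random(3)
        protein = random_protein(100, rng)
        cds = back_translate(protein, rng)
        contig = random_dna(400, rng) + cds + random_dna(400, rng)
        regions = find_candidate_regions({"c": contig}, protein, flank=100)
        assert len(regions) == 1
        r = regions[0]
        assert r.strand == "+"
        assert r.start <= 400 and r.end >= 400 + len(cds)
        assert r.start >= 300 and r.end <= 400 + len(cds) + 100

    def test_nearby_clusters_merge_after_flanking(self):
        rng = random.Random(4)
        protein = random_protein(40, rng)
        cds = back_translate(protein, rng)
        contig = random_dna(600, rng) + cds + random_dna(100, rng) + cds + random_dna(600, rng)
        regions = find_candidate_regions({"c": contig}, protein, flank=500)
        assert len(regions) == 1  # extended intervals overlap across the 100 nt gap

    def test_no_shared_words_yields_empty(self):
        regions = find_candidate_regions({"c": "AAA" * 200}, "WDYH" * 10, flank=100)
        assert regions == []

    def test_reference_shorter_than_word_size_rejected(self):
        with pytest.raises(ValueError, match="word size"):
            find_candidate_regions({"c": "ACGT" * 100}, "MK", k=4)


class TestExtractBestGene:
    def _region_for(self, contig, protein, flank=100):
        regions = find_candidate_regions({"c": contig}, protein, flank=flank)
        assert regions
        return regions[0]

    def test_exact_copy_recovered_identically(self):
        rng = random.Random(5)
        protein = random_protein(80, rng)
        cds = back_translate(protein, rng)
        contig = random_dna(300, rng) + cds + random_dna(300, rng)
        region = self._region_for(contig, protein)
        gene = extract_best_gene(contig, region, protein)
        assert gene is not None
        assert gene.protein == protein
        assert gene.score == extract_best_gene(contig, region, protein).score  # deterministic
        assert gene.start == 300 and gene.end == 300 + len(cds)

    def test_low_scoring_region_returns_none(self):
        rng = random.Random(6)
        protein = random_protein(100, rng)
        contig = random_dna(600, rng)
        regions = find_candidate_regions({"c": contig}, protein, k=2, min_word_hits=1, flank=50)
        if regions:  # chance dipeptide hits
            assert extract_best_gene(contig, regions[0], protein, min_score=400) is None

    def test_ctg_at_leucine_codon_reads_l_with_correct_coordinates(self):
        rng = random.Random(7)
        protein = random_protein(60, rng) + "L" + random_protein(60, rng)
        codons = [rng.choice([c for c in STANDARD.codons_for(aa) if c != "CTG"]) for aa in protein]
        codons[60] = "CTG"
        cds = "".join(codons)
        contig = random_dna(200, rng) + cds + random_dna(200, rng)
        region = self._region_for(contig, protein)
        gene = extract_best_gene(contig, region, protein)
        assert gene.protein[60] == "L"
        assert gene.codons[60] == "CTG"
        assert contig[gene.codon_starts[60] : gene.codon_starts[60] + 3] == "CTG"
        assert gene.cug_residues() == [61]

    def test_minus_strand_gene_recovered(self):
        rng = random.Random(8)
        protein = random_protein(80, rng)
        cds = back_translate(protein, rng)
        contig = random_dna(300, rng) + reverse_complement(cds) + random_dna(300, rng)
        regions = find_candidate_regions({"c": contig}, protein, flank=100)
        minus = [r for r in regions if r.strand == "-"]
        assert minus
        gene = extract_best_gene(contig, minus[0], protein)
        assert gene.protein == protein
        assert gene.strand == "-"


class TestOnSimulatedGenome:
    def test_codon_coordinate_roundtrip(self, small_bundle, small_config, small_genomes):
        """Every predicted residue's codon translates back to that residue."""
        from cugscribe.cug_classifier import predict_decoding

        bundle, _ = small_bundle
        contigs, _ = small_genomes["standard"]
        verdict = predict_decoding(contigs, bundle, flank=small_config.flank)
        checked = 0
        for fp in verdict.families:
            gene = fp.gene
            if gene is None:
                continue
            contig = contigs[gene.contig_id]
            for i, aa in enumerate(gene.protein):
                s = gene.codon_starts[i]
                codon = contig[s : s + 3]
                if gene.strand == "-":
                    codon = reverse_complement(codon)
                assert codon == gene.codons[i]
                assert translate(codon, STANDARD) == aa
                checked += 1
        assert checked > 100

    def test_planted_genes_recovered_exactly_at_full_identity(self, small_bundle, small_config):
        from dataclasses import replace

        bundle, _ = small_bundle
        cfg = replace(small_config, query_identity=1.0, indel_rate=0.0)
        contigs, truth = simulate_query_genome(bundle, "standard", cfg, seed=5)
        by_family = {}
        for g in truth.genes:
            by_family.setdefault(g.family_id, []).append(g)
        from cugscribe.cug_classifier import predict_decoding

        verdict = predict_decoding(contigs, bundle, flank=cfg.flank)
        found = 0
        for fp in verdict.families:
            if fp.gene is None:
                continue
            planted = [g.protein_cug_as_leu for g in by_family[fp.family_id]]
            assert fp.gene.protein in planted
            found += 1
        assert found == len(by_family)
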