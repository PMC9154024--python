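import math

import pytest

from splicigen.config import PipelineConfig
from splicigen.io import Annotation, Gene
from splicigen.peptides import translate_cds
from splicigen.simulate import (
    JUNCTION_CLASSES,
    derive_truth_junctions,
    evaluate_predictions,
    make_fixture_genome,
    simulate_reads,
    simulate_variant_annotation,
)
from splicigen.splice_graph import extract_junction_support
from splicigen.transcripts import classify_junction


@pytest.fixture(scope="module")
def small_fixture():
    cfg = PipelineConfig()
    genome, annotation = make_fixture_genome(n_genes=3, n_chroms=2, seed=11, cfg=cfg)
    return genome, annotation, cfg


class TestFixtureGenome:
    def test_deterministic_per_seed(self, tmp_path):
        d1, d2, d3 = tmp_path / "a", tmp_path / "b", tmp_path / "c"
        make_fixture_genome(2, 1, seed=5, out_dir=d1)
        make_fixture_genome(2, 1, seed=5, out_dir=d2)
        make_fixture_genome(2, 1, seed=6, out_dir=d3)
        assert (d1 / "genome.fa").read_bytes() == (d2 / "genome.fa").read_bytes()
        assert (d1 / "annotation.gtf").read_bytes() == (d2 / "annotation.gtf").read_bytes()
        assert (d1 / "genome.fa").read_bytes() != (d3 / "genome.fa").read_bytes()

    def test_single_gene_has_min_isoforms(self):
        _, ann = make_fixture_genome(n_genes=1, seed=0)
        assert len(ann.genes) == 1
        (gene,) = ann.genes.values()
        assert len(gene.transcripts) >= PipelineConfig().sim_min_isoforms

    def test_every_isoform_cds_is_stop_free(self, small_fixture):
        genome, annotation, _ = small_fixture
        for t in annotation.transcripts():
            cds = t.cds_sequence(genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = translate_cds(cds, 0)
            assert len(protein) == len(cds) // 3  # no internal stop
            # and the codon after the CDS is a stop
            full = t.spliced_sequence(genome)
            assert full[len(cds) : len(cds) + 3] in {"TAA", "TAG", "TGA"}

    def test_exon_counts_in_range(self, small_fixture):
        _, annotation, _ = small_fixture
        for g in annotation.genes.values():
            full = max(g.transcripts.values(), key=lambda t: len(t.exons))
            assert 8 <= len(full.exons) <= 12

    def test_invalid_n_genes(self):
        with pytest.raises(ValueError):
            make_fixture_genome(0)


class TestInjection:
    @pytest.mark.parametrize("junction_class", JUNCTION_CLASSES)
    def test_injected_class_round_trip(self, small_fixture, junction_class):
        genome, annotation, cfg = small_fixture
        truth = simulate_variant_annotation(annotation, junction_class, cfg, seed=2)
        assert truth.junctions
        for j in truth.junctions:
            assert classify_junction(j.key, annotation) == junction_class
            assert not annotation.is_annotated_intron(*j.key)
            # the junction is present in every affected tumor transcript
            tg = truth.tumor_annotation.genes[j.gene_id]
            for t in tg.transcripts.values():
                assert (j.intron_start, j.intron_end) in t.introns

    def test_ineligible_gene_never_selected(self, small_fixture):
        genome, annotation, cfg = small_fixture
        pruned = []
        for i, g in enumerate(annotation.genes.values()):
            keep = dict(sorted(g.transcripts.items())[: 7 if i == 0 else None])
            ng = Gene(g.gene_id, g.chrom, g.strand, g.name, g.biotype,
                      transcripts=keep, start=g.start, end=g.end)
            pruned.append(ng)
        ineligible_id = pruned[0].gene_id
        ann2 = Annotation(pruned)
        truth = simulate_variant_annotation(ann2, "exon_skipping", cfg, seed=3)
        assert ineligible_id not in {j.gene_id for j in truth.junctions}

    def test_genes_per_chromosome_cap(self):
        cfg = PipelineConfig()
        _, ann = make_fixture_genome(n_genes=12, n_chroms=1, seed=4, cfg=cfg)
        truth = simulate_variant_annotation(ann, "exon_skipping", cfg, seed=4)
        assert len(truth.junctions) == cfg.sim_genes_per_chrom

    def test_no_eligible_gene_errors(self, small_fixture):
        _, annotation, cfg = small_fixture
        strict = cfg.replace(sim_min_isoforms=10_000)
        with pytest.raises(ValueError, match="eligible"):
            simulate_variant_annotation(annotation, "exon_skipping", strict, seed=0)

    def test_normal_set_is_reference_of_retained_transcripts(self, small_fixture):
        genome, annotation, cfg = small_fixture
        truth = simulate_variant_annotation(annotation, "partial_exon_loss", cfg, seed=9)
        for j in truth.junctions:
            tumor_ids = set(truth.tumor_annotation.genes[j.gene_id].transcripts)
            normal_ids = set(truth.normal_annotation.genes[j.gene_id].transcripts)
            assert {tid + "_var" for tid in normal_ids} == tumor_ids
            for tid in normal_ids:  # normal transcripts are unmodified reference
                ref = annotation.genes[j.gene_id].transcripts[tid]
                assert truth.normal_annotation.genes[j.gene_id].transcripts[tid].exons == ref.exons


class TestReadSimulation:
    def test_pair_count_and_validity(self, small_fixture):
        genome, annotation, _ = small_fixture
        cfg = PipelineConfig(sim_reads_per_transcript=40)
        gene = next(iter(annotation.genes.values()))
        sub = Annotation([gene])
        n_tx = len(gene.transcripts)
        reads = simulate_reads(sub, genome, cfg, seed=0)
        assert len(reads) == 2 * 40 * n_tx  # pairs
        for r in reads[:200]:
            r.validate()
            assert r.nh == 1 and r.is_paired

    def test_noiseless_reads_match_genome(self, small_fixture):
        genome, annotation, _ = small_fixture
        cfg = PipelineConfig(sim_reads_per_transcript=10, sim_error_rate=0.0)
        gene = next(iter(annotation.genes.values()))
        reads = simulate_reads(Annotation([gene]), genome, cfg, seed=1)
        for r in reads:
            expect = []
            ref = r.pos
            for op, n in r.cigar:
                if op == "M":
                    expect.append(genome.fetch(r.chrom, ref, ref + n))
                    ref += n
                elif op == "N":
                    ref += n
            assert "".join(expect) == r.seq

    def test_deterministic_per_seed(self, small_fixture):
        genome, annotation, _ = small_fixture
        cfg = PipelineConfig(sim_reads_per_transcript=15)
        gene = next(iter(annotation.genes.values()))
        a = simulate_reads(Annotation([gene]), genome, cfg, seed=7)
        b = simulate_reads(Annotation([gene]), genome, cfg, seed=7)
        assert [(r.name, r.seq, r.pos, r.cigar) for r in a] == [
            (r.name, r.seq, r.pos, r.cigar) for r in b
        ]

    def test_short_transcript_skipped(self, small_fixture):
        genome, annotation, _ = small_fixture
        cfg = PipelineConfig(sim_reads_per_transcript=5, sim_read_len=10_000)
        gene = next(iter(annotation.genes.values()))
        assert simulate_reads(Annotation([gene]), genome, cfg, seed=0) == []

    def test_injected_junction_gets_coverage_share(self, small_fixture):
        genome, annotation, cfg0 = small_fixture
        cfg = PipelineConfig(sim_reads_per_transcript=200)
        truth = simulate_variant_annotation(annotation, "exon_skipping", cfg, seed=5)
        reads = simulate_reads(truth.tumor_annotation, genome, cfg, seed=6)
        table = extract_junction_support(reads, cfg)
        for j in truth.junctions:
            # an internal junction of a ~300 bp transcript is crossed by a
            # large fraction of its 100 bp reads; demand a loose floor
            assert table.unique_count(j.key) >= 40


class TestTruthAndScoring:
    def test_truth_filter_boundaries(self, cfg):
        tumor = {("c", 0, 10): (11, 11), ("c", 20, 30): (10, 10), ("c", 40, 50): (30, 30)}
        normal = {("c", 40, 50): (25, 25), ("c", 60, 70): (11, 11)}
        truth = derive_truth_junctions(tumor, normal, cfg)
        assert truth == {("c", 0, 10)}  # 11 > 10 in; 10 filtered; shared excluded

    def test_normal_below_filter_does_not_mask(self, cfg):
        tumor = {("c", 0, 10): (15, 15)}
        normal = {("c", 0, 10): (10, 10)}  # filtered out of the normal set
        assert derive_truth_junctions(tumor, normal, cfg) == {("c", 0, 10)}

    def test_evaluation_arithmetic(self):
        truth = {(f"c", i, i + 10): "exon_skipping" for i in range(0, 50, 10)}
        pred = set(list(truth)[:4]) | {("c", 900, 910)}
        rep = evaluate_predictions(pred, truth)
        assert rep.overall.tp == 4 and rep.overall.fp == 1 and rep.overall.fn == 1
        assert rep.overall.sensitivity == pytest.approx(0.8)
        assert rep.overall.precision == pytest.approx(0.8)
        # the FP is attributed to the nearest truth junction's class
        assert rep.per_class["exon_skipping"].fp == 1

    def test_evaluation_identity_and_degenerate(self):
        truth = {("c", 0, 10): "other"}
        perfect = evaluate_predictions(set(truth), truth)
        assert perfect.overall.sensitivity == 1.0 and perfect.overall.precision == 1.0
        empty = evaluate_predictions(set(), truth)
        assert empty.overall.sensitivity == 0.0
        assert math.isnan(empty.overall.precision) and empty.overall.fp == 0
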