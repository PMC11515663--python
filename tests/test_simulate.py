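"""Synthetic data generation and the mapping / DE scorers."""

import numpy as np
import pytest

from samlite.alphabet import AA_LETTERS, reverse_complement, translate_frame
from samlite.io_formats import read_fastq
from samlite.simulate import (
    SimConfig,
    SimTruth,
    generate_proteome,
    load_truth,
    reverse_translate,
    score_de,
    score_mappings,
    simulate_reads,
    write_ortholog_map,
)


def small_config(**overrides):
    defaults = dict(
        n_genes=5, isoforms_per_gene=1, n_fragments=50, replicates=1,
        error_rate=0.0, mean_protein_length=150, seed=1,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="de_fraction"):
            SimConfig(de_fraction=1.5)
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(read_length=300, fragment_length_mean=250)
        with pytest.raises(ValueError, match="positive"):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError, match="fold_changes"):
            SimConfig(fold_changes=(0.5,))


class TestGenerateProteome:
    def test_deterministic_and_sized(self):
        cfg = small_config(n_genes=10)
        p1 = generate_proteome(cfg)
        p2 = generate_proteome(cfg)
        assert p1.proteins == p2.proteins
        assert len(p1.proteins) == 10
        assert all(set(seq) <= set(AA_LETTERS) for _, seq in p1.proteins)

    def test_different_seeds_differ(self):
        p1 = generate_proteome(small_config(seed=1))
        p2 = generate_proteome(small_config(seed=2))
        assert p1.proteins != p2.proteins

    def test_isoform_counts_and_identity(self):
        cfg = small_config(n_genes=5, isoforms_per_gene=2)
        prot = generate_proteome(cfg)
        assert len(prot.proteins) == 10
        assert prot.table["gene_id"].nunique() == 5
        seqs = dict(prot.proteins)
        for gene, products in prot.gene_products.items():
            a, b = sorted(products)
            s1, s2 = seqs[a], seqs[b]
            identity = sum(x == y for x, y in zip(s1, s2)) / len(s1)
            assert identity >= 0.5  # isoforms must multi-map


class TestReverseTranslate:
    def test_met_codon(self):
        cds = reverse_translate("M", 0)
        assert cds[:3] == "ATG" and len(cds) == 6
        assert translate_frame(cds, 0).sequence.endswith("*")

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_through_translation(self, seed):
        rng = np.random.default_rng(seed)
        protein = "".join(rng.choice(list(AA_LETTERS), size=60))
        cds = reverse_translate(protein, seed)
        assert len(cds) == 3 * len(protein) + 3
        assert translate_frame(cds, 0).sequence == protein + "*"

    def test_synonymous_codons_vary_with_seed(self):
        variants = {reverse_translate("LLLLLLLL", s) for s in range(10)}
        assert len(variants) > 1
        assert all(
            translate_frame(v, 0).sequence == "LLLLLLLL*" for v in variants
        )


class TestSimulateReads:
    def test_error_free_reads_are_cds_substrings(self, tmp_path):
        cfg = small_config(n_genes=1, n_fragments=10)
        prot = generate_proteome(cfg)
        result = simulate_reads(cfg, prot, tmp_path, compress=False)
        cds = reverse_translate(prot.proteins[0][1], np.random.default_rng(cfg.seed))
        # regenerate the CDS the simulator built (same rng stream position)
        for sample, p1, p2 in result.samples:
            for rec in read_fastq(p1):
                assert rec.sequence in cds
            for rec in read_fastq(p2):
                assert reverse_complement(rec.sequence) in cds

    def test_same_seed_identical_bytes(self, tmp_path):
        cfg = small_config(n_genes=3, n_fragments=30, error_rate=0.01)
        r1 = simulate_reads(cfg, generate_proteome(cfg), tmp_path / "a")
        r2 = simulate_reads(cfg, generate_proteome(cfg), tmp_path / "b")
        for (_, a1, a2), (_, b1, b2) in zip(r1.samples, r2.samples):
            assert a1.read_bytes() == b1.read_bytes()
            assert a2.read_bytes() == b2.read_bytes()

    def test_truth_covers_every_fragment(self, tmp_path):
        cfg = small_config(n_genes=4, n_fragments=40, replicates=2)
        result = simulate_reads(cfg, generate_proteome(cfg), tmp_path, compress=False)
        n_reads = sum(
            sum(1 for _ in read_fastq(p1)) for _, p1, _ in result.samples
        )
        assert n_reads == len(result.truth.read_source)
        assert set(result.truth.gene_products) == {f"g{i:04d}" for i in range(4)}

    def test_fold_change_reflected_in_fragment_counts(self, tmp_path):
        """DE genes' expected condition-2/condition-1 fragment ratio tracks
        the simulated fold-change (Poisson sampling, so compare aggregates)."""
        cfg = SimConfig(
            n_genes=12, isoforms_per_gene=1, n_fragments=6000, replicates=2,
            de_fraction=0.5, fold_changes=(4.0,), error_rate=0.0, seed=3,
            mean_protein_length=150,
        )
        result = simulate_reads(cfg, generate_proteome(cfg), tmp_path)
        counts = {"cond1": {}, "cond2": {}}
        for rid, (sample, gene, _, _) in result.truth.read_source.items():
            cond = sample.split("_")[0]
            counts[cond][gene] = counts[cond].get(gene, 0) + 1
        for gene, fc in result.truth.gene_fold_change.items():
            c1 = counts["cond1"].get(gene, 0)
            c2 = counts["cond2"].get(gene, 0)
            if min(c1, c2) < 50:
                continue  # too few fragments for a stable ratio
            ratio = c2 / c1
            assert ratio == pytest.approx(fc, rel=0.35)

    def test_truth_files_roundtrip(self, tmp_path):
        cfg = small_config(n_genes=4, n_fragments=30, de_fraction=0.5)
        result = simulate_reads(cfg, generate_proteome(cfg), tmp_path)
        truth = load_truth(
            tmp_path / "truth.tsv",
            tmp_path / "gene_to_protein.tsv",
            tmp_path / "de_genes.tsv",
        )
        assert truth.read_source == result.truth.read_source
        assert truth.gene_products == result.truth.gene_products
        assert truth.gene_fold_change == pytest.approx(result.truth.gene_fold_change)


def _toy_truth():
    return SimTruth(
        read_source={
            "r1": ("s", "g1", "t1", "P1"),
            "r2": ("s", "g1", "t1", "P1"),
            "r3": ("s", "g2", "t2", "P2"),
        },
        gene_products={"g1": {"P1"}, "g2": {"P2"}},
        gene_fold_change={"g1": 4.0, "g2": 0.25},
    )


class TestScoreMappings:
    def test_correct_incorrect_unmapped(self):
        truth = _toy_truth()
        score = score_mappings(
            [("r1", ["P1", "P7"]), ("r3", ["P7"])], truth,
        )
        # r1 intersects M_g1 -> correct; r3 misses M_g2 -> incorrect;
        # r2 has no record -> unmapped, in neither tally
        assert (score.correct, score.incorrect, score.unmapped) == (1, 1, 1)
        assert score.total == 3

    def test_ortholog_groups_rescue_cross_references(self):
        truth = _toy_truth()
        orthologs = {"P1": "OG1", "P7": "OG1", "P2": "OG2"}
        score = score_mappings([("r1", ["P7"])], truth, orthologs=orthologs)
        assert score.correct == 1 and score.incorrect == 0

    def test_unknown_read_rejected(self):
        with pytest.raises(ValueError, match="unknown read"):
            score_mappings([("zz", ["P1"])], _toy_truth())

    def test_universe_restriction(self):
        truth = _toy_truth()
        score = score_mappings([("r1", ["P1"])], truth, read_ids=["r1", "r2"])
        assert score.total == 2 and score.unmapped == 1


class TestScoreDE:
    def test_perfect_predictions(self):
        truth = _toy_truth()
        score = score_de({"P1"}, {"P2"}, truth)
        assert score.precision == 1.0 and score.recall == 1.0

    def test_empty_predictions_degenerate(self):
        score = score_de(set(), set(), _toy_truth())
        assert score.precision == 0.0 and score.recall == 0.0
        assert score.degenerate

    def test_partial_recall(self):
        score = score_de({"P1"}, set(), _toy_truth())
        assert score.precision == 1.0 and score.recall == 0.5

    def test_wrong_direction_is_a_false_call(self):
        score = score_de(set(), {"P1"}, _toy_truth())  # g1 is up, predicted down
        assert score.precision == 0.0 and score.recall == 0.0

    def test_ortholog_aware_prediction(self):
        truth = _toy_truth()
        orthologs = {"P1": "OG1", "P9": "OG1", "P2": "OG2"}
        score = score_de({"P9"}, set(), truth, orthologs=orthologs)
        assert score.precision == 1.0 and score.recall == 0.5


def test_ortholog_map_groups_gene_products(tmp_path):
    cfg = small_config(n_genes=3, isoforms_per_gene=2)
    prot = generate_proteome(cfg)
    mapping = write_ortholog_map(prot, tmp_path / "orth.tsv")
    for gene, products in prot.gene_products.items():
        assert {mapping[p] for p in products} == {f"OG_{gene}"}
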