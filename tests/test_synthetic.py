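import hashlib
from collections import Counter

import numpy as np
import pytest

from tillermir.expression import call_de, call_tissue_specific
from tillermir.io import TillermirError, parse_annotation_map, parse_expression_table, parse_fasta, read_design
from tillermir.synthetic import (
    GeneratorConfig,
    PlantedDe,
    PlantedTs,
    SiteSpec,
    SyntheticTruth,
    generate_expression,
    generate_full_dataset,
    generate_sequences,
    plant_target_sites,
    sample_mirna_lengths,
)
from tillermir.targetscan import filter_hits, scan_targets


class TestSequences:
    def test_counts_and_length_window(self):
        transcripts, mirnas = generate_sequences(5, n_mirnas=100, seed=3)
        assert len(transcripts) == 5 and len(mirnas) == 100
        assert all(18 <= m.length <= 30 for m in mirnas)

    def test_determinism(self):
        a = generate_sequences(10, n_mirnas=10, seed=8)
        b = generate_sequences(10, n_mirnas=10, seed=8)
        assert [(t.id, t.seq) for t in a[0]] == [(t.id, t.seq) for t in b[0]]
        assert [(m.id, m.seq, m.origin) for m in a[1]] == [
            (m.id, m.seq, m.origin) for m in b[1]
        ]

    def test_length_mixture_histogram(self):
        rng = np.random.default_rng(0)
        lengths = sample_mirna_lengths(10000, rng)
        freq = Counter(int(x) for x in lengths)
        assert abs(freq[21] / 10000 - 0.43) < 0.03
        assert abs(freq[24] / 10000 - 0.37) < 0.03
        other = sum(v for k, v in freq.items() if k not in (21, 24))
        assert abs(other / 10000 - 0.20) < 0.03

    def test_invalid_length_spec_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(TillermirError):
            sample_mirna_lengths(10, rng, {35: 1.0})


class TestPlanting:
    @staticmethod
    def _setup(seed=0):
        transcripts, mirnas = generate_sequences(
            2, transcript_len=(200, 200), n_mirnas=1,
            mirna_lengths={21: 1.0}, seed=seed,
        )
        return transcripts, mirnas

    @pytest.mark.parametrize(
        "counts, budget",
        [((0, 0, 0, 0), 0.0), ((1, 0, 0, 0), 2.0), ((0, 3, 0, 2), 4.0)],
    )
    def test_budget_reported_by_scanner(self, counts, budget):
        transcripts, mirnas = self._setup()
        sm, nm, sw, nw = counts
        spec = SiteSpec(mirnas[0].id, transcripts[0].id, 50, sm, nm, sw, nw)
        assert spec.budget() == budget
        planted_tx, sites = plant_target_sites(transcripts, mirnas, [spec], seed=4)
        hits = scan_targets(mirnas[0], planted_tx[0], max_report_score=budget)
        at_site = [h for h in hits if h.site_start == 50]
        assert len(at_site) == 1
        assert at_site[0].score == budget
        retained = filter_hits(hits)
        if budget < 4.0:
            assert any(h.site_start == 50 for h in retained)
        else:
            assert not any(h.site_start == 50 for h in retained)

    def test_overlapping_sites_rejected(self):
        transcripts, mirnas = self._setup()
        specs = [SiteSpec(mirnas[0].id, transcripts[0].id, 50),
                 SiteSpec(mirnas[0].id, transcripts[0].id, 60)]
        with pytest.raises(TillermirError, match="verlapping"):
            plant_target_sites(transcripts, mirnas, specs, seed=0)

    def test_site_must_fit(self):
        transcripts, mirnas = self._setup()
        spec = SiteSpec(mirnas[0].id, transcripts[0].id, 195)
        with pytest.raises(TillermirError, match="fit"):
            plant_target_sites(transcripts, mirnas, [spec], seed=0)


class TestExpressionGeneration:
    def test_zero_noise_gives_exact_tissue_means(self):
        m, _ = generate_expression(["g0", "g1"], noise_sd=0.0, seed=1)
        for t in ("TP", "ST", "YS"):
            vals = m.tissue_values(t)
            assert (vals.nunique(axis=1) == 1).all()

    def test_double_ts_spec_rejected(self):
        with pytest.raises(TillermirError, match="g0"):
            generate_expression(
                ["g0"], planted_ts=[PlantedTs("g0", "TP", 3), PlantedTs("g0", "ST", 3)]
            )

    def test_planted_ts_gene_recovered(self):
        m, _ = generate_expression(
            [f"g{i}" for i in range(50)],
            planted_ts=[PlantedTs("g0", "YS", 4.0)],
            noise_sd=0.05,
            seed=2,
        )
        calls = call_tissue_specific(m)
        assert ("g0", "YS") in {(c.feature_id, c.tissue) for c in calls}

    def test_null_features_rarely_flagged_de(self):
        # type-I control at gene defaults (|log2FC|>=1 AND FDR<=0.01)
        false_flags = total = 0
        for seed in range(200):
            m, _ = generate_expression(
                [f"g{i}" for i in range(50)],
                planted_de=[PlantedDe(f"g{i}", "TP", "YS", 0.0) for i in range(50)],
                noise_sd=0.2,
                seed=seed,
            )
            recs = call_de(m, "TP", "YS")
            false_flags += sum(r.is_de for r in recs)
            total += len(recs)
        assert false_flags / total < 0.05


class TestFullDataset:
    def test_files_parse_back(self, dataset):
        ds, outdir = dataset
        transcripts = parse_fasta(outdir / "transcripts.fasta")
        mirnas = parse_fasta(outdir / "mirnas.fasta", kind="mirna")
        assert len(transcripts) == len(ds.transcripts)
        assert len(mirnas) == len(ds.mirnas)
        gm = parse_expression_table(
            outdir / "gene_fpkm.tsv", read_design(outdir / "gene_design.tsv"), "FPKM"
        )
        assert gm.feature_ids == ds.gene_matrix.feature_ids
        amap = parse_annotation_map(outdir / "annotations.tsv")
        assert amap.terms == ds.annotations.terms

    def test_truth_manifest_roundtrip(self, dataset, tmp_path):
        ds, _ = dataset
        p = tmp_path / "truth.tsv"
        ds.truth.save(p)
        back = SyntheticTruth.load(p)
        assert back.seed == ds.truth.seed
        assert back.ts_genes == ds.truth.ts_genes
        assert back.de_genes == ds.truth.de_genes
        assert back.de_mirnas == ds.truth.de_mirnas
        assert back.target_sites == ds.truth.target_sites
        assert back.negative_pairs == ds.truth.negative_pairs
        assert back.decoys == ds.truth.decoys

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = GeneratorConfig(n_genes=120, n_mirnas=20, n_trend_genes_per_shape=2)
        hashes = []
        for sub in ("a", "b"):
            outdir = tmp_path / sub
            generate_full_dataset(cfg, seed=77, outdir=outdir)
            hashes.append({
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(outdir.iterdir())
            })
        assert hashes[0] == hashes[1]

    def test_config_contradictions_rejected(self):
        with pytest.raises(TillermirError, match="n_genes"):
            generate_full_dataset(GeneratorConfig(n_genes=10), seed=0)
        with pytest.raises(TillermirError, match="budget"):
            generate_full_dataset(
                GeneratorConfig(pair_budgets=(0.0,) * 7 + (5.0,)), seed=0
            )

    def test_decoys_each_violate_one_condition(self, dataset):
        ds, _ = dataset
        truth = ds.truth
        kinds = {d.violated for d in truth.decoys}
        assert kinds == {"direction", "gene_not_de", "mirna_fc", "site_score"}
        de_mirna = {d.feature_id: d for d in truth.de_mirnas}
        de_gene = {d.feature_id: d for d in truth.de_genes}
        sites = {(s.mirna_id, s.transcript_id): s for s in truth.target_sites}
        for d in truth.decoys:
            m_lfc = de_mirna[d.mirna_id].log2fc
            g_lfc = de_gene[d.gene_id].log2fc
            site = sites[(d.mirna_id, d.gene_id)]
            checks = {
                "mirna_fc": abs(m_lfc) > 2,
                "gene_not_de": abs(g_lfc) >= 1,
                "direction": m_lfc * g_lfc < 0,
                "site_score": site.budget < 4,
            }
            assert not checks.pop(d.violated)
            assert all(checks.values()), f"decoy {d} violates extra conditions"
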