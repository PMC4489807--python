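import numpy as np
import pytest

from dellaseq.io import GenomeAnnotation
from dellaseq.merging import MergeParams, cluster_summits, define_binding_sites
from dellaseq.motifs import ScanParams, count_hit_sequences
from dellaseq.simulate import (
    CapacityError, GroundTruth, SimulationConfig, default_motif_library,
    generate_genome, generate_qpcr_dataset, generate_summit_replicates,
    generate_true_sites, plant_motif_instances,
    GENE_LENGTH, MIN_GENE_GAP,
)


CFG = SimulationConfig(seed=101)


class TestGenome:
    def test_requested_shape(self):
        genome, ann = generate_genome(CFG)
        assert set(genome) == {"chr1", "chr2"}
        assert all(len(s) == CFG.chrom_len for s in genome.values())
        assert len(ann.genes) == CFG.n_genes

    def test_genes_disjoint_with_min_gap(self):
        _, ann = generate_genome(CFG)
        by_chrom = {}
        for g in ann.genes.values():
            by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 >= MIN_GENE_GAP
                assert e1 - s1 == GENE_LENGTH

    def test_fixed_architecture(self):
        _, ann = generate_genome(CFG)
        g = next(iter(ann.genes.values()))
        assert g.exons == [(g.tx_start, g.tx_start + 450), (g.tx_start + 650, g.tx_end)]
        assert (g.cds_start, g.cds_end) == (g.tx_start + 100, g.tx_end - 100)

    def test_same_seed_reproducible(self):
        g1, a1 = generate_genome(CFG)
        g2, a2 = generate_genome(SimulationConfig(seed=101))
        assert g1 == g2
        assert sorted(a1.genes) == sorted(a2.genes)

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            generate_genome(SimulationConfig(seed=0, n_genes=500, chrom_len=50_000))


class TestTrueSites:
    def test_uniform_sites_well_separated(self):
        _, ann = generate_genome(CFG)
        sites = generate_true_sites(ann, CFG)
        assert len(sites) == CFG.n_true_sites
        min_sep = 2 * CFG.merge_distance + CFG.site_width
        by_chrom = {}
        for c, p in sites:
            by_chrom.setdefault(c, []).append(p)
        for ps in by_chrom.values():
            ps.sort()
            assert all(b - a >= min_sep for a, b in zip(ps, ps[1:]))

    def test_promoter_sites_land_upstream(self):
        cfg = SimulationConfig(seed=9, true_site_placement="promoter", n_true_sites=30)
        _, ann = generate_genome(cfg)
        sites = generate_true_sites(ann, cfg)
        genes = list(ann.genes.values())
        for chrom, pos in sites:
            hits = [
                g for g in genes
                if g.chrom == chrom and (
                    (g.strand == "+" and g.tss - 2500 <= pos < g.tss)
                    or (g.strand == "-" and g.tss < pos <= g.tss + 2500)
                )
            ]
            assert hits, f"site {chrom}:{pos} not in any promoter window"

    def test_promoter_capacity_error(self):
        cfg = SimulationConfig(
            seed=9, true_site_placement="promoter", n_genes=5, n_true_sites=30
        )
        _, ann = generate_genome(cfg)
        with pytest.raises(CapacityError):
            generate_true_sites(ann, cfg)


class TestSummits:
    def setup_method(self):
        _, self.ann = generate_genome(CFG)
        self.truth = generate_true_sites(self.ann, CFG)
        self.reps = generate_summit_replicates(self.truth, CFG, self.ann.chrom_lengths)

    def test_replicate_composition(self):
        assert len(self.reps) == CFG.n_replicates
        for rep in self.reps:
            assert len(rep) == CFG.n_true_sites + CFG.false_summits_per_replicate

    def test_decoys_far_from_truth(self):
        for rep in self.reps:
            decoys = rep[CFG.n_true_sites:]
            for d in decoys:
                assert all(
                    c != d.chrom or abs(p - d.pos) >= 2 * CFG.merge_distance
                    for c, p in self.truth
                )

    def test_merging_recovers_exactly_the_true_sites(self):
        params = MergeParams(CFG.merge_distance, None, CFG.site_width)
        clusters = cluster_summits(self.reps, params, self.ann.chrom_lengths)
        sites = define_binding_sites(clusters, params, self.ann.chrom_lengths)
        assert len(sites) == CFG.n_true_sites
        recovered = {(s.chrom, s.mean_summit) for s in sites}
        for chrom, pos in self.truth:
            assert any(
                c == chrom and abs(m - pos) <= 3 * CFG.summit_jitter_sd
                for c, m in recovered
            )


class TestMotifPlanting:
    def test_flags_match_scanner_hits(self):
        cfg = SimulationConfig(
            seed=13, planted_motif_probs={"SYNM001": 0.6, "SYNM002": 0.4}
        )
        genome, ann = generate_genome(cfg)
        sites = generate_true_sites(ann, cfg)
        pwms = default_motif_library()
        genome, flags = plant_motif_instances(genome, sites, pwms, cfg)
        params = ScanParams()
        half = cfg.site_width // 2
        for pwm in pwms[:2]:
            for chrom, pos in sites:
                window = genome[chrom][pos - half: pos + half]
                hit = count_hit_sequences([window], pwm, params) == 1
                if flags[f"{chrom}:{pos}"][pwm.id]:
                    assert hit, f"planted {pwm.id} not detected at {chrom}:{pos}"

    def test_unlisted_motifs_never_planted(self):
        cfg = SimulationConfig(seed=13, planted_motif_probs={"SYNM001": 1.0})
        genome, ann = generate_genome(cfg)
        sites = generate_true_sites(ann, cfg)
        _, flags = plant_motif_instances(genome, sites, default_motif_library(), cfg)
        for per_site in flags.values():
            assert per_site["SYNM001"] is True
            assert not any(v for k, v in per_site.items() if k != "SYNM001")

    def test_planting_rate_tracks_probability(self):
        cfg = SimulationConfig(
            seed=29, n_true_sites=60, n_genes=100, planted_motif_probs={"SYNM003": 0.5}
        )
        genome, ann = generate_genome(cfg)
        sites = generate_true_sites(ann, cfg)
        _, flags = plant_motif_instances(genome, sites, default_motif_library(), cfg)
        rate = np.mean([f["SYNM003"] for f in flags.values()])
        # binomial(60, 0.5): 3 SD ~ 0.19
        assert abs(rate - 0.5) < 0.2


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_replicates": 1},
            {"background_freqs": (0.5, 0.5, 0.25, 0.25)},
            {"planted_motif_probs": {"M": 1.5}},
            {"class_counts": {"arr1_independent": 300}, "n_genes": 100},
            {"qpcr_efficiency": 0.9},
            {"n_genes": 0},
        ],
    )
    def test_rejects_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, **kwargs)

    def test_stage_streams_independent(self):
        a = SimulationConfig(seed=77)
        r1 = a.rng("genome").integers(0, 1 << 30, 4)
        r2 = a.rng("sites").integers(0, 1 << 30, 4)
        assert not np.array_equal(r1, r2)
        again = SimulationConfig(seed=77).rng("genome").integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(r1, again)


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path):
        truth = GroundTruth(
            true_site_positions=[("chr1", 100), ("chr2", 5000)],
            planted_motif_flags={"chr1:100": {"SYNM001": True}},
            gene_classes={"SYNG0001": "null"},
            true_qpcr_enrichments={"SCL3pro": 4.0},
        )
        p = tmp_path / "truth.json"
        truth.to_json(p)
        assert GroundTruth.from_json(p) == truth


class TestQpcrGenerator:
    def test_row_layout(self):
        cfg = SimulationConfig(seed=19)
        ct = generate_qpcr_dataset({"SCL3pro": 4.0}, cfg, conditions=("mock", "dex"))
        # (control + 1 target) x 2 fractions x 2 conditions x 3 technical
        assert len(ct) == 2 * 2 * 2 * 3
        assert set(ct["amplicon"]) == {"HSF", "SCL3pro"}

    def test_rejects_nonpositive_truth(self):
        with pytest.raises(ValueError, match="positive"):
            generate_qpcr_dataset({"X": 0.0}, SimulationConfig(seed=19))
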