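import dataclasses

import numpy as np
import pytest
from scipy import stats

from mirtronkit.io_formats import revcomp
from mirtronkit.synthetic_data import (
    SimConfig,
    build_truth,
    default_manifest,
    simulate_expression,
    simulate_reads,
)
from tests.conftest import noiseless


class TestBuildTruth:
    def test_no_planted_loci_leaves_only_bulk(self):
        cfg = SimConfig(seed=1, n_bulk_genes=5, class_counts={})
        truth = build_truth(cfg)
        assert truth.planted == []
        assert len(truth.bulk_introns) == len(truth.introns)

    def test_class_counts_respected(self, small_truth, small_config):
        got = {}
        for p in small_truth.planted:
            got[p.subtype] = got.get(p.subtype, 0) + 1
        assert got == small_config.class_counts

    def test_all_introns_canonical_gt_ag(self, small_truth):
        for intr in small_truth.introns:
            assert intr.donor_dinucleotide(small_truth.genome) == "GT"
            assert intr.acceptor_dinucleotide(small_truth.genome) == "AG"

    def test_hairpins_lie_within_host_introns(self, small_truth):
        for p in small_truth.mirtrons():
            h5, h3 = p.hairpin_in_intron
            assert 0 <= h5 < h3 <= p.intron.length
            assert h3 - h5 == p.hairpin_len

    def test_subtype_end_geometry(self, small_truth):
        for p in small_truth.mirtrons():
            h5, h3 = p.hairpin_in_intron
            L = p.intron.length
            if p.subtype == "conventional":
                assert (h5, h3) == (0, L)
            elif p.subtype == "5p_tailed":
                assert h3 == L and h5 >= 10
            elif p.subtype == "3p_tailed":
                assert h5 == 0 and h3 <= L - 10
            else:  # two_tailed
                assert h5 >= 5 and h3 <= L - 5

    def test_5p_tail_arithmetic(self):
        cfg = SimConfig(
            seed=4, n_bulk_genes=2,
            class_counts={"5p_tailed": 1},
            tail5_length_range=(150, 150),
        )
        truth = build_truth(cfg)
        (p,) = truth.mirtrons()
        h5, h3 = p.hairpin_in_intron
        assert h5 == 150
        assert h3 == p.intron.length

    def test_arms_reverse_complementary_up_to_mismatch_rate(self, small_truth, small_config):
        for p in small_truth.mirtrons():
            hp = p.sense_hairpin_seq(small_truth.genome)
            arm = p.arm_len
            fivep, threep = hp[:arm], hp[-arm:]
            paired = revcomp(fivep[: arm - 2])
            matches = sum(a == b for a, b in zip(threep, paired))
            assert matches >= (arm - 2) * (1 - small_config.stem_mismatch_rate - 0.05)

    def test_deterministic_under_seed(self, small_config):
        t1, t2 = build_truth(small_config), build_truth(small_config)
        assert t1.genome.sequence("chrS") == t2.genome.sequence("chrS")
        assert [p.hairpin_genomic for p in t1.planted] == [
            p.hairpin_genomic for p in t2.planted
        ]


class TestSimulateReads:
    def test_empty_manifest_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate_reads(small_truth, [])

    def test_depth_conservation(self, small_truth, small_manifest, small_reads):
        batches, _ = small_reads
        for m in small_manifest:
            assert batches[m.library_id].total_reads == small_truth.config.depth_per_library

    def test_degenerate_config_reads_match_genome_exactly(self):
        cfg = noiseless(
            SimConfig(
                seed=9, n_bulk_genes=3,
                class_counts={"conventional": 1, "5p_tailed": 1},
                depth_per_library=2000,
                loop_read_rate=0.0,
            )
        )
        truth = build_truth(cfg)
        manifest = default_manifest(n_total=1, n_ago=0, n_control=0, n_input=0)
        batches, ledger = simulate_reads(truth, manifest)
        genome_fwd = truth.genome.sequence("chrS")
        by_locus = {p.locus_id: p for p in truth.planted}
        for seq in batches["total_0"].species:
            assert seq in genome_fwd or revcomp(seq) in genome_fwd
        # every splice-defined terminus exact
        for row in ledger.itertuples():
            assert row.modification == ""
            p = by_locus[row.locus_id]
            hp = p.sense_hairpin_seq(truth.genome)
            if row.arm == "5p":
                assert row.sequence == hp[: p.mature_len]
            else:
                assert row.sequence == hp[-p.mature_len :]

    def test_forced_uridylation_tails_every_acceptor_read(self):
        cfg = noiseless(
            SimConfig(
                seed=9, n_bulk_genes=2,
                class_counts={"conventional": 1, "5p_tailed": 1},
                depth_per_library=1000,
                loop_read_rate=0.0,
            ),
            uridylation_prob=1.0,
        )
        truth = build_truth(cfg)
        manifest = default_manifest(n_total=1, n_ago=0, n_control=0, n_input=0)
        _, ledger = simulate_reads(truth, manifest)
        threep = ledger[ledger["arm"] == "3p"]
        assert len(threep) > 0
        assert (threep["modification"].str.startswith("tail:T")).all()
        assert threep["sequence"].str.endswith("T").all()

    def test_star_asymmetry_within_binomial_error(self):
        cfg = noiseless(
            SimConfig(
                seed=13, n_bulk_genes=2,
                class_counts={"conventional": 1},
                depth_per_library=1100,
                star_asymmetry=10.0,
                loop_read_rate=0.0,
                locus_weight_sigma=0.0,
            )
        )
        truth = build_truth(cfg)
        manifest = default_manifest(n_total=1, n_ago=0, n_control=0, n_input=0)
        _, ledger = simulate_reads(truth, manifest)
        mature = int(ledger.loc[ledger["origin"] == "mature", "count"].sum())
        star = int(ledger.loc[ledger["origin"] == "star", "count"].sum())
        n = mature + star
        assert stats.binomtest(mature, n, 10 / 11).pvalue > 0.001

    def test_loop_reads_only_in_total_libraries(self, small_reads):
        _, ledger = small_reads
        loops = ledger[ledger["origin"] == "loop"]
        assert len(loops) > 0
        assert set(loops["library_id"].str.split("_").str[0]) == {"total"}

    def test_control_ip_receives_only_background(self, small_reads):
        _, ledger = small_reads
        ctrl = ledger[ledger["library_id"].str.startswith("control_ip")]
        assert len(ctrl) > 0
        assert set(ctrl["origin"]) == {"background"}

    def test_ledger_accounts_for_every_read(self, small_reads, small_manifest, small_truth):
        batches, ledger = small_reads
        per_lib = ledger.groupby("library_id")["count"].sum()
        for m in small_manifest:
            assert per_lib[m.library_id] == small_truth.config.depth_per_library

    def test_deterministic_under_seed(self, small_truth, small_manifest):
        b1, l1 = simulate_reads(small_truth, small_manifest)
        b2, l2 = simulate_reads(small_truth, small_manifest)
        assert {k: v.species for k, v in b1.items()} == {
            k: v.species for k, v in b2.items()
        }
        assert l1.equals(l2)


class TestSimulateExpression:
    def test_zero_noise_correlated_gives_r_one(self):
        cfg = SimConfig(
            seed=21, n_bulk_genes=2,
            class_counts={"conventional": 2, "5p_tailed": 2},
            discordant_frac=0.0,
            expression_noise_sigma=0.0,
        )
        truth = build_truth(cfg)
        tables = simulate_expression(truth)
        mir = tables["mirtron_rpmm"].set_index("locus_id")
        host = tables["host_junction_rpm"].set_index("locus_id")
        for locus in mir.index:
            r = np.corrcoef(mir.loc[locus], host.loc[locus])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_discordant_loci_expressed_in_tissue_subset(self):
        cfg = SimConfig(
            seed=22, n_bulk_genes=2,
            class_counts={"conventional": 4, "5p_tailed": 4},
            discordant_frac=1.0,
        )
        truth = build_truth(cfg)
        tables = simulate_expression(truth)
        mir = tables["mirtron_rpmm"].set_index("locus_id")
        host = tables["host_junction_rpm"].set_index("locus_id")
        for locus in mir.index:
            assert (mir.loc[locus] > 0).sum() <= 2
            assert (host.loc[locus] > 0).all()

    def test_host_levels_mutually_consistent(self, small_truth):
        tables = simulate_expression(small_truth)
        j = tables["host_junction_rpm"].set_index("locus_id")
        f = tables["host_flank_rpkm"].set_index("locus_id")
        g = tables["host_gene_rpkm"].set_index("locus_id")
        assert (j.values <= f.values + 1e-9).all()
        assert (f.values <= g.values + 1e-9).all()

    def test_requires_three_tissues(self, small_truth):
        with pytest.raises(ValueError):
            simulate_expression(small_truth, tissues=["a", "b"])

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(uridylation_prob=1.2).validate()
        with pytest.raises(ValueError):
            SimConfig(uridylation_prob=0.7, adenylation_prob=0.5).validate()
        with pytest.raises(ValueError):
            SimConfig(jitter5={0: 0.5}).validate()

    def test_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = SimConfig.from_yaml(p)
        assert back == small_config
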