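"""Generator contracts: determinism, TA placement, essential exclusion,
expansion/sorting expectations, read materialisation, image truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from predfit import simulate as sim
from predfit.simulate import SimConfig, SimulationError


def ta_count(genome: str) -> int:
    return sum(
        1 for i in range(len(genome) - 1) if genome[i : i + 2] == "TA"
    )


class TestGenGenome:
    def test_constructive_postconditions(self, small_genome):
        cfg, genome, genes = small_genome
        assert len(genome) == 10_000
        assert len(genes) == 10
        g = genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()
        assert set(g["strand"]) <= {"+", "-"}
        assert (g["start"] >= 1).all() and (g["end"] <= 10_000).all()

    def test_deterministic_for_fixed_seed(self, small_genome):
        cfg, genome, genes = small_genome
        genome2, genes2 = sim.gen_genome(cfg)
        assert genome2 == genome
        pd.testing.assert_frame_equal(genes2, genes)

    def test_ta_density_floor(self, small_genome):
        _, genome, _ = small_genome
        # at least one TA per 50 bp on average
        assert ta_count(genome) >= len(genome) / 50

    def test_ta_enrichment_monotone(self, small_genome):
        cfg, genome, _ = small_genome
        richer, _ = sim.gen_genome(
            dataclasses.replace(cfg, ta_enrichment=2 * cfg.ta_enrichment)
        )
        assert ta_count(richer) > ta_count(genome)

    def test_infeasible_config_raises(self):
        cfg = SimConfig(
            genome_length=5_000, n_genes=20, gene_length_range=(400, 500), seed=0
        )
        with pytest.raises(SimulationError, match="cannot fit"):
            sim.gen_genome(cfg)


class TestGenLibrary:
    def test_every_insertion_on_ta(self, recovery_world):
        genome = recovery_world["genome"]
        truth = recovery_world["truth"]
        for pos in truth["position"]:
            assert genome[pos - 1 : pos + 1] == "TA"

    def test_essential_genes_receive_zero_insertions(self, recovery_world):
        truth = recovery_world["truth"]
        assert not truth["gene_id"].isin(recovery_world["essential"]).any()

    def test_frequencies_sum_to_one(self, recovery_world):
        assert recovery_world["truth"]["input_freq"].sum() == pytest.approx(1, abs=1e-9)

    def test_insufficient_ta_sites_raises(self, small_genome):
        cfg, genome, genes = small_genome
        bad = dataclasses.replace(cfg, n_insertions=100_000)
        with pytest.raises(SimulationError, match="admissible TA sites"):
            sim.gen_library(genome, genes, bad)

    def test_insertions_proportional_to_ta_content(self, small_genome):
        """With all genes neutral, per-gene insertion counts track gene TA
        content within multinomial sampling error (chi-square)."""
        cfg, genome, genes = small_genome
        cfg = dataclasses.replace(cfg, n_insertions=600, seed=11)
        sites, _ = sim.gen_library(genome, genes, cfg)
        tas = sim.ta_positions(genome)
        lookup_counts, expected = [], []
        for row in genes.itertuples(index=False):
            length = row.end - row.start + 1
            kept = int(np.floor(length * 0.9))
            if row.strand == "+":
                lo, hi = row.start, row.start + kept - 1
            else:
                lo, hi = row.end - kept + 1, row.end
            n_ta = ((tas >= lo) & (tas <= hi)).sum()
            expected.append(n_ta)
            lookup_counts.append((sites["gene_id"] == row.gene_id).sum())
        observed = np.array(lookup_counts)
        # hypergeometric-ish draw; chi-square against TA-content proportions
        expected = np.array(expected) / len(tas) * cfg.n_insertions
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=len(expected) - 1)


class TestSimulateExpansion:
    def test_neutral_world_preserves_frequencies(self, readback_world):
        truth = readback_world["truth"].copy()
        truth["true_W"] = 1.0
        f_out = sim.expected_output_frequencies(truth, d=100.0)
        np.testing.assert_allclose(f_out, truth["input_freq"], rtol=1e-12)

    def test_dead_mutant_diluted_d_fold(self):
        """A W=0 mutant in an otherwise neutral bulk is expected at
        f/d in the output, to first order in f."""
        truth = pd.DataFrame(
            {
                "input_freq": [0.001] + [0.999 / 9] * 9,
                "true_W": [0.0] + [1.0] * 9,
            },
            index=[f"m{i}" for i in range(10)],
        )
        f_out = sim.expected_output_frequencies(truth, d=100.0)
        assert f_out.iloc[0] == pytest.approx(0.001 / 100, rel=2e-3)

    def test_depth_conservation_and_replicate_independence(self, recovery_world):
        table = recovery_world["table"]
        assert (table.column_totals() == 2_000_000).all()
        r1 = table.counts["input_r1"]
        r2 = table.counts["input_r2"]
        assert not r1.equals(r2)

    def test_invalid_d_raises(self, readback_world):
        with pytest.raises(SimulationError):
            sim.simulate_expansion(readback_world["truth"], d=1.0, depth=100)


class TestSorting:
    def test_uniform_attachment_gives_equal_pools(self):
        truth = sim.make_pool_truth(20, 0, prob_range=(0.3, 0.3), seed=2)
        table = sim.simulate_sorting(truth, depth=200_000, seed=2, n_replicates=2)
        att = table.frequencies("attached_r1")
        una = table.frequencies("unattached_r1")
        np.testing.assert_allclose(att, una, atol=0.01)

    def test_zero_probability_mutant_absent_from_selected_pool(self):
        truth = sim.make_pool_truth(10, 0, prob_range=(0.0, 0.5), seed=2)
        table = sim.simulate_sorting(truth, depth=100_000, seed=2, n_replicates=3)
        first = truth.index[truth["attach_prob"] == 0.0]
        assert (table.counts.loc[first, ["attached_r1", "attached_r2"]] == 0).all().all()

    def test_bdelloplast_trivial_cases(self):
        truth = sim.make_pool_truth(10, 0, prob_range=(1.0, 1.0), which="round", seed=2)
        table = sim.simulate_bdelloplast(truth, contamination=0.0, depth=100_000, seed=2)
        np.testing.assert_allclose(
            table.frequencies("bdelloplast_r1"),
            truth["input_freq"],
            atol=0.01,
        )
        truth2 = sim.make_pool_truth(10, 0, prob_range=(0.0, 1.0), which="round", seed=3)
        table2 = sim.simulate_bdelloplast(truth2, contamination=0.0, depth=100_000, seed=3)
        zero = truth2.index[truth2["round_prob"] == 0.0]
        assert (table2.counts.loc[zero, "bdelloplast_r1"] == 0).all()


class TestGenReads:
    def test_reads_are_tag_plus_genomic_prefix(self, readback_world):
        genome = readback_world["genome"]
        table = readback_world["table"]
        tag = "ACAGGTTGGATGA"
        reads = sim.gen_reads(table, genome, read_length=50, tn_tag=tag)
        sid = table.sites.index[0]
        pos = int(table.sites.loc[sid, "position"])
        strand = table.sites.loc[sid, "strand"]
        n = int(table.counts.loc[sid, "input_r1"])
        mine = [seq for rid, seq, _ in reads["input_r1"] if rid.startswith(f"{sid}|")]
        assert len(mine) == n
        for seq in mine:
            assert seq.startswith(tag)
            frag = seq[len(tag) :]
            assert frag.startswith("TA")
            if strand == "+":
                assert genome[pos - 1 : pos - 1 + len(frag)] == frag

    def test_empty_count_table_gives_empty_fastq(self, readback_world):
        table = readback_world["table"]
        zeroed = type(table)(
            sites=table.sites,
            counts=table.counts * 0,
            samples=table.samples,
        )
        reads = sim.gen_reads(zeroed, readback_world["genome"])
        assert all(len(v) == 0 for v in reads.values())


class TestGenImages:
    def test_circle_truth_eccentricity_zero(self):
        _, truth = sim.gen_images([(50, 50, 12, 12, 0.0)], shape=(100, 100), seed=0)
        assert truth["true_eccentricity"].iloc[0] == 0.0

    def test_ellipse_truth_eccentricity(self):
        _, truth = sim.gen_images([(50, 50, 10, 6, 0.0)], shape=(100, 100), seed=0)
        assert truth["true_eccentricity"].iloc[0] == pytest.approx(0.8)

    def test_fifty_cells_give_fifty_truth_rows_and_regions(self):
        from predfit.imaging import segment

        cells = sim.random_cell_field(50, shape=(700, 700), seed=4)
        img, truth = sim.gen_images(cells, shape=(700, 700), seed=4)
        assert len(truth) == 50
        assert not truth["overlaps"].any()
        regions = segment(img)
        assert len(regions) == 50

    def test_overlapping_cells_flagged(self):
        _, truth = sim.gen_images(
            [(50, 50, 10, 8, 0.0), (52, 55, 10, 8, 1.0)], shape=(100, 100), seed=0
        )
        assert truth["overlaps"].all()
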