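"""The synthetic-data generator: trees, rates, traits, planted genomes."""

import json

import numpy as np
import pandas as pd
import pytest

from hormonescan.motifs import default_motifs, read_fasta, scan_genome
from hormonescan.phylo import phylo_vcv, tip_labels, tree_depth
from hormonescan.simulate import (
    GroundTruth,
    SimulationConfig,
    brownian_on_tree,
    pick_burst_clade,
    sim_genomes,
    sim_rates_and_counts,
    sim_traits,
    sim_tree,
    simulate_species_dataset,
    write_dataset,
)
from hormonescan.traits import compute_ssd
from hormonescan.windows import build_windows, count_hits_dedup, count_hits_per_gene


class TestSimTree:
    def test_deterministic_given_seed(self):
        a = sim_tree(8, 1.0, seed=7).as_string(schema="newick")
        b = sim_tree(8, 1.0, seed=7).as_string(schema="newick")
        assert a == b

    def test_tip_count_and_unit_depth(self):
        tree = sim_tree(12, seed=1)
        assert len(tip_labels(tree)) == 12
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert np.allclose(depths, 1.0, atol=1e-9)

    def test_terminal_branches_strictly_positive(self):
        tree = sim_tree(16, seed=3)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length > 0


def test_brownian_variance_scales_with_depth(rng):
    # across replicates, tip variance approximates sigma2 * depth (= 1)
    tree = sim_tree(6, seed=5)
    draws = [
        np.mean(list(brownian_on_tree(tree, 0.0, 2.0, rng).values()))
        for _ in range(300)
    ]
    assert np.var(draws) > 0  # smoke: varies across replicates
    one = brownian_on_tree(tree, 3.0, 0.0, rng)
    assert all(v == 3.0 for v in one.values())  # zero variance -> root value


class TestRatesAndCounts:
    def test_zero_variance_no_burst_shares_root_rate(self):
        tree = sim_tree(10, seed=2)
        cfg = SimulationConfig(seed=2, n_species=10, rate_bm_var=0.0)
        rng = np.random.default_rng(0)
        _, truth = sim_rates_and_counts(tree, cfg, rng)
        rates = list(truth.log_rates["ARE"].values())
        assert rates == pytest.approx([cfg.are_root_log_rate] * 10)

    def test_burst_clade_rate_multiplied(self):
        tree = sim_tree(24, seed=6)
        clade = pick_burst_clade(tree, 0.33)
        assert 3 <= len(clade) <= 16
        cfg = SimulationConfig(seed=6, n_species=24, rate_bm_var=0.0,
                               burst_clade=list(clade), burst_multiplier=4.0)
        rng = np.random.default_rng(0)
        counts, truth = sim_rates_and_counts(tree, cfg, rng)
        totals = counts.groupby("species")["ARE"].sum()
        inside = totals[totals.index.isin(clade)].mean()
        outside = totals[~totals.index.isin(clade)].mean()
        # Poisson around a 4x rate ratio; generous error bounds
        assert 2.5 < inside / outside < 6.0
        for sp in clade:
            assert truth.log_rates["ARE"][sp] == pytest.approx(
                cfg.are_root_log_rate + np.log(4.0)
            )

    def test_independent_mode_decorrelates_genes(self):
        tree = sim_tree(40, seed=8)
        rng = np.random.default_rng(1)
        cfg = SimulationConfig(seed=8, n_species=40, gene_rate_mode="independent",
                               n_genes=12)
        counts, _ = sim_rates_and_counts(tree, cfg, rng)
        wide = counts.pivot(index="species", columns="gene_id", values="ARE")
        corr = wide.corr().to_numpy()
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.abs(np.nanmean(off)) < 0.35

    def test_deterministic_given_seed(self):
        tree = sim_tree(8, seed=4)
        cfg = SimulationConfig(seed=4, n_species=8)
        a, _ = sim_rates_and_counts(tree, cfg, np.random.default_rng(9))
        b, _ = sim_rates_and_counts(tree, cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)


class TestSimTraits:
    def _setup(self, **kw):
        cfg = SimulationConfig(seed=5, n_species=12, **kw)
        tree = sim_tree(12, seed=5)
        totals = {sp: 40.0 for sp in tip_labels(tree)}
        return tree, totals, cfg

    def test_masses_back_solve_ssd_and_body_exactly(self):
        tree, totals, cfg = self._setup()
        truth = GroundTruth(cfg.beta_are, cfg.beta_body, cfg.lam)
        traits = sim_traits(tree, totals, cfg, np.random.default_rng(3), truth=truth)
        for _, row in traits.iterrows():
            ssd = compute_ssd(row.male_mass, row.female_mass)
            assert ssd == pytest.approx(truth.ssd[row.species], abs=1e-12)

    def test_degenerate_noise_reduces_to_deterministic_model(self):
        tree, totals, cfg = self._setup(beta_are=0.0, lam=0.0, residual_sd=0.0)
        traits = sim_traits(tree, totals, cfg, np.random.default_rng(3))
        body = (traits.male_mass + traits.female_mass) / 2
        ssd = np.log(traits.male_mass / traits.female_mass)
        assert np.allclose(ssd, cfg.beta_body * np.log(body), atol=1e-9)

    def test_negative_totals_rejected(self):
        tree, totals, cfg = self._setup()
        totals[next(iter(totals))] = -1
        with pytest.raises(ValueError, match="negative"):
            sim_traits(tree, totals, cfg, np.random.default_rng(0))


class TestSimGenomes:
    def test_planted_motifs_recovered_exactly_by_scanner_and_counter(self):
        cfg = SimulationConfig(seed=9, n_species=4, n_genes=4, plant_flank=400)
        ds = simulate_species_dataset(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        truth = GroundTruth(cfg.beta_are, cfg.beta_body, cfg.lam)
        genomes, annotations = sim_genomes(ds.tree, ds.per_gene_counts, cfg, rng,
                                           truth=truth)
        motifs = default_motifs()
        for sp, genome in genomes.items():
            hits = scan_genome(genome, motifs)
            planted = truth.planted[sp]
            assert len(hits) == len(planted)
            assert {(h.start, h.motif_name) for h in hits} == {
                (d["start"], d["motif_name"]) for d in planted
            }
            # dedup counting over the planting windows gives the planted totals
            clens = {c: len(s) for c, s in genome.items()}
            ws = build_windows(annotations[sp], cfg.plant_flank, clens)
            dedup = count_hits_dedup(hits, ws)["by_class"]
            expected = ds.per_gene_counts[ds.per_gene_counts.species == sp]
            assert dedup["ARE"] == expected["ARE"].sum()
            assert dedup["ERE"] == expected["ERE"].sum()

    def test_shared_window_hit_counts_once_dedup_twice_per_gene(self):
        # at 3x the planting flank the two middle windows overlap, so some
        # planted motifs can sit near two genes; construction guarantees the
        # invariant dedup <= per-gene sum with equality iff no sharing
        cfg = SimulationConfig(seed=11, n_species=3, n_genes=3, plant_flank=300)
        ds = simulate_species_dataset(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        genomes, annotations = sim_genomes(ds.tree, ds.per_gene_counts, cfg, rng)
        sp = sorted(genomes)[0]
        hits = scan_genome(genomes[sp], default_motifs())
        clens = {c: len(s) for c, s in genomes[sp].items()}
        wide = build_windows(annotations[sp], 3 * cfg.plant_flank + 300, clens)
        dedup = count_hits_dedup(hits, wide)["by_class"]["ARE"]
        per_gene = count_hits_per_gene(
            hits, annotations[sp], 3 * cfg.plant_flank + 300, clens
        )["ARE"].sum()
        assert dedup <= per_gene
        assert dedup == len([h for h in hits if h.hre_class == "ARE"])


class TestWriteDataset:
    def test_round_trip_and_determinism(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_species=4, n_genes=3, plant_flank=300)
        out1 = write_dataset(tmp_path / "a", cfg)
        out2 = write_dataset(tmp_path / "b", cfg)
        gt1 = (out1 / "ground_truth.json").read_text()
        gt2 = (out2 / "ground_truth.json").read_text()
        assert gt1 == gt2  # byte-identical reruns

        truth = json.loads(gt1)
        traits = pd.read_csv(out1 / "traits.csv")
        nwk = (out1 / "tree.nwk").read_text()
        assert all(sp in nwk for sp in traits["species"])

        # re-scanning the emitted FASTA reproduces the recorded planted set
        motifs = default_motifs()
        for sp in traits["species"]:
            genome = read_fasta(out1 / "genomes" / f"{sp}.fa")
            hits = scan_genome(genome, motifs)
            assert {(h.start, h.motif_name) for h in hits} == {
                (d["start"], d["motif_name"]) for d in truth["planted"][sp]
            }

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_species=4, n_genes=3, plant_flank=300)
        out = tmp_path / "d"
        write_dataset(out, cfg)
        with pytest.raises(FileExistsError):
            write_dataset(out, cfg)
        write_dataset(out, cfg, force=True)  # succeeds


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(lam=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(gc_fraction=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(burst_multiplier=0.5)
    with pytest.raises(ValueError):
        sim_tree(2)
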