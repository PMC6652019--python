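"""Generators: planted-signal placement, determinism, round-trips."""
import numpy as np
import pandas as pd
import pytest

from symscreen import io
from symscreen.expression_screen import (
    FUNGUS_THRESHOLDS,
    build_expression_table,
    classify_differential,
)
from symscreen.secretome import call_secretome
from symscreen.synthetic_data import (
    CiliacutSpec,
    ClusterSpec,
    ExpressionSpec,
    IslandSpec,
    RateSpec,
    SecretomeSpec,
    SimulationConfig,
    simulate_alignments,
    simulate_expression,
    simulate_genome,
    simulate_homology,
    simulate_secretion_calls,
)


def small_config(**kwargs):
    defaults = dict(seed=5, genome_length=60_000, n_genes=60)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_island_gc_recovered(self, island_config, island_genome):
        lo, hi = island_genome.truth.island_interval
        sub = island_genome.sequence[lo - 1 : hi]
        gc = (sub.count("G") + sub.count("C")) / len(sub)
        assert abs(gc - island_config.island.gc) < 0.01

    def test_background_gc_recovered(self, island_config, island_genome):
        lo, hi = island_genome.truth.island_interval
        outside = island_genome.sequence[: lo - 1]
        gc = (outside.count("G") + outside.count("C")) / len(outside)
        assert abs(gc - island_config.background_gc) < 0.01

    def test_deterministic_outputs(self, tmp_path):
        cfg = small_config(island=IslandSpec(start=10_001, length=20_000))
        paths = []
        for run in ("a", "b"):
            sim = simulate_genome(cfg)
            fa = tmp_path / f"{run}.fasta"
            gff = tmp_path / f"{run}.gff3"
            io.write_fasta({cfg.scaffold: sim.sequence}, fa)
            io.write_gff3(sim.genes, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]

    def test_zero_length_island(self):
        sim = simulate_genome(small_config(island=IslandSpec(length=0)))
        assert sim.truth.island_interval is None
        assert sim.truth.island_genes == set()
        assert sim.repeat_unit is None

    def test_island_exceeding_scaffold_rejected(self):
        cfg = small_config(island=IslandSpec(start=50_001, length=20_000))
        with pytest.raises(ValueError):
            simulate_genome(cfg)

    def test_island_overlapping_array_rejected(self):
        # Island nominally fits but runs into the terminal repeat array.
        cfg = small_config(
            island=IslandSpec(start=40_001, length=19_000, repeat_copies=10)
        )
        with pytest.raises(ValueError):
            simulate_genome(cfg)

    def test_gff3_round_trip(self, island_genome, tmp_path):
        path = tmp_path / "genes.gff3"
        io.write_gff3(island_genome.genes, path)
        back = io.read_gff3(path)
        pd.testing.assert_frame_equal(
            back, island_genome.genes.reset_index(drop=True)
        )

    def test_truth_sets_subset_of_annotation(self, island_genome):
        ids = set(island_genome.genes["gene_id"])
        assert island_genome.truth.island_genes <= ids

    def test_repeat_array_at_terminus(self, island_config, island_genome):
        unit = island_genome.repeat_unit
        copies = island_config.island.repeat_copies
        assert island_genome.sequence.endswith(unit * copies)


class TestExpression:
    def test_planted_fold_recovered_over_seeds(self):
        # Monte-Carlo oracle: mean Co/Mo of planted genes across 200 seeds.
        spec = ExpressionSpec(
            n_induced=5, n_repressed=0, fold_induced=3.0, dispersion=0.05
        )
        genome = simulate_genome(small_config())
        ratios = []
        for seed in range(200):
            sim = simulate_expression(genome.genes, spec, seed)
            table = build_expression_table(
                sim.counts,
                pd.Series(
                    (genome.genes["end"] - genome.genes["start"] + 1).to_numpy(),
                    index=genome.genes["gene_id"],
                ),
                sim.library_sizes,
            )
            table = classify_differential(table, FUNGUS_THRESHOLDS)
            planted = table["gene_id"].isin(sim.truth.induced_genes)
            ratios.extend(table.loc[planted, "ratio"].tolist())
        mean_ratio = float(np.mean([r for r in ratios if np.isfinite(r)]))
        assert 2.7 <= mean_ratio <= 3.3

    def test_null_false_positive_rate_measured(self):
        # Null simulation: report (not assume) the induced false-positive
        # rate, then require a second null run to stay within it.
        genome = simulate_genome(small_config())
        spec = ExpressionSpec(n_induced=0, n_repressed=0, dispersion=0.05)
        lengths = pd.Series(
            (genome.genes["end"] - genome.genes["start"] + 1).to_numpy(),
            index=genome.genes["gene_id"],
        )
        rates = []
        for seed in range(20):
            sim = simulate_expression(genome.genes, spec, seed)
            table = classify_differential(
                build_expression_table(sim.counts, lengths, sim.library_sizes),
                FUNGUS_THRESHOLDS,
            )
            rates.append((table["class"] == "induced").mean())
        measured_fpr = max(rates)
        sim = simulate_expression(genome.genes, spec, 999)
        table = classify_differential(
            build_expression_table(sim.counts, lengths, sim.library_sizes),
            FUNGUS_THRESHOLDS,
        )
        assert (table["class"] == "induced").mean() <= max(measured_fpr, 0.05)

    def test_zero_depth_all_not_detected(self):
        genome = simulate_genome(small_config())
        spec = ExpressionSpec(
            n_induced=0, n_repressed=0, library_size_mono=0, library_size_co=0
        )
        sim = simulate_expression(genome.genes, spec, 0)
        assert (sim.counts[["count_mono", "count_co"]] == 0).all().all()
        table = sim.counts.copy()
        table["rpkm_mono"] = 0.0
        table["rpkm_co"] = 0.0
        classified = classify_differential(table, FUNGUS_THRESHOLDS)
        assert (classified["class"] == "not_detected").all()

    def test_bad_dispersion_rejected(self):
        genome = simulate_genome(small_config())
        with pytest.raises(ValueError):
            simulate_expression(genome.genes, ExpressionSpec(dispersion=0.0), 0)

    def test_disjoint_planted_sets(self):
        genome = simulate_genome(small_config())
        sim = simulate_expression(
            genome.genes, ExpressionSpec(n_induced=10, n_repressed=10), 3
        )
        assert not sim.truth.induced_genes & sim.truth.repressed_genes


class TestSecretion:
    def test_perfect_concordance_exact_recovery(self):
        genome = simulate_genome(small_config())
        spec = SecretomeSpec(
            n_true_secreted=15, concordance=1.0, false_positive_rate=0.0
        )
        sim = simulate_secretion_calls(genome.genes, spec, 0)
        called = call_secretome(sim.calls)
        recovered = set(called.loc[called["secreted"], "gene_id"])
        assert recovered == sim.truth.secreted_genes

    def test_partial_concordance_binomial_interval(self):
        # Closed-form oracle: recovery ~ Binomial(100, 0.9^3); 99% interval.
        genome = simulate_genome(small_config(genome_length=200_000, n_genes=200))
        spec = SecretomeSpec(
            n_true_secreted=100, concordance=0.9, false_positive_rate=0.0
        )
        p = 0.9**3
        mean, sd = 100 * p, np.sqrt(100 * p * (1 - p))
        lo, hi = mean - 2.576 * sd, mean + 2.576 * sd
        sim = simulate_secretion_calls(genome.genes, spec, 42)
        called = call_secretome(sim.calls)
        recovered = set(called.loc[called["secreted"], "gene_id"])
        k = len(recovered & sim.truth.secreted_genes)
        assert lo <= k <= hi

    def test_concordance_out_of_range_rejected(self):
        genome = simulate_genome(small_config())
        with pytest.raises(ValueError):
            simulate_secretion_calls(
                genome.genes, SecretomeSpec(concordance=1.2), 0
            )

    def test_tm_first_start_iff_tm_count(self):
        genome = simulate_genome(small_config())
        sim = simulate_secretion_calls(
            genome.genes, SecretomeSpec(n_true_secreted=10, concordance=0.7), 1
        )
        has_tm = sim.calls["tm_count"] >= 1
        assert sim.calls.loc[has_tm, "tm_first_start"].notna().all()
        assert sim.calls.loc[~has_tm, "tm_first_start"].isna().all()


class TestHomology:
    def test_planted_pairs_are_mutual_best(self):
        sim = simulate_homology(ClusterSpec(), CiliacutSpec(), seed=3)
        (qt, st) = next(iter(sim.pair_hits))
        hits = sim.pair_hits[(qt, st)]
        planted = hits[hits["evalue"] < 1e-5]
        for row in planted.itertuples(index=False):
            assert row.query.split("|")[1] == row.subject.split("|")[1]

    def test_decoys_above_threshold(self):
        sim = simulate_homology(ClusterSpec(), CiliacutSpec(), seed=3)
        for frame in sim.pair_hits.values():
            decoys = frame[
                frame.apply(
                    lambda r: r["query"].split("|")[1] != r["subject"].split("|")[1],
                    axis=1,
                )
            ]
            assert (decoys["evalue"] >= 1e-5).all()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_homology(
                ClusterSpec(), CiliacutSpec(panel=[["only", True]]), seed=0
            )

    def test_cluster_members_pass_retention_filter(self):
        spec = ClusterSpec(
            member_gene_ids=["g1", "g2", "g3"],
            decoy_gene_ids=[f"d{i}" for i in range(30)],
        )
        sim = simulate_homology(spec, CiliacutSpec(), seed=9)
        hits = sim.cluster_hits
        members = hits[hits["subject"].isin(spec.member_gene_ids)]
        assert (members["similarity"] >= 45).all()
        assert members["coverage"].between(0.5, 1.5).all()
        decoys = hits[~hits["subject"].isin(spec.member_gene_ids)]
        passing = (
            (decoys["similarity"] >= 45)
            & decoys["coverage"].between(0.5, 1.5)
        )
        assert not passing.any()


class TestAlignments:
    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            simulate_alignments(RateSpec(alignment_length=49), 0)

    def test_zero_branch_length_identical(self):
        spec = RateSpec(
            n_orthogroups=2, n_slow=0, n_fast=0, branch_length=0.0,
            alignment_length=100, n_triplets=2,
        )
        sim = simulate_alignments(spec, 0)
        for aln in sim.alignments:
            seqs = set(aln.sequences.values())
            assert len(seqs) == 1

    def test_triplet_table_covers_all_orthogroups(self):
        spec = RateSpec(n_orthogroups=4, n_slow=1, n_fast=1, n_triplets=3)
        sim = simulate_alignments(spec, 1)
        assert set(sim.triplets["orthogroup"]) == {a.orthogroup for a in sim.alignments}
        assert (sim.triplets.groupby("orthogroup").size() == 3).all()

    def test_truth_labels_match_multipliers(self):
        spec = RateSpec(n_orthogroups=6, n_slow=2, n_fast=2)
        sim = simulate_alignments(spec, 2)
        for aln in sim.alignments:
            if aln.orthogroup in sim.truth.slow_orthogroups:
                assert aln.multiplier < 1
            elif aln.orthogroup in sim.truth.fast_orthogroups:
                assert aln.multiplier > 1
            else:
                assert aln.multiplier == 1.0
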