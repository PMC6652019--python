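"""Synthetic fixture generators with planted ground truth."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .. import io
from .alignments import SimulatedAlignments, simulate_alignments
from .config import (
    CiliacutSpec,
    ClusterSpec,
    ExpressionSpec,
    IslandSpec,
    RateSpec,
    SecretomeSpec,
    SimulationConfig,
)
from .expression import SimulatedExpression, simulate_expression
from .genome import SimulatedGenome, simulate_genome
from .ground_truth import GroundTruth
from .homology import SimulatedHomology, simulate_homology
from .secretion import SimulatedSecretion, simulate_secretion_calls

__all__ = [
    "SimulationConfig",
    "IslandSpec",
    "ExpressionSpec",
    "SecretomeSpec",
    "ClusterSpec",
    "CiliacutSpec",
    "RateSpec",
    "GroundTruth",
    "simulate_genome",
    "simulate_expression",
    "simulate_secretion_calls",
    "simulate_homology",
    "simulate_alignments",
    "simulate_all",
    "write_fixture",
    "FixtureSet",
]


@dataclass
class FixtureSet:
    genome: SimulatedGenome
    expression: SimulatedExpression
    secretion: SimulatedSecretion
    homology: SimulatedHomology
    alignments: SimulatedAlignments
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> FixtureSet:
    """Run every simulator off the one master seed and merge their truths."""
    config.validate()
    genome = simulate_genome(config)
    expression = simulate_expression(genome.genes, config.expression, config.seed)
    secretion = simulate_secretion_calls(genome.genes, config.secretome, config.seed)

    cluster_spec = config.cluster
    gene_ids = list(genome.genes["gene_id"])
    if cluster_spec.member_gene_ids and not cluster_spec.decoy_gene_ids:
        members = set(cluster_spec.member_gene_ids)
        cluster_spec = ClusterSpec(
            member_gene_ids=cluster_spec.member_gene_ids,
            decoy_gene_ids=[g for g in gene_ids if g not in members],
            max_gap=cluster_spec.max_gap,
            n_queries=cluster_spec.n_queries,
            n_decoy_hits=cluster_spec.n_decoy_hits,
        )
    homology = simulate_homology(cluster_spec, config.ciliacut, config.seed)
    alignments = simulate_alignments(config.rates, config.seed)

    truth = genome.truth
    for part in (expression, secretion, homology, alignments):
        truth = truth.merge(part.truth)
    truth.validate(set(gene_ids))
    return FixtureSet(
        genome=genome,
        expression=expression,
        secretion=secretion,
        homology=homology,
        alignments=alignments,
        truth=truth,
    )


def write_fixture(fixture: FixtureSet, outdir: str | Path, scaffold: str) -> None:
    """Write the full fixture as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta({scaffold: fixture.genome.sequence}, outdir / "genome.fasta")
    io.write_gff3(fixture.genome.genes, outdir / "genes.gff3")
    io.write_table(fixture.expression.counts, outdir / "counts.tsv")
    io.write_json(fixture.expression.library_sizes, outdir / "library_sizes.json")
    io.write_table(fixture.secretion.calls, outdir / "secretion_calls.tsv")
    io.write_table(fixture.homology.cluster_hits, outdir / "cluster_hits.tsv")
    pair_dir = outdir / "pair_hits"
    pair_dir.mkdir(exist_ok=True)
    for (qt, st), frame in fixture.homology.pair_hits.items():
        io.write_table(frame, pair_dir / f"{qt}__vs__{st}.tsv")
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for aln in fixture.alignments.alignments:
        io.write_alignment_fasta(aln.sequences, aln_dir / f"{aln.orthogroup}.fasta")
    io.write_table(fixture.alignments.triplets, outdir / "triplets.tsv")
    io.write_json(fixture.truth.to_dict(), outdir / "ground_truth.json")
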