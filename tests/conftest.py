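import numpy as np
import pandas as pd
import pytest

from methgrass import dmr, simulate
from methgrass.io import AnnotationSet, MethylomeTable


@pytest.fixture(scope="session")
def default_study():
    """Full default-configuration study (2 Mb, planted DMRs, MeDIP)."""
    return simulate.simulate_study(simulate.SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def recovery_run():
    """Caller-performance study: default parameters, unbiased NegBin depth
    (mean 20), 100 planted CG DMRs of effect 0.5 in a 2 Mb genome."""
    cfg = simulate.SimulationConfig(seed=3, depth_meth_bias=0.0)
    genome = simulate.simulate_genome(cfg)
    ann = simulate.simulate_annotation(cfg, genome)
    table_a, table_b, truth = simulate.simulate_methylome_pair(cfg, genome, ann)
    result = dmr.dmr_pipeline(table_a, table_b)
    return {"truth": truth, "result": result,
            "table_a": table_a, "table_b": table_b}


@pytest.fixture(scope="session")
def small_study():
    """300 kb study for integration-level module tests."""
    cfg = simulate.SimulationConfig(seed=5, chrom_length=150_000, n_genes=40,
                                    n_tes=55, n_dmrs=10)
    return simulate.simulate_study(cfg)


def make_table(rows, sample_id="t"):
    """rows: (chrom, pos, strand, n_meth, n_unmeth, context)"""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "n_meth",
                                     "n_unmeth", "context"])
    return MethylomeTable(df, sample_id=sample_id)


def toy_annotation():
    """Three plus-strand genes on a 100 kb chromosome, five TEs.

    gene_a: [10000,12000) with CDS/UTR/introns; gene_b: [30000,31000);
    gene_c: [50000,52000) minus strand.
    TEs: Gypsy [20000,21000), Gypsy [22000,22400), Copia [40000,40800),
    LINE [60000,60500), DNA [11200,11350) (inside gene_a's intron).
    """
    genes = pd.DataFrame([
        ("ChrT", 10000, 12000, "+", "gene_a"),
        ("ChrT", 30000, 31000, "+", "gene_b"),
        ("ChrT", 50000, 52000, "-", "gene_c"),
    ], columns=["chrom", "start", "end", "strand", "gene_id"])
    subs = pd.DataFrame([
        ("ChrT", 10000, 10100, "+", "gene_a", "five_prime_UTR"),
        ("ChrT", 10100, 11000, "+", "gene_a", "CDS"),
        ("ChrT", 11000, 11500, "+", "gene_a", "intron"),
        ("ChrT", 11500, 11900, "+", "gene_a", "CDS"),
        ("ChrT", 11900, 12000, "+", "gene_a", "three_prime_UTR"),
        ("ChrT", 30000, 31000, "+", "gene_b", "CDS"),
        ("ChrT", 50000, 51000, "-", "gene_c", "CDS"),
        ("ChrT", 51000, 51400, "-", "gene_c", "intron"),
        ("ChrT", 51400, 52000, "-", "gene_c", "CDS"),
    ], columns=["chrom", "start", "end", "strand", "gene_id", "feature"])
    tes = pd.DataFrame([
        ("ChrT", 20000, 21000, ".", "te_1", "LTR/Gypsy"),
        ("ChrT", 22000, 22400, ".", "te_2", "LTR/Gypsy"),
        ("ChrT", 40000, 40800, ".", "te_3", "LTR/Copia"),
        ("ChrT", 60000, 60500, ".", "te_4", "LINE"),
        ("ChrT", 11200, 11350, ".", "te_5", "DNA"),
    ], columns=["chrom", "start", "end", "strand", "te_id", "te_class"])
    return AnnotationSet(genes, subs, tes, {"ChrT": 100_000})
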