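import numpy as np
import pytest

from regland.genome_io import GenomeAnnotation, Interval, Transcript
from regland.synthetic_data import SimConfig, generate_genome


# Reduced study conditions used where a test needs many repeated runs; the
# planted structure (roles, widths, mixture) matches the default config.
SMALL_SIM = SimConfig(
    genome_size=400_000,
    n_chromosomes=2,
    n_genes=40,
    n_nfrs=40,
    n_motifs=4,
    fragments_per_replicate=40_000,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_genome(SMALL_SIM, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_genome(SimConfig(), seed=1)


@pytest.fixture()
def toy_annotation():
    """Two genes on a 10 kb chromosome: one + strand, one - strand.

    geneA (+): [2000, 4800) with exons 2000-2250 / 3150-3550 / 4450-4800,
    5'UTR 2000-2150, 3'UTR 4600-4800.
    geneB (-): [6000, 8800) mirrored (TSS at 8799).
    """
    chrom = "chr1"

    def make(gid, start, strand):
        lens = (250, 400, 350) if strand == "+" else (350, 400, 250)
        exons = []
        p = start
        for j, el in enumerate(lens):
            exons.append(Interval(chrom, p, p + el, strand))
            p += el + (900 if j < 2 else 0)
        end = start + 2800
        gene = Interval(chrom, start, end, strand)
        if strand == "+":
            u5 = (Interval(chrom, start, start + 150, strand),)
            u3 = (Interval(chrom, end - 200, end, strand),)
        else:
            u5 = (Interval(chrom, end - 150, end, strand),)
            u3 = (Interval(chrom, start, start + 200, strand),)
        return gene, Transcript(f"{gid}.t1", gid, gene, tuple(exons)), u5, u3

    ga, ta, u5a, u3a = make("geneA", 2000, "+")
    gb, tb, u5b, u3b = make("geneB", 6000, "-")
    return GenomeAnnotation(
        genes={"geneA": ga, "geneB": gb},
        transcripts={"geneA.t1": ta, "geneB.t1": tb},
        chrom_sizes={chrom: 10_000},
        utr5={"geneA.t1": u5a, "geneB.t1": u5b},
        utr3={"geneA.t1": u3a, "geneB.t1": u3b},
    )


def bh_oracle(pvals):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q
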