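import numpy as np
import pytest

from meiochip.io_formats import GeneAnnotation, TagCollection
from meiochip.synthetic import SyntheticSpec, make_annotation, simulate_expression


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(n_autosomal_genes=120, n_x_genes=30, seed=7)


@pytest.fixture(scope="session")
def large_dataset():
    spec = SyntheticSpec(seed=1)  # default scale: 900 autosomal + 100 X genes
    genes = make_annotation(spec)
    table, truth = simulate_expression(spec, genes)
    return spec, genes, table, truth


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    genes = make_annotation(small_spec)
    table, truth = simulate_expression(small_spec, genes)
    return small_spec, genes, table, truth


def make_tags(chrom, pos, strand, mark="m", stage="GS", library_size=None):
    """Build a TagCollection from plain lists."""
    n = len(pos)
    return TagCollection(
        mark=mark,
        stage=stage,
        chrom=np.array([chrom] * n if isinstance(chrom, str) else chrom, dtype=object),
        pos5=np.array(pos, dtype=np.int64),
        strand=np.array(strand, dtype="<U1"),
        library_size=library_size,
    )


def plus_gene(tss=10_000, length=2_000, gene_id="g+", chrom="chr1", is_x=False):
    return GeneAnnotation(gene_id, chrom, tss, tss + length, "+", is_x)


def minus_gene(tss=10_000, length=2_000, gene_id="g-", chrom="chr1", is_x=False):
    return GeneAnnotation(gene_id, chrom, tss - length + 1, tss + 1, "-", is_x)
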