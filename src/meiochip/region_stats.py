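"""Region read-count comparisons and chromosome-enrichment tests.

Two strand-aware region kinds are supported: a TSS flank (upstream /
downstream extents, e.g. -500 bp to +500 bp around the TSS) and a
promoter-to-TES region (an upstream extent through the end of the gene
body, e.g. -1 kb from TSS to TES). Counts of shifted tags in these
regions are compared between conditions (e.g. wild-type vs knockout)
with a two-sided Wilcoxon rank-sum (Mann-Whitney U) test; class
composition between the X chromosome and autosomes is compared with a
Pearson chi-square test on the 2x2 contingency table (no continuity
correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu

from .expression import ClassificationResult
from .io_formats import GeneAnnotation, TagCollection

__all__ = [
    "RegionSpec",
    "TestResult",
    "EnrichmentResult",
    "parse_region_spec",
    "resolve_region",
    "region_counts",
    "wilcoxon_rank_sum",
    "chisq_2x2",
    "chisq_enrichment",
]

#: significance star thresholds (strict): * below 0.05, ** below 0.001
STAR_THRESHOLDS = (0.05, 0.001)


@dataclass(frozen=True)
class RegionSpec:
    """A strand-aware gene-anchored region.

    kind "tss_flank": [TSS - upstream, TSS + downstream) in 5'->3' sense.
    kind "promoter_to_tes": [TSS - upstream, TES] in 5'->3' sense.
    """

    kind: str
    upstream: int = 0
    downstream: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("tss_flank", "promoter_to_tes"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("extents must be >= 0")
        if self.kind == "tss_flank" and self.upstream + self.downstream == 0:
            raise ValueError("tss_flank region is empty")


def parse_region_spec(text: str) -> RegionSpec:
    """Parse CLI region syntax: ``tss:-500:+500`` or ``body:-1000``."""
    parts = text.split(":")
    if parts[0] == "tss" and len(parts) == 3:
        return RegionSpec(
            kind="tss_flank",
            upstream=abs(int(parts[1])),
            downstream=abs(int(parts[2])),
        )
    if parts[0] == "body" and len(parts) == 2:
        return RegionSpec(kind="promoter_to_tes", upstream=abs(int(parts[1])))
    raise ValueError(f"cannot parse region spec {text!r}")


def resolve_region(gene: GeneAnnotation, spec: RegionSpec) -> tuple[int, int]:
    """Genomic half-open interval of the region for one gene.

    Upstream always means 5' of the TSS on the gene's own strand, so for
    minus-strand genes upstream extents grow towards larger coordinates.
    The interval is clamped at coordinate 0; an empty result raises.
    """
    u = spec.upstream
    if spec.kind == "tss_flank":
        d = spec.downstream
        if gene.strand == "+":
            start, end = gene.tss - u, gene.tss + d
        else:
            start, end = gene.tss - d + 1, gene.tss + u + 1
    else:  # promoter_to_tes
        if gene.strand == "+":
            start, end = gene.tss - u, gene.tes + 1
        else:
            start, end = gene.tes, gene.tss + u + 1
    start = max(0, start)
    if start >= end:
        raise ValueError(
            f"{gene.gene_id}: region resolves to empty interval [{start}, {end})"
        )
    return start, end


def region_counts(
    shifted: TagCollection,
    genes: Sequence[GeneAnnotation],
    spec: RegionSpec,
    per_million: bool = False,
) -> pd.Series:
    """Shifted-tag counts inside each gene's resolved region.

    Containment is half-open: a tag exactly at the start is counted, one
    at the end is not. With ``per_million`` counts are divided by the
    library size in millions.
    """
    by_chrom = shifted.positions_by_chrom()
    empty = np.empty(0, dtype=np.int64)
    out = {}
    for g in genes:
        start, end = resolve_region(g, spec)
        pos = by_chrom.get(g.chrom, empty)
        n = int(
            np.searchsorted(pos, end, side="left")
            - np.searchsorted(pos, start, side="left")
        )
        out[g.gene_id] = n
    counts = pd.Series(out, name="region_count", dtype=float)
    if per_million:
        counts = counts / (shifted.library_size / 1e6)
    return counts


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int

    @property
    def significance_stars(self) -> str:
        if self.p_value < STAR_THRESHOLDS[1]:
            return "**"
        if self.p_value < STAR_THRESHOLDS[0]:
            return "*"
        return "ns"


def wilcoxon_rank_sum(counts_a, counts_b) -> TestResult:
    """Two-sided Mann-Whitney U test on two count vectors.

    Uses the exact null distribution (full enumeration) when the combined
    sample size is at most 12 and there are no ties, and the normal
    approximation with tie correction otherwise. The reported statistic
    is U for sample A.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    exact = (a.size + b.size) <= 12 and no_ties
    res = mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="wilcoxon-exact" if exact else "wilcoxon-normal-approx",
        n_a=a.size,
        n_b=b.size,
    )


def chisq_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no Yates correction.

    A table with identical row proportions returns statistic 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        bad = "row" if np.any(rows == 0) else "column"
        raise ValueError(f"degenerate table: a {bad} marginal is zero")
    stat, p, _, _ = chi2_contingency(t, correction=correction)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method="chi-square" + ("-yates" if correction else ""),
        n_a=int(rows[0]),
        n_b=int(rows[1]),
    )


@dataclass
class EnrichmentResult:
    test: TestResult
    table: pd.DataFrame  # rows X / autosome, columns target / other
    x_in_class: int
    x_total: int

    @property
    def x_percent(self) -> float:
        """Percentage of X-linked genes in the target class, one decimal."""
        return round(100.0 * self.x_in_class / self.x_total, 1)


def chisq_enrichment(
    result: ClassificationResult,
    annotation: Sequence[GeneAnnotation],
    target_class: str,
    correction: bool = False,
    y_chrom_name: str = "chrY",
) -> EnrichmentResult:
    """Is ``target_class`` over-represented on the X chromosome?

    Builds the 2x2 table {X, autosome} x {target_class, other} from the
    primary labels (Y-linked genes excluded) and applies the Pearson
    chi-square test.
    """
    by_id = {g.gene_id: g for g in annotation}
    missing = [gid for gid in result.table.index if gid not in by_id]
    if missing:
        raise KeyError(f"gene(s) absent from annotation: {missing[:5]}")
    counts = np.zeros((2, 2))
    for gid, label in result.primary.items():
        g = by_id[gid]
        if g.chrom == y_chrom_name:
            continue
        row = 0 if g.is_x else 1
        col = 0 if label == target_class else 1
        counts[row, col] += 1
    table = pd.DataFrame(
        counts,
        index=["X", "autosome"],
        columns=[target_class, "other"],
        dtype=int,
    )
    test = chisq_2x2(counts, correction=correction)
    return EnrichmentResult(
        test=test,
        table=table,
        x_in_class=int(counts[0, 0]),
        x_total=int(counts[0].sum()),
    )
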