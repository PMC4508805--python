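"""RPKM-based stage classification of spermatogenesis genes.

Genes profiled in germline stem cells (GS), pachytene spermatocytes (PS)
and round spermatids (RS) are assigned to stage classes by three joint
criteria on each pairwise comparison: a fold-change threshold (default
4-fold), a significance threshold on the BH-adjusted p-value of an exact
conditional binomial test on the raw count pair (default 0.05), and a
minimum expression level in at least one stage (default RPKM >= 5).
Constitutive classes follow level-only rules: active means RPKM > 5 in
all three stages with less than two-fold spread, inactive means RPKM < 3
in all three stages.

The differential test conditions on the total count of a gene in the two
libraries: under the null of equal per-million rates, the count in
library A given the total n is Binomial(n, lib_a/(lib_a+lib_b)). The
two-sided p-value sums all outcomes no more likely than the observed one
(the "minlike" convention). With no replicates in the design this is the
assumption-lightest exact test available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneAnnotation

__all__ = [
    "STAGES",
    "PAIRS",
    "CLASS_LABELS",
    "ExpressionTable",
    "ClassParams",
    "ClassificationResult",
    "rpkm",
    "filter_expressed",
    "diff_expr_test",
    "bh_adjust",
    "classify_genes",
    "class_summary",
    "read_expression_tsv",
    "write_expression_tsv",
]

STAGES = ("GS", "PS", "RS")
PAIRS = (("GS", "PS"), ("GS", "RS"), ("PS", "RS"))

#: precedence order for the primary label: both-stage classes first, then
#: single-stage classes, then constitutive classes.
CLASS_LABELS = (
    "PS/RS active",
    "PS/RS inactive",
    "PS active",
    "RS active",
    "PS inactive",
    "RS inactive",
    "constitutively active",
    "constitutively inactive",
)


def rpkm(count: float, gene_length: float, library_size: float) -> float:
    """Reads per kilobase of gene model per million mapped reads."""
    if gene_length <= 0:
        raise ValueError(f"gene_length must be > 0, got {gene_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (gene_length / 1_000.0) / (library_size / 1_000_000.0)


@dataclass
class ExpressionTable:
    """Per-gene RPKM across stages, with optional raw counts behind it."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame | None = None
    gene_length: pd.Series | None = None
    library_size: dict[str, int] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.rpkm.columns]
        if missing:
            raise ValueError(f"expression table lacks stage column(s) {missing}")
        if (self.rpkm[list(STAGES)] < 0).any().any():
            raise ValueError("negative RPKM")
        if self.counts is not None:
            if self.gene_length is None or self.library_size is None:
                raise ValueError("counts require gene_length and library_size")
            self._check_consistency()

    def _check_consistency(self) -> None:
        for s in STAGES:
            expect = (
                self.counts[s]
                / (self.gene_length / 1_000.0)
                / (self.library_size[s] / 1_000_000.0)
            )
            if not np.allclose(expect, self.rpkm[s], rtol=1e-9, atol=1e-12):
                raise ValueError(f"rpkm inconsistent with counts for stage {s}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        gene_length: pd.Series,
        library_size: Mapping[str, int],
    ) -> "ExpressionTable":
        vals = {
            s: counts[s]
            / (gene_length / 1_000.0)
            / (library_size[s] / 1_000_000.0)
            for s in counts.columns
        }
        return cls(
            rpkm=pd.DataFrame(vals, index=counts.index),
            counts=counts,
            gene_length=gene_length,
            library_size=dict(library_size),
        )


def write_expression_tsv(table: ExpressionTable, path: str) -> None:
    """Write an expression table as TSV; library sizes go into # headers."""
    df = table.rpkm[list(STAGES)].copy()
    if table.counts is not None:
        for s in STAGES:
            df[f"count_{s}"] = table.counts[s]
        df["gene_length"] = table.gene_length
    with open(path, "w") as fh:
        if table.library_size is not None:
            for s in STAGES:
                fh.write(f"# library_size {s}={table.library_size[s]}\n")
        df.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str) -> ExpressionTable:
    lib: dict[str, int] = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("# library_size"):
                key, val = line.split()[2].split("=")
                lib[key] = int(val)
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", index_col="gene_id")
    counts = None
    length = None
    if all(f"count_{s}" in df.columns for s in STAGES) and "gene_length" in df.columns:
        counts = df[[f"count_{s}" for s in STAGES]].rename(
            columns={f"count_{s}": s for s in STAGES}
        )
        length = df["gene_length"]
    return ExpressionTable(
        rpkm=df[list(STAGES)],
        counts=counts,
        gene_length=length,
        library_size=lib or None,
    )


def filter_expressed(table: ExpressionTable, threshold: float = 3.0) -> set[str]:
    """Genes whose maximum stage RPKM strictly exceeds ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    maxr = table.rpkm[list(STAGES)].max(axis=1)
    return set(table.gene_ids[maxr > threshold])


# ---------------------------------------------------------------------------
# exact conditional binomial test


def _binom_two_sided(k: np.ndarray, n: np.ndarray, theta: float) -> np.ndarray:
    """Vectorized two-sided exact binomial p-value (minlike convention).

    For each (k, n): sums Binomial(n, theta) probabilities of all outcomes
    whose probability does not exceed (1 + 1e-7) x that of k. The opposite
    tail boundary is found by bisection on the monotone flank of the pmf.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    out = np.ones(np.broadcast(k, n).shape, dtype=float)
    k, n = np.broadcast_arrays(k, n)
    logt, log1mt = np.log(theta), np.log1p(-theta)

    def logpmf(j, nn):
        return (
            gammaln(nn + 1)
            - gammaln(j + 1)
            - gammaln(nn - j + 1)
            + j * logt
            + (nn - j) * log1mt
        )

    flat_k = k.ravel()
    flat_n = n.ravel()
    res = out.ravel()
    for i in range(flat_k.size):
        ki, ni = int(flat_k[i]), int(flat_n[i])
        if ni == 0:
            continue
        mode = int(np.floor((ni + 1) * theta))
        mode = min(mode, ni)
        d = logpmf(ki, ni) + np.log1p(1e-7)
        if logpmf(mode, ni) <= d:
            continue  # observed value is (numerically) the mode: p = 1
        if ki < mode:
            # smallest j in (mode, n] with pmf(j) <= pmf(k); pmf decreasing there
            lo, hi = mode, ni + 1
            while lo + 1 < hi:
                mid = (lo + hi) // 2
                if logpmf(mid, ni) <= d:
                    hi = mid
                else:
                    lo = mid
            p = binom.cdf(ki, ni, theta)
            if hi <= ni:
                p += binom.sf(hi - 1, ni, theta)
        else:
            # largest j in [0, mode) with pmf(j) <= pmf(k); pmf increasing there
            lo, hi = -1, mode
            while lo + 1 < hi:
                mid = (lo + hi) // 2
                if logpmf(mid, ni) <= d:
                    lo = mid
                else:
                    hi = mid
            p = binom.sf(ki - 1, ni, theta)
            if lo >= 0:
                p += binom.cdf(lo, ni, theta)
        res[i] = min(1.0, float(p))
    return out


def diff_expr_test(
    count_a,
    count_b,
    lib_a: int,
    lib_b: int,
):
    """Exact conditional binomial test for differential expression.

    Given total ``n = count_a + count_b``, tests ``count_a ~ Binomial(n,
    lib_a / (lib_a + lib_b))`` two-sided. Accepts scalars or arrays;
    returns p-values in (0, 1].
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be > 0")
    ka = np.asarray(count_a)
    kb = np.asarray(count_b)
    if np.any(ka < 0) or np.any(kb < 0):
        raise ValueError("negative counts")
    theta = lib_a / (lib_a + lib_b)
    p = _binom_two_sided(ka, ka + kb, theta)
    if p.shape == ():
        return float(p)
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassParams:
    """Thresholds for stage-class assignment.

    fold / alpha_adj / rpkm_min_any gate the differential classes;
    const_active_min / const_active_maxfold / const_inactive_max define the
    constitutive classes; expressed_min is the genome-wide expressed filter
    (strictly greater than).
    """

    fold: float = 4.0
    alpha_adj: float = 0.05
    rpkm_min_any: float = 5.0
    const_active_min: float = 5.0
    const_active_maxfold: float = 2.0
    const_inactive_max: float = 3.0
    expressed_min: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "fold",
            "alpha_adj",
            "rpkm_min_any",
            "const_active_min",
            "const_active_maxfold",
            "const_inactive_max",
            "expressed_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold <= self.const_active_maxfold:
            raise ValueError("fold must exceed const_active_maxfold")


@dataclass
class ClassificationResult:
    """Per-gene labels plus the pairwise evidence behind them.

    ``table`` is indexed by gene_id with columns ``primary_class``,
    ``all_classes`` (tuple of every satisfied label), and per pair (A, B)
    in GS/PS, GS/RS, PS/RS order: ``fc_B_vs_A`` (RPKM ratio B/A),
    ``p_A_B`` and ``padj_A_B``.
    """

    table: pd.DataFrame
    params: ClassParams
    pvalues_available: bool = True

    @property
    def primary(self) -> pd.Series:
        return self.table["primary_class"]

    def genes_in_class(self, label: str, primary_only: bool = True) -> list[str]:
        if primary_only:
            return list(self.table.index[self.table["primary_class"] == label])
        return list(
            self.table.index[
                self.table["all_classes"].map(lambda cs: label in cs)
            ]
        )


def classify_genes(
    table: ExpressionTable,
    annotation: Sequence[GeneAnnotation] | None = None,
    params: ClassParams | None = None,
) -> ClassificationResult:
    """Assign every gene a primary stage class and all satisfied labels.

    A pairwise "up" call up(X, Y) requires RPKM_X >= fold x RPKM_Y, an
    adjusted p <= alpha_adj for the (X, Y) comparison, and a maximum stage
    RPKM >= rpkm_min_any. If no raw counts are available the significance
    criterion cannot be evaluated and is treated as satisfied (with a
    warning); fold-change and level criteria still apply.
    """
    params = params or ClassParams()
    r = table.rpkm[list(STAGES)]
    maxr = r.max(axis=1)
    n = len(r)

    padj: dict[tuple[str, str], np.ndarray] = {}
    praw: dict[tuple[str, str], np.ndarray] = {}
    pvalues_available = table.counts is not None
    for a, b in PAIRS:
        if pvalues_available:
            p = diff_expr_test(
                table.counts[a].to_numpy(),
                table.counts[b].to_numpy(),
                table.library_size[a],
                table.library_size[b],
            )
            p = np.atleast_1d(p)
        else:
            p = np.zeros(n)
        praw[(a, b)] = p
        padj[(a, b)] = bh_adjust(p) if pvalues_available else p
    if not pvalues_available:
        warnings.warn(
            "no raw counts in expression table: significance criterion "
            "treated as satisfied (fold-change and level thresholds only)",
            stacklevel=2,
        )

    def up(x: str, y: str) -> np.ndarray:
        key = (x, y) if (x, y) in padj else (y, x)
        fold_ok = r[x].to_numpy() >= params.fold * r[y].to_numpy()
        return (
            fold_ok
            & (padj[key] <= params.alpha_adj)
            & (maxr.to_numpy() >= params.rpkm_min_any)
        )

    rmat = r.to_numpy()
    const_active = (rmat > params.const_active_min).all(axis=1) & (
        rmat.max(axis=1) < params.const_active_maxfold * rmat.min(axis=1)
    )
    const_inactive = (rmat < params.const_inactive_max).all(axis=1)

    satisfied = {
        "PS/RS active": up("PS", "GS") & up("RS", "GS"),
        "PS active": up("PS", "GS") & up("PS", "RS"),
        "RS active": up("RS", "GS") & up("RS", "PS"),
        "PS/RS inactive": up("GS", "PS") & up("GS", "RS"),
        "PS inactive": up("GS", "PS") & up("RS", "PS"),
        "RS inactive": up("GS", "RS") & up("PS", "RS"),
        "constitutively active": const_active,
        "constitutively inactive": const_inactive,
    }

    primary = np.full(n, "unclassified", dtype=object)
    for label in reversed(CLASS_LABELS):  # earlier labels overwrite later ones
        primary[satisfied[label]] = label

    all_classes = [
        tuple(lbl for lbl in CLASS_LABELS if satisfied[lbl][i]) for i in range(n)
    ]

    out = pd.DataFrame(index=r.index)
    out["primary_class"] = primary
    out["all_classes"] = all_classes
    with np.errstate(divide="ignore", invalid="ignore"):
        for a, b in PAIRS:
            out[f"fc_{b}_vs_{a}"] = r[b].to_numpy() / r[a].to_numpy()
            out[f"p_{a}_{b}"] = praw[(a, b)]
            out[f"padj_{a}_{b}"] = padj[(a, b)]
    return ClassificationResult(
        table=out, params=params, pvalues_available=pvalues_available
    )


def class_summary(
    result: ClassificationResult,
    annotation: Sequence[GeneAnnotation],
    y_chrom_name: str = "chrY",
) -> pd.DataFrame:
    """Counts per class x {autosomal, X}; Y-linked genes are excluded.

    Every gene in the result must be present in the annotation.
    """
    by_id = {g.gene_id: g for g in annotation}
    missing = [gid for gid in result.table.index if gid not in by_id]
    if missing:
        raise KeyError(f"gene(s) absent from annotation: {missing[:5]}")
    rows = list(CLASS_LABELS) + ["unclassified"]
    counts = pd.DataFrame(0, index=rows, columns=["autosomal", "X"])
    for gid, label in result.primary.items():
        g = by_id[gid]
        if g.chrom == y_chrom_name:
            continue
        counts.loc[label, "X" if g.is_x else "autosomal"] += 1
    return counts
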