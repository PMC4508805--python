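"""Fragment-length estimation, tag shifting, and tag-density profiles.

ChIP-seq tags mark the 5' end of sequenced fragments, so plus- and
minus-strand tag pileups flank the true protein footprint by one
fragment length. The fragment length is estimated by maximizing, over a
lag range, the Pearson correlation between the per-base plus-strand
5'-end counts and the minus-strand counts shifted towards them; tags are
then shifted by half the estimated length towards the fragment centre
before any counting.

Two profile anchors are supported. TSS-anchored matrices count shifted
tags in fixed windows tiled across +/- span around each TSS, oriented
5'->3' (minus-strand genes mirrored). Scaled gene-body (metagene)
matrices divide each gene body TSS..TES into a fixed number of equal
fractions flanked by fixed-width windows, so genes of different lengths
are averaged on a common axis. Densities are reported as tags per kb
per million mapped tags throughout, which makes curves comparable
across libraries.

Average profiles over a gene set are unweighted means of the per-gene
rows; curves sampled at a step finer than the window width are smoothed
with a centred boxcar (truncated at the edges), which reproduces
sliding-window densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .io_formats import GeneAnnotation, TagCollection

__all__ = [
    "ProfileParams",
    "FragmentEstimate",
    "ProfileMatrix",
    "ATDProfile",
    "estimate_fragment_length",
    "shift_tags",
    "tss_density_matrix",
    "average_profile",
    "smooth_profile",
    "metagene_matrix",
    "heatmap_matrix",
]


@dataclass
class ProfileParams:
    """Geometry of the profiles.

    window: density window width in bp (heatmap tiles and smoothing width)
    span: flank extent around the anchor in bp
    step: sampling step for average profiles (sliding-window resolution)
    body_bins / flank_bins: metagene geometry; flank_bins * window == span
    min_gene_length: genes shorter than this are excluded from metagenes
    """

    window: int = 200
    span: int = 5_000
    step: int = 50
    body_bins: int = 60
    flank_bins: int = 25
    normalization: str = "tags_per_kb_per_million"
    min_gene_length: int = 600

    def __post_init__(self) -> None:
        if self.window % self.step != 0:
            raise ValueError("window must be a multiple of step")
        if self.span % self.window != 0:
            raise ValueError("span must be a multiple of window")
        if self.flank_bins * self.window != self.span:
            raise ValueError("flank_bins * window must equal span")
        if self.normalization != "tags_per_kb_per_million":
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class FragmentEstimate:
    length: int
    lags: np.ndarray
    lag_correlations: np.ndarray
    flat: bool = False


@dataclass
class ProfileMatrix:
    """Per-gene binned density matrix, rows oriented 5'->3'."""

    gene_ids: list[str]
    offsets: np.ndarray  # bin start offsets (bp for TSS anchor, bin index for scaled)
    values: np.ndarray  # (n_genes, n_bins) density, tags/kb/million
    anchor: str  # "TSS" or "scaled-body"
    bin_width: int
    body_bins: int = 0
    flank_bins: int = 0
    excluded: list[str] = field(default_factory=list)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.offsets,
        )


@dataclass
class ATDProfile:
    """Average tag density over a gene set."""

    x_offsets: np.ndarray  # bin centers
    values: np.ndarray
    n_genes: int
    anchor: str = "TSS"
    smoothed: bool = False


# ---------------------------------------------------------------------------
# fragment length


def estimate_fragment_length(
    tags: TagCollection, lag_range: tuple[int, int] = (50, 500)
) -> FragmentEstimate:
    """Strand cross-correlation estimate of the sequenced fragment length.

    For each lag, minus-strand 5'-end counts are shifted left by lag - 1
    and Pearson-correlated with the plus-strand counts, pooling pairs over
    all chromosomes; the returned length is the argmax lag (smallest on
    ties). If the correlation peak does not rise above the null
    fluctuation scale (4 / sqrt(n pairs)) the profile is considered flat:
    a warning is issued and the midpoint of the range is returned.
    """
    lo, hi = lag_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid lag range {lag_range}")
    plus = tags.positions_by_chrom("+")
    minus = tags.positions_by_chrom("-")
    if not plus or not minus:
        raise ValueError("both strands must be represented to estimate fragment length")

    lags = np.arange(lo, hi + 1)
    ds = lags - 1  # minus offset relative to plus
    nl = lags.size
    N = np.zeros(nl)
    SX = np.zeros(nl)
    SY = np.zeros(nl)
    SXX = np.zeros(nl)
    SYY = np.zeros(nl)
    SXY = np.zeros(nl)

    for chrom in set(plus) & set(minus):
        p = plus[chrom]
        m = minus[chrom]
        n = int(max(p.max(), m.max())) + 1
        valid = ds <= n - 2  # at least two (x, y) pairs at this offset
        if not valid.any():
            continue
        dv = ds[valid]
        x = np.bincount(p, minlength=n).astype(float)
        y = np.bincount(m, minlength=n).astype(float)
        # cross products for every offset at once: corr[n-1+d] = sum_i x[i] y[i+d]
        corr = fftconvolve(y, x[::-1])
        sxy = corr[n - 1 + dv]
        cx = np.concatenate([[0.0], np.cumsum(x)])
        cy = np.concatenate([[0.0], np.cumsum(y)])
        cxx = np.concatenate([[0.0], np.cumsum(x * x)])
        cyy = np.concatenate([[0.0], np.cumsum(y * y)])
        N[valid] += n - dv  # pairs (x[i], y[i+d]), i in [0, n-d)
        SX[valid] += cx[n - dv]  # sum x[0 : n-d]
        SXX[valid] += cxx[n - dv]
        SY[valid] += cy[n] - cy[dv]  # sum y[d : n]
        SYY[valid] += cyy[n] - cyy[dv]
        SXY[valid] += np.round(sxy)  # counts are integers; kill FFT noise

    if not N.any():
        raise ValueError("no chromosome long enough for the requested lag range")
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * SXY - SX * SY
        varx = N * SXX - SX**2
        vary = N * SYY - SY**2
        r = cov / np.sqrt(varx * vary)
    r = np.where(np.isfinite(r), r, -np.inf)

    best = int(np.argmax(r))  # first occurrence == smallest lag on ties
    peak = r[best]
    floor = 4.0 / np.sqrt(max(N[best], 1.0))
    if not np.isfinite(peak) or peak < floor:
        warnings.warn(
            "strand cross-correlation is flat (no distinct peak); "
            "returning the midpoint of the lag range",
            stacklevel=2,
        )
        return FragmentEstimate(
            length=int((lo + hi) // 2), lags=lags, lag_correlations=r, flat=True
        )
    return FragmentEstimate(length=int(lags[best]), lags=lags, lag_correlations=r)


def shift_tags(tags: TagCollection, fragment_length: int) -> TagCollection:
    """Shift tags by half the fragment length towards the fragment centre.

    Plus tags move right, minus tags move left, both by
    ``fragment_length // 2``; positions shifted below 0 are clamped with a
    warning. Library size is unchanged.
    """
    if fragment_length < 0:
        raise ValueError("fragment_length must be >= 0")
    half = fragment_length // 2
    shift = np.where(tags.strand == "+", half, -half)
    new = tags.pos5 + shift
    if np.any(new < 0):
        warnings.warn("shifted tag position(s) < 0 clamped to 0", stacklevel=2)
        new = np.maximum(new, 0)
    return tags.with_positions(new)


# ---------------------------------------------------------------------------
# TSS-anchored profiles


def _norm_factor(library_size: int) -> float:
    if library_size <= 0:
        raise ValueError("library_size must be > 0 to normalize densities")
    return library_size / 1e6


def tss_density_matrix(
    shifted: TagCollection,
    genes: Sequence[GeneAnnotation],
    params: ProfileParams | None = None,
    bin_width: int | None = None,
) -> ProfileMatrix:
    """Per-gene tag densities in fixed windows tiled across TSS +/- span.

    ``bin_width`` defaults to ``params.window`` (heatmap tiles); pass
    ``params.step`` to sample finely for average profiles. Windows
    truncated at the chromosome start are normalized by the width they
    actually cover.
    """
    params = params or ProfileParams()
    bw = bin_width or params.window
    span = params.span
    if span % bw != 0:
        raise ValueError("span must be a multiple of bin_width")
    ncols = 2 * span // bw
    lib = _norm_factor(shifted.library_size)
    by_chrom = shifted.positions_by_chrom()

    values = np.zeros((len(genes), ncols))
    gene_ids = [g.gene_id for g in genes]
    empty = np.empty(0, dtype=np.int64)
    for i, g in enumerate(genes):
        pos = by_chrom.get(g.chrom, empty)
        if g.strand == "+":
            lo = np.searchsorted(pos, g.tss - span, side="left")
            hi = np.searchsorted(pos, g.tss + span, side="left")
            offs = pos[lo:hi] - g.tss
            win_starts = g.tss - span + np.arange(ncols) * bw
        else:
            lo = np.searchsorted(pos, g.tss - span + 1, side="left")
            hi = np.searchsorted(pos, g.tss + span + 1, side="left")
            offs = g.tss - pos[lo:hi]
            # genomic window for column k is (tss - (k+1)*bw + span, tss - k*bw + span]
            win_starts = g.tss + span - (np.arange(ncols) + 1) * bw + 1
        counts = np.bincount((offs + span) // bw, minlength=ncols)[:ncols]
        covered = np.clip(win_starts + bw, 0, None) - np.clip(win_starts, 0, None)
        covered = np.clip(covered, 0, bw)
        with np.errstate(divide="ignore", invalid="ignore"):
            row = counts / (covered / 1_000.0) / lib
        values[i] = np.where(covered > 0, row, 0.0)

    return ProfileMatrix(
        gene_ids=gene_ids,
        offsets=np.arange(-span, span, bw),
        values=values,
        anchor="TSS",
        bin_width=bw,
    )


def average_profile(
    matrix: ProfileMatrix, gene_set: Iterable[str] | None = None
) -> ATDProfile:
    """Unweighted mean density over a gene set (default: all rows)."""
    if gene_set is None:
        rows = np.arange(len(matrix.gene_ids))
    else:
        wanted = set(gene_set)
        missing = wanted - set(matrix.gene_ids)
        if missing:
            raise KeyError(f"gene(s) not in matrix: {sorted(missing)[:5]}")
        rows = np.array(
            [i for i, gid in enumerate(matrix.gene_ids) if gid in wanted]
        )
    if rows.size == 0:
        raise ValueError("empty gene set")
    if matrix.anchor == "TSS":
        centers = matrix.offsets + matrix.bin_width / 2
    else:
        centers = matrix.offsets + 0.5
    return ATDProfile(
        x_offsets=centers,
        values=matrix.values[rows].mean(axis=0),
        n_genes=rows.size,
        anchor=matrix.anchor,
    )


def smooth_profile(profile: ATDProfile, window_bp: int = 200) -> ATDProfile:
    """Centred boxcar smoothing over ``window_bp`` of profile x-axis.

    The number of points averaged is ``window_bp / step`` where step is the
    profile's sampling interval; edge windows are truncated. If the window
    does not exceed the step the profile is returned unchanged with a
    warning.
    """
    x = np.asarray(profile.x_offsets, dtype=float)
    if x.size > 1:
        step = x[1] - x[0]
    else:
        step = float(window_bp)
    npts = int(window_bp // step)
    if npts <= 1:
        warnings.warn(
            "smoothing window does not exceed the sampling step; no-op",
            stacklevel=2,
        )
        return replace(profile, values=profile.values.copy())
    sm = (
        pd.Series(profile.values)
        .rolling(window=npts, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ATDProfile(
        x_offsets=x.copy(),
        values=sm,
        n_genes=profile.n_genes,
        anchor=profile.anchor,
        smoothed=True,
    )


# ---------------------------------------------------------------------------
# scaled gene-body metagene


def _metagene_bounds(g: GeneAnnotation, params: ProfileParams) -> tuple[np.ndarray, np.ndarray]:
    """Genomic [start, end) bounds of every metagene column, 5'->3' order."""
    w = params.window
    span = params.span
    B = params.body_bins
    L = g.length
    up = np.arange(params.flank_bins)
    body = np.arange(B)
    down = np.arange(params.flank_bins)

    def ceil_div(a, b):
        return -(-a // b)

    body_edges = np.array([ceil_div(j * L, B) for j in range(B + 1)], dtype=np.int64)
    if g.strand == "+":
        starts = np.concatenate(
            [
                g.start - span + up * w,
                g.start + body_edges[:-1],
                g.end + down * w,
            ]
        )
        ends = np.concatenate(
            [
                g.start - span + (up + 1) * w,
                g.start + body_edges[1:],
                g.end + (down + 1) * w,
            ]
        )
    else:
        starts = np.concatenate(
            [
                g.end + span - (up + 1) * w,
                g.end - body_edges[1:],
                g.start - (down + 1) * w,
            ]
        )
        ends = np.concatenate(
            [
                g.end + span - up * w,
                g.end - body_edges[:-1],
                g.start - down * w,
            ]
        )
    return starts, ends


def metagene_matrix(
    shifted: TagCollection,
    genes: Sequence[GeneAnnotation],
    params: ProfileParams | None = None,
) -> ProfileMatrix:
    """Scaled gene-body density matrix: flank | body (scaled) | flank.

    The body TSS..TES is divided into ``body_bins`` equal fractions and
    each bin is normalized by the width it actually covers; flanks are
    fixed ``window``-bp bins. Genes shorter than ``min_gene_length`` are
    excluded and reported on the returned matrix.
    """
    params = params or ProfileParams()
    lib = _norm_factor(shifted.library_size)
    keep = [g for g in genes if g.length >= params.min_gene_length]
    excluded = [g.gene_id for g in genes if g.length < params.min_gene_length]
    if not keep:
        raise ValueError("all genes shorter than min_gene_length")
    ncols = params.body_bins + 2 * params.flank_bins
    by_chrom = shifted.positions_by_chrom()
    values = np.zeros((len(keep), ncols))
    empty = np.empty(0, dtype=np.int64)
    for i, g in enumerate(keep):
        pos = by_chrom.get(g.chrom, empty)
        starts, ends = _metagene_bounds(g, params)
        counts = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        covered = np.clip(ends, 0, None) - np.clip(starts, 0, None)
        covered = np.clip(covered, 0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            row = counts / (covered / 1_000.0) / lib
        values[i] = np.where(covered > 0, row, 0.0)
    return ProfileMatrix(
        gene_ids=[g.gene_id for g in keep],
        offsets=np.arange(ncols),
        values=values,
        anchor="scaled-body",
        bin_width=params.window,
        body_bins=params.body_bins,
        flank_bins=params.flank_bins,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# heatmap ordering


def heatmap_matrix(
    matrix: ProfileMatrix,
    sort_key="mean_density",
) -> ProfileMatrix:
    """Reorder rows descending by key (ties broken by gene_id, stable).

    ``sort_key`` is either the string ``"mean_density"`` or a mapping /
    Series gene_id -> value covering every row.
    """
    if isinstance(sort_key, str):
        if sort_key != "mean_density":
            raise ValueError(f"unknown sort key {sort_key!r}")
        key = matrix.values.mean(axis=1)
    else:
        getter = sort_key.get if hasattr(sort_key, "get") else None
        vals = []
        for gid in matrix.gene_ids:
            v = getter(gid) if getter else sort_key[gid]
            if v is None:
                raise KeyError(f"sort key missing entry for {gid!r}")
            vals.append(float(v))
        key = np.array(vals)
    ids = np.array(matrix.gene_ids, dtype=object)
    order = np.lexsort((ids, -key))
    return ProfileMatrix(
        gene_ids=list(ids[order]),
        offsets=matrix.offsets.copy(),
        values=matrix.values[order],
        anchor=matrix.anchor,
        bin_width=matrix.bin_width,
        body_bins=matrix.body_bins,
        flank_bins=matrix.flank_bins,
        excluded=list(matrix.excluded),
    )
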