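"""Synthetic annotation, expression and ChIP-seq tag data.

The generator plants the structures the downstream analysis is designed
to detect, at a desk scale that runs in seconds: a small genome of two
autosomes plus chrX; per-stage RPKM tables with genes drawn from the
eight stage classes (including an excess of RS-active genes on the X,
emulating postmeiotic escape-gene enrichment); and stranded tag files in
which fragments are placed by a mark-specific spatial shape (a TSS-focal
Gaussian for promoter marks such as H3K4me3/RNAPII, a uniform gene-body
distribution for broad marks such as H3K4me2, or pure background for
input-like tracks), each fragment emitting a single tag on a random
strand at the fragment end so the plus/minus offset encodes the planted
fragment length.

Expression noise is multiplicative log-normal on the class-mean RPKM,
followed by Poisson sampling of raw counts; the table's RPKM column is
recomputed from the sampled counts so counts and RPKM stay consistent.

All generators are deterministic functions of ``SyntheticSpec.seed``;
each generator derives an independent stream from the seed plus a fixed
per-generator salt, so adding one simulation does not shift another.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CLASS_LABELS, ExpressionTable, STAGES
from .io_formats import GeneAnnotation, TagCollection

__all__ = [
    "SyntheticSpec",
    "ACTIVE_STAGES",
    "DEFAULT_CLASS_PROPORTIONS",
    "DEFAULT_MARK_SHAPES",
    "make_annotation",
    "simulate_expression",
    "simulate_tags",
    "chrom_sizes_from_annotation",
    "derive_seed",
]

#: stages in which each planted class is transcriptionally active; active
#: chromatin marks follow this activity in the tag simulator.
ACTIVE_STAGES: dict[str, frozenset] = {
    "PS/RS active": frozenset({"PS", "RS"}),
    "PS active": frozenset({"PS"}),
    "RS active": frozenset({"RS"}),
    "PS/RS inactive": frozenset({"GS"}),
    "PS inactive": frozenset({"GS", "RS"}),
    "RS inactive": frozenset({"GS", "PS"}),
    "constitutively active": frozenset(STAGES),
    "constitutively inactive": frozenset(),
}

# Autosomal class mix loosely mirroring the genome-wide proportions of the
# profiled mouse stages (a large constitutively silent majority, ~1/6 of
# genes switching on and ~1/6 switching off across the transition).
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "PS/RS active": 0.17,
    "PS/RS inactive": 0.16,
    "PS active": 0.04,
    "RS active": 0.02,
    "PS inactive": 0.03,
    "RS inactive": 0.03,
    "constitutively active": 0.06,
    "constitutively inactive": 0.49,
}

DEFAULT_MARK_SHAPES: dict[str, dict] = {
    "H3K4me3": {"kind": "tss_peak", "sd": 100},
    "RNAPII": {"kind": "tss_peak", "sd": 80},
    "Kcr": {"kind": "tss_peak", "sd": 150},
    "H3K4me2": {"kind": "body_broad"},
    "input": {"kind": "background"},
}


def derive_seed(seed: int, salt: str) -> int:
    """Stable per-stream seed below 2**31, from a master seed and a name."""
    return (int(seed) ^ zlib.crc32(salt.encode())) % (2**31)


@dataclass
class SyntheticSpec:
    """Parameters of the planted study conditions."""

    n_autosomal_genes: int = 900
    n_x_genes: int = 100
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    x_rs_active_fraction: float = 0.10
    base_rpkm: float = 20.0
    fold_change: float = 10.0
    rpkm_noise_cv: float = 0.2
    fragment_length: int = 150
    tags_per_gene_mean: float = 50.0
    mark_shapes: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARK_SHAPES.items()}
    )
    enrichment_ratio: float = 8.0
    rna_library_size: int = 20_000_000
    min_gene_length: int = 2_000
    max_gene_length: int = 50_000
    n_autosomes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autosomal_genes < 0 or self.n_x_genes < 0:
            raise ValueError("gene counts must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class label(s) {sorted(unknown)}")
        if self.fragment_length < 50:
            raise ValueError("fragment_length must be >= 50")
        if self.enrichment_ratio < 1:
            raise ValueError("enrichment_ratio must be >= 1")
        if not 0 <= self.x_rs_active_fraction <= 1:
            raise ValueError("x_rs_active_fraction must be in [0, 1]")
        if self.min_gene_length < 1 or self.max_gene_length < self.min_gene_length:
            raise ValueError("invalid gene length range")


def make_annotation(
    spec: SyntheticSpec,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GeneAnnotation]:
    """Place non-overlapping genes on ``n_autosomes`` autosomes plus chrX.

    Gene lengths are log-uniform on [min_gene_length, max_gene_length];
    intergenic gaps are uniform on [5, 20] kb. If ``chrom_sizes`` is given
    and the genes do not fit, raises.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "annotation"))
    chroms = [f"chr{i + 1}" for i in range(spec.n_autosomes)] + ["chrX"]
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(spec.n_autosomal_genes):
        per_chrom[chroms[i % spec.n_autosomes]] += 1
    per_chrom["chrX"] = spec.n_x_genes

    genes: list[GeneAnnotation] = []
    aut_idx = x_idx = 0
    for chrom in chroms:
        n = per_chrom[chrom]
        pos = int(rng.integers(5_000, 20_001))
        for _ in range(n):
            length = int(
                round(
                    np.exp(
                        rng.uniform(
                            np.log(spec.min_gene_length),
                            np.log(spec.max_gene_length),
                        )
                    )
                )
            )
            strand = "+" if rng.random() < 0.5 else "-"
            if chrom == "chrX":
                x_idx += 1
                gid = f"gX{x_idx:05d}"
            else:
                aut_idx += 1
                gid = f"gA{aut_idx:05d}"
            end = pos + length
            if chrom_sizes is not None and end > chrom_sizes[chrom]:
                raise ValueError(
                    f"genome too small: gene {gid} would end at {end} on "
                    f"{chrom} (size {chrom_sizes[chrom]})"
                )
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    chrom=chrom,
                    start=pos,
                    end=end,
                    strand=strand,
                    is_x=(chrom == "chrX"),
                )
            )
            pos = end + int(rng.integers(5_000, 20_001))
    return genes


def chrom_sizes_from_annotation(
    genes: Sequence[GeneAnnotation], margin: int = 10_000
) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end + margin)
    return sizes


def _class_means(label: str, base: float, fold: float) -> tuple[float, float, float]:
    """(GS, PS, RS) mean RPKM for a planted class."""
    b = base
    table = {
        "PS/RS active": (b, b * fold, b * fold),
        "PS active": (b, b * fold, b),
        "RS active": (b, b, b * fold),
        "PS/RS inactive": (b, b / fold, b / fold),
        "PS inactive": (b, b / fold, b),
        "RS inactive": (b, b, b / fold),
        "constitutively active": (b, b, b),
        "constitutively inactive": (0.5, 0.5, 0.5),
    }
    return table[label]


def _assign_classes(spec: SyntheticSpec, genes, rng) -> pd.Series:
    labels = np.array(list(spec.class_proportions), dtype=object)
    probs = np.array([spec.class_proportions[l] for l in labels], dtype=float)
    probs = probs / probs.sum()

    # X genes: RS-active planted at x_rs_active_fraction, the remainder
    # drawn from the autosomal mix with RS-active removed.
    x_labels = labels[labels != "RS active"]
    x_probs = probs[labels != "RS active"]
    x_probs = x_probs / x_probs.sum()

    gene_ids = [g.gene_id for g in genes]
    is_x = np.array([g.is_x for g in genes], dtype=bool)
    assigned = np.empty(len(genes), dtype=object)
    n_aut = int((~is_x).sum())
    n_x = int(is_x.sum())
    if n_aut:
        assigned[~is_x] = rng.choice(labels, size=n_aut, p=probs)
    if n_x:
        x_assigned = rng.choice(x_labels, size=n_x, p=x_probs)
        rs_mask = rng.random(n_x) < spec.x_rs_active_fraction
        x_assigned[rs_mask] = "RS active"
        assigned[is_x] = x_assigned
    return pd.Series(assigned, index=gene_ids, name="planted_class")


def simulate_expression(
    spec: SyntheticSpec, annotation: Sequence[GeneAnnotation]
) -> tuple[ExpressionTable, pd.Series]:
    """Simulate a three-stage count/RPKM table with planted classes.

    Returns the table and the per-gene truth labels. With
    ``rpkm_noise_cv = 0`` the log-normal factor is 1 and the Poisson draw
    is replaced by the rounded expectation, so class means are exact.
    """
    if spec.fold_change < 4 and spec.rpkm_noise_cv == 0:
        warnings.warn(
            "fold_change < 4: planted differential classes cannot satisfy "
            "the 4-fold rule",
            stacklevel=2,
        )
    rng = np.random.default_rng(derive_seed(spec.seed, "expression"))
    truth = _assign_classes(spec, annotation, rng)
    gene_ids = [g.gene_id for g in annotation]
    lengths = pd.Series({g.gene_id: g.length for g in annotation}, name="gene_length")
    lib = {s: spec.rna_library_size for s in STAGES}

    cv = spec.rpkm_noise_cv
    sigma = np.sqrt(np.log1p(cv**2))
    means = np.array(
        [_class_means(truth[gid], spec.base_rpkm, spec.fold_change) for gid in gene_ids]
    )
    noisy = means
    if cv > 0:
        noisy = means * rng.lognormal(
            mean=-(sigma**2) / 2, sigma=sigma, size=means.shape
        )
    lam = noisy * lengths.to_numpy()[:, None] * spec.rna_library_size / 1e9
    # at CV = 0 the Poisson draw is replaced by the expectation so class
    # means are exact and the planted classes are recovered deterministically
    raw = np.round(lam).astype(np.int64) if cv == 0 else rng.poisson(lam)
    counts = pd.DataFrame(
        raw, index=pd.Index(gene_ids, name="gene_id"), columns=list(STAGES)
    )
    table = ExpressionTable.from_counts(counts, lengths.loc[gene_ids], lib)
    truth = truth.loc[gene_ids]
    return table, truth


def simulate_tags(
    spec: SyntheticSpec,
    annotation: Sequence[GeneAnnotation],
    truth: pd.Series,
    mark: str,
    stage: str,
    enrichment_override: Mapping[str, float] | None = None,
) -> TagCollection:
    """Simulate one mark x stage tag collection.

    Per gene, the expected total tag yield is ``tags_per_gene_mean``; a
    fraction 1 - 1/r of it is placed by the mark's spatial shape and the
    rest joins a genome-wide uniform background pool, where r is
    ``enrichment_ratio`` for genes active at this stage and 1 otherwise
    (so r = 1 means pure background and a flat profile). Each fragment of
    length L centred at m emits one tag on a random strand: a plus tag at
    m - L//2 or a minus tag at m - L//2 + L - 1, so the strand offset
    recovers L exactly.

    ``enrichment_override`` maps gene_id -> ratio and models genotype
    effects (e.g. a knockout in which escape genes lose their enrichment).
    """
    shape = spec.mark_shapes.get(mark)
    if shape is None or shape.get("kind") not in ("tss_peak", "body_broad", "background"):
        raise ValueError(f"unknown mark or shape for {mark!r}")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(derive_seed(spec.seed, f"tags:{mark}:{stage}"))
    sizes = chrom_sizes_from_annotation(annotation)
    kind = shape["kind"]
    fl = spec.fragment_length
    half = fl // 2

    chroms: list[np.ndarray] = []
    mids: list[np.ndarray] = []
    n_background = 0.0
    for g in annotation:
        label = truth[g.gene_id]
        r = (
            spec.enrichment_ratio
            if stage in ACTIVE_STAGES[label]
            else 1.0
        )
        if enrichment_override is not None and g.gene_id in enrichment_override:
            r = float(enrichment_override[g.gene_id])
        if kind == "background":
            r = 1.0
        n_total = rng.poisson(spec.tags_per_gene_mean)
        n_sig = rng.binomial(n_total, 1.0 - 1.0 / r) if r > 1 else 0
        n_background += n_total - n_sig
        if n_sig == 0:
            continue
        if kind == "tss_peak":
            sd = float(shape.get("sd", 100))
            m = rng.normal(loc=g.tss, scale=sd, size=n_sig)
        else:  # body_broad
            m = rng.integers(g.start, g.end, size=n_sig).astype(float)
        m = np.clip(np.round(m), 0, sizes[g.chrom] - 1).astype(np.int64)
        mids.append(m)
        chroms.append(np.full(n_sig, g.chrom, dtype=object))

    # genome-wide uniform background
    n_bg = int(n_background)
    if n_bg > 0:
        names = list(sizes)
        lens = np.array([sizes[c] for c in names], dtype=float)
        pick = rng.choice(len(names), size=n_bg, p=lens / lens.sum())
        pos = rng.integers(0, lens[pick].astype(np.int64))
        mids.append(pos.astype(np.int64))
        chroms.append(np.array([names[i] for i in pick], dtype=object))

    if mids:
        mid = np.concatenate(mids)
        chrom = np.concatenate(chroms)
    else:
        mid = np.empty(0, dtype=np.int64)
        chrom = np.empty(0, dtype=object)

    plus = rng.random(mid.size) < 0.5
    pos5 = np.where(plus, mid - half, mid - half + fl - 1)
    pos5 = np.maximum(pos5, 0)
    strand = np.where(plus, "+", "-").astype("<U1")
    return TagCollection(
        mark=mark,
        stage=stage,
        chrom=chrom,
        pos5=pos5.astype(np.int64),
        strand=strand,
        library_size=mid.size,
    )
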