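import numpy as np
import pandas as pd
import pytest

from meiochip.io_formats import GeneAnnotation, TagCollection
from meiochip.profiles import (
    ATDProfile,
    ProfileParams,
    average_profile,
    estimate_fragment_length,
    heatmap_matrix,
    metagene_matrix,
    shift_tags,
    smooth_profile,
    tss_density_matrix,
)
from meiochip.synthetic import SyntheticSpec, make_annotation, simulate_tags

from conftest import make_tags, minus_gene, plus_gene


# ---------------------------------------------------------------------------
# brute-force oracles: naive per-gene, per-window counting straight from the
# genomic definition of each window, independent of the implementation


def oracle_tss_matrix(tags, genes, span, bw, lib):
    ncols = 2 * span // bw
    out = np.zeros((len(genes), ncols))
    for i, g in enumerate(genes):
        on_chrom = tags.pos5[np.asarray(tags.chrom, dtype=object) == g.chrom]
        for k in range(ncols):
            off_lo = k * bw - span  # 5'->3' offset window [off_lo, off_lo + bw)
            if g.strand == "+":
                gstart, gend = g.tss + off_lo, g.tss + off_lo + bw
            else:
                gstart, gend = g.tss - (off_lo + bw) + 1, g.tss - off_lo + 1
            count = int(np.sum((on_chrom >= gstart) & (on_chrom < gend)))
            lo, hi = max(0, gstart), gend
            width = max(0, hi - lo)
            out[i, k] = 0.0 if width == 0 else count / (width / 1e3) / (lib / 1e6)
    return out


def oracle_metagene(tags, genes, params, lib):
    B, F, w, span = params.body_bins, params.flank_bins, params.window, params.span
    ncols = B + 2 * F
    keep = [g for g in genes if g.length >= params.min_gene_length]
    out = np.zeros((len(keep), ncols))

    chrom_arr = np.asarray(tags.chrom, dtype=object)

    def count_in(g, gstart, gend):
        on_chrom = tags.pos5[chrom_arr == g.chrom]
        return int(np.sum((on_chrom >= max(0, gstart)) & (on_chrom < gend)))

    for i, g in enumerate(keep):
        L = g.length
        for col in range(ncols):
            if col < F:  # upstream flank, 5'->3' window index col
                s_lo, s_hi = col * w - span, (col + 1) * w - span
            elif col < F + B:  # body fraction
                j = col - F
                s_lo = -(-(j * L) // B)
                s_hi = -(-((j + 1) * L) // B)
            else:  # downstream flank
                k = col - F - B
                s_lo, s_hi = L + k * w, L + (k + 1) * w
            if g.strand == "+":
                gstart, gend = g.start + s_lo, g.start + s_hi
            else:
                gstart, gend = g.end - s_hi, g.end - s_lo
            count = count_in(g, gstart, gend)
            width = max(0, gend - max(0, gstart))
            out[i, col] = 0.0 if width == 0 else count / (width / 1e3) / (lib / 1e6)
    return out


def random_instance(rng, n_genes=8, n_tags=400):
    genes = []
    pos = 6000
    for i in range(n_genes):
        length = int(rng.integers(700, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(f"g{i}", "chr1", pos, pos + length, strand)
        )
        pos += length + int(rng.integers(100, 3000))
    tags = make_tags(
        "chr1",
        rng.integers(0, pos + 6000, size=n_tags),
        rng.choice(["+", "-"], size=n_tags),
    )
    return genes, tags


# ---------------------------------------------------------------------------


class TestFragmentLength:
    def test_constructed_offset(self):
        tags = make_tags(
            "chr1",
            [100, 200, 300, 249, 349, 449],
            ["+", "+", "+", "-", "-", "-"],
        )
        est = estimate_fragment_length(tags, (50, 500))
        assert est.length == 150
        assert not est.flat

    def test_white_noise_warns_and_returns_midpoint(self):
        rng = np.random.default_rng(42)
        n = 40_000
        tags = make_tags(
            "chr1",
            rng.integers(0, 2_000_000, size=n),
            rng.choice(["+", "-"], size=n),
        )
        with pytest.warns(UserWarning, match="flat"):
            est = estimate_fragment_length(tags, (50, 500))
        assert est.flat and est.length == 275

    def test_single_strand_rejected(self):
        tags = make_tags("chr1", [1, 2, 3], ["+", "+", "+"])
        with pytest.raises(ValueError, match="strand"):
            estimate_fragment_length(tags)

    @pytest.mark.parametrize("planted", [120, 180])
    def test_recovery_from_synthetic_tags(self, planted):
        spec = SyntheticSpec(
            n_autosomal_genes=150, n_x_genes=0, fragment_length=planted,
            tags_per_gene_mean=100, enrichment_ratio=50,
            mark_shapes={"m": {"kind": "tss_peak", "sd": 20}},
            class_proportions={"constitutively active": 1.0},
            seed=planted,
        )
        genes = make_annotation(spec)
        truth = pd.Series({g.gene_id: "constitutively active" for g in genes})
        tags = simulate_tags(spec, genes, truth, "m", "GS")
        assert len(tags) >= 10_000
        est = estimate_fragment_length(tags)
        assert abs(est.length - planted) <= 5


class TestShiftTags:
    def test_half_fragment_shift_each_strand(self):
        tags = make_tags("chr1", [100, 249], ["+", "-"])
        shifted = shift_tags(tags, 150)
        assert list(shifted.pos5) == [175, 174]
        assert shifted.library_size == tags.library_size

    def test_zero_is_identity(self):
        tags = make_tags("chr1", [5, 10], ["+", "-"])
        assert list(shift_tags(tags, 0).pos5) == [5, 10]

    def test_negative_positions_clamped_with_warning(self):
        tags = make_tags("chr1", [10], ["-"])
        with pytest.warns(UserWarning, match="clamp"):
            shifted = shift_tags(tags, 100)
        assert shifted.pos5[0] == 0


class TestTssDensityMatrix:
    def test_single_tag_plus_gene(self):
        g = plus_gene(tss=10_000)
        tags = make_tags("chr1", [10_050], ["+"], library_size=10**6)
        m = tss_density_matrix(tags, [g], ProfileParams())
        col = list(m.offsets).index(0)
        assert m.values[0, col] == pytest.approx(5.0)  # 1 / 0.2 kb / 1 M
        assert m.values[0].sum() == pytest.approx(5.0)

    def test_minus_gene_mirrored(self):
        g = minus_gene(tss=10_000)
        tags = make_tags("chr1", [9_950], ["+"], library_size=10**6)
        m = tss_density_matrix(tags, [g], ProfileParams())
        col = list(m.offsets).index(0)  # offset bin [0, 200) downstream of TSS
        assert m.values[0, col] == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        params = ProfileParams(window=100, span=1_000, step=50, flank_bins=10)
        for _ in range(10):
            genes, tags = random_instance(rng)
            m = tss_density_matrix(tags, genes, params)
            ref = oracle_tss_matrix(tags, genes, 1_000, 100, tags.library_size)
            np.testing.assert_allclose(m.values, ref, rtol=1e-12)

    def test_normalization_scales(self):
        g = plus_gene(tss=10_000)
        tags = make_tags("chr1", [10_050, 10_060], ["+", "+"], library_size=100)
        dense = tss_density_matrix(tags, [g], ProfileParams())
        doubled = make_tags(
            "chr1", [10_050, 10_060, 10_050, 10_060], ["+"] * 4, library_size=200
        )
        same = tss_density_matrix(doubled, [g], ProfileParams())
        np.testing.assert_allclose(same.values, dense.values)
        more = make_tags(
            "chr1", [10_050, 10_060, 10_050, 10_060], ["+"] * 4, library_size=100
        )
        np.testing.assert_allclose(
            tss_density_matrix(more, [g], ProfileParams()).values, 2 * dense.values
        )

    def test_orientation_mirror_invariance(self):
        rng = np.random.default_rng(3)
        tss = 50_000
        pos = rng.integers(tss - 4_000, tss + 4_000, size=200)
        fwd = plus_gene(tss=tss, length=3_000, gene_id="g")
        rev = GeneAnnotation("g", "chr1", tss - 2_999, tss + 1, "-")
        tags_fwd = make_tags("chr1", pos, ["+"] * 200)
        tags_rev = make_tags("chr1", 2 * tss - pos, ["+"] * 200)
        m_fwd = tss_density_matrix(tags_fwd, [fwd], ProfileParams())
        m_rev = tss_density_matrix(tags_rev, [rev], ProfileParams())
        np.testing.assert_allclose(m_fwd.values, m_rev.values)


class TestAverageAndSmooth:
    def test_identical_rows_average_to_the_row(self):
        row = np.arange(10.0)
        m = tss_matrix_like(np.stack([row, row]))
        atd = average_profile(m)
        np.testing.assert_allclose(atd.values, row)
        assert atd.n_genes == 2

    def test_singleton_set_is_identity(self):
        m = tss_matrix_like(np.array([[1.0, 2.0], [5.0, 9.0]]), span=100)
        atd = average_profile(m, ["g0"])
        np.testing.assert_allclose(atd.values, [1.0, 2.0])

    def test_stratified_means_recombine(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 8))
        m = tss_matrix_like(vals, span=400)
        sub_a = average_profile(m, [f"g{i}" for i in range(4)])
        sub_b = average_profile(m, ["g4", "g5"])
        total = average_profile(m)
        np.testing.assert_allclose(
            total.values, (4 * sub_a.values + 2 * sub_b.values) / 6
        )

    def test_empty_set_rejected(self):
        m = tss_matrix_like(np.ones((2, 2)), span=100)
        with pytest.raises(ValueError, match="empty"):
            average_profile(m, [])

    def test_boxcar_with_truncated_edges(self):
        profile = ATDProfile(
            x_offsets=np.array([0.0, 50.0, 100.0]), values=np.array([0.0, 3.0, 0.0]),
            n_genes=1,
        )
        sm = smooth_profile(profile, window_bp=150)  # 3-point boxcar
        np.testing.assert_allclose(sm.values, [1.5, 1.0, 1.5])
        assert sm.smoothed

    def test_constant_profile_unchanged(self):
        profile = ATDProfile(
            x_offsets=np.arange(0, 500, 50.0), values=np.full(10, 2.5), n_genes=1
        )
        np.testing.assert_allclose(
            smooth_profile(profile, 200).values, np.full(10, 2.5)
        )

    def test_interior_mass_conserved(self):
        rng = np.random.default_rng(8)
        vals = rng.random(60)
        profile = ATDProfile(
            x_offsets=np.arange(60) * 50.0, values=vals, n_genes=1
        )
        sm = smooth_profile(profile, window_bp=200)  # 4-point boxcar
        # away from the edges a centred boxcar preserves total mass
        assert sm.values[5:-5].sum() == pytest.approx(
            np.convolve(vals, np.ones(4) / 4, mode="same")[5:-5].sum(), rel=1e-9
        )

    def test_window_not_exceeding_step_warns(self):
        profile = ATDProfile(
            x_offsets=np.arange(0, 1000, 200.0), values=np.ones(5), n_genes=1
        )
        with pytest.warns(UserWarning):
            sm = smooth_profile(profile, window_bp=200)
        np.testing.assert_allclose(sm.values, profile.values)


def tss_matrix_like(values, span=None):
    from meiochip.profiles import ProfileMatrix

    values = np.asarray(values, dtype=float)
    n, ncols = values.shape
    span = span if span is not None else ncols * 100 // 2
    bw = 2 * span // ncols
    return ProfileMatrix(
        gene_ids=[f"g{i}" for i in range(n)],
        offsets=np.arange(-span, span, bw),
        values=values,
        anchor="TSS",
        bin_width=bw,
    )


class TestMetagene:
    def test_uniform_width_gene_matches_fixed_windows(self):
        params = ProfileParams()
        g = plus_gene(tss=100_000, length=params.body_bins * 200, gene_id="g")
        rng = np.random.default_rng(2)
        pos = rng.integers(80_000, 130_000, size=500)
        tags = make_tags("chr1", pos, ["+"] * 500)
        meta = metagene_matrix(tags, [g], params)
        # body bins of a gene of exactly body_bins * 200 bp are plain 200-bp
        # genomic tiles: compare against a histogram over those tiles
        edges = np.arange(g.start, g.end + 1, 200)
        counts, _ = np.histogram(tags.pos5[tags.pos5 < g.end], bins=edges)
        expected = counts / 0.2 / (tags.library_size / 1e6)
        body = meta.values[0, params.flank_bins : params.flank_bins + params.body_bins]
        np.testing.assert_allclose(body, expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        params = ProfileParams(
            window=100, span=500, step=50, body_bins=7, flank_bins=5,
            min_gene_length=600,
        )
        for _ in range(8):
            genes, tags = random_instance(rng)
            meta = metagene_matrix(tags, genes, params)
            ref = oracle_metagene(tags, genes, params, tags.library_size)
            np.testing.assert_allclose(meta.values, ref, rtol=1e-12)

    def test_minus_gene_tag_near_tes_lands_in_last_body_bin(self):
        g = minus_gene(tss=20_000, length=6_000, gene_id="g")
        tags = make_tags("chr1", [g.tes], ["+"])  # single tag at the TES
        params = ProfileParams(body_bins=10)
        meta = metagene_matrix(tags, [g], params)
        body = meta.values[0, params.flank_bins : params.flank_bins + 10]
        assert body[-1] > 0
        assert body[:-1].sum() == 0

    def test_short_genes_excluded_and_reported(self):
        good = plus_gene(tss=50_000, length=5_000, gene_id="ok")
        short = plus_gene(tss=80_000, length=300, gene_id="tiny")
        tags = make_tags("chr1", [50_100], ["+"])
        meta = metagene_matrix(tags, [good, short], ProfileParams())
        assert meta.gene_ids == ["ok"]
        assert meta.excluded == ["tiny"]
        with pytest.raises(ValueError, match="short"):
            metagene_matrix(tags, [short], ProfileParams())


class TestHeatmap:
    def test_sorted_descending_by_mean(self):
        m = tss_matrix_like(np.array([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]]), span=100)
        ordered = heatmap_matrix(m)
        assert ordered.gene_ids == ["g1", "g2", "g0"]
        np.testing.assert_allclose(ordered.values[:, 0], [3.0, 2.0, 1.0])

    def test_ties_stable_by_gene_id(self):
        m = tss_matrix_like(np.array([[2.0, 2.0], [2.0, 2.0], [5.0, 5.0]]), span=100)
        ordered = heatmap_matrix(m)
        assert ordered.gene_ids == ["g2", "g0", "g1"]

    def test_resorting_is_idempotent(self):
        rng = np.random.default_rng(5)
        m = tss_matrix_like(rng.random((5, 4)), span=200)
        once = heatmap_matrix(m)
        twice = heatmap_matrix(once)
        assert once.gene_ids == twice.gene_ids
        np.testing.assert_array_equal(once.values, twice.values)

    def test_external_key_and_missing_entry(self):
        m = tss_matrix_like(np.ones((2, 2)), span=100)
        ordered = heatmap_matrix(m, sort_key={"g0": 1.0, "g1": 9.0})
        assert ordered.gene_ids == ["g1", "g0"]
        with pytest.raises(KeyError):
            heatmap_matrix(m, sort_key={"g0": 1.0})
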