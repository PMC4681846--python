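"""Canonical k-mer counting, PCA, cutoff calibration, 9-mer binning."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prodege.composition import (
    CLEAN,
    CONTAMINANT,
    DistanceCutoff,
    KmerProjection,
    calibrate_cutoff,
    canonical_kmer_count,
    classify_by_distance,
    fit_pca,
    kmer_frequencies,
    kmer_frequency_matrix,
    ninemer_binning,
)
from prodege.homology import revcomp
from prodege.seqio import Contig, RunConfig

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_kmer_freqs(seq: str, k: int) -> dict[str, float]:
    """Dictionary-based canonical k-mer counter, the independent oracle."""
    counts: Counter[str] = Counter()
    total = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(ch not in "ACGT" for ch in w):
            continue
        counts[min(w, revcomp(w))] += 1
        total += 1
    return {w: c / total for w, c in counts.items()} if total else {}


def canonical_kmer_list(k: int) -> list[str]:
    """All canonical k-mers in lexicographic order (enumeration oracle)."""
    alphabet = "ACGT"

    def kmers(n):
        if n == 0:
            yield ""
            return
        for prefix in kmers(n - 1):
            for ch in alphabet:
                yield prefix + ch

    return sorted({min(w, revcomp(w)) for w in kmers(k)})


def random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# k-mer frequencies
# ---------------------------------------------------------------------------


class TestKmerFrequencies:
    def test_single_window_poly_a(self):
        f = kmer_frequencies(Contig("c", "AAAAA"), 5)
        assert f.shape == (canonical_kmer_count(5),)
        assert np.flatnonzero(f).tolist() == [0]  # canonical AAAAA
        assert f[0] == 1.0

    @pytest.mark.parametrize("k,expected", [(1, 2), (2, 10), (3, 32), (5, 512), (9, 131072)])
    def test_canonical_dimension(self, k, expected):
        # (4^k + #self-reverse-complement k-mers) / 2
        assert canonical_kmer_count(k) == expected

    def test_dimension_matches_enumeration_oracle(self):
        for k in (1, 2, 3, 4):
            assert canonical_kmer_count(k) == len(canonical_kmer_list(k))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        kmers5 = canonical_kmer_list(5)
        for _ in range(30):
            seq = random_seq(rng, 1000)
            got = kmer_frequencies(Contig("c", seq), 5)
            expected = brute_force_kmer_freqs(seq, 5)
            for j, w in enumerate(kmers5):
                assert got[j] == pytest.approx(expected.get(w, 0.0), abs=0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=300),
        k=st.sampled_from([3, 5]),
    )
    def test_reverse_complement_invariance(self, seq, k):
        a = kmer_frequencies(Contig("c", seq), k)
        b = kmer_frequencies(Contig("c", revcomp(seq)), k)
        assert np.array_equal(a, b)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGTN", min_size=6, max_size=300))
    def test_normalization(self, seq):
        f = kmer_frequencies(Contig("c", seq), 5)
        s = f.sum()
        assert s == 0.0 or s == pytest.approx(1.0, abs=1e-9)

    def test_all_n_yields_zero_vector_and_unprojectable(self):
        contigs = [Contig("a", "N" * 100), Contig("b", "ACGT" * 50)]
        mat, projectable = kmer_frequency_matrix(contigs, 5)
        assert projectable.tolist() == [False, True]
        assert mat[0].nnz == 0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmer_frequencies(Contig("c", "ACGT"), 13)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestFitPca:
    def test_collinear_rows_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 12)[:, None]
        rows = t * np.array([1.0, 2.0, -1.0])
        model = fit_pca(rows, n_components=2)
        ratio = model.explained_variance[0] / model.explained_variance.sum()
        assert ratio == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_covariance_eigendecomposition(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n, d = rng.integers(5, 21), rng.integers(4, 21)
            X = rng.random((n, d))
            k = min(3, n - 1, d)
            model = fit_pca(X, n_components=k)
            cov = np.cov(X, rowvar=False)
            evals = np.sort(np.linalg.eigvalsh(cov))[::-1][:k]
            scale = max(evals.max(), 1e-12)
            assert np.allclose(model.explained_variance, evals, rtol=1e-8, atol=1e-8 * scale)
            # components span the same subspace as the top eigenvectors
            _, vecs = np.linalg.eigh(cov)
            top = vecs[:, np.argsort(np.linalg.eigvalsh(cov))[::-1][:k]]
            overlap = np.abs(model.components @ top)
            assert np.allclose(np.sort(overlap.max(axis=1)), 1.0, atol=1e-6)

    def test_components_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(3)
        X = rng.random((15, 8))
        model = fit_pca(X, n_components=4)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(4), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_full_reconstruction_recovers_centered_matrix(self):
        rng = np.random.default_rng(5)
        X = rng.random((9, 5))
        model = fit_pca(X, n_components=5)
        coords = model.transform(X)
        recon = coords @ model.components + model.mean
        assert np.allclose(recon, X, atol=1e-8)

    def test_sparse_iterative_path_agrees_with_dense(self):
        # Enough nonzero columns to force the implicitly-centered SVD path.
        import scipy.sparse as sp

        rng = np.random.default_rng(17)
        dense = np.zeros((25, 6000))
        for i in range(25):
            cols = rng.choice(6000, size=800, replace=False)
            dense[i, cols] = rng.random(800)
            dense[i] /= dense[i].sum()
        sparse = sp.csr_matrix(dense)
        m_sparse = fit_pca(sparse, n_components=3)
        cov = np.cov(dense, rowvar=False)
        # compare against dense eigendecomposition of the same covariance
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1][:3]
        assert np.allclose(m_sparse.explained_variance, evals, rtol=1e-6)

    def test_single_row_is_an_error(self):
        with pytest.raises(ValueError, match="homology"):
            fit_pca(np.ones((1, 4)), n_components=1)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).random((4, 3)), n_components=4)


# ---------------------------------------------------------------------------
# Cutoff calibration and distance classification
# ---------------------------------------------------------------------------


def _pt(cid, x, weight=1):
    return KmerProjection(cid, np.atleast_1d(np.asarray(x, dtype=float)), weight)


class TestCalibrateCutoff:
    def test_radius_just_below_nearest_contaminant(self):
        clean = [_pt("a", 0.1), _pt("b", -0.1)]
        contam = [_pt("x", 5.0), _pt("y", 6.0), _pt("z", 7.0)]
        cutoff = calibrate_cutoff(clean, contam, 0.8)
        assert 4.99 < cutoff.radius < 5.0
        labels = classify_by_distance(contam, cutoff)
        assert set(labels.values()) == {CONTAMINANT}

    def test_empty_contaminants_slack_rule(self):
        clean = [_pt("a", 2.0), _pt("b", -2.0)]
        cutoff = calibrate_cutoff(clean, [], 0.8)
        assert cutoff.radius == pytest.approx(3.0)  # max distance 2.0 x 1.5

    def test_full_specificity_excludes_every_contaminant(self):
        clean = [_pt("a", 0.0)]
        contam = [_pt("x", 1.0), _pt("y", 2.0)]
        cutoff = calibrate_cutoff(clean, contam, 1.0)
        assert cutoff.radius < 1.0

    def test_no_clean_points_is_an_error(self):
        with pytest.raises(ValueError, match="9-mer"):
            calibrate_cutoff([], [_pt("x", 1.0)], 0.8)

    def test_specificity_by_construction_weighted(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            clean = [_pt(f"c{i}", rng.normal(0, 1, 3), int(rng.integers(1, 9000)))
                     for i in range(rng.integers(1, 20))]
            contam = [_pt(f"x{i}", rng.normal(0, 6, 3), int(rng.integers(1, 9000)))
                      for i in range(rng.integers(1, 30))]
            s = float(rng.uniform(0.5, 1.0))
            cutoff = calibrate_cutoff(clean, contam, s)
            w_in = sum(p.weight for p in contam
                       if np.linalg.norm(p.coords - cutoff.center) <= cutoff.radius)
            w_tot = sum(p.weight for p in contam)
            assert w_in / w_tot <= (1 - s) + 1e-9

    def test_radius_monotone_in_target_specificity(self):
        rng = np.random.default_rng(29)
        clean = [_pt(f"c{i}", rng.normal(0, 1, 3)) for i in range(10)]
        contam = [_pt(f"x{i}", rng.normal(0, 5, 3)) for i in range(25)]
        radii = [calibrate_cutoff(clean, contam, s).radius
                 for s in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)]
        assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(radii, radii[1:]))


class TestClassifyByDistance:
    cutoff = DistanceCutoff(np.zeros(3), 1.0, "USER")

    def test_center_is_clean(self):
        assert classify_by_distance([_pt("a", [0, 0, 0])], self.cutoff) == {"a": CLEAN}

    def test_boundary_is_inclusive(self):
        labels = classify_by_distance([_pt("a", [1.0, 0, 0])], self.cutoff)
        assert labels == {"a": CLEAN}

    def test_unprojectable_is_contaminant(self):
        p = KmerProjection("a", np.zeros(3), 10, projectable=False)
        assert classify_by_distance([p], self.cutoff) == {"a": CONTAMINANT}

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(31)
        pts = [_pt(f"p{i}", rng.normal(0, 2, 3)) for i in range(200)]
        labels = classify_by_distance(pts, self.cutoff)
        for p in pts:
            d = sum((a - b) ** 2 for a, b in zip(p.coords, self.cutoff.center)) ** 0.5
            assert labels[p.contig_id] == (CLEAN if d <= 1.0 else CONTAMINANT)


# ---------------------------------------------------------------------------
# 9-mer binning
# ---------------------------------------------------------------------------


class TestNinemerBinning:
    def test_two_separated_clusters_split_by_source(self, small_mixture):
        mix = small_mixture
        result = ninemer_binning(mix.assembly, RunConfig(seed=5))
        src = dict(zip(mix.truth.contig_id, mix.truth.source))
        lens = {c.id: c.length for c in mix.assembly}
        target_bases = sum(lens[i] for i, s in src.items() if s == "target")
        clean_target = sum(
            lens[i] for i, l in result.labels.items()
            if l == CLEAN and src[i] == "target"
        )
        contam_bases = sum(lens[i] for i, s in src.items() if s != "target")
        removed_contam = sum(
            lens[i] for i, l in result.labels.items()
            if l == CONTAMINANT and src[i] != "target"
        )
        assert clean_target / target_bases >= 0.7
        assert removed_contam / contam_bases >= 0.8

    def test_single_source_keeps_bulk_of_bases(self):
        from prodege.synth import MixtureSpec, SourceGenomeSpec, generate_mixture, make_lineage

        mix = generate_mixture(
            MixtureSpec(
                target=SourceGenomeSpec(
                    lineage=make_lineage("T"), length=400_000, gc=0.45, seed=3
                ),
                contaminants=(),
                n_contigs=80,
                seed=7,
            )
        )
        result = ninemer_binning(mix.assembly, RunConfig(seed=7))
        lens = {c.id: c.length for c in mix.assembly}
        total = sum(lens.values())
        clean = sum(lens[i] for i, l in result.labels.items() if l == CLEAN)
        # The dominant bin holds the bulk of the assembly and is retained;
        # isolated noisy outliers may still fall outside the radius.
        assert clean / total >= 0.7
        bins = result.bin_of
        target_bases = sum(
            lens[i] for i, b in bins.items() if b == result.target_bin
        )
        assert target_bases / total >= 0.5

    def test_majority_contamination_inverts_labels(self):
        from prodege.synth import MixtureSpec, SourceGenomeSpec, generate_mixture, make_lineage

        mix = generate_mixture(
            MixtureSpec(
                target=SourceGenomeSpec(
                    lineage=make_lineage("T"), length=300_000, gc=0.38, seed=3
                ),
                contaminants=(
                    (
                        SourceGenomeSpec(
                            lineage=make_lineage("C1"), length=700_000, gc=0.62, seed=4
                        ),
                        0.65,
                    ),
                ),
                n_contigs=120,
                seed=9,
            )
        )
        result = ninemer_binning(mix.assembly, RunConfig(seed=9))
        src = dict(zip(mix.truth.contig_id, mix.truth.source))
        lens = {c.id: c.length for c in mix.assembly}
        contam_clean = sum(
            lens[i] for i, l in result.labels.items()
            if l == CLEAN and src[i] != "target"
        )
        contam_total = sum(lens[i] for i, s in src.items() if s != "target")
        target_clean = sum(
            lens[i] for i, l in result.labels.items()
            if l == CLEAN and src[i] == "target"
        )
        target_total = sum(lens[i] for i, s in src.items() if s == "target")
        # the contaminant source is now the "target" bin
        assert contam_clean / contam_total > 0.5
        assert target_clean / target_total < 0.5

    def test_too_few_contigs_labels_everything_clean_with_warning(self):
        contigs = [Contig("a", "N" * 3000), Contig("b", "N" * 3000)]
        result = ninemer_binning(contigs, RunConfig())
        assert set(result.labels.values()) == {CLEAN}
        assert any("insufficient" in w for w in result.warnings)

    def test_user_cutoff_replaces_radius(self, small_mixture):
        result = ninemer_binning(
            small_mixture.assembly, RunConfig(user_cutoff=0.5, seed=5)
        )
        assert result.cutoff.source == "USER"
        assert result.cutoff.radius == 0.5

    def test_strand_invariance_of_labels(self, small_mixture):
        rng = np.random.default_rng(41)
        flipped = [
            Contig(c.id, revcomp(c.seq)) if rng.random() < 0.5 else c
            for c in small_mixture.assembly
        ]
        a = ninemer_binning(small_mixture.assembly, RunConfig(seed=5))
        b = ninemer_binning(flipped, RunConfig(seed=5))
        assert a.labels == b.labels
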