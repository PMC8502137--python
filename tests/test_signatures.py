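"""Signature layer: catalogs, NMF, cosine matching, exposure recovery."""

import numpy as np
import pytest

from gcsubtype.signatures import (
    MutationalCatalog,
    _nmf_mu,
    compute_exposures,
    cosine,
    match_reference,
    nmf_extract,
    select_rank,
    sig_cluster,
    tabulate_96,
)
from gcsubtype.types import ReferenceSignatureSet

from conftest import mixture_catalog
from test_io import make_mutation


class TestTabulate96:
    def test_single_pyrimidine_record(self):
        catalog = tabulate_96([make_mutation(ref="C", alt="A", context3="ACA")])
        assert catalog.counts.sum() == 1
        assert catalog.to_frame().loc["S1", "A[C>A]A"] == 1

    def test_purine_record_collapses(self):
        catalog = tabulate_96([make_mutation(ref="G", alt="T", context3="TGT")])
        assert catalog.to_frame().loc["S1", "A[C>A]A"] == 1

    def test_strand_collapse_doubles_catalog(self, small_cohort):
        from gcsubtype.channels import reverse_complement

        snvs = [m for m in small_cohort.mutations if m.is_snv][:500]
        flipped = [make_mutation(sample_id=m.sample_id, ref=reverse_complement(m.ref),
                                 alt=reverse_complement(m.alt),
                                 context3=reverse_complement(m.context3),
                                 vaf=m.vaf, alt_depth=m.alt_depth,
                                 total_depth=m.total_depth)
                   for m in snvs]
        single = tabulate_96(snvs)
        doubled = tabulate_96(snvs + flipped)
        np.testing.assert_array_equal(doubled.counts, 2 * single.counts)

    def test_counts_conserved_and_indels_skipped(self, small_cohort):
        catalog = tabulate_96(small_cohort.mutations)
        n_snv = sum(m.is_snv for m in small_cohort.mutations)
        assert catalog.counts.sum() == n_snv - catalog.n_rejected
        assert catalog.n_indels_skipped == len(small_cohort.mutations) - n_snv


class TestNmf:
    def test_rank_one_catalog_recovered_exactly(self):
        rng = np.random.default_rng(0)
        profile = rng.dirichlet(np.ones(96))
        counts = np.outer(rng.integers(200, 800, size=20), profile)
        catalog = MutationalCatalog(samples=[f"S{i}" for i in range(20)],
                                    counts=counts)
        signatures, loadings, err, _ = nmf_extract(catalog, k=1, n_restarts=3, seed=0)
        assert err / np.linalg.norm(counts) < 1e-6
        assert cosine(signatures[:, 0], profile) > 1 - 1e-9

    def test_objective_non_increasing_every_iteration(self):
        rng = np.random.default_rng(1)
        V = rng.poisson(5.0, size=(15, 96)).astype(float)
        _, _, history = _nmf_mu(V, k=3, rng=np.random.default_rng(2))
        diffs = np.diff(history)
        assert (diffs <= 1e-9 * np.abs(history[:-1])).all()

    def test_two_separated_signatures_recovered(self, reference):
        # Signature 1 vs Signature 29: cosine < 0.3 by construction
        pair = np.column_stack([reference.column("Signature 1"),
                                reference.column("Signature 29")])
        rng = np.random.default_rng(3)
        counts = np.zeros((50, 96))
        for i in range(50):
            w = rng.dirichlet([2, 2])
            counts[i] = rng.multinomial(500, pair @ w)
        catalog = MutationalCatalog(samples=[f"S{i}" for i in range(50)], counts=counts)
        signatures, _, _, _ = nmf_extract(catalog, k=2, n_restarts=5, seed=0)
        sims = np.array([[cosine(signatures[:, i], pair[:, j]) for j in range(2)]
                         for i in range(2)])
        assert sims.max(axis=1).min() >= 0.95

    def test_identical_seed_identical_factorization(self, reference):
        catalog, _ = mixture_catalog(np.random.default_rng(4), reference,
                                     n_samples=20, muts_per_sample=200)
        a = nmf_extract(catalog, k=3, n_restarts=3, seed=7)
        b = nmf_extract(catalog, k=3, n_restarts=3, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_bad_rank_or_empty_catalog_rejected(self):
        catalog = MutationalCatalog(samples=["A"], counts=np.zeros((1, 96)))
        with pytest.raises(ValueError):
            nmf_extract(catalog, k=1)
        catalog = MutationalCatalog(samples=["A"], counts=np.ones((1, 96)))
        with pytest.raises(ValueError):
            nmf_extract(catalog, k=2)

    def test_matches_sklearn_reconstruction_quality(self, reference):
        """Independent cross-check: our multiplicative-update NMF reaches a
        reconstruction error comparable to sklearn's NMF on the same data."""
        from sklearn.decomposition import NMF

        catalog, _ = mixture_catalog(np.random.default_rng(5), reference,
                                     n_samples=30, muts_per_sample=300)
        _, _, err, _ = nmf_extract(catalog, k=4, n_restarts=5, seed=0)
        model = NMF(n_components=4, init="nndsvda", max_iter=600, random_state=0)
        W = model.fit_transform(catalog.counts.astype(float))
        sk_err = np.linalg.norm(catalog.counts - W @ model.components_, "fro")
        assert err <= 1.1 * sk_err


class TestCosineAndMatching:
    def test_closed_forms(self):
        v = np.zeros(96); v[0] = 1
        u = np.zeros(96); u[0] = 1; u[1] = 1
        w = np.zeros(96); w[2] = 1
        assert cosine(v, v) == pytest.approx(1.0)
        assert cosine(v, w) == pytest.approx(0.0)
        assert cosine(u, v) == pytest.approx(1 / np.sqrt(2))
        with pytest.raises(ValueError):
            cosine(v, np.zeros(96))

    def test_exact_copy_assigned_with_cosine_one(self, reference):
        extracted = reference.column("Signature 6")[:, None]
        assert match_reference(extracted, reference) == ["Signature 6"]

    def test_below_threshold_unassigned(self, reference):
        rng = np.random.default_rng(6)
        noise = rng.dirichlet(np.ones(96))[:, None]
        best = max(cosine(noise[:, 0], reference.matrix[:, j]) for j in range(4))
        assert best < 0.9  # flat noise resembles nothing
        assert match_reference(noise, reference) == ["unassigned"]

    def test_duplicate_claim_falls_back_to_next_best(self):
        """Two extracted copies of the same reference: the higher cosine
        wins; the other takes its next-best match (exhaustive toy check)."""
        rng = np.random.default_rng(7)
        a = rng.dirichlet(np.ones(96) * 0.2)
        b = rng.dirichlet(np.ones(96) * 0.2)
        c = rng.dirichlet(np.ones(96) * 0.2)
        ref = ReferenceSignatureSet(names=["R1", "R2", "R3"],
                                    matrix=np.column_stack([a, b, c]))
        near_a = 0.70 * a + 0.30 * b
        nearer_a = 0.95 * a + 0.05 * c
        mapping = match_reference(np.column_stack([near_a, nearer_a]), ref,
                                  threshold=0.2)
        assert mapping[1] == "R1"    # the closer copy keeps R1
        assert mapping[0] == "R2"    # the other falls back to its 2nd-best

    def test_channel_order_mismatch_rejected(self, reference):
        with pytest.raises(ValueError):
            match_reference(reference.matrix[:, :1], reference,
                            channel_order=["x"] * 96)


class TestExposuresAndCluster:
    def test_exposure_rows_sum_to_one_and_sparse_samples_refit(self, reference):
        rng = np.random.default_rng(8)
        catalog, _ = mixture_catalog(rng, reference, n_samples=10, muts_per_sample=300)
        catalog.counts[3] = 0
        catalog.counts[3, 5] = 4  # sparse sample: NNLS refit path
        signatures, loadings, _, _ = nmf_extract(catalog, k=4, n_restarts=3, seed=0)
        names = match_reference(signatures, reference)
        exposures = compute_exposures(catalog, signatures, loadings, names, reference)
        np.testing.assert_allclose(exposures.exposures.sum(axis=1), 1.0, atol=1e-8)

    def test_pure_exposure_groups_split_perfectly(self):
        from sklearn.metrics import adjusted_rand_score

        from gcsubtype.signatures import ExposureMatrix

        rows = np.vstack([np.tile([1, 0, 0], (5, 1)), np.tile([0, 1, 0], (5, 1)),
                          np.tile([0, 0, 1], (5, 1))]).astype(float)
        exposures = ExposureMatrix(samples=[f"S{i}" for i in range(15)],
                                   exposures=rows, signature_names=list("ABC"))
        labels = sig_cluster(exposures, k=3)
        assert adjusted_rand_score([0] * 5 + [1] * 5 + [2] * 5, labels) == 1.0

    def test_k_larger_than_n_rejected(self):
        from gcsubtype.signatures import ExposureMatrix

        exposures = ExposureMatrix(samples=["A", "B"], exposures=np.eye(2),
                                   signature_names=["x", "y"])
        with pytest.raises(ValueError):
            sig_cluster(exposures, k=3)


class TestRankSelection:
    def test_rank_one_catalog_selects_one(self):
        rng = np.random.default_rng(9)
        profile = rng.dirichlet(np.ones(96))
        counts = np.outer(rng.integers(300, 600, size=25), profile)
        catalog = MutationalCatalog(samples=[f"S{i}" for i in range(25)],
                                    counts=counts)
        k, diagnostics = select_rank(catalog, 1, 4, n_restarts=3, seed=0)
        assert k == 1
        assert list(diagnostics["k"]) == [1, 2, 3, 4]  # one row per rank

    def test_four_planted_signatures_selects_four(self, reference):
        """Rank scan lands on 4 in >= 80% of seeds for catalogs built from
        the four planted signatures at cohort-like mixtures."""
        mixtures = [[0.08, 0.30, 0.50, 0.12], [0.08, 0.50, 0.30, 0.12],
                    [0.10, 0.10, 0.10, 0.70], [0.70, 0.10, 0.08, 0.12]]
        n_ok = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            catalog, _ = mixture_catalog(rng, reference, n_samples=40,
                                         muts_per_sample=400, mixtures=mixtures)
            k, _ = select_rank(catalog, 2, 6, n_restarts=4, seed=seed)
            n_ok += k == 4
        assert n_ok >= 0.8 * n_seeds
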