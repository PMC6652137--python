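import numpy as np
import pytest

from genopanel import (
    DEFAULT_COMPONENTS,
    DEFAULT_MAF,
    MISSING,
    GenotypeTable,
    SiteKey,
    compute_maf,
    filter_by_maf,
    fit_panel,
    impute_and_center,
)
from genopanel.errors import EmptyPanelError, ParameterError

from conftest import random_table, table_from_array
from oracles import impute_center_brute, maf_filter_brute, pca_eig_oracle


class TestSiteKey:
    def test_valid(self):
        s = SiteKey("1", 1000, "A", "G")
        assert (s.chrom, s.pos, s.ref, s.alt) == ("1", 1000, "A", "G")

    @pytest.mark.parametrize("kwargs", [
        dict(chrom="1", pos=0, ref="A", alt="G"),
        dict(chrom="1", pos=10, ref="A", alt="A"),
        dict(chrom="1", pos=10, ref="A", alt="G,T"),
        dict(chrom="1", pos=10, ref="A", alt=""),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ParameterError):
            SiteKey(**kwargs)


class TestGenotypeTable:
    def test_shape_mismatch(self):
        with pytest.raises(ParameterError, match="shape"):
            GenotypeTable(sites=[SiteKey("1", 1, "A", "G")],
                          accessions=["a", "b"],
                          dosages=np.zeros((2, 2), dtype=np.int8))

    def test_duplicate_labels(self):
        with pytest.raises(ParameterError, match="unique"):
            table_from_array([[0, 1]], labels=["a", "a"])

    def test_bad_dosage_value(self):
        with pytest.raises(ParameterError, match="dosages"):
            table_from_array([[0, 3]])


class TestComputeMaf:
    def test_half(self):
        # alt freq 3/6 = 0.5
        t = table_from_array([[0, 1, 2]])
        assert compute_maf(t)[0] == pytest.approx(0.5)

    def test_monomorphic(self):
        t = table_from_array([[0, 0, 0]])
        assert compute_maf(t)[0] == 0.0

    def test_missing_excluded_from_count(self):
        # alt freq over non-missing: 3/4 = 0.75 -> MAF 0.25
        t = table_from_array([[2, MISSING, 1]])
        assert compute_maf(t)[0] == pytest.approx(0.25)

    def test_all_missing_is_nan(self):
        t = table_from_array([[MISSING, MISSING]])
        assert np.isnan(compute_maf(t)[0])

    def test_range(self):
        rng = np.random.default_rng(5)
        maf = compute_maf(random_table(rng, 80, 15))
        ok = ~np.isnan(maf)
        assert ((maf[ok] >= 0) & (maf[ok] <= 0.5)).all()


class TestFilterByMaf:
    def test_hand_example(self):
        # per-site MAFs: 0.5, 0.0, 0.3, 0.1 -> threshold 0.2 keeps 1st, 3rd
        t = table_from_array([
            [1, 1, 1, 1, 1],
            [0, 0, 0, 0, 0],
            [1, 1, 1, 0, 0],
            [1, 0, 0, 0, 0],
        ])
        kept = filter_by_maf(t, threshold=0.2)
        assert [s.pos for s in kept.sites] == [100, 300]
        assert kept.accessions == t.accessions

    def test_default_threshold_is_02(self):
        assert DEFAULT_MAF == 0.2

    def test_all_monomorphic_errors(self):
        t = table_from_array(np.zeros((5, 4), dtype=np.int8))
        with pytest.raises(EmptyPanelError):
            filter_by_maf(t, threshold=0.1)

    @pytest.mark.parametrize("threshold", [0.0, -0.1, 0.6])
    def test_bad_threshold(self, threshold):
        t = table_from_array([[0, 1, 2]])
        with pytest.raises(ParameterError):
            filter_by_maf(t, threshold=threshold)

    def test_call_rate_floor(self):
        # site 2 has 1/4 calls (< 50%), polymorphic enough but dropped
        t = table_from_array([
            [1, 1, 0, 0],
            [1, MISSING, MISSING, MISSING],
        ])
        kept = filter_by_maf(t, threshold=0.2)
        assert len(kept.sites) == 1
        kept2 = filter_by_maf(t, threshold=0.2, min_call_rate=0.0)
        assert len(kept2.sites) == 2

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            t = random_table(rng, int(rng.integers(2, 50)),
                             int(rng.integers(2, 50)), missing_rate=0.2)
            thr = float(rng.uniform(0.05, 0.5))
            expected = maf_filter_brute(t.dosages, thr, 0.5)
            if not expected:
                with pytest.raises(EmptyPanelError):
                    filter_by_maf(t, thr)
                continue
            kept = filter_by_maf(t, thr)
            got = [t.sites.index(s) for s in kept.sites]
            assert got == expected


class TestImputeAndCenter:
    def test_hand_example(self):
        t = table_from_array([[0, MISSING, 2]])
        x, means = impute_and_center(t)
        assert means[0] == pytest.approx(1.0)
        np.testing.assert_allclose(x[0], [-1.0, 0.0, 1.0])

    def test_no_missing_centers_only(self):
        t = table_from_array([[0, 1, 2], [2, 2, 0]])
        x, means = impute_and_center(t)
        np.testing.assert_allclose(x.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(means, [1.0, 4 / 3])

    def test_constant_site(self):
        t = table_from_array([[2, 2, 2]])
        x, _ = impute_and_center(t)
        np.testing.assert_allclose(x[0], 0.0)

    def test_all_missing_site_rejected(self):
        t = table_from_array([[MISSING, MISSING]])
        with pytest.raises(ParameterError, match="non-missing"):
            impute_and_center(t)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 30, 12, missing_rate=0.25)
        x, _ = impute_and_center(t)
        np.testing.assert_allclose(x, impute_center_brute(t.dosages), atol=1e-12)


class TestFitPanel:
    def test_defaults(self):
        import inspect
        sig = inspect.signature(fit_panel)
        assert sig.parameters["maf_threshold"].default == 0.2
        assert sig.parameters["n_components"].default == DEFAULT_COMPONENTS == 20

    def test_rank_one_toy(self):
        # two perfectly correlated sites -> evr (1, 0)
        row = [0, 1, 2, 1, 0]
        t = table_from_array([row, row])
        panel = fit_panel(t, maf_threshold=0.2, n_components=2)
        np.testing.assert_allclose(panel.model.evr, [1.0, 0.0], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        t = random_table(rng, 4, 5, missing_rate=0.1)
        panel = fit_panel(t, maf_threshold=0.05, n_components=3,
                          min_call_rate=0.0)
        x, _ = impute_and_center(filter_by_maf(t, 0.05, 0.0))
        loadings, evr, scores = pca_eig_oracle(x, 3)
        np.testing.assert_allclose(panel.model.loadings, loadings, atol=1e-8)
        np.testing.assert_allclose(panel.model.evr, evr, atol=1e-8)
        np.testing.assert_allclose(panel.scores, scores, atol=1e-8)

    def test_pca_equivalence_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            ns = int(rng.integers(4, 21))
            na = int(rng.integers(4, 21))
            t = random_table(rng, ns, na, missing_rate=0.05)
            try:
                filtered = filter_by_maf(t, 0.05, 0.0)
            except EmptyPanelError:
                continue
            k = min(3, filtered.n_sites, filtered.n_accessions)
            panel = fit_panel(t, 0.05, k, min_call_rate=0.0)
            x, _ = impute_and_center(filtered)
            loadings, evr, scores = pca_eig_oracle(x, k)
            np.testing.assert_allclose(panel.scores, scores, atol=1e-8)
            np.testing.assert_allclose(panel.model.evr, evr, atol=1e-8)

    def test_component_bound_error_names_both(self):
        t = table_from_array(np.tile([0, 1, 2, 1], (6, 1)).astype(np.int8))
        with pytest.raises(ParameterError) as err:
            fit_panel(t, 0.2, 10)
        assert "sites" in str(err.value) and "accessions" in str(err.value)

    def test_training_roundtrip(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 60, 15, missing_rate=0.1)
        panel = fit_panel(t, 0.1, 8, min_call_rate=0.0)
        filtered = filter_by_maf(t, 0.1, 0.0)
        for j in range(panel.n_accessions):
            got = panel.model.project(filtered.dosages[:, j])
            np.testing.assert_allclose(got, panel.scores[:, j], atol=1e-8)

    def test_evr_properties(self):
        rng = np.random.default_rng(17)
        t = random_table(rng, 40, 12, missing_rate=0.05)
        panel = fit_panel(t, 0.1, 10, min_call_rate=0.0)
        evr = panel.model.evr
        assert ((evr >= 0) & (evr <= 1)).all()
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1 + 1e-8

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(21)
        t = random_table(rng, 50, 14, missing_rate=0.0)
        panel = fit_panel(t, 0.1, 6, min_call_rate=0.0)
        gram = panel.model.loadings @ panel.model.loadings.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-10)

    def test_accession_permutation_equivariance(self):
        rng = np.random.default_rng(31)
        t = random_table(rng, 40, 10, missing_rate=0.1)
        perm = rng.permutation(10)
        t2 = GenotypeTable(sites=t.sites,
                           accessions=[t.accessions[i] for i in perm],
                           dosages=t.dosages[:, perm])
        p1 = fit_panel(t, 0.1, 5, min_call_rate=0.0)
        p2 = fit_panel(t2, 0.1, 5, min_call_rate=0.0)
        for j, i in enumerate(perm):
            np.testing.assert_allclose(p2.scores[:, j], p1.scores[:, i],
                                       atol=1e-8)
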