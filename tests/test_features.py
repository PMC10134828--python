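"""Phylogenetic and carbon PCs, metabolic distance, feature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairfx.features import (
    FeatureOptions,
    aligned_labels,
    assemble_features,
    carbon_pcs,
    impute_profiles,
    metabolic_distance,
    metabolic_distance_matrix,
    phylo_pcs,
    project_heldout_carbon,
    read_features,
    write_features,
    MANDATORY_COLUMNS,
)


def two_clade_distance_fixture():
    species = [f"S{i}" for i in range(6)]
    d = np.full((6, 6), 2.0)
    d[:3, :3] = 0.2
    d[3:, 3:] = 0.2
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=species, columns=species)


class TestPhyloPCs:
    def test_zero_matrix_gives_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        coords, evr = phylo_pcs(d)
        np.testing.assert_array_equal(coords.to_numpy(), 0.0)

    def test_pc1_separates_clades(self):
        coords, _ = phylo_pcs(two_clade_distance_fixture())
        c1 = coords.iloc[:3, 0].to_numpy()
        c2 = coords.iloc[3:, 0].to_numpy()
        gap = abs(c1.mean() - c2.mean())
        spread = max(np.ptp(c1), np.ptp(c2))
        assert spread < gap

    def test_matches_eigendecomposition_oracle(self):
        # generic symmetric fixture: eigenvalues distinct, PCs unique up to sign
        rng = np.random.default_rng(8)
        a = rng.uniform(0.5, 3.0, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        d = pd.DataFrame(a, index=[f"S{i}" for i in range(6)],
                         columns=[f"S{i}" for i in range(6)])
        coords, evr = phylo_pcs(d, n_components=2)
        X = d.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(evr, w[:2] / w.sum(), atol=1e-9)
        oracle = Xc @ v[:, :2]
        np.testing.assert_allclose(np.abs(coords.to_numpy()), np.abs(oracle),
                                   atol=1e-9)

    def test_asymmetric_input_rejected(self):
        d = two_clade_distance_fixture()
        d.iloc[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            phylo_pcs(d)


class TestCarbonPCs:
    def _mono(self, seed=0, n_species=6, n_carbons=8):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(0.5, 5, size=(n_species, n_carbons)),
            index=[f"S{i}" for i in range(n_species)],
            columns=[f"C{i}" for i in range(n_carbons)],
        )

    def test_duplicate_carbons_map_together(self):
        mono = self._mono()
        mono["C1"] = mono["C0"]
        coords, _ = carbon_pcs(mono, n_components=3)
        np.testing.assert_allclose(coords.loc["C0"], coords.loc["C1"], atol=1e-12)

    def test_rank_deficient_matrix_rejected(self):
        base = np.outer(np.arange(1, 5), np.arange(1, 7))  # rank 1
        mono = pd.DataFrame(base, index=list("ABCD"),
                            columns=[f"C{i}" for i in range(6)])
        with pytest.raises(ValueError, match="rank"):
            carbon_pcs(mono, n_components=4)

    def test_matches_eigendecomposition_oracle(self):
        mono = self._mono(seed=1, n_carbons=5)
        coords, proj = carbon_pcs(mono, n_components=3)
        X = mono.to_numpy().T
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        oracle = Xc @ v[:, order[:3]]
        np.testing.assert_allclose(np.abs(coords.to_numpy()), np.abs(oracle),
                                   atol=1e-9)

    def test_projection_reproduces_training_coordinates(self):
        mono = self._mono(seed=2)
        coords, proj = carbon_pcs(mono, n_components=4)
        profiles = impute_profiles(mono).to_numpy().T
        again = project_heldout_carbon(proj, profiles)
        np.testing.assert_allclose(again, coords.to_numpy(), atol=1e-9)

    def test_mean_profile_projects_to_origin(self):
        mono = self._mono(seed=3)
        _, proj = carbon_pcs(mono, n_components=4)
        mean_profile = impute_profiles(mono).to_numpy().T.mean(axis=0)
        np.testing.assert_allclose(project_heldout_carbon(proj, mean_profile),
                                   0.0, atol=1e-9)

    def test_projection_matches_hand_linear_algebra(self):
        mono = self._mono(seed=4)
        _, proj = carbon_pcs(mono, n_components=2)
        profile = np.linspace(1, 2, mono.shape[0])
        oracle = proj.components @ (profile - proj.center)
        np.testing.assert_allclose(project_heldout_carbon(proj, profile), oracle)

    def test_dimension_mismatch_rejected(self):
        _, proj = carbon_pcs(self._mono(), n_components=2)
        with pytest.raises(ValueError, match="dimensions"):
            project_heldout_carbon(proj, np.ones(3))


class TestMetabolicDistance:
    def _mono(self, profiles):
        return pd.DataFrame(profiles, index=["A", "B"],
                            columns=[f"C{i}" for i in range(len(profiles[0]))]).T.T

    @pytest.mark.parametrize("pa, pb, expected", [
        ([1.0, 2.0, 2.0], [1.0, 2.0, 2.0], 0.0),
        ([1.0, 2.0, 2.0], [1.0, 5.0, 2.0], 3.0),
        ([1.0, 2.0, 2.0], [3.0, 0.0, 1.0], 3.0),  # sqrt(4+4+1)
    ])
    def test_hand_values(self, pa, pb, expected):
        mono = self._mono([pa, pb])
        assert metabolic_distance(mono, "A", "B") == pytest.approx(expected)

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            metabolic_distance(self._mono([[1.0], [2.0]]), "A", "Z")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        mono = pd.DataFrame(rng.uniform(0, 4, size=(4, 5)),
                            index=list("ABCD"), columns=[f"C{i}" for i in range(5)])
        d = metabolic_distance_matrix(mono)
        a = d.to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 0)
        viol = a[:, :, None] + a[None, :, :] - a[:, None, :]
        assert (viol >= -1e-9).all()


class TestAssemble:
    def test_mandatory_column_count_and_order(self, small_dataset):
        ds, _ = small_dataset
        X = assemble_features(ds)
        assert list(X.columns) == MANDATORY_COLUMNS
        assert len(MANDATORY_COLUMNS) == 11
        assert not X.isna().any().any()
        assert X.index.is_unique

    def test_carbon_pcs_constant_within_carbon(self, small_dataset):
        ds, _ = small_dataset
        X = assemble_features(ds)
        per_carbon = X.groupby(level=2)["carbon_pc1"].nunique()
        assert (per_carbon == 1).all()

    def test_drop_monoculture_toggle(self, small_dataset):
        ds, _ = small_dataset
        X = assemble_features(ds, FeatureOptions(drop_monoculture_features=True))
        assert not {"mono_affected", "mono_affecting", "metab_dist"} & set(X.columns)

    def test_reciprocal_feature_is_mirror_effect(self, small_dataset):
        ds, _ = small_dataset
        X = assemble_features(ds, FeatureOptions(reciprocal_effect=True))
        lookup = ds.effect_lookup()
        sample = X.sample(50, random_state=0)
        for (a, b, c), row in sample.iterrows():
            assert row["reciprocal_effect"] == lookup[(b, a, c)]

    def test_labels_align(self, small_dataset):
        ds, _ = small_dataset
        X = assemble_features(ds)
        y = aligned_labels(ds, X)
        assert len(y) == len(X)
        assert ((y["effect"] > 0) == (y["sign"] == "positive")).all()

    def test_feature_csv_roundtrip(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        X = assemble_features(ds)
        write_features(X, tmp_path / "f.csv")
        back = read_features(tmp_path / "f.csv")
        np.testing.assert_array_equal(X.to_numpy(), back.to_numpy())
        assert list(back.columns) == list(X.columns)
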