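"""Feature engineering for directed-effect prediction.

Each directed (affected, affecting, carbon) record is described by:

- the monoculture yields of both species in the focal carbon,
- the metabolic distance between the two species (Euclidean distance of
  their monoculture yield profiles across carbons),
- two phylogenetic principal components per species (PCA on the rows of the
  phylogenetic distance matrix),
- four carbon principal components (PCA on carbon metabolic profiles, i.e.
  the vector of all species' monoculture yields in that carbon),
- optional blocks: carbon one-hot, carbon chemistry, pathway presence,
  and the measured reciprocal effect.

Carbon PCA returns a reusable projection so that a held-out environment can
be embedded into the training PC space without refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import InteractionDataset

MANDATORY_COLUMNS = [
    "mono_affected", "mono_affecting", "metab_dist",
    "affected_phylo_pc1", "affected_phylo_pc2",
    "affecting_phylo_pc1", "affecting_phylo_pc2",
    "carbon_pc1", "carbon_pc2", "carbon_pc3", "carbon_pc4",
]


@dataclass
class PCAProjection:
    """A fitted PCA embedding: coordinates = components @ (x - center)."""

    center: np.ndarray          # (p,)
    components: np.ndarray      # (k, p), rows are unit loadings
    explained_variance_ratio: np.ndarray  # (k,)
    feature_labels: list[str]   # labels of the p input dimensions

    def transform(self, profile: np.ndarray) -> np.ndarray:
        profile = np.asarray(profile, dtype=float)
        if profile.shape[-1] != self.center.shape[0]:
            raise ValueError(
                f"profile has {profile.shape[-1]} dimensions, "
                f"projection expects {self.center.shape[0]}"
            )
        return (profile - self.center) @ self.components.T


def _pca(X: np.ndarray, n_components: int) -> tuple[np.ndarray, PCAProjection]:
    """Column-centered PCA with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive (eigenvector signs are otherwise arbitrary and platform
    dependent).  Raises if more components are requested than the matrix
    rank supports.
    """
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    rank = int((s > s[0] * 1e-10).sum()) if total > 0 else 0
    if total == 0:
        # no variance at all: legal, all coordinates are zero
        k = n_components
        comps = np.zeros((k, X.shape[1]))
        proj = PCAProjection(center, comps, np.zeros(k), [])
        return np.zeros((X.shape[0], k)), proj
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but matrix rank is {rank}"
        )
    comps = Vt[:n_components]
    flip = np.sign(comps[np.arange(n_components),
                         np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    coords = Xc @ comps.T
    evr = (s[:n_components] ** 2) / total
    proj = PCAProjection(center, comps, evr, [])
    return coords, proj


def phylo_pcs(
    phylo_dist: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Species coordinates on the top PCs of the distance matrix.

    Each species' row of distances to all species is its feature vector;
    columns are centered and the top components extracted.  (This is plain
    PCA on the matrix rows, not classical MDS/PCoA.)  Returns the
    coordinates and the explained-variance ratios.
    """
    a = phylo_dist.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("phylogenetic distance matrix must be symmetric")
    coords, proj = _pca(a, n_components)
    cols = [f"phylo_pc{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=phylo_dist.index, columns=cols),
        proj.explained_variance_ratio,
    )


def impute_profiles(mono_yields: pd.DataFrame) -> pd.DataFrame:
    """Fill missing species x carbon yields with the species' mean yield.

    Used only for profile-based features (carbon PCs, metabolic distance);
    per-row monoculture features are never imputed.
    """
    means = mono_yields.mean(axis=1)
    return mono_yields.apply(lambda col: col.fillna(means))


def carbon_pcs(
    mono_yields: pd.DataFrame, n_components: int = 4
) -> tuple[pd.DataFrame, PCAProjection]:
    """Carbon-environment coordinates on the top PCs of metabolic profiles.

    A carbon's metabolic profile is the vector of all species' monoculture
    yields in it.  Returns coordinates plus the fitted projection (center
    and loadings) for embedding held-out environments.
    """
    if mono_yields.shape[1] < n_components + 1:
        raise ValueError("need at least n_components + 1 carbons")
    filled = impute_profiles(mono_yields)
    X = filled.to_numpy(dtype=float).T  # carbons x species
    coords, proj = _pca(X, n_components)
    proj.feature_labels = list(mono_yields.index)
    cols = [f"carbon_pc{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=mono_yields.columns, columns=cols), proj


def project_heldout_carbon(
    projection: PCAProjection, heldout_profile: np.ndarray
) -> np.ndarray:
    """Embed a new environment's profile into a fitted carbon PC space.

    coordinates = loadings @ (profile - training center); never a refit.
    """
    return projection.transform(np.asarray(heldout_profile, dtype=float))


def metabolic_distance(mono_yields: pd.DataFrame, species_a: str, species_b: str) -> float:
    """Euclidean distance between two species' monoculture yield profiles."""
    for s in (species_a, species_b):
        if s not in mono_yields.index:
            raise KeyError(f"unknown species {s!r}")
    filled = impute_profiles(mono_yields)
    diff = filled.loc[species_a].to_numpy() - filled.loc[species_b].to_numpy()
    return float(np.linalg.norm(diff))


def metabolic_distance_matrix(mono_yields: pd.DataFrame) -> pd.DataFrame:
    filled = impute_profiles(mono_yields).to_numpy(dtype=float)
    sq = ((filled[:, None, :] - filled[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(sq)
    return pd.DataFrame(d, index=mono_yields.index, columns=mono_yields.index)


@dataclass
class FeatureOptions:
    """Toggles for the feature table.

    ``log_mono`` applies the natural log to the per-row monoculture yield
    features (profiles and distances always use raw yields).
    """

    drop_monoculture_features: bool = False
    drop_phylo: bool = False
    drop_carbon: bool = False
    log_mono: bool = False
    one_hot_carbon: bool = False
    chemistry: pd.DataFrame | None = None   # carbon-indexed extra columns
    pathways: pd.DataFrame | None = None    # species-indexed binary block
    reciprocal_effect: bool = False
    n_phylo_pcs: int = 2
    n_carbon_pcs: int = 4


def assemble_features(
    dataset: InteractionDataset,
    options: FeatureOptions | None = None,
    carbon_projection: PCAProjection | None = None,
) -> pd.DataFrame:
    """Build the model feature table, one row per directed effect record.

    Rows are indexed by (affected, affecting, carbon).  Rows whose focal
    monoculture yields are missing are excluded (they correspond to dropped
    screen combinations and are never imputed).  If ``carbon_projection``
    is given, carbon PCs for *all* carbons are computed by projecting their
    profiles through it (used when an environment is held out of the fit).
    """
    opts = options or FeatureOptions()
    eff = dataset.effects
    idx = pd.MultiIndex.from_frame(eff[["affected", "affecting", "carbon"]])
    out = pd.DataFrame(index=idx)

    mono = dataset.mono_yields
    if not opts.drop_monoculture_features:
        ma = np.array([mono.at[a, c] for a, _, c in idx])
        mb = np.array([mono.at[b, c] for _, b, c in idx])
        if opts.log_mono:
            with np.errstate(divide="ignore"):
                ma, mb = np.log(ma), np.log(mb)
        out["mono_affected"] = ma
        out["mono_affecting"] = mb
        mdist = metabolic_distance_matrix(mono)
        out["metab_dist"] = [mdist.at[a, b] for a, b, _ in idx]

    if not opts.drop_phylo:
        pcs, _ = phylo_pcs(dataset.phylo_dist, opts.n_phylo_pcs)
        for k in range(opts.n_phylo_pcs):
            col = f"phylo_pc{k + 1}"
            out[f"affected_{col}"] = pcs[col].reindex([a for a, _, _ in idx]).to_numpy()
        for k in range(opts.n_phylo_pcs):
            col = f"phylo_pc{k + 1}"
            out[f"affecting_{col}"] = pcs[col].reindex([b for _, b, _ in idx]).to_numpy()

    if not opts.drop_carbon:
        if carbon_projection is None:
            cpcs, _ = carbon_pcs(mono, opts.n_carbon_pcs)
        else:
            filled = impute_profiles(mono)
            order = carbon_projection.feature_labels or list(mono.index)
            profiles = filled.loc[order].to_numpy(dtype=float).T
            coords = carbon_projection.transform(profiles)
            cpcs = pd.DataFrame(
                coords, index=mono.columns,
                columns=[f"carbon_pc{i + 1}" for i in range(coords.shape[1])],
            )
        for col in cpcs.columns:
            out[col] = cpcs[col].reindex([c for _, _, c in idx]).to_numpy()

    if opts.one_hot_carbon:
        onehot = pd.get_dummies(pd.Series([c for _, _, c in idx], index=out.index),
                                prefix="carbon_is", dtype=float)
        out = pd.concat([out, onehot], axis=1)

    if opts.chemistry is not None:
        chem = opts.chemistry.reindex([c for _, _, c in idx])
        chem.index = out.index
        out = pd.concat([out, chem.add_prefix("chem_")], axis=1)

    if opts.pathways is not None:
        pw = opts.pathways
        blk_a = pw.reindex([a for a, _, _ in idx]).add_prefix("pathway_affected_")
        blk_b = pw.reindex([b for _, b, _ in idx]).add_prefix("pathway_affecting_")
        blk_a.index = blk_b.index = out.index
        out = pd.concat([out, blk_a, blk_b], axis=1)

    if opts.reciprocal_effect:
        lookup = dataset.effect_lookup()
        out["reciprocal_effect"] = [
            lookup.get((b, a, c), np.nan) for a, b, c in idx
        ]

    # rows with missing mandatory values correspond to dropped combinations
    mandatory = [c for c in out.columns if not c.startswith(("chem_", "pathway_"))]
    keep = out[mandatory].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} rows with missing mandatory features",
                      stacklevel=2)
    return out[keep]


def aligned_labels(dataset: InteractionDataset, features: pd.DataFrame) -> pd.DataFrame:
    """Effect strength and sign labels aligned to a feature table's index."""
    eff = dataset.effects.set_index(["affected", "affecting", "carbon"])
    return eff.loc[features.index, ["effect", "sign"]]


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=[0, 1, 2], float_precision="round_trip")
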