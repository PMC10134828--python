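"""Synthetic coculture screens with the statistical structure of real ones.

The generator is phenomenological: it plants the four regularities the
analysis relies on, without simulating any metabolism mechanistically.

1. A two-clade ultrametric phylogeny; within-clade distances are smaller
   than between-clade distances.
2. Monoculture log-yields whose species profiles are correlated across the
   phylogeny (Ornstein-Uhlenbeck-style kernel ``exp(-d/scale)``), at a
   tunable strength.
3. Directed effects that are mostly negative (calibrated intercept), depend
   negatively on the affected species' monoculture yield, weakly positively
   on the affecting species' yield, and carry a phylogenetically conserved
   component (close species give and receive similar effects).
4. Reciprocal effects that are only weakly dependent, replicate-level
   multiplicative noise, and a fraction of pair x carbon combinations
   missing at random.

Generation is a pure function of the config (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth
from .growth import MONO, InteractionDataset

__all__ = [
    "SyntheticConfig",
    "simulate_tree_distances",
    "simulate_monoculture_yields",
    "simulate_effects",
    "generate_dataset",
    "write_synthetic",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters of the synthetic screen.

    The defaults emulate the screen's scale and statistics: 20 species from
    two clades, 40 carbon environments, 3 replicates, ~76% negative effects,
    ~7% of directed pair x carbon combinations missing.
    """

    n_species: int = 20
    n_clades: int = 2
    n_carbons: int = 40
    n_replicates: int = 3

    #: strength (in [0,1]) of phylogenetic signal in monoculture yields
    yield_phylo_corr: float = 0.7
    #: coefficient of the affected species' standardized log mono yield
    beta_affected: float = -0.8
    #: coefficient of the affecting species' standardized log mono yield
    beta_affecting: float = 0.2
    #: sd of the phylogenetically conserved effect component
    conservation_sd: float = 0.35
    #: sd of the idiosyncratic effect component
    noise_sd: float = 0.35
    #: target fraction of negative effects (intercept is calibrated to it)
    target_negative_frac: float = 0.76
    #: fraction of directed (pair, carbon) coculture combinations deleted
    missing_frac: float = 0.07
    #: replicate-level multiplicative noise (coefficient of variation)
    replicate_cv: float = 0.1
    seed: int = 0

    # yield-model scales (log space)
    log_yield_mean: float = 1.0
    log_yield_sd: float = 0.6
    carbon_log_sd: float = 0.15
    species_log_sd: float = 0.3
    #: length scale of the phylogenetic kernel exp(-d/kernel_scale)
    kernel_scale: float = 0.5

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_clades > self.n_species:
            raise ValueError("n_clades cannot exceed n_species")
        if not 0 <= self.yield_phylo_corr <= 1:
            raise ValueError("yield_phylo_corr must be in [0, 1]")
        if not 0 <= self.missing_frac < 1:
            raise ValueError("missing_frac must be in [0, 1)")
        for name in ("conservation_sd", "noise_sd", "replicate_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def species_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_species)]

    @property
    def carbon_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_carbons)]

    def clade_of(self) -> dict[str, int]:
        """Species -> clade index, contiguous near-equal blocks."""
        bounds = np.linspace(0, self.n_species, self.n_clades + 1).astype(int)
        clades = {}
        for k in range(self.n_clades):
            for s in self.species_ids[bounds[k]:bounds[k + 1]]:
                clades[s] = k
        return clades


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    # per-stage seeding: each simulate_* is deterministic on its own
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(stage,)))


def simulate_tree_distances(config: SyntheticConfig) -> pd.DataFrame:
    """Patristic distances of a random ultrametric multi-clade tree.

    Each clade is a random coalescent (tips merge pairwise at increasing
    heights below 0.45); all clades join at the root (height 1.0), so
    within-clade distances (< 0.9) are always smaller than between-clade
    distances (= 2.0).  Ultrametric distances satisfy the triangle
    inequality by construction.
    """
    rng = _rng(config, 0)
    species = config.species_ids
    clades = config.clade_of()
    n = len(species)
    depth = np.full((n, n), 1.0)  # MRCA height; root at 1.0
    np.fill_diagonal(depth, 0.0)
    idx = {s: i for i, s in enumerate(species)}
    for k in range(config.n_clades):
        members = [s for s in species if clades[s] == k]
        clusters = [[idx[s]] for s in members]
        if len(clusters) < 2:
            continue
        heights = np.sort(rng.uniform(0.05, 0.45, size=len(clusters) - 1))
        for h in heights:
            i, j = rng.choice(len(clusters), size=2, replace=False)
            a, b = clusters[int(i)], clusters[int(j)]
            for u in a:
                for v in b:
                    depth[u, v] = depth[v, u] = h
            merged = a + b
            clusters = [c for t, c in enumerate(clusters) if t not in (int(i), int(j))]
            clusters.append(merged)
    dist = 2.0 * depth
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=species, columns=species)


def _phylo_kernel(config: SyntheticConfig, phylo_dist: pd.DataFrame) -> np.ndarray:
    K = np.exp(-phylo_dist.to_numpy(dtype=float) / config.kernel_scale)
    return K


def _chol(K: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(K + 1e-9 * np.eye(K.shape[0]))


def simulate_monoculture_yields(
    config: SyntheticConfig, phylo_dist: pd.DataFrame
) -> pd.DataFrame:
    """Log-normal monoculture yields with a planted phylogenetic signal.

    log yield[s, c] = mean + species_intercept[s] + carbon_intercept[c]
                      + sd * (sqrt(rho) * u[s, c] + sqrt(1 - rho) * e[s, c])

    where for each carbon the u column is multivariate normal with
    covariance exp(-d/scale) over species (so close species have similar
    yield profiles at strength rho = yield_phylo_corr) and e is iid.
    """
    rng = _rng(config, 1)
    species, carbons = list(phylo_dist.index), config.carbon_ids
    n, m = len(species), len(carbons)
    L = _chol(_phylo_kernel(config, phylo_dist))
    u = L @ rng.standard_normal((n, m))
    e = rng.standard_normal((n, m))
    b_s = rng.normal(0.0, config.species_log_sd, size=n)[:, None]
    a_c = rng.normal(0.0, config.carbon_log_sd, size=m)[None, :]
    rho = config.yield_phylo_corr
    logy = (
        config.log_yield_mean + b_s + a_c
        + config.log_yield_sd * (np.sqrt(rho) * u + np.sqrt(1 - rho) * e)
    )
    return pd.DataFrame(np.exp(logy), index=species, columns=carbons)


def _zscore_columns(logy: np.ndarray) -> np.ndarray:
    """Per-carbon standardization of log monoculture yields (ddof=0)."""
    mu = logy.mean(axis=0, keepdims=True)
    sd = logy.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (logy - mu) / sd


def latent_effects(
    config: SyntheticConfig, phylo_dist: pd.DataFrame, mono_yields: pd.DataFrame
) -> pd.DataFrame:
    """Latent (noise-free at the replicate level) directed effects.

    effect(A <- B, c) = intercept + beta_affected * z(log mono_A, c)
                        + beta_affecting * z(log mono_B, c)
                        + conserved(A, B, c) + eps(A, B, c)

    The conserved term has separable covariance
    ``conservation_sd^2 * K[A,A'] * K[B,B']`` per carbon with
    ``K = exp(-d/scale)``: phylogenetically close species both exert and
    receive similar effects.  The intercept is calibrated by bisection so
    the realized negative-sign fraction matches the configured target.
    """
    rng = _rng(config, 2)
    species = list(phylo_dist.index)
    n, m = len(species), config.n_carbons
    z = _zscore_columns(np.log(mono_yields.to_numpy(dtype=float)))
    L = _chol(_phylo_kernel(config, phylo_dist))

    off = ~np.eye(n, dtype=bool)
    comp = np.empty((n, n, m))
    for c in range(m):
        conserved = config.conservation_sd * (L @ rng.standard_normal((n, n)) @ L.T)
        eps = rng.normal(0.0, config.noise_sd, size=(n, n))
        comp[:, :, c] = (
            config.beta_affected * z[:, c][:, None]
            + config.beta_affecting * z[:, c][None, :]
            + conserved + eps
        )
    values = comp[off, :].ravel()
    intercept = _calibrate_intercept(values, config.target_negative_frac)

    rows = []
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i == j:
                continue
            for c, carbon in enumerate(config.carbon_ids):
                rows.append((a, b, carbon, intercept + comp[i, j, c]))
    out = pd.DataFrame(rows, columns=["affected", "affecting", "carbon", "effect"])
    out.attrs["intercept"] = intercept
    return out


def _calibrate_intercept(values: np.ndarray, target: float, tol: float = 0.05) -> float:
    """Bisection on the intercept so that P(value + intercept < 0) = target."""
    lo, hi = float(values.min()) - 1.0, float(values.max()) + 1.0
    # fraction negative is monotone decreasing in the intercept
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(values + mid < 0))
        if frac > target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    frac = float(np.mean(values + mid < 0))
    if abs(frac - target) > tol:
        if np.unique(values).size == 1:
            # fully degenerate effect distribution: only fractions 0 and 1
            # are achievable; pin all effects at zero (negative class)
            import warnings

            warnings.warn(
                "target sign fraction unreachable for a constant effect "
                "distribution; effects pinned at the intercept", stacklevel=2)
            return -float(values[0])
        raise RuntimeError(
            f"intercept calibration failed: reached negative fraction {frac:.3f}, "
            f"target {target:.3f}"
        )
    return mid


def simulate_effects(
    config: SyntheticConfig, phylo_dist: pd.DataFrame, mono_yields: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-level growth table realizing the latent effect model.

    Returns ``(growth_table, truth)`` where the growth table holds mono and
    coculture replicate records (coculture yield of the affected species =
    mono yield x exp(latent effect), with multiplicative replicate noise of
    coefficient of variation ``replicate_cv``), and truth holds the latent
    effects for recovery tests.  A ``missing_frac`` fraction of directed
    (pair, carbon) combinations is deleted uniformly at random.
    """
    truth = latent_effects(config, phylo_dist, mono_yields)
    rng = _rng(config, 3)
    species = list(phylo_dist.index)
    cv = config.replicate_cv
    # lognormal multiplicative noise with mean 1 and the requested CV
    sig = np.sqrt(np.log1p(cv * cv))

    def noise(size):
        if cv == 0:
            return np.ones(size)
        return np.exp(rng.normal(-0.5 * sig * sig, sig, size=size))

    rows = []
    for s in species:
        for c in config.carbon_ids:
            base = mono_yields.loc[s, c]
            for r, y in enumerate(base * noise(config.n_replicates), start=1):
                rows.append((s, MONO, c, r, y))

    keep = rng.random(len(truth)) >= config.missing_frac
    truth = truth.assign(observed=keep)
    for rec, kept in zip(truth.itertuples(index=False), keep):
        if not kept:
            continue
        base = mono_yields.loc[rec.affected, rec.carbon] * np.exp(rec.effect)
        for r, y in enumerate(base * noise(config.n_replicates), start=1):
            rows.append((rec.affected, rec.affecting, rec.carbon, r, y))

    table = pd.DataFrame(rows, columns=growth.GROWTH_COLUMNS)
    return table, truth


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[InteractionDataset, pd.DataFrame]:
    """Full generative path, routed through the real data-processing code.

    Returns ``(dataset, truth)``.  The growth table is passed through the
    replicate filter and the log-ratio effect computation, so the entire
    loading path is exercised; with ``replicate_cv=0`` the recovered effects
    equal the latent ones exactly.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    phylo = simulate_tree_distances(config)
    mono = simulate_monoculture_yields(config, phylo)
    table, truth = simulate_effects(config, phylo, mono)
    min_reps = min(3, config.n_replicates)
    dataset = growth.build_dataset(table, phylo, min_reps=min_reps)
    return dataset, truth


def write_synthetic(config: SyntheticConfig, outdir) -> None:
    """Write growth.csv, phylo_dist.csv and truth.csv for a config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phylo = simulate_tree_distances(config)
    mono = simulate_monoculture_yields(config, phylo)
    table, truth = simulate_effects(config, phylo, mono)
    growth.write_growth_table(table, outdir / "growth.csv")
    phylo.to_csv(outdir / "phylo_dist.csv", float_format="%.17g")
    truth.to_csv(outdir / "truth.csv", index=False, float_format="%.17g")
    pd.Series(asdict(config)).to_json(outdir / "config.json")
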