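"""Replicate-level growth tables and directed growth effects.

A coculture screen yields endpoint growth of each species alone (monoculture)
and in pair coculture, across carbon environments, with a few replicates per
condition.  The directed effect of species B on species A in carbon c is the
log ratio of A's mean coculture yield (with B) to A's mean monoculture yield
in that carbon.  Negative effects are inhibition, positive facilitation.

The long-format growth table has columns ``species, partner, carbon,
replicate, yield`` where ``partner == "MONO"`` marks monoculture records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dataclasses_field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel partner id for monoculture records.
MONO = "MONO"

GROWTH_COLUMNS = ["species", "partner", "carbon", "replicate", "yield"]
EFFECT_COLUMNS = ["affected", "affecting", "carbon", "effect", "sign"]

POSITIVE = "positive"
NEGATIVE = "negative"

PAIR_TYPES = ("competition", "mutualism", "parasitism")


@dataclass
class InteractionDataset:
    """Directed effects plus the monoculture yields and phylogeny behind them.

    Attributes
    ----------
    effects : pandas.DataFrame
        One row per directed (affected, affecting, carbon) with the log-ratio
        ``effect`` and its ``sign`` label.
    mono_yields : pandas.DataFrame
        species x carbon matrix of mean monoculture yields (NaN = missing).
    phylo_dist : pandas.DataFrame
        species x species symmetric patristic/phylogenetic distances,
        zero diagonal.
    """

    effects: pd.DataFrame
    mono_yields: pd.DataFrame
    phylo_dist: pd.DataFrame
    _lookup_cache: dict | None = dataclasses_field(default=None, init=False, repr=False)
    _profile_cache: pd.DataFrame | None = dataclasses_field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        validate_phylo_dist(self.phylo_dist)
        eff_species = set(self.effects["affected"]) | set(self.effects["affecting"])
        missing = eff_species - set(self.mono_yields.index)
        if missing:
            raise ValueError(f"species in effects absent from mono_yields: {sorted(missing)}")
        missing_c = set(self.effects["carbon"]) - set(self.mono_yields.columns)
        if missing_c:
            raise ValueError(f"carbons in effects absent from mono_yields: {sorted(missing_c)}")

    @property
    def species(self) -> list[str]:
        return list(self.mono_yields.index)

    @property
    def carbons(self) -> list[str]:
        return list(self.mono_yields.columns)

    def effect_lookup(self) -> dict[tuple[str, str, str], float]:
        """Mapping (affected, affecting, carbon) -> effect value (cached)."""
        if self._lookup_cache is None:
            self._lookup_cache = {
                (r.affected, r.affecting, r.carbon): r.effect
                for r in self.effects.itertuples(index=False)
            }
        return self._lookup_cache

    def imputed_profiles(self) -> pd.DataFrame:
        """Monoculture yields with missing entries imputed (cached)."""
        if self._profile_cache is None:
            from .features import impute_profiles

            self._profile_cache = impute_profiles(self.mono_yields)
        return self._profile_cache


def validate_phylo_dist(d: pd.DataFrame) -> None:
    if list(d.index) != list(d.columns):
        raise ValueError("phylo_dist must have identical row and column labels")
    a = d.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("phylo_dist must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("phylo_dist must have a zero diagonal")
    if (a < -1e-12).any():
        raise ValueError("phylo_dist must be non-negative")


def validate_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column names, non-negative yields and key uniqueness."""
    missing = [c for c in GROWTH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"growth table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("empty growth table")
    if (table["yield"] < 0).any():
        raise ValueError("yields must be non-negative")
    if (table["species"] == MONO).any():
        raise ValueError(f"species id equal to the {MONO} sentinel")
    keys = table[["species", "partner", "carbon", "replicate"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (species, partner, carbon, replicate) keys")
    return table


def filter_min_replicates(raw: pd.DataFrame, min_reps: int = 3) -> pd.DataFrame:
    """Drop every (species, partner, carbon) group with fewer replicates.

    The screen excludes conditions represented by fewer than three replicates;
    ``min_reps=1`` is a no-op.  The dropped fraction of records is logged.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    validate_growth_table(raw)
    sizes = raw.groupby(["species", "partner", "carbon"])["yield"].transform("size")
    out = raw[sizes >= min_reps].reset_index(drop=True)
    dropped = 1.0 - len(out) / len(raw)
    logger.info(
        "replicate filter (min %d): kept %d/%d records (dropped fraction %.4f)",
        min_reps, len(out), len(raw), dropped,
    )
    return out


def mono_yield_matrix(filtered: pd.DataFrame) -> pd.DataFrame:
    """species x carbon matrix of mean monoculture yields over replicates."""
    mono = filtered[filtered["partner"] == MONO]
    return mono.pivot_table(index="species", columns="carbon", values="yield", aggfunc="mean")


def compute_effects(filtered: pd.DataFrame) -> pd.DataFrame:
    """Directed log-ratio effects from a replicate-filtered growth table.

    effect(A <- B, c) = ln( mean coculture yield of A with B in c
                            / mean monoculture yield of A in c )

    Means are arithmetic over surviving replicates (mono and co droplets are
    unpaired).  Records whose monoculture reference is missing, or whose
    mono/co mean is zero, are dropped with a warning.
    """
    validate_growth_table(filtered)
    mono_means = (
        filtered[filtered["partner"] == MONO]
        .groupby(["species", "carbon"])["yield"].mean()
    )
    co = filtered[filtered["partner"] != MONO]
    co_means = co.groupby(["species", "partner", "carbon"])["yield"].mean()

    rows = []
    n_dropped = 0
    for (affected, affecting, carbon), co_mean in co_means.items():
        mono_mean = mono_means.get((affected, carbon))
        if mono_mean is None:
            n_dropped += 1
            continue
        if co_mean == 0.0 or mono_mean == 0.0:
            n_dropped += 1
            continue
        effect = float(np.log(co_mean / mono_mean))
        rows.append((affected, affecting, carbon, effect,
                     POSITIVE if effect > 0 else NEGATIVE))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} coculture conditions with zero or missing "
            "monoculture reference", stacklevel=2,
        )
    out = pd.DataFrame(rows, columns=EFFECT_COLUMNS)
    return out.sort_values(["affected", "affecting", "carbon"]).reset_index(drop=True)


def label_pair_type(e_ab, e_ba) -> str:
    """Classify a two-way interaction: (-,-) competition, (+,+) mutualism,
    mixed signs parasitism.

    Both records must be the two directions of the same pair in the same
    carbon environment.
    """
    if e_ab["carbon"] != e_ba["carbon"] or (
        e_ab["affected"] != e_ba["affecting"] or e_ab["affecting"] != e_ba["affected"]
    ):
        raise ValueError("records are not the two directions of one pair in one carbon")
    s1, s2 = e_ab["sign"], e_ba["sign"]
    if s1 == NEGATIVE and s2 == NEGATIVE:
        return "competition"
    if s1 == POSITIVE and s2 == POSITIVE:
        return "mutualism"
    return "parasitism"


def build_dataset(
    growth: pd.DataFrame,
    phylo_dist: pd.DataFrame,
    min_reps: int = 3,
) -> InteractionDataset:
    """Full path: replicate filter -> effects -> canonical dataset."""
    filtered = filter_min_replicates(growth, min_reps=min_reps)
    effects = compute_effects(filtered)
    mono = mono_yield_matrix(filtered)
    species = sorted(set(mono.index) | set(phylo_dist.index))
    species = [s for s in phylo_dist.index if s in set(species)]
    mono = mono.reindex(index=list(phylo_dist.index))
    return InteractionDataset(effects=effects, mono_yields=mono, phylo_dist=phylo_dist)


# ---------------------------------------------------------------------------
# I/O

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def read_growth_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"species": str, "partner": str, "carbon": str})
    return validate_growth_table(table)


def write_growth_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_effects(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_effects(path) -> pd.DataFrame:
    eff = pd.read_csv(path, dtype={"affected": str, "affecting": str, "carbon": str},
                      float_precision="round_trip")
    missing = [c for c in EFFECT_COLUMNS if c not in eff.columns]
    if missing:
        raise ValueError(f"effects table missing columns: {missing}")
    return eff


def write_dataset(dataset: InteractionDataset, outdir) -> None:
    """Serialize the canonical dataset (effects, mono yields, distances)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_effects(dataset.effects, outdir / "effects.csv")
    dataset.mono_yields.to_csv(outdir / "mono_yields.csv", float_format=_FLOAT_FMT)
    dataset.phylo_dist.to_csv(outdir / "phylo_dist.csv", float_format=_FLOAT_FMT)


def read_dataset(outdir) -> InteractionDataset:
    from pathlib import Path

    outdir = Path(outdir)
    effects = read_effects(outdir / "effects.csv")
    mono = pd.read_csv(outdir / "mono_yields.csv", index_col=0,
                       float_precision="round_trip")
    phylo = pd.read_csv(outdir / "phylo_dist.csv", index_col=0,
                        float_precision="round_trip")
    return InteractionDataset(effects=effects, mono_yields=mono, phylo_dist=phylo)


def read_phylo_distances(path) -> pd.DataFrame:
    """Read species distances from a square CSV or a newick tree.

    Newick trees (``.nwk``, ``.newick``, ``.tre``) are converted to patristic
    distances (sum of branch lengths along the path between tips).
    """
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in {".nwk", ".newick", ".tre", ".tree"}:
        import dendropy

        tree = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        labels = [t.label for t in taxa]
        n = len(labels)
        mat = np.zeros((n, n))
        for i, ti in enumerate(taxa):
            for j, tj in enumerate(taxa):
                if i < j:
                    mat[i, j] = mat[j, i] = pdm.patristic_distance(ti, tj)
        d = pd.DataFrame(mat, index=labels, columns=labels)
    else:
        d = pd.read_csv(path, index_col=0)
        d.columns = [str(c) for c in d.columns]
        d.index = [str(i) for i in d.index]
    validate_phylo_dist(d)
    return d
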