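"""Assemble the model feature table.

Phylogenetic PCs (2 per species), carbon metabolic-profile PCs (4),
metabolic distance and both monoculture yields, one row per directed
effect.  Prints the variance captured by the retained components.
"""

import argparse
from pathlib import Path

from pairfx import growth
from pairfx.features import assemble_features, carbon_pcs, phylo_pcs, write_features

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "results" / "dataset")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "features.csv")
    args = ap.parse_args()

    ds = growth.read_dataset(args.dataset)
    _, phylo_evr = phylo_pcs(ds.phylo_dist)
    _, proj = carbon_pcs(ds.mono_yields)
    X = assemble_features(ds)
    write_features(X, args.out)

    print(f"{X.shape[0]} rows x {X.shape[1]} features -> {args.out}")
    print(f"  phylogenetic PC1-2 explained variance: {phylo_evr.sum():.1%}")
    print(f"  carbon PC1-4 explained variance: "
          f"{proj.explained_variance_ratio.sum():.1%}")


if __name__ == "__main__":
    main()
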