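"""Replicate filter and directed log-ratio effects.

Reads the replicate-level growth table written by 01_simulate_screen.py,
drops conditions with fewer than three replicates, computes
effect = ln(coculture mean / monoculture mean) for every directed pair x
carbon, and writes the canonical dataset under results/dataset/.
"""

import argparse
import logging
from pathlib import Path

from pairfx import growth
from pairfx.interpretation import reciprocal_pairs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "dataset")
    ap.add_argument("--min-reps", type=int, default=3)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO)

    table = growth.read_growth_table(args.data / "growth.csv")
    phylo = growth.read_phylo_distances(args.data / "phylo_dist.csv")
    ds = growth.build_dataset(table, phylo, min_reps=args.min_reps)
    growth.write_dataset(ds, args.out)

    neg = (ds.effects["sign"] == "negative").mean()
    print(f"{len(ds.effects)} directed effects -> {args.out}")
    print(f"  negative fraction: {neg:.3f}")
    pairs = reciprocal_pairs(ds.effects)
    types = pairs.apply(
        lambda r: "competition" if r.effect_on_a <= 0 and r.effect_on_b <= 0
        else "mutualism" if r.effect_on_a > 0 and r.effect_on_b > 0
        else "parasitism", axis=1).value_counts(normalize=True)
    print("  two-way interaction types:")
    for name, frac in types.items():
        print(f"    {name}: {frac:.3f}")


if __name__ == "__main__":
    main()
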