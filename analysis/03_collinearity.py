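#!/usr/bin/env python
"""Detect collinear blocks for every genome pair (self-comparisons
included).

Anchors come from the all-vs-all homology table (top 5 hits per gene per
target genome); blocks need >= 5 collinear anchors with <= 25 intervening
genes between consecutive anchors. Writes results/blocks_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mybsynnet.collinearity import ChainParams, all_pairs_synteny, blocks_to_table
from mybsynnet.pipeline import load_dataset

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=ROOT / "scratch" / "dataset")
    args = ap.parse_args()
    ds = load_dataset(args.datadir)
    blocks = all_pairs_synteny(ds.registry, ds.hits, ChainParams())
    table = blocks_to_table(blocks)
    table.to_csv(ROOT / "scratch" / "blocks.tsv", sep="\t", index=False)
    summary = (
        table.groupby(["species_a", "species_b", "block_id"])
        .agg(n_anchors=("gene_a", "size"))
        .reset_index()
        .groupby(["species_a", "species_b"])
        .agg(n_blocks=("block_id", "nunique"), anchors=("n_anchors", "sum"))
        .reset_index()
    )
    out = ROOT / "results" / "blocks_summary.tsv"
    out.parent.mkdir(exist_ok=True)
    summary.to_csv(out, sep="\t", index=False)
    n_self = sum(b.species_a == b.species_b for b in blocks)
    print(f"{len(blocks)} blocks ({n_self} intra-genome) over "
          f"{len(summary)} genome pairs -> {out}")


if __name__ == "__main__":
    main()
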