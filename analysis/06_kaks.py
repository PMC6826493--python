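#!/usr/bin/env python
"""Nei-Gojobori Ka/Ks over the focal/reference syntelog pairs.

The pair set is the synteny-network edges between the two species
(computed by 04_network_clusters.py) — homologs supported by conserved
gene order, the family-scan analog of a curated homologous pair list.
Each pair is codon-aligned and scored; the selection-class breakdown is
written to results/kaks_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mybsynnet.io_formats import read_edgelist
from mybsynnet.kaks import codon_align, family_pair_scan
from mybsynnet.pipeline import load_dataset

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=ROOT / "scratch" / "dataset")
    ap.add_argument("--edges", type=Path,
                    default=ROOT / "scratch" / "pipeline" / "edges.tsv")
    ap.add_argument("--focal", default="ros1")
    ap.add_argument("--reference", default="ros2")
    args = ap.parse_args()
    if not args.edges.exists():
        raise SystemExit(f"{args.edges} not found; run 04_network_clusters.py first")
    ds = load_dataset(args.datadir)
    pairs = []
    for a, b in sorted(read_edgelist(args.edges)):
        species = {ds.registry.gene(a).species, ds.registry.gene(b).species}
        if species == {args.focal, args.reference}:
            if ds.registry.gene(a).species != args.focal:
                a, b = b, a
            pairs.append((a, b))
    alignments = {}
    for ga, gb in pairs:
        pa, pb = ds.proteins[ga], ds.proteins[gb]
        if len(pa) == len(pb):
            alignments[(ga, gb)] = codon_align((pa, pb), ds.cds[ga], ds.cds[gb])
    fam_a = sorted({a for a, _ in pairs})
    fam_b = sorted({b for _, b in pairs})
    table, summary = family_pair_scan(fam_a, fam_b, alignments)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "kaks_pairs.tsv", sep="\t", index=False,
                 float_format="%.4f")
    pd.Series(summary).to_csv(results / "kaks_summary.tsv", sep="\t",
                              header=False, float_format="%.4f")
    print(f"{int(summary['n_pairs'])} syntelog pairs "
          f"({int(summary['n_defined'])} with defined rates): "
          f"purifying {summary['frac_purifying']:.2%}, "
          f"positive {summary['frac_positive']:.2%}, "
          f"neutral {summary['frac_neutral']:.2%}")


if __name__ == "__main__":
    main()
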