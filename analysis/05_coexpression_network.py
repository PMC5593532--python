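#!/usr/bin/env python
"""Build the coding-noncoding correlation network over DE-passing genes.

Pearson correlations over all pooled arrays for every cross-biotype pair;
edges retained at |r| > 0.90 and p < 0.01. Writes the edge list and GraphML.
"""

import argparse
from pathlib import Path

import pandas as pd

from cerna_forge import io
from cerna_forge.coexpression import build_cnc_network
from cerna_forge.model import Config
from cerna_forge.pipeline import combine_matrices

ROOT = Path(__file__).resolve().parent.parent
STEMS = {"lncRNA": "lncrna", "mRNA": "mrna", "miRNA": "mirna"}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--norm-dir", type=Path,
                        default=ROOT / "results" / "normalized")
    parser.add_argument("--de-dir", type=Path, default=ROOT / "results" / "de")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "network")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = Config()
    matrices = {
        biotype: io.read_expression_table(
            args.norm_dir / f"{stem}_matrix.tsv", args.norm_dir / f"{stem}_labels.tsv"
        )
        for biotype, stem in STEMS.items()
    }
    passing = set(pd.read_csv(args.de_dir / "de_passing.tsv", sep="\t")["gene_id"])
    combined = combine_matrices(matrices).subset_genes(passing)
    edges = build_cnc_network(combined, config=config)
    io.write_network(edges, args.out_dir / "cnc_network")

    by_kind: dict[str, int] = {}
    for e in edges:
        kind = "-".join(sorted((e.biotype_a, e.biotype_b)))
        by_kind[kind] = by_kind.get(kind, 0) + 1
    print(f"{len(edges)} edges among {len(combined.gene_ids)} DE genes at "
          f"|r| > {config.r_threshold}, p < {config.p_threshold_corr}")
    for kind, count in sorted(by_kind.items()):
        print(f"  {kind}: {count}")


if __name__ == "__main__":
    main()
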