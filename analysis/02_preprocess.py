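#!/usr/bin/env python
"""Background-filter every matrix and quantile-normalize the miRNA arrays.

Mirrors vendor practice for this study design: signals never rising above
the background floor are dropped, and the miRNA matrix is forced onto a
common intensity distribution (the lncRNA/mRNA arrays keep their vendor
normalization, i.e. pass through unchanged).
"""

import argparse
from pathlib import Path

from cerna_forge import io
from cerna_forge.model import Config
from cerna_forge.pipeline import preprocess_matrices

ROOT = Path(__file__).resolve().parent.parent
STEMS = {"lncRNA": "lncrna", "mRNA": "mrna", "miRNA": "mirna"}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out-dir", type=Path,
                        default=ROOT / "results" / "normalized")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = Config()
    matrices = {
        biotype: io.read_expression_table(
            args.data_dir / f"{stem}_matrix.tsv", args.data_dir / f"{stem}_labels.tsv"
        )
        for biotype, stem in STEMS.items()
    }
    processed, removed = preprocess_matrices(matrices, config)
    with open(args.out_dir / "filtered_genes.txt", "w") as fh:
        for biotype, genes in removed.items():
            for g in genes:
                fh.write(f"{biotype}\t{g}\n")
    for biotype, matrix in processed.items():
        stem = STEMS[biotype]
        io.write_expression_table(matrix, args.out_dir / f"{stem}_matrix.tsv",
                                  args.out_dir / f"{stem}_labels.tsv")
        mode = ("quantile-normalized" if biotype == "miRNA" else "passed through")
        print(f"{biotype}: kept {len(matrix.gene_ids)} genes "
              f"(removed {len(removed[biotype])} below background "
              f"{config.background_level}), {mode}")


if __name__ == "__main__":
    main()
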