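#!/usr/bin/env python
"""Paired differential-expression screening of all three biotypes.

Screens every gene with the paired t-test and the biotype's fold-change
cutoff (linear FC > 2.0 for lncRNA/mRNA, > 1.5 for miRNA, p <= 0.05) and
exports full results, the passing set, and volcano-plot coordinates.
"""

import argparse
from pathlib import Path

import pandas as pd

from cerna_forge import io
from cerna_forge.diffexpr import compute_differential, records_to_frame, volcano_coordinates
from cerna_forge.model import Config

ROOT = Path(__file__).resolve().parent.parent
STEMS = {"lncRNA": "lncrna", "mRNA": "mrna", "miRNA": "mirna"}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data-dir", type=Path,
                        default=ROOT / "results" / "normalized")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "de")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = Config()
    all_frames = []
    for biotype, stem in STEMS.items():
        matrix = io.read_expression_table(
            args.data_dir / f"{stem}_matrix.tsv", args.data_dir / f"{stem}_labels.tsv"
        )
        records = compute_differential(matrix, config)
        frame = records_to_frame(records)
        all_frames.append(frame)
        volcano_coordinates(records, config.volcano_y_cap).to_csv(
            args.out_dir / f"volcano_{stem}.tsv", sep="\t", index=False,
            float_format="%.6g")
        up = int(((frame["passes"]) & (frame["direction"] == "up")).sum())
        down = int(((frame["passes"]) & (frame["direction"] == "down")).sum())
        print(f"{biotype}: {up + down} differentially expressed "
              f"({up} up, {down} down) of {len(frame)} "
              f"at FC > {config.fc_threshold_for(biotype)}, "
              f"p <= {config.p_threshold_de}")

    combined = pd.concat(all_frames, ignore_index=True)
    combined.to_csv(args.out_dir / "de_results.tsv", sep="\t", index=False,
                    float_format="%.6g")
    combined[combined["passes"]].to_csv(args.out_dir / "de_passing.tsv", sep="\t",
                                        index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
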