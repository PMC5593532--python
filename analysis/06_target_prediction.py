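#!/usr/bin/env python
"""Predict miRNA seed targets, cis/trans lncRNA targets and promoter TF sites.

Four screens over the dataset's sequences and coordinates: exact 7mer seed
complements in 3'UTRs and lncRNA transcripts; lncRNA-mRNA pairs within
10 kb; BLAT-like ungapped similarity between lncRNAs and 3'UTRs; and TF
consensus motifs in the -2000/+500 bp promoter windows.
"""

import argparse
from pathlib import Path

from cerna_forge import io
from cerna_forge.model import Config
from cerna_forge.simulate import default_motifs
from cerna_forge.targets import cis_targets, scan_tf_motifs, seed_targets, trans_targets

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "targets")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = Config()
    seqs = io.read_fasta(args.data_dir / "sequences.fasta")

    matches = seed_targets(seqs, seqs)
    with open(args.out_dir / "seed_matches.tsv", "w") as fh:
        fh.write("mirna_id\ttarget_id\ttarget_role\toffset\tmatch_type\n")
        for m in matches:
            fh.write(f"{m.mirna_id}\t{m.target_id}\t{m.target_role}\t"
                     f"{m.offset}\t{m.match_type}\n")

    annotations = io.read_annotation(args.data_dir / "annotation.bed")
    lnc = [a for a in annotations if a.biotype == "lncRNA"]
    mrna = [a for a in annotations if a.biotype == "mRNA"]
    cis = cis_targets(lnc, mrna, config.cis_window_bp)
    with open(args.out_dir / "cis_pairs.tsv", "w") as fh:
        fh.write("lncrna_id\tmrna_id\tdistance_bp\n")
        for l, g, d in cis:
            fh.write(f"{l}\t{g}\t{d}\n")

    trans = trans_targets(seqs, seqs, config)
    with open(args.out_dir / "trans_hits.tsv", "w") as fh:
        fh.write("lncrna_id\tmrna_id\taligned_length\tidentity\tscore\n")
        for h in trans:
            fh.write(f"{h.lncrna_id}\t{h.mrna_id}\t{h.aligned_length}\t"
                     f"{h.identity:.4f}\t{h.score}\n")

    tf_hits = scan_tf_motifs(seqs, default_motifs(), config)
    with open(args.out_dir / "tf_hits.tsv", "w") as fh:
        fh.write("motif_id\tlncrna_id\tposition\tstrand\tscore\n")
        for h in tf_hits:
            fh.write(f"{h.motif_id}\t{h.lncrna_id}\t{h.position}\t"
                     f"{h.strand}\t{h.score}\n")

    print(f"{len(matches)} seed matches "
          f"({sum(m.target_role == 'three_prime_utr' for m in matches)} in 3'UTRs, "
          f"{sum(m.target_role == 'transcript' for m in matches)} in lncRNAs)")
    print(f"{len(cis)} cis pairs within {config.cis_window_bp / 1000:.0f} kb")
    print(f"{len(trans)} trans hits at identity >= {config.trans_min_identity}")
    print(f"{len(tf_hits)} TF motif hits in promoter windows")


if __name__ == "__main__":
    main()
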