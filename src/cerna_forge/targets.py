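"""Target prediction: miRNA seed matches, cis (genomic proximity) and trans
(sequence similarity) lncRNA targets, and TF motifs in promoter windows.

miRNA targeting uses the canonical 7mer seed rule: an exact match of the
DNA reverse complement of miRNA positions 2-8 in an mRNA 3'UTR or a lncRNA
transcript. Trans prediction is an 11-mer seed-and-extend ungapped local
aligner with BLAT-like defaults (tile 11, +1/-3 scoring, X-drop 10); cis
prediction keeps lncRNA-mRNA pairs whose genomic intervals lie within a
10 kb gap on the same chromosome. TF scanning covers a strand-aware window
from 2000 bp upstream to 500 bp downstream of each lncRNA's transcription
start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DataError, FormatError
from .model import Config, GeneAnnotation, SequenceSet
from .motifs import Motif, reverse_complement

log = logging.getLogger(__name__)

SEED_LENGTH = 7  # miRNA positions 2-8


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    target_id: str
    target_role: str  # three_prime_utr | transcript
    offset: int
    match_type: str = "7mer"


@dataclass(frozen=True)
class TransHit:
    lncrna_id: str
    mrna_id: str
    aligned_length: int
    identity: float
    score: int


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    lncrna_id: str
    position: int  # relative to TSS; negative = upstream
    strand: str
    score: float


def seed_sequence(mirna_seq: str) -> str:
    """DNA reverse complement of the miRNA seed (positions 2-8)."""
    if len(mirna_seq) < 8:
        raise FormatError(f"miRNA sequence shorter than 8 nt: {mirna_seq!r}")
    seed_rna = mirna_seq[1:8]
    return reverse_complement(seed_rna.replace("U", "T"))


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return
        yield pos
        start = pos + 1  # overlapping occurrences count


def seed_targets(
    mirnas: SequenceSet,
    targets: SequenceSet,
    roles: Sequence[str] = ("three_prime_utr", "transcript"),
) -> list[SeedMatch]:
    """All exact 7mer seed-complement occurrences in the target sequences."""
    matches: list[SeedMatch] = []
    for mirna_id in mirnas.ids_with_role("mirna"):
        site = seed_sequence(mirnas[mirna_id])
        for role in roles:
            for target_id in targets.ids_with_role(role):
                for offset in _find_all(targets[target_id], site):
                    matches.append(SeedMatch(mirna_id, target_id, role, offset))
    return matches


def interval_gap(a: GeneAnnotation, b: GeneAnnotation) -> int | None:
    """Genomic gap between two loci; 0 when overlapping, None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def cis_targets(
    lnc_annotations: Sequence[GeneAnnotation],
    mrna_annotations: Sequence[GeneAnnotation],
    window_bp: int = 10_000,
) -> list[tuple[str, str, int]]:
    """lncRNA-mRNA pairs whose intervals lie within ``window_bp`` (inclusive).

    Distance is the interval gap, strand-blind; overlapping loci have
    distance 0.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for m in mrna_annotations:
        by_chrom.setdefault(m.chrom, []).append(m)
    out = []
    for lnc in lnc_annotations:
        for m in by_chrom.get(lnc.chrom, ()):
            gap = interval_gap(lnc, m)
            if gap is not None and gap <= window_bp:
                out.append((lnc.gene_id, m.gene_id, gap))
    return out


# ---------------------------------------------------------------------------
# trans prediction: 11-mer seed-and-extend ungapped local alignment


def _extend_ungapped(a: str, b: str, i: int, j: int, length: int,
                     match: int, mismatch: int, xdrop: int):
    """Extend an exact seed at a[i:i+length] == b[j:j+length] in both
    directions without gaps; each side stops when the running score falls
    ``xdrop`` below its maximum. Returns (a_start, a_end, score, matches)."""
    score = length * match
    # right
    best, best_k = 0, 0
    run = 0
    k = 0
    while i + length + k < len(a) and j + length + k < len(b):
        run += match if a[i + length + k] == b[j + length + k] else mismatch
        k += 1
        if run > best:
            best, best_k = run, k
        if run <= best - xdrop:
            break
    right_ext, right_gain = best_k, best
    # left
    best, best_k = 0, 0
    run = 0
    k = 0
    while i - 1 - k >= 0 and j - 1 - k >= 0:
        run += match if a[i - 1 - k] == b[j - 1 - k] else mismatch
        k += 1
        if run > best:
            best, best_k = run, k
        if run <= best - xdrop:
            break
    left_ext, left_gain = best_k, best
    a_start = i - left_ext
    a_end = i + length + right_ext
    total = score + left_gain + right_gain
    n_match = sum(
        1 for off in range(a_end - a_start)
        if a[a_start + off] == b[j - left_ext + off]
    )
    return a_start, a_end, total, n_match


def trans_targets(
    lnc_seqs: SequenceSet,
    utr_seqs: SequenceSet,
    config: Config | None = None,
) -> list[TransHit]:
    """Best ungapped local-similarity hit per lncRNA-mRNA pair.

    Shared 11-mers between a lncRNA transcript and an mRNA 3'UTR seed
    ungapped extensions; overlapping extensions on one diagonal are merged
    by skipping seeds inside an already-extended segment. A pair is reported
    when its best hit reaches the minimum identity (default 0.90) and
    aligned length (default 20).
    """
    config = config or Config()
    tile = config.trans_tile_size
    lnc_ids = lnc_seqs.ids_with_role("transcript")
    utr_ids = utr_seqs.ids_with_role("three_prime_utr")
    if not lnc_ids or not utr_ids:
        raise DataError("trans prediction needs non-empty lncRNA and 3'UTR sets")

    index: dict[str, list[tuple[str, int]]] = {}
    for uid in utr_ids:
        seq = utr_seqs[uid]
        for j in range(len(seq) - tile + 1):
            index.setdefault(seq[j : j + tile], []).append((uid, j))

    best: dict[tuple[str, str], TransHit] = {}
    for lid in lnc_ids:
        a = lnc_seqs[lid]
        covered: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for i in range(len(a) - tile + 1):
            for uid, j in index.get(a[i : i + tile], ()):
                diag = i - j
                if any(s <= i < e for s, e in covered.get((uid, diag), ())):
                    continue
                b = utr_seqs[uid]
                a_start, a_end, score, n_match = _extend_ungapped(
                    a, b, i, j, tile,
                    config.trans_match_score, config.trans_mismatch_score,
                    config.trans_xdrop,
                )
                covered.setdefault((uid, diag), []).append((a_start, a_end))
                length = a_end - a_start
                identity = n_match / length
                if length < config.trans_min_length or identity < config.trans_min_identity:
                    continue
                hit = TransHit(lid, uid, length, identity, score)
                key = (lid, uid)
                if key not in best or hit.score > best[key].score:
                    best[key] = hit
    return sorted(best.values(), key=lambda h: (h.lncrna_id, h.mrna_id))


# ---------------------------------------------------------------------------
# TF motif scanning


def extract_promoters(
    genome: SequenceSet,
    annotations: Sequence[GeneAnnotation],
    upstream_bp: int = 2_000,
    downstream_bp: int = 500,
) -> tuple[SequenceSet, dict[str, int]]:
    """Strand-aware promoter windows around each gene's TSS.

    Returns the promoter sequences (read 5'->3' on the gene's strand) and a
    per-gene offset of the TSS within its window (``upstream_bp`` unless the
    window was truncated at a chromosome boundary, which logs a warning).
    """
    seqs: dict[str, str] = {}
    roles: dict[str, str] = {}
    tss_offset: dict[str, int] = {}
    for ann in annotations:
        chrom_seq = genome[ann.chrom]
        tss = ann.tss
        if ann.strand == "+":
            lo, hi = tss - upstream_bp, tss + downstream_bp
        else:
            lo, hi = tss - downstream_bp + 1, tss + upstream_bp + 1
        clipped_lo, clipped_hi = max(0, lo), min(len(chrom_seq), hi)
        if (clipped_lo, clipped_hi) != (lo, hi):
            log.warning(
                "promoter window of %s truncated to chromosome bounds", ann.gene_id
            )
        window = chrom_seq[clipped_lo:clipped_hi]
        if ann.strand == "+":
            offset = tss - clipped_lo
        else:
            window = reverse_complement(window)
            offset = clipped_hi - 1 - tss
        seqs[ann.gene_id] = window
        roles[ann.gene_id] = "promoter"
        tss_offset[ann.gene_id] = offset
    return SequenceSet(seqs, roles), tss_offset


def scan_tf_motifs(
    promoters: SequenceSet,
    motifs: Sequence[Motif],
    config: Config | None = None,
    tss_offset_of: Mapping[str, int] | None = None,
) -> list[MotifHit]:
    """Motif occurrences in promoter windows, positions relative to the TSS.

    Consensus motifs match by IUPAC expansion on both strands. PWMs score
    log2(p/0.25) and hit at >= ``pwm_score_fraction`` of the motif's maximum
    score. Reported positions are window offsets minus the TSS offset, so
    negative positions are upstream of the start site on the gene's strand.
    """
    config = config or Config()
    hits: list[MotifHit] = []
    for gene in promoters.ids_with_role("promoter"):
        seq = promoters[gene]
        anchor = (tss_offset_of or {}).get(gene, config.promoter_upstream_bp)
        for motif in motifs:
            if motif.consensus is not None:
                for strand, pattern in (
                    ("+", motif.to_regex()),
                    ("-", Motif.from_consensus(
                        motif.motif_id, reverse_complement(motif.consensus)
                    ).to_regex()),
                ):
                    start = 0
                    while (m := pattern.search(seq, start)) is not None:
                        hits.append(
                            MotifHit(motif.motif_id, gene, m.start() - anchor,
                                     strand, 1.0)
                        )
                        start = m.start() + 1
            else:
                threshold = config.pwm_score_fraction * motif.max_score()
                w = motif.width
                for start in range(len(seq) - w + 1):
                    window = seq[start : start + w]
                    for strand, target in (("+", window),
                                           ("-", reverse_complement(window))):
                        s = motif.score(target)
                        if s >= threshold:
                            hits.append(
                                MotifHit(motif.motif_id, gene, start - anchor,
                                         strand, round(s, 6))
                            )
    return hits
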