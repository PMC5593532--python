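"""Five-step ceRNA (lncRNA-miRNA-mRNA) triplet construction.

A competing-endogenous-RNA triplet is the intersection of three screened
relations over differentially expressed genes:

1. negatively correlated miRNA-mRNA pairs where the mRNA carries a seed
   match for the miRNA;
2. negatively correlated miRNA-lncRNA pairs where the lncRNA carries a seed
   match for the miRNA (its miRNA response element);
3. positively co-expressed lncRNA-mRNA pairs;
4. lncRNA-mRNA pairs sharing a miRNA across (1) and (2);
5. the intersection of (3) and (4).

All three correlation edges use the same |r| and p thresholds as the CNC
network; the output is the sorted list of triplets with their supporting
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .coexpression import CorrelationEdge
from .targets import SeedMatch

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    edge_lnc_mir: CorrelationEdge
    edge_mir_mrna: CorrelationEdge
    edge_lnc_mrna: CorrelationEdge
    mrna_is_target: bool = True
    lncrna_is_target: bool = True

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


def _typed_edges(corr_edges: Iterable[CorrelationEdge]):
    """Index deduplicated edges as (miRNA, other) / (lncRNA, mRNA) keyed maps."""
    mir_mrna: dict[tuple[str, str], CorrelationEdge] = {}
    mir_lnc: dict[tuple[str, str], CorrelationEdge] = {}
    lnc_mrna: dict[tuple[str, str], CorrelationEdge] = {}
    for e in corr_edges:
        kinds = {e.biotype_a, e.biotype_b}
        if kinds == {"miRNA", "mRNA"}:
            mir = e.gene_a if e.biotype_a == "miRNA" else e.gene_b
            g = e.gene_b if e.biotype_a == "miRNA" else e.gene_a
            mir_mrna.setdefault((mir, g), e)
        elif kinds == {"miRNA", "lncRNA"}:
            mir = e.gene_a if e.biotype_a == "miRNA" else e.gene_b
            l = e.gene_b if e.biotype_a == "miRNA" else e.gene_a
            mir_lnc.setdefault((mir, l), e)
        elif kinds == {"lncRNA", "mRNA"}:
            l = e.gene_a if e.biotype_a == "lncRNA" else e.gene_b
            g = e.gene_b if e.biotype_a == "lncRNA" else e.gene_a
            lnc_mrna.setdefault((l, g), e)
        else:
            log.warning("edge with unsupported biotype pair %s ignored: %s-%s",
                        sorted(kinds), e.gene_a, e.gene_b)
    return mir_mrna, mir_lnc, lnc_mrna


def build_cerna_network(
    corr_edges: Sequence[CorrelationEdge],
    seed_matches: Sequence[SeedMatch],
) -> list[CeRNATriplet]:
    """Intersect signed correlation edges with seed-match evidence (steps 1-5)."""
    mir_mrna, mir_lnc, lnc_mrna = _typed_edges(corr_edges)
    targeted = {(m.mirna_id, m.target_id) for m in seed_matches}

    s1 = {k: e for k, e in mir_mrna.items() if e.sign == "-" and k in targeted}
    s2 = {k: e for k, e in mir_lnc.items() if e.sign == "-" and k in targeted}
    s3 = {k: e for k, e in lnc_mrna.items() if e.sign == "+"}

    by_mir_mrnas: dict[str, list[str]] = {}
    for mir, g in s1:
        by_mir_mrnas.setdefault(mir, []).append(g)

    triplets: list[CeRNATriplet] = []
    for (mir, lnc), e_ml in s2.items():
        for g in by_mir_mrnas.get(mir, ()):     # step 4: shared miRNA
            e_lg = s3.get((lnc, g))             # step 5: intersect with step 3
            if e_lg is None:
                continue
            triplets.append(
                CeRNATriplet(
                    lncrna_id=lnc,
                    mirna_id=mir,
                    mrna_id=g,
                    edge_lnc_mir=e_ml,
                    edge_mir_mrna=s1[(mir, g)],
                    edge_lnc_mrna=e_lg,
                )
            )
    triplets.sort(key=lambda t: t.key)
    return triplets


def network_summary(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    """Node degrees in the tripartite graph plus triplet counts per miRNA.

    Degree counts distinct neighbors over the union of the triplets' edges
    (lncRNA-miRNA, miRNA-mRNA, lncRNA-mRNA).
    """
    neighbors: dict[str, set[str]] = {}
    role: dict[str, str] = {}
    triplet_count: dict[str, int] = {}
    for t in triplets:
        for a, b in ((t.lncrna_id, t.mirna_id), (t.mirna_id, t.mrna_id),
                     (t.lncrna_id, t.mrna_id)):
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)
        role[t.lncrna_id] = "lncRNA"
        role[t.mirna_id] = "miRNA"
        role[t.mrna_id] = "mRNA"
        triplet_count[t.mirna_id] = triplet_count.get(t.mirna_id, 0) + 1
    rows = [
        (node, len(neighbors[node]), role[node], triplet_count.get(node, 0))
        for node in sorted(neighbors)
    ]
    return pd.DataFrame(rows, columns=["node", "degree", "role", "triplets"])


def triplets_to_frame(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                t.lncrna_id, t.mirna_id, t.mrna_id,
                t.edge_lnc_mir.r, t.edge_mir_mrna.r, t.edge_lnc_mrna.r,
                t.mrna_is_target, t.lncrna_is_target,
            )
            for t in triplets
        ],
        columns=[
            "lncrna_id", "mirna_id", "mrna_id",
            "r_lnc_mir", "r_mir_mrna", "r_lnc_mrna",
            "mrna_is_target", "lncrna_is_target",
        ],
    )
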