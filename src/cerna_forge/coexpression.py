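"""Coding-noncoding (CNC) co-expression network construction.

Every requested cross-biotype gene pair is scored with the sample Pearson
correlation over all arrays (case and control pooled) and the two-sided
p-value of t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom. Edges are
retained when |r| strictly exceeds the correlation threshold (default 0.90)
and p is strictly below the p threshold (default 0.01). With the study's
n = 6 arrays these correlations are low-powered; a warning is logged for
n < 8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DataError
from .model import Config, ExpressionMatrix

log = logging.getLogger(__name__)

# biotype pairs feeding the CNC network and the downstream ceRNA intersection
CROSS_BIOTYPE_PAIRS = (("lncRNA", "mRNA"), ("miRNA", "mRNA"), ("miRNA", "lncRNA"))


@dataclass(frozen=True)
class CorrelationEdge:
    """Undirected typed gene pair; ids are stored in canonical (sorted) order."""

    gene_a: str
    gene_b: str
    biotype_a: str
    biotype_b: str
    r: float
    p_value: float

    def __post_init__(self):
        if self.gene_b < self.gene_a:
            a, b = self.gene_a, self.gene_b
            ba, bb = self.biotype_a, self.biotype_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)
            object.__setattr__(self, "biotype_a", bb)
            object.__setattr__(self, "biotype_b", ba)

    @property
    def sign(self) -> str:
        return "+" if self.r >= 0 else "-"

    def biotype_of(self, gene: str) -> str:
        return self.biotype_a if gene == self.gene_a else self.biotype_b


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; zero variance is an error, not NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DataError("pearson_r needs equal-length vectors with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise DataError("undefined correlation: zero variance input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p of the correlation t-test with n-2 df; |r| = 1 -> p = 0."""
    if n < 3:
        raise DataError(f"correlation test needs n >= 3, got {n}")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def build_cnc_network(
    de_matrix: ExpressionMatrix,
    pairs=None,
    config: Config | None = None,
) -> list[CorrelationEdge]:
    """Correlation edges over DE genes passing the |r| and p thresholds.

    ``pairs`` may be an explicit iterable of (gene_a, gene_b); by default all
    cross-biotype pairs (lncRNA-mRNA, miRNA-mRNA, miRNA-lncRNA) are tested,
    plus within-biotype pairs when ``config.within_biotype_edges`` is set.
    """
    config = config or Config()
    n = len(de_matrix.sample_ids)
    if n < 3:
        raise DataError("correlation network needs >= 3 samples")
    if n < 8:
        log.warning(
            "correlations over only %d arrays are low-powered; "
            "interpret retained edges cautiously", n
        )

    values = de_matrix.values.to_numpy(dtype=float)
    if config.correlation_method == "spearman":
        values = np.apply_along_axis(stats.rankdata, 1, values)
    gene_index = {g: i for i, g in enumerate(de_matrix.gene_ids)}

    sd = values.std(axis=1)
    degenerate = {g for g, i in gene_index.items() if sd[i] == 0.0}
    for g in sorted(degenerate):
        log.info("gene %s excluded from correlation: zero variance", g)

    if pairs is None:
        by_biotype = {
            b: [g for g in de_matrix.gene_ids if de_matrix.biotype_of.get(g) == b]
            for b in ("lncRNA", "mRNA", "miRNA")
        }
        pairs = [
            (a, b)
            for ba, bb in CROSS_BIOTYPE_PAIRS
            for a in by_biotype[ba]
            for b in by_biotype[bb]
        ]
        if config.within_biotype_edges:
            for genes in by_biotype.values():
                pairs.extend(combinations(genes, 2))

    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))

    edges: list[CorrelationEdge] = []
    for a, b in pairs:
        if a in degenerate or b in degenerate or a == b:
            continue
        ia, ib = gene_index[a], gene_index[b]
        r = float(np.clip(centered[ia] @ centered[ib] / (norms[ia] * norms[ib]), -1, 1))
        if abs(r) <= config.r_threshold:
            continue
        p = correlation_p(r, n)
        if p >= config.p_threshold_corr:
            continue
        edges.append(
            CorrelationEdge(
                gene_a=a,
                gene_b=b,
                biotype_a=de_matrix.biotype_of.get(a, ""),
                biotype_b=de_matrix.biotype_of.get(b, ""),
                r=r,
                p_value=p,
            )
        )
    # canonical ordering may merge duplicates handed in via explicit pairs
    seen: dict[tuple[str, str], CorrelationEdge] = {}
    for e in edges:
        seen.setdefault((e.gene_a, e.gene_b), e)
    return sorted(seen.values(), key=lambda e: (e.gene_a, e.gene_b))
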