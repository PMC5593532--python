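"""Paired differential-expression screening.

Each gene is tested with a paired two-sided t-test across case/control
sample pairs; fold change is the exponentiated difference of log2 group
means, reported as a linear ratio >= 1 with an up/down direction. A gene
passes when its linear fold change strictly exceeds the biotype's threshold
(2.0 for lncRNA/mRNA, 1.5 for miRNA) and the paired p-value is <= 0.05.
No multiple-testing correction is applied by default; Benjamini-Hochberg is
available behind ``Config.apply_bh``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, MetadataError
from .model import Config, ExpressionMatrix


@dataclass
class DifferentialRecord:
    gene_id: str
    biotype: str
    mean_case: float
    mean_control: float
    log2fc: float
    fc_linear: float
    direction: str  # "up" | "down"
    p_value: float
    passes: bool
    degenerate: bool = False


def _paired_t(case_values, control_values) -> tuple[float, float, bool]:
    """Paired t statistic, two-sided p, and a zero-variance degeneracy flag."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.shape != control.shape:
        raise DataError("case and control vectors must have equal length")
    n = case.size
    if n < 2:
        raise DataError(f"paired t-test needs >= 2 pairs, got {n}")
    d = case - control
    dbar = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if dbar == 0.0:
            return 0.0, 1.0, False
        # identical nonzero differences: evaluate at machine-limit variance
        sd = math.sqrt(np.finfo(float).tiny)
        t = dbar / (sd / math.sqrt(n))
        return t, 2.0 * stats.t.sf(abs(t), df=n - 1), True
    t = dbar / (sd / math.sqrt(n))
    return t, 2.0 * stats.t.sf(abs(t), df=n - 1), False


def paired_t_test(case_values, control_values) -> float:
    """Two-sided p-value of the paired t-test (pairs aligned by index)."""
    return _paired_t(case_values, control_values)[1]


def compute_differential(
    matrix: ExpressionMatrix, config: Config | None = None
) -> list[DifferentialRecord]:
    """Screen every gene of the matrix with the paired FC/p criteria."""
    config = config or Config()
    case_cols, control_cols = matrix.paired_columns()
    case = matrix.values[case_cols].to_numpy(dtype=float)
    control = matrix.values[control_cols].to_numpy(dtype=float)

    records: list[DifferentialRecord] = []
    for i, gene in enumerate(matrix.gene_ids):
        biotype = matrix.biotype_of.get(gene)
        if biotype is None:
            raise MetadataError(f"gene {gene!r} has no biotype annotation")
        mean_case = float(case[i].mean())
        mean_control = float(control[i].mean())
        log2fc = mean_case - mean_control
        _, p, degenerate = _paired_t(case[i], control[i])
        fc_linear = 2.0 ** abs(log2fc)
        direction = "up" if log2fc > 0 else "down"
        records.append(
            DifferentialRecord(
                gene_id=gene,
                biotype=biotype,
                mean_case=mean_case,
                mean_control=mean_control,
                log2fc=log2fc,
                fc_linear=fc_linear,
                direction=direction,
                p_value=p,
                passes=False,
                degenerate=degenerate,
            )
        )

    p_for_screen = np.array([r.p_value for r in records])
    if config.apply_bh and len(records):
        p_for_screen = stats.false_discovery_control(p_for_screen, method="bh")
    for r, p_adj in zip(records, p_for_screen):
        r.passes = (
            r.fc_linear > config.fc_threshold_for(r.biotype)
            and p_adj <= config.p_threshold_de
        )
    return records


def volcano_coordinates(
    records, y_cap: float = 300.0
) -> pd.DataFrame:
    """Volcano-plot table: x = signed log2 FC, y = -log10 p, class by screen."""
    rows = []
    for r in records:
        capped = False
        if r.p_value <= 0.0:
            y = y_cap
            capped = True
        else:
            y = -math.log10(r.p_value)
            if y > y_cap:
                y, capped = y_cap, True
        cls = "unchanged" if not r.passes else r.direction
        rows.append((r.gene_id, r.log2fc, y, cls, capped))
    return pd.DataFrame(rows, columns=["gene", "x", "y", "class", "y_capped"])


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.gene_id, r.biotype, r.mean_case, r.mean_control, r.log2fc,
                r.fc_linear, r.direction, r.p_value, r.passes, r.degenerate,
            )
            for r in records
        ],
        columns=[
            "gene_id", "biotype", "mean_case", "mean_control", "log2fc",
            "fc_linear", "direction", "p_value", "passes", "degenerate",
        ],
    )
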