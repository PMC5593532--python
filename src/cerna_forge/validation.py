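"""qPCR relative quantification (2^-ddCt) and the two-sample t power analysis.

Relative expression follows the comparative-Ct method with reference-gene
normalization: per sample dCt = Ct_gene - mean(Ct_reference), per sample
ddCt = dCt - mean(dCt over controls), fold = 2^-ddCt. Reference genes are
chosen per biotype (a U6-like small RNA for miRNAs, an actin-like mRNA
otherwise). Group comparison is a plain two-sided Student t-test on dCt
values; statistical power for the two-sample design is computed exactly
from the noncentral t distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

DEFAULT_REFERENCES = {"miRNA": ["U6"], "mRNA": ["Actb"], "lncRNA": ["Actb"]}


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    group: str  # case | control
    gene_id: str
    ct: float
    is_reference: bool = False


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    mean_fc: float
    sd_fc: float
    p_value: float
    direction: str
    mean_fc_control: float = 1.0
    sd_fc_control: float = 0.0


def _as_frame(ct) -> pd.DataFrame:
    if isinstance(ct, pd.DataFrame):
        return ct
    return pd.DataFrame([r.__dict__ for r in ct])


def ddct_fold_change(ct, gene: str, reference_genes: Sequence[str]) -> FoldChangeResult:
    """2^-ddCt fold change of ``gene`` normalized to ``reference_genes``.

    Control-group folds are computed against the same control dCt mean, so
    the control mean fold is 1 by construction and its SD is interpretable.
    The p-value is a two-sided two-sample t-test on the dCt values.
    """
    table = _as_frame(ct)
    gene_rows = table[table["gene_id"] == gene]
    if gene_rows.empty:
        raise DataError(f"gene {gene!r} absent from Ct table")

    dct: dict[str, float] = {}
    group_of: dict[str, str] = {}
    for _, row in gene_rows.iterrows():
        sample = row["sample_id"]
        refs = table[(table["sample_id"] == sample)
                     & (table["gene_id"].isin(reference_genes))]
        missing = set(reference_genes) - set(refs["gene_id"])
        if missing:
            raise DataError(
                f"sample {sample!r}: missing reference measurement(s) {sorted(missing)}"
            )
        dct[sample] = float(row["ct"]) - float(refs["ct"].mean())
        group_of[sample] = row["group"]

    case_dct = np.array([v for s, v in dct.items() if group_of[s] == "case"])
    control_dct = np.array([v for s, v in dct.items() if group_of[s] == "control"])
    if case_dct.size == 0 or control_dct.size == 0:
        raise DataError(f"gene {gene!r}: need Ct values in both groups")

    baseline = control_dct.mean()
    case_fold = 2.0 ** -(case_dct - baseline)
    control_fold = 2.0 ** -(control_dct - baseline)
    p = group_compare(case_dct, control_dct)
    mean_fc = float(case_fold.mean())
    return FoldChangeResult(
        gene_id=gene,
        mean_fc=mean_fc,
        sd_fc=float(case_fold.std(ddof=1)) if case_fold.size > 1 else 0.0,
        p_value=p,
        direction="up" if mean_fc > 1 else "down",
        mean_fc_control=float(control_fold.mean()),
        sd_fc_control=float(control_fold.std(ddof=1)) if control_fold.size > 1 else 0.0,
    )


def qpcr_summarize(
    ct,
    biotype_of: Mapping[str, str],
    references: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fold-change results for every non-reference gene, reference per biotype."""
    references = references or DEFAULT_REFERENCES
    table = _as_frame(ct)
    genes = sorted(set(table.loc[~table["is_reference"], "gene_id"]))
    rows = []
    for gene in genes:
        refs = references.get(biotype_of.get(gene, "mRNA"), ["Actb"])
        res = ddct_fold_change(table, gene, refs)
        rows.append(
            (gene, biotype_of.get(gene, ""), res.mean_fc, res.sd_fc,
             res.mean_fc_control, res.sd_fc_control, res.p_value, res.direction)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "biotype", "mean_fc_case", "sd_fc_case",
                 "mean_fc_control", "sd_fc_control", "p_value", "direction"],
    )


def group_compare(values_case, values_control) -> float:
    """Two-sided two-sample Student t-test p (pooled variance)."""
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise DataError("group comparison needs >= 2 values per group")
    n1, n2 = case.size, control.size
    s2 = (
        (n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)
    ) / (n1 + n2 - 2)
    diff = case.mean() - control.mean()
    if s2 == 0.0:
        if diff == 0.0:
            return 1.0
        s2 = np.finfo(float).tiny  # degenerate: identical within-group values
    t = diff / math.sqrt(s2 * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)


def welch_compare(values_case, values_control) -> float:
    """Welch's unequal-variance alternative to :func:`group_compare`."""
    res = stats.ttest_ind(np.asarray(values_case, float),
                          np.asarray(values_control, float), equal_var=False)
    return float(res.pvalue)


def ttest_power(
    effect_size_d: float,
    n_per_group: int,
    alpha: float = 0.05,
    tails: str = "two",
) -> float:
    """Power of the two-sample pooled t-test via the noncentral t distribution.

    ncp = d * sqrt(n/2), df = 2n - 2; two-tailed power is
    P(T' > t_{1-a/2}) + P(T' < -t_{1-a/2}).
    """
    if effect_size_d < 0 or n_per_group < 2 or not (0 < alpha < 1):
        raise ValueError("need d >= 0, n >= 2 and alpha in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = effect_size_d * math.sqrt(n_per_group / 2.0)
    if tails == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if tails == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
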