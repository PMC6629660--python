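"""Expression quantification: FPKM, amplified-vs-neutral comparison, qPCR.

FPKM = read count / ((library size / 1e6) x (gene length / 1e3)). The
amplified-vs-neutral comparison contrasts a gene's expression in samples
where it is copy-number amplified against samples where it is neutral, with
a two-sided Wilcoxon rank-sum test. qPCR relative expression is cycle-scale:
r = e - c against the reference gene, and the fold change between conditions
is fc = 2**(r_control - r).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)


def compute_fpkm(
    counts: pd.DataFrame,
    library_size: float | pd.Series | None = None,
) -> pd.DataFrame:
    """Add an ``fpkm`` column to a (gene, count, length) table.

    ``library_size`` defaults to the column sum of counts; zero lengths or
    library sizes are errors.
    """
    if (counts["length"] <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if library_size is None:
        library_size = float(counts["count"].sum())
    if np.any(np.asarray(library_size) <= 0):
        raise ValueError("library size must be > 0")
    out = counts.copy()
    out["fpkm"] = out["count"] / ((library_size / 1e6) * (out["length"] / 1e3))
    return out


def compare_amplified_expression(
    expression: pd.DataFrame,
    amplified: pd.DataFrame,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Expression where a gene is amplified vs where it is copy-number neutral.

    ``expression`` is a long table (sample_id, gene_id, fpkm); ``amplified``
    a (sample_id, gene_id, amplified) table of boolean calls — pairs absent
    from it are treated as neutral. By default all amplified/neutral values
    are pooled into one rank-sum test; with ``per_gene`` each gene with at
    least one sample in both groups is tested separately (others skipped and
    logged). Reports the two-sided p and the median log2 fold difference.
    """
    amp_pairs = {
        (s, g)
        for s, g, a in amplified[["sample_id", "gene_id", "amplified"]].itertuples(index=False)
        if a
    }
    is_amp = [
        (s, g) in amp_pairs
        for s, g in expression[["sample_id", "gene_id"]].itertuples(index=False)
    ]
    expr = expression.assign(amplified=is_amp)

    def one_test(sub: pd.DataFrame, label: str) -> dict | None:
        a = sub.loc[sub["amplified"], "fpkm"].to_numpy(dtype=float)
        b = sub.loc[~sub["amplified"], "fpkm"].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            logger.info("comparison %r skipped: a group is empty", label)
            return None
        _, p = mannwhitneyu(a, b, alternative="two-sided")
        eps = 1e-9
        shift = float(np.median(np.log2(a + eps)) - np.median(np.log2(b + eps)))
        return {
            "gene_id": label, "n_amplified": len(a), "n_neutral": len(b),
            "median_log2_fold": shift, "p": float(p),
        }

    rows = []
    if per_gene:
        for gene, sub in expr.groupby("gene_id"):
            row = one_test(sub, str(gene))
            if row:
                rows.append(row)
    else:
        row = one_test(expr, "pooled")
        if row:
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["gene_id", "n_amplified", "n_neutral", "median_log2_fold", "p"]
    )


def qpcr_relative_expression(e: float, c: float) -> float:
    """Cycle-scale expression relative to the reference gene: r = e - c."""
    return e - c


def qpcr_fold_change(e: float, c: float, e_control: float, c_control: float) -> float:
    """Fold change between a condition and its control: fc = 2**(r_control - r)."""
    r = qpcr_relative_expression(e, c)
    r_control = qpcr_relative_expression(e_control, c_control)
    return 2.0 ** (r_control - r)
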