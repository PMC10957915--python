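"""NF-κB expression index and cohort classification.

The index is the cohort-standardized geometric mean of 11 NF-κB target
genes computed on variance-stabilized (strictly positive) expression
values. A sample is called NF-κB+ when its index is positive AND at
least one signature gene's expression strictly exceeds that gene's 75th
percentile across the cohort; otherwise NF-κB−.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 11 NF-κB target genes whose geometric mean defines the index.
DEFAULT_SIGNATURE: tuple[str, ...] = (
    "BIRC3",
    "NFKB2",
    "TNFAIP3",
    "IL2RG",
    "NFKBIE",
    "RELB",
    "NFKBIA",
    "CD74",
    "PLEK",
    "MALT1",
    "WNT10A",
)

GROUP_PLUS = "NFkB_plus"
GROUP_MINUS = "NFkB_minus"


@dataclass(frozen=True)
class SignatureConfig:
    """Ordered gene signature driving the index."""

    signature_genes: tuple[str, ...] = DEFAULT_SIGNATURE

    def __post_init__(self):
        if len(self.signature_genes) < 2:
            raise ValueError("signature needs at least 2 genes")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise ValueError("signature genes must be unique")


def _signature_values(expr: pd.DataFrame, sig: SignatureConfig) -> pd.DataFrame:
    missing = [g for g in sig.signature_genes if g not in expr.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {', '.join(missing)}")
    sub = expr.loc[list(sig.signature_genes)]
    bad = sub <= 0
    if bad.to_numpy().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(
            f"non-positive expression for gene {gene} in sample {sample}; "
            "the index requires variance-stabilized positive values"
        )
    return sub


def geometric_mean_index(
    expr: pd.DataFrame, sig: SignatureConfig | None = None
) -> pd.Series:
    """Per-sample geometric mean of signature-gene expression.

    ``expr`` is a genes x samples frame of positive values. Equals
    ``exp(mean(ln(value)))`` over signature genes.
    """
    sig = sig or SignatureConfig()
    sub = _signature_values(expr, sig)
    gm = np.exp(np.log(sub).mean(axis=0))
    gm.name = "raw_gm"
    return gm


def standardize(raw_gm: pd.Series) -> pd.Series:
    """Convert raw geometric means to standard scores (n−1 denominator)."""
    if len(raw_gm) < 2:
        raise ValueError("standardization needs at least 2 samples")
    sd = raw_gm.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate cohort: zero variance in geometric means")
    z = (raw_gm - raw_gm.mean()) / sd
    z.name = "index"
    return z


def classify_samples(
    expr: pd.DataFrame,
    sig: SignatureConfig | None = None,
    index: pd.Series | None = None,
) -> pd.Series:
    """Assign each sample NF-κB+ / NF-κB−.

    NF-κB+ requires a positive index and at least one signature gene whose
    value strictly exceeds that gene's cohort 75th percentile
    (linear-interpolation quantile).
    """
    sig = sig or SignatureConfig()
    sub = _signature_values(expr, sig)
    if index is None:
        index = standardize(geometric_mean_index(expr, sig))
    q3 = sub.quantile(0.75, axis=1)  # linear interpolation (type 7)
    beyond_q3 = sub.gt(q3, axis=0).any(axis=0)
    group = pd.Series(
        np.where((index > 0) & beyond_q3.reindex(index.index), GROUP_PLUS, GROUP_MINUS),
        index=index.index,
        name="group",
    )
    return group


def index_cohort(
    expr: pd.DataFrame, sig: SignatureConfig | None = None
) -> pd.DataFrame:
    """Full indexing: raw geometric mean, standardized index and group."""
    sig = sig or SignatureConfig()
    raw = geometric_mean_index(expr, sig)
    idx = standardize(raw)
    group = classify_samples(expr, sig, index=idx)
    out = pd.DataFrame({"raw_gm": raw, "index": idx, "group": group})
    out.index.name = "sample"
    return out


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression matrix (first column gene symbols, header =
    sample ids)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")
    return expr


def write_index(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", float_format="%.6g")
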