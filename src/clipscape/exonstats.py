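"""Last-exon differential-expression statistics.

Consumes exon-level DE tables (one row per flattened exonic part, with
log2 fold change and adjusted p) and computes: the 2x2 Fisher enrichment
of DE among last vs internal exonic parts, up/down direction summaries,
CDF comparisons between record subsets, per-position (from the 3' end)
fold-change profiles, and cross-condition exon correlations.

Input TSV contract (header required): gene_id, part_id, pos_from_3p,
log2fc, padj; is_last is derived from pos_from_3p == 1 when absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clipscape.stats import (
    ecdf,
    fisher_exact_2x2,
    mannwhitney_u,
    odds_ratio_haldane,
    pearson_r,
    student_t,
)

REQUIRED_COLUMNS = ("gene_id", "part_id", "pos_from_3p", "log2fc", "padj")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} missing columns {missing}")
    return normalize_de_table(df)


def normalize_de_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "is_last" not in df.columns:
        df["is_last"] = df["pos_from_3p"] == 1
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    return df


@dataclass
class EnrichmentResult:
    table: np.ndarray           # [[last DE, last not], [internal DE, internal not]]
    odds_ratio: float
    p: float
    direction_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def last_exon_enrichment(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_lfc: float = 0.0,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher's exact test of DE status (padj < alpha and |log2FC| >=
    min_abs_lfc) against last-vs-internal exonic-part position.

    The odds ratio is (a*d)/(b*c) with a Haldane 0.5 correction when any
    cell is zero."""
    df = normalize_de_table(records)
    if not df["is_last"].any():
        raise ValueError("no last exons present in records")
    de = (df["padj"] < alpha) & (df["log2fc"].abs() >= min_abs_lfc)
    a = int((df["is_last"] & de).sum())
    b = int((df["is_last"] & ~de).sum())
    c = int((~df["is_last"] & de).sum())
    d = int((~df["is_last"] & ~de).sum())
    _, p = fisher_exact_2x2([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        np.array([[a, b], [c, d]]), odds_ratio_haldane(a, b, c, d), p
    )


def direction_summary(
    records: pd.DataFrame, alpha: float = 0.05, min_abs_lfc: float = 0.5
) -> dict[str, dict[str, int]]:
    """Up/down counts among DE records, stratified by last vs internal.

    DE = padj < alpha and |log2FC| >= min_abs_lfc; up = log2FC > 0,
    down = log2FC < 0; exact-zero fold changes are reported separately."""
    df = normalize_de_table(records)
    de = df[(df["padj"] < alpha) & (df["log2fc"].abs() >= min_abs_lfc)]
    out = {}
    for stratum, sub in (("last", de[de["is_last"]]), ("internal", de[~de["is_last"]])):
        out[stratum] = {
            "up": int((sub["log2fc"] > 0).sum()),
            "down": int((sub["log2fc"] < 0).sum()),
            "zero": int((sub["log2fc"] == 0).sum()),
        }
    return out


def cdf_compare(values_a, values_b):
    """Mann-Whitney U comparison plus empirical CDF step curves.

    Returns (p, (xa, Fa), (xb, Fb))."""
    _, p = mannwhitney_u(values_a, values_b, alternative="two-sided")
    return p, ecdf(values_a), ecdf(values_b)


def position_profile(records: pd.DataFrame, max_pos: int = 10) -> pd.DataFrame:
    """Per-position (from the 3' end) log2FC distribution summaries and a
    two-tailed t-test of position-1 values against all internal positions
    pooled.

    Positions with n < 2 report summaries but skip the test (flagged in
    the ``test_skipped`` column)."""
    df = normalize_de_table(records)
    if df["pos_from_3p"].nunique() < 2:
        raise ValueError("records span fewer than two positions")
    rows = []
    for pos in range(1, max_pos + 1):
        vals = df.loc[df["pos_from_3p"] == pos, "log2fc"].to_numpy()
        # pooled internal reference: positions >= 2, excluding this one
        ref = df.loc[
            (df["pos_from_3p"] >= 2) & (df["pos_from_3p"] != pos), "log2fc"
        ].to_numpy()
        row = {
            "pos_from_3p": pos,
            "n": vals.size,
            "median": float(np.median(vals)) if vals.size else np.nan,
            "q25": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "q75": float(np.percentile(vals, 75)) if vals.size else np.nan,
            "t": np.nan,
            "p": np.nan,
            "test_skipped": True,
            "degenerate": False,
        }
        if vals.size >= 2 and ref.size >= 2:
            res = student_t(vals, ref)
            row.update(t=res.statistic, p=res.p, test_skipped=False,
                       degenerate=res.degenerate)
        rows.append(row)
    return pd.DataFrame(rows)


def exon_correlation(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    require_de_in_both: bool = False,
    alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Pearson correlation of log2FC over exonic parts shared between two
    conditions, joined on (gene_id, part_id).

    Returns (r, p, n).  Requires at least 3 shared parts after filtering."""
    a = normalize_de_table(records_a)
    b = normalize_de_table(records_b)
    merged = a.merge(b, on=["gene_id", "part_id"], suffixes=("_a", "_b"))
    if require_de_in_both:
        merged = merged[(merged["padj_a"] < alpha) & (merged["padj_b"] < alpha)]
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared exonic parts after filtering")
    r, p = pearson_r(merged["log2fc_a"], merged["log2fc_b"])
    return r, p, len(merged)
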