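"""Gene-level hit calling from guide-level enrichment.

A guide "passes" when it is both significantly enriched (p < alpha) and
strongly enriched (log2FC >= fc_threshold, inclusive); a gene is a hit when
at least ``min_sgrnas`` of its guides pass. Both comparisons are inclusive
thresholds and the two guide criteria are conjunctive. Non-targeting
controls never participate in gene calling. No gene-level multiple-testing
correction enters the hit decision; a BH-adjusted one-sample-t gene p-value
is reported as an advisory column only.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import stats

from .library import CONTROL_LABEL


def _advisory_gene_q(table: pd.DataFrame) -> pd.Series:
    """BH-adjusted two-sided one-sample t p-value per gene (advisory)."""
    g = table.groupby("gene")["log2fc"]
    n = g.size()
    mean = g.mean()
    sd = g.std(ddof=1)
    t = mean / (sd / np.sqrt(n))
    p = pd.Series(2.0 * stats.t.sf(np.abs(t), df=n - 1), index=t.index)
    p[(n >= 2) & (sd == 0) & (mean != 0)] = 0.0  # constant nonzero fold change
    p[(n >= 2) & (sd == 0) & (mean == 0)] = 1.0
    p[n < 2] = np.nan
    ok = p.notna()
    q = p.copy()
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def call_hits(
    enrichment: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_sgrnas: int = 3,
) -> pd.DataFrame:
    """Apply the two-criteria gene-level hit rule.

    ``enrichment`` must carry columns gene, log2fc, p_value (one row per
    library guide). Returns one row per targeting gene with
    n_sgrna_total, n_sgrna_passing, median_fc, max_fc, gene_q (advisory)
    and is_hit, sorted by (n_sgrna_passing, median_fc) descending.
    """
    if fc_threshold <= 0 or alpha <= 0 or min_sgrnas <= 0:
        raise ValueError("fc_threshold, alpha and min_sgrnas must be positive")
    required = {"gene", "log2fc", "p_value"}
    if not required <= set(enrichment.columns):
        raise ValueError(f"enrichment table missing columns {required - set(enrichment.columns)}")

    targeting = enrichment[enrichment["gene"] != CONTROL_LABEL].copy()
    targeting["passes"] = (targeting["p_value"] < alpha) & (
        targeting["log2fc"] >= fc_threshold
    )
    grouped = targeting.groupby("gene")
    out = pd.DataFrame(
        {
            "n_sgrna_total": grouped.size(),
            "n_sgrna_passing": grouped["passes"].sum().astype(int),
            "median_fc": grouped["log2fc"].median(),
            "max_fc": grouped["log2fc"].max(),
        }
    )
    out["gene_q"] = _advisory_gene_q(targeting)
    out["is_hit"] = out["n_sgrna_passing"] >= min_sgrnas
    out = out.sort_values(
        ["n_sgrna_passing", "median_fc"], ascending=[False, False]
    )
    out.index.name = "gene"
    out.attrs.update(fc_threshold=fc_threshold, alpha=alpha, min_sgrnas=min_sgrnas)
    return out


def hit_genes(hits: pd.DataFrame) -> list[str]:
    """The called hit genes, in ranked order."""
    return list(hits.index[hits["is_hit"]])


def enriched_sgrna_count(
    gene: str,
    enrichment: pd.DataFrame,
    fc_threshold: float = 2.0,
) -> int:
    """Number of a gene's guides with log2FC >= ``fc_threshold``."""
    rows = enrichment[enrichment["gene"] == gene]
    if rows.empty:
        raise KeyError(f"gene {gene!r} not present in enrichment table")
    return int((rows["log2fc"] >= fc_threshold).sum())


def write_hits(hits: pd.DataFrame, path, summary_path=None) -> None:
    """Write the hits TSV and an optional JSON run summary."""
    hits.to_csv(path, sep="\t", index_label="gene")
    if summary_path is not None:
        summary = {
            "n_genes": int(len(hits)),
            "n_hits": int(hits["is_hit"].sum()),
            "thresholds": {
                k: hits.attrs[k]
                for k in ("fc_threshold", "alpha", "min_sgrnas")
                if k in hits.attrs
            },
        }
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
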