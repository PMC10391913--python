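"""Differential-expression thresholds and cross-source evidence tables.

Consumes an externally produced differential-expression table (gene,
log2 fold-change with direction population A over population B, p-value)
and applies the two printed threshold rules:

* genome-wide DEG call: |log2FC| >= 2 (inclusive) and p < 0.01 (strict);
* candidate-gene expression check: |log2FC| >= 1 and p < 0.05.

Evidence from sweep scans (both directions), GWAS hits per trait, and DEG
calls is combined into one boolean table per gene.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def read_deg_table(path) -> pd.DataFrame:
    """DEG TSV with header: gene, log2fc, pvalue (extra columns ignored)."""
    t = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in t.columns}
    gene = cols.get("gene", t.columns[0])
    lfc = cols.get("log2fc", t.columns[1])
    pcol = cols.get("pvalue", cols.get("p", t.columns[2]))
    logger.info("read_deg_table: using p-value column %r", pcol)
    out = t[[gene, lfc, pcol]].copy()
    out.columns = ["gene", "log2fc", "pvalue"]
    if out["gene"].duplicated().any():
        raise ValueError("duplicate gene identifier in DEG table")
    return out


def filter_degs(
    table: pd.DataFrame, lfc: float = 2.0, p: float = 0.01
) -> tuple[list[str], list[str]]:
    """Up- and down-regulated gene lists.

    Fold-change bounds are inclusive (>= lfc, <= -lfc), the p threshold is
    strict (< p), exactly as conventionally printed.
    """
    sig = table["pvalue"] < p
    up = sorted(table.loc[sig & (table["log2fc"] >= lfc), "gene"])
    down = sorted(table.loc[sig & (table["log2fc"] <= -lfc), "gene"])
    return up, down


def candidate_expression(
    table: pd.DataFrame, genes: list[str], lfc: float = 1.0, p: float = 0.05
) -> pd.DataFrame:
    """Expression status of candidate genes at the looser thresholds.

    Returns one row per requested gene with status 'Up', 'Down',
    'not significant' or 'not assayed'.
    """
    lookup = table.set_index("gene")
    rows = []
    for g in genes:
        if g not in lookup.index:
            rows.append((g, None, None, "not assayed"))
            continue
        rec = lookup.loc[g]
        fc, pv = float(rec["log2fc"]), float(rec["pvalue"])
        if pv < p and fc >= lfc:
            status = "Up"
        elif pv < p and fc <= -lfc:
            status = "Down"
        else:
            status = "not significant"
        rows.append((g, fc, pv, status))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "status"])


def build_evidence(
    sweep_genes: dict[str, list[str]] | None = None,
    gwas_genes: dict[str, list[str]] | None = None,
    deg_up: list[str] | None = None,
    deg_down: list[str] | None = None,
) -> pd.DataFrame:
    """Outer union of gene identifiers with boolean evidence flags.

    ``sweep_genes`` maps a scan direction label (e.g. 'sweep_a_over_b') to
    its candidate-gene list; ``gwas_genes`` maps a trait name to its hit
    genes. Row order is lexicographic by gene; deterministic.
    """
    sweep_genes = sweep_genes or {}
    gwas_genes = gwas_genes or {}
    deg_up = deg_up or []
    deg_down = deg_down or []
    columns: dict[str, set[str]] = {}
    for label, lst in sweep_genes.items():
        columns[label] = set(lst)
    for trait, lst in gwas_genes.items():
        columns[f"gwas_{trait}"] = set(lst)
    columns["deg_up"] = set(deg_up)
    columns["deg_down"] = set(deg_down)

    all_genes = sorted(set().union(*columns.values())) if columns else []
    out = pd.DataFrame({"gene": all_genes})
    for label in columns:
        out[label] = out["gene"].isin(columns[label])
    out["candidate_expression"] = out["deg_up"] | out["deg_down"]
    return out
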