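"""The sponge screen: correlation, target-set enrichment, network selection.

The statistical idea: if a lncRNA sequesters a miRNA, the miRNA's target
genes are de-repressed in samples where the lncRNA is abundant, so their
expression is positively correlated with the lncRNA. The screen therefore

1. computes the Pearson correlation of every measured gene with the
   designated lncRNA across samples,
2. for each candidate miRNA compares the absolute correlations of its
   target set against the absolute correlations of the common background
   (the union of all candidates' target sets) with a Welch two-sample
   t-test,
3. adjusts the per-miRNA p-values with the Benjamini–Hochberg step-up
   procedure, and
4. calls a miRNA a network component when its adjusted p is below alpha
   *and* its target set is more correlated than background (direction is
   reported explicitly rather than folded into a one-sided p).

Selected target genes are those predicted for at least one significant
miRNA whose own gene-level correlation is positive with p < alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assembly import TargetMap
from .io import ExpressionMatrix

logger = logging.getLogger("cernet")

__all__ = [
    "CeRNANetwork",
    "correlate_with_lnc",
    "welch_t_test",
    "benjamini_hochberg",
    "mirna_enrichment",
    "select_network",
    "rank_target_genes",
    "write_network",
    "read_network",
]

CORRELATION_COLUMNS = ["gene_id", "r", "n", "p"]
ENRICHMENT_COLUMNS = [
    "mirna_id", "n_targets", "mean_abs_r_targets", "mean_abs_r_background",
    "t", "df", "p", "p_adj", "significant",
]


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the exact t-transform (n-2 df)."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = np.where(np.isinf(t) | (np.abs(r) >= 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return p


def correlate_with_lnc(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation of every gene with the lncRNA row.

    Correlations use pairwise-complete samples (both the gene and the
    lncRNA non-missing); genes with fewer than 3 complete pairs, or with
    zero variance over the complete pairs, are excluded and logged. The
    p-value is the exact t-transform of r with n-2 degrees of freedom.

    Returns a frame with columns ``gene_id, r, n, p`` in matrix gene order
    (the lncRNA row itself is not reported).
    """
    if matrix.has_duplicate_genes:
        raise ValueError("expression matrix must be collapsed before correlation")
    lnc = matrix.lnc_values()
    lnc_mask = np.isfinite(lnc)
    if lnc_mask.sum() < 3:
        raise ValueError("lncRNA row has fewer than 3 non-missing values")
    if np.nanstd(lnc) == 0.0:
        raise ValueError("lncRNA row is constant; correlation undefined")

    genes = [g for g in matrix.gene_ids if g != matrix.lnc_id]
    G = matrix.data.loc[genes].to_numpy(dtype=float)

    complete = np.isfinite(G).all(axis=1) & lnc_mask.all()
    records: dict[str, tuple[float, int]] = {}

    if complete.any():
        sub = G[complete]
        b = lnc - lnc.mean()
        A = sub - sub.mean(axis=1, keepdims=True)
        denom = np.sqrt((A * A).sum(axis=1)) * math.sqrt((b * b).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (A @ b) / denom
        for gene, ri in zip(np.array(genes)[complete], r):
            records[gene] = (float(ri), lnc.size)

    for idx in np.nonzero(~complete)[0]:
        row = G[idx]
        mask = np.isfinite(row) & lnc_mask
        n = int(mask.sum())
        if n < 3:
            logger.info("gene %s excluded: %d complete pair(s) < 3", genes[idx], n)
            continue
        x, y = row[mask], lnc[mask]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            records[genes[idx]] = (float("nan"), n)
            continue
        records[genes[idx]] = (float(np.corrcoef(x, y)[0, 1]), n)

    rows = []
    for gene in genes:
        if gene not in records:
            continue
        r, n = records[gene]
        if not np.isfinite(r):
            logger.info("gene %s excluded: zero variance over complete pairs", gene)
            continue
        rows.append((gene, min(max(r, -1.0), 1.0), n))
    out = pd.DataFrame(rows, columns=["gene_id", "r", "n"])
    out["p"] = _pearson_p(out["r"].to_numpy(), out["n"].to_numpy(dtype=float))
    return out[CORRELATION_COLUMNS]


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Two-sample t-test with unequal-variance (Welch) standard error.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom and a
    two-sided p from the t-distribution. Requires at least two observations
    per sample. Zero variance in one sample is handled normally; zero
    variance in both with equal means leaves the statistic undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            raise ValueError("both samples constant with equal means: t undefined")
        t = math.inf if x.mean() > y.mean() else -math.inf
        return t, float(x.size + y.size - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved.

    Sort ascending, take q(i) = min over j >= i of m*p(j)/j clipped at 1,
    and map back to the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mirna_enrichment(
    correlations: pd.DataFrame,
    target_map: TargetMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA target-set enrichment of absolute lncRNA correlation.

    For each testable miRNA m the sample ``x`` is the absolute correlation
    of its measured targets and ``y`` is the absolute correlation of the
    common background (the union of all candidates' targets; a miRNA's own
    targets are not removed). Welch t-test per miRNA, Benjamini–Hochberg
    across the tested miRNAs; ``significant`` additionally requires the
    target mean to exceed the background mean.
    """
    abs_r = dict(zip(correlations["gene_id"], correlations["r"].abs()))
    background = [abs_r[g] for g in sorted(target_map.background) if g in abs_r]
    if len(background) < 2:
        raise ValueError("background holds fewer than 2 correlated genes")
    y = np.asarray(background, dtype=float)

    rows = []
    for mirna, genes in target_map.entries.items():
        x = np.asarray([abs_r[g] for g in sorted(genes) if g in abs_r], dtype=float)
        if x.size < 2:
            logger.info("miRNA %s skipped: %d correlated target(s) < 2", mirna, x.size)
            continue
        t, df, p = welch_t_test(x, y)
        rows.append(
            {
                "mirna_id": mirna,
                "n_targets": int(x.size),
                "mean_abs_r_targets": float(x.mean()),
                "mean_abs_r_background": float(y.mean()),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no testable miRNA: every candidate was skipped")
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = (out["p_adj"] < alpha) & (
        out["mean_abs_r_targets"] > out["mean_abs_r_background"]
    )
    return out[ENRICHMENT_COLUMNS]


@dataclass
class CeRNANetwork:
    """Bipartite-plus-hub graph: lncRNA → significant miRNAs → selected genes.

    ``mirna_table`` holds the significant enrichment records (sorted by
    adjusted p ascending), ``gene_table`` the correlation records of the
    selected genes (sorted by r descending, ties broken lexicographically),
    and ``edges`` the sponge (lncRNA→miRNA) and target (miRNA→gene) edges.
    """

    lnc_id: str
    mirna_table: pd.DataFrame
    gene_table: pd.DataFrame
    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["source", "target", "kind"])
    )

    def __post_init__(self) -> None:
        nodes = {self.lnc_id} | set(self.mirna_table.get("mirna_id", [])) | set(
            self.gene_table.get("gene_id", [])
        )
        for row in self.edges.itertuples(index=False):
            if row.source == row.target:
                raise ValueError(f"self-loop on node {row.source!r}")
            if row.source not in nodes or row.target not in nodes:
                raise ValueError(f"edge endpoint missing from nodes: {row.source}->{row.target}")

    @property
    def n_nodes(self) -> int:
        return 1 + len(self.mirna_table) + len(self.gene_table)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(self.lnc_id, kind="lncRNA")
        for row in self.mirna_table.itertuples(index=False):
            g.add_node(
                row.mirna_id, kind="miRNA", p_adj=float(row.p_adj), t=float(row.t),
            )
        for row in self.gene_table.itertuples(index=False):
            g.add_node(row.gene_id, kind="gene", r=float(row.r), p=float(row.p))
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, kind=row.kind)
        return g


def select_network(
    enrichment: pd.DataFrame,
    correlations: pd.DataFrame,
    target_map: TargetMap,
    alpha: float = 0.05,
    lnc_id: str = "lncRNA",
) -> CeRNANetwork:
    """Assemble the ceRNA network from significant miRNAs and their genes.

    Gene nodes are targets of at least one significant miRNA whose own
    Pearson correlation is positive with p < alpha (the sponge model
    predicts positive lncRNA–target co-expression). Node ordering is
    deterministic: miRNAs by adjusted p ascending (then id), genes by r
    descending (then id). An empty network (no significant miRNA) is valid.
    """
    sig = (
        enrichment[enrichment["significant"]]
        .sort_values(["p_adj", "mirna_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    sig_mirnas = list(sig["mirna_id"])
    covered: set[str] = set()
    for m in sig_mirnas:
        covered |= target_map.entries.get(m, set())

    corr = correlations.set_index("gene_id")
    selected = [
        g for g in covered
        if g in corr.index and corr.at[g, "r"] > 0 and corr.at[g, "p"] < alpha
    ]
    gene_table = (
        corr.loc[selected].reset_index()
        .sort_values(["r", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )

    edge_rows = [
        {"source": lnc_id, "target": m, "kind": "sponge"} for m in sig_mirnas
    ]
    gene_set = set(gene_table["gene_id"])
    for m in sig_mirnas:
        for g in sorted(target_map.entries.get(m, set()) & gene_set):
            edge_rows.append({"source": m, "target": g, "kind": "target"})
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "kind"])
    return CeRNANetwork(
        lnc_id=lnc_id, mirna_table=sig, gene_table=gene_table, edges=edges,
    )


def rank_target_genes(network: CeRNANetwork, k: int = 20) -> pd.DataFrame:
    """Top-k gene nodes by correlation, ties broken lexicographically."""
    if k <= 0:
        raise ValueError("k must be a positive integer")
    return network.gene_table.head(k).reset_index(drop=True)


def write_network(network: CeRNANetwork, out_prefix: str | Path) -> dict[str, Path]:
    """Write node/edge TSV tables and a GraphML document with the same topology.

    Produces ``<prefix>_nodes.tsv``, ``<prefix>_edges.tsv`` and
    ``<prefix>.graphml``; returns the paths keyed by artifact kind.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    node_rows = [{"id": network.lnc_id, "kind": "lncRNA"}]
    for row in network.mirna_table.itertuples(index=False):
        node_rows.append(
            {
                "id": row.mirna_id, "kind": "miRNA", "t": row.t, "df": row.df,
                "p": row.p, "p_adj": row.p_adj,
            }
        )
    for row in network.gene_table.itertuples(index=False):
        node_rows.append({"id": row.gene_id, "kind": "gene", "r": row.r, "p": row.p})
    columns = ["id", "kind", "r", "t", "df", "p", "p_adj"]
    nodes = pd.DataFrame(node_rows).reindex(columns=columns)

    paths = {
        "nodes": prefix.with_name(prefix.name + "_nodes.tsv"),
        "edges": prefix.with_name(prefix.name + "_edges.tsv"),
        "graphml": prefix.with_suffix(".graphml"),
    }
    nodes.to_csv(paths["nodes"], sep="\t", index=False, na_rep="NA")
    network.edges.to_csv(paths["edges"], sep="\t", index=False)
    nx.write_graphml(network.to_networkx(), paths["graphml"])
    return paths


def read_network(prefix: str | Path) -> nx.DiGraph:
    """Re-read the GraphML document written by :func:`write_network`."""
    return nx.read_graphml(Path(prefix).with_suffix(".graphml"))
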