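"""Candidate assembly: collapse probes, list candidate miRNAs, intersect evidence.

The sponge screen needs (i) the set of miRNAs predicted to bind the lncRNA
and (ii), for each of them, the set of predicted target genes supported by
at least ``min_sources`` independent databases, restricted to genes actually
measured on the expression matrix. The union of all intersected target sets
is the common background against which every miRNA's target set is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import COLLAPSE_METHODS, ExpressionMatrix

logger = logging.getLogger("cernet")

__all__ = [
    "TargetMap",
    "collapse_probes",
    "candidate_mirnas",
    "intersect_targets",
    "restrict_to_measured",
    "target_map_to_frame",
    "target_map_from_frame",
]


@dataclass
class TargetMap:
    """miRNA → measured target-gene sets after evidence intersection.

    Attributes
    ----------
    entries : dict
        miRNA identifier → set of target-gene identifiers, each supported by
        at least ``min_sources`` databases.
    background : set
        Union of all entry sets, exactly.
    provenance : dict
        ``(mirna_id, gene_id)`` → frozenset of supporting source names.
    untested : dict
        miRNA identifier → human-readable reason it was removed from the
        testable entries (e.g. too few measured targets).
    """

    entries: dict[str, set[str]]
    background: set[str] = field(default_factory=set)
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    untested: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for genes in self.entries.values():
            union |= genes
        if not self.background:
            self.background = union
        elif self.background != union:
            raise ValueError("background must equal the union of all entry sets")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.entries)


def collapse_probes(matrix: ExpressionMatrix, method: str = "max-variance") -> ExpressionMatrix:
    """Collapse duplicate gene rows (array probes mapping to one symbol).

    ``max-variance`` keeps, per duplicated identifier, the row with the
    largest sample variance (ties broken by first occurrence); ``mean``
    averages the duplicated rows element-wise; ``first`` keeps the first
    occurrence. Without duplicates the matrix is returned unchanged.
    """
    if method not in COLLAPSE_METHODS:
        raise ValueError(f"collapse method must be one of {COLLAPSE_METHODS}, got {method!r}")
    data = matrix.data
    if not data.index.duplicated().any():
        return matrix

    if method == "first":
        collapsed = data.loc[~data.index.duplicated(keep="first")]
    elif method == "mean":
        collapsed = data.groupby(level=0, sort=False).mean()
    else:  # max-variance
        variances = data.var(axis=1, ddof=1).to_numpy()
        best: dict[str, int] = {}
        for pos, (gene, v) in enumerate(zip(data.index, variances)):
            if gene not in best:
                best[gene] = pos
            else:
                prev = variances[best[gene]]
                # strict > keeps the first occurrence on ties
                if np.isnan(prev) or (not np.isnan(v) and v > prev):
                    best[gene] = pos
        collapsed = data.iloc[sorted(best.values())]
        # sorted positions preserve first-occurrence gene order because the
        # retained row of each gene is re-labelled, not re-ordered
        collapsed = collapsed.set_axis(
            [g for g, _ in sorted(best.items(), key=lambda kv: kv[1])], axis=0
        )
    n_dropped = len(data) - len(collapsed)
    logger.info("collapse_probes(%s): %d row(s) collapsed", method, n_dropped)
    return ExpressionMatrix(data=collapsed, lnc_id=matrix.lnc_id)


def candidate_mirnas(binding: pd.DataFrame, lnc_id: str) -> list[str]:
    """miRNAs predicted to bind the designated lncRNA.

    Deduplicated, input order preserved. An empty result is a warning, not
    an error — the screen then simply has nothing to test.
    """
    hits = binding.loc[binding["lnc_id"] == lnc_id, "mirna_id"]
    out = list(dict.fromkeys(hits))
    if not out:
        logger.warning("no binding record names lncRNA %r; candidate list is empty", lnc_id)
    return out


def intersect_targets(
    predictions: pd.DataFrame,
    candidates: Iterable[str],
    min_sources: int = 2,
) -> TargetMap:
    """Keep, per candidate miRNA, targets supported by >= ``min_sources`` databases.

    ``predictions`` is the long table produced by
    :func:`cernet.io.read_prediction_tables` (columns ``mirna_id``,
    ``gene_id``, ``source``). Provenance (which sources support each kept
    pair) is recorded; the background is the union of all kept sets.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("candidate miRNA set is empty")
    n_available = predictions["source"].nunique()
    if min_sources > n_available:
        raise ValueError(
            f"min_sources={min_sources} exceeds the {n_available} configured source(s)"
        )
    cand_set = set(candidates)
    sub = predictions[predictions["mirna_id"].isin(cand_set)]
    support = sub.groupby(["mirna_id", "gene_id"], sort=False)["source"].agg(
        lambda s: frozenset(s)
    )

    entries: dict[str, set[str]] = {m: set() for m in candidates}
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    for (mirna, gene), sources in support.items():
        if len(sources) >= min_sources:
            entries[mirna].add(gene)
            provenance[(mirna, gene)] = sources
    return TargetMap(entries=entries, provenance=provenance)


def restrict_to_measured(
    target_map: TargetMap,
    matrix: ExpressionMatrix,
    min_target_set: int = 5,
) -> TargetMap:
    """Restrict a target map to genes measured on the (collapsed) matrix.

    Identifier matching is exact-string after case normalization; no alias
    resolution is attempted. miRNAs left with fewer than ``min_target_set``
    measured targets are moved to the ``untested`` list with a logged
    reason (a location test on a handful of observations is unstable).
    """
    if matrix.has_duplicate_genes:
        raise ValueError("expression matrix must be collapsed before restriction")
    lookup = {g.casefold(): g for g in matrix.gene_ids}

    entries: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    untested = dict(target_map.untested)
    for mirna, genes in target_map.entries.items():
        measured = {}
        for gene in genes:
            hit = lookup.get(gene.casefold())
            if hit is not None:
                measured[gene] = hit
        if len(measured) < min_target_set:
            reason = (
                f"{len(measured)} measured target(s) < min_target_set={min_target_set}"
            )
            untested[mirna] = reason
            logger.info("miRNA %s marked untested: %s", mirna, reason)
            continue
        entries[mirna] = set(measured.values())
        for gene, hit in measured.items():
            sources = target_map.provenance.get((mirna, gene))
            if sources is not None:
                provenance[(mirna, hit)] = sources
    return TargetMap(entries=entries, provenance=provenance, untested=untested)


def target_map_to_frame(target_map: TargetMap) -> pd.DataFrame:
    """Flatten a target map to a TSV-ready table (one row per kept pair)."""
    rows = []
    for mirna, genes in target_map.entries.items():
        for gene in sorted(genes):
            sources = sorted(target_map.provenance.get((mirna, gene), frozenset()))
            rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "n_sources": len(sources),
                    "sources": ",".join(sources),
                }
            )
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_sources", "sources"])


def target_map_from_frame(frame: pd.DataFrame) -> TargetMap:
    """Inverse of :func:`target_map_to_frame` (untested list is not persisted)."""
    entries: dict[str, set[str]] = {}
    provenance: dict[tuple[str, str], frozenset[str]] = {}
    for row in frame.itertuples(index=False):
        entries.setdefault(row.mirna_id, set()).add(row.gene_id)
        sources = frozenset(str(row.sources).split(",")) if row.sources else frozenset()
        provenance[(row.mirna_id, row.gene_id)] = sources
    return TargetMap(entries=entries, provenance=provenance)
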