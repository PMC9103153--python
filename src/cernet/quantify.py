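"""Bench-data arithmetic: ddCT, median normalization, RIP, RNAscope scoring.

CT tables are long frames with columns ``sample_id, group, gene_id,
replicate, ct`` (one replicate measurement per row). Replicates are
averaged on the CT scale before any differencing; amplification efficiency
is fixed at 2, so one cycle equals a two-fold abundance difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CT_COLUMNS

logger = logging.getLogger("cernet")

__all__ = [
    "delta_delta_ct",
    "median_normalize",
    "rip_enrichment",
    "rnascope_score",
    "RNAscopeScore",
]


def _check_ct(table: pd.DataFrame, name: str = "CT table") -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{name} is missing column(s) {missing}; expected {list(CT_COLUMNS)}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError(f"{name} contains non-finite CT values")
    return table


def _mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicates on the CT scale: one row per (sample, group, gene)."""
    return (
        table.groupby(["sample_id", "group", "gene_id"], sort=False, as_index=False)["ct"]
        .mean()
    )


def delta_delta_ct(table: pd.DataFrame, ref_gene: str, control_group: str) -> pd.DataFrame:
    """Relative expression by the ddCT method.

    dCT = CT_target - CT_ref per sample (replicates averaged first);
    ddCT = dCT - mean dCT over the control group; fold change = 2**(-ddCT).
    A gene's geometric-mean fold change over the control group is 1 by
    construction. Samples lacking the reference gene are excluded with a
    warning.
    """
    table = _check_ct(table)
    mean = _mean_ct(table)
    ref = mean[mean["gene_id"] == ref_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene!r} absent from the table")
    have_ref = mean["sample_id"].isin(ref.index)
    dropped = sorted(mean.loc[~have_ref, "sample_id"].unique())
    if dropped:
        logger.warning("samples without reference gene %s excluded: %s", ref_gene, dropped)
    mean = mean[have_ref].copy()

    mean["delta_ct"] = mean["ct"] - mean["sample_id"].map(ref)
    control = mean[mean["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    control_dct = control.groupby("gene_id")["delta_ct"].mean()
    mean = mean[mean["gene_id"].isin(control_dct.index)].copy()
    mean["delta_delta_ct"] = mean["delta_ct"] - mean["gene_id"].map(control_dct)
    mean["fold_change"] = 2.0 ** (-mean["delta_delta_ct"])
    return mean[
        ["sample_id", "group", "gene_id", "delta_ct", "delta_delta_ct", "fold_change"]
    ].reset_index(drop=True)


def median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median CT from its CT values (miRNA panels)."""
    table = _check_ct(table)
    counts = table.groupby("sample_id")["ct"].size()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(
            f"median normalization needs >=2 features per sample; "
            f"offending sample(s): {sorted(thin.index)}"
        )
    out = table.copy()
    out["ct"] = out["ct"] - out.groupby("sample_id")["ct"].transform("median")
    return out


def rip_enrichment(
    ip_table: pd.DataFrame,
    input_table: pd.DataFrame,
    igg_group: str,
) -> pd.DataFrame:
    """RNA-immunoprecipitation fold enrichment over the IgG control.

    Each immunoprecipitate CT is first normalized to its matched input
    fraction (dCT = CT_IP - CT_input, matched per sample and gene,
    replicates averaged first), then referenced to the IgG control group
    per gene (ddCT), and exponentiated: enrichment = 2**(-ddCT). The IgG
    group's geometric-mean enrichment is 1 by construction. An IP
    measurement without a matched input is a hard error.
    """
    ip = _mean_ct(_check_ct(ip_table, "IP table"))
    inp = _mean_ct(_check_ct(input_table, "input table"))
    inp_ct = inp.set_index(["sample_id", "gene_id"])["ct"]

    keys = pd.MultiIndex.from_frame(ip[["sample_id", "gene_id"]])
    unmatched = ~keys.isin(inp_ct.index)
    if unmatched.any():
        bad = ip.loc[unmatched, ["sample_id", "gene_id"]].iloc[0]
        raise ValueError(
            f"IP measurement without matched input: sample {bad['sample_id']!r}, "
            f"gene {bad['gene_id']!r}"
        )
    ip = ip.copy()
    ip["delta_ct"] = ip["ct"].to_numpy() - inp_ct.loc[keys].to_numpy()

    igg = ip[ip["group"] == igg_group]
    if igg.empty:
        raise ValueError(f"IgG control group {igg_group!r} has no samples")
    igg_dct = igg.groupby("gene_id")["delta_ct"].mean()
    ip = ip[ip["gene_id"].isin(igg_dct.index)].copy()
    ip["delta_delta_ct"] = ip["delta_ct"] - ip["gene_id"].map(igg_dct)
    ip["fold_enrichment"] = 2.0 ** (-ip["delta_delta_ct"])
    return ip[
        ["sample_id", "group", "gene_id", "delta_ct", "delta_delta_ct", "fold_enrichment"]
    ].reset_index(drop=True)


@dataclass(frozen=True)
class RNAscopeScore:
    """Semiquantitative in situ hybridization score: quality x quantity.

    quality grades signal intensity per cell (0 negative, 1 single signal,
    2 = 2-4 signals, 3 = >=5 signals); quantity grades the fraction of
    positive cells (0 negative up to 4 = >80%). The total is their product
    (0-12) and falls in exactly one category band.
    """

    quality: int
    quantity: int
    total: int
    category: str


_BANDS = ((0, 0, "absent"), (1, 4, "weak"), (5, 8, "moderate"), (9, 12, "strong"))


def rnascope_score(quality: int, quantity: int) -> RNAscopeScore:
    """Score a core: total = quality x quantity, banded absent/weak/moderate/strong."""
    if quality not in (0, 1, 2, 3):
        raise ValueError(f"quality sub-score must be an integer in 0..3, got {quality!r}")
    if quantity not in (0, 1, 2, 3, 4):
        raise ValueError(f"quantity sub-score must be an integer in 0..4, got {quantity!r}")
    total = quality * quantity
    category = next(name for lo, hi, name in _BANDS if lo <= total <= hi)
    return RNAscopeScore(quality=quality, quantity=quantity, total=total, category=category)
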