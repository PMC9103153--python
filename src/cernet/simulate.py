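"""Synthetic data with planted ground truth for every pipeline input.

The sponge generator encodes the statistical structure the screen assumes,
as a linear-Gaussian system. Per sample s:

* lncRNA abundance  L_s ~ N(0, 1)
* miRNA activity    a_js = m_js - theta * L_s   for sponged miRNA j
                    a_js = m_js                 otherwise, m_js ~ N(0, 1)
* target gene g of miRNA j:  x_gs = -beta * a_js + eps,  eps ~ N(0, sigma^2)
* null genes: pure N(0, sigma^2) noise.

High lncRNA lowers the free activity of a sponged miRNA, de-repressing its
targets, so a sponged miRNA's targets correlate positively with the lncRNA:
corr(x, L) = beta*theta / sqrt(beta^2*(1+theta^2) + sigma^2), which tends
to theta/sqrt(1+theta^2) as sigma -> 0. Targets of unsponged miRNAs and
null genes are uncorrelated with L.

Prediction tables list every true (miRNA, target) pair in 2 or 3 of the 3
sources, plus twice as many decoy pairs listed in exactly 1 source, so the
evidence-intersection step is exercised non-trivially. The binding table
lists every miRNA against the lncRNA. All generators are pure functions of
their configuration (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SpongeSimConfig",
    "GroundTruth",
    "simulate_cerna_dataset",
    "simulate_survival",
    "simulate_qpcr",
    "sponge_target_correlation",
    "write_cerna_dataset",
]

SOURCES = ("srcA", "srcB", "srcC")


@dataclass(frozen=True)
class SpongeSimConfig:
    """Conditions of the planted sponge simulation (defaults = study conditions)."""

    n_samples: int = 50
    n_mirnas: int = 20
    n_sponged: int = 5
    targets_per_mirna: int = 30
    n_null_genes: int = 500
    sponge_strength: float = 0.5   # theta
    repression: float = 0.8        # beta
    noise_sd: float = 1.0          # sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.n_mirnas < 1 or self.targets_per_mirna < 1 or self.n_null_genes < 0:
            raise ValueError("counts must be positive (n_null_genes may be 0)")
        if not 0 <= self.n_sponged <= self.n_mirnas:
            raise ValueError("n_sponged must lie in [0, n_mirnas]")
        if self.sponge_strength < 0 or self.repression < 0:
            raise ValueError("sponge_strength and repression must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: which miRNAs are sponged and who their targets are."""

    lnc_id: str
    sponged_mirnas: list[str]
    target_assignments: dict[str, set[str]] = field(default_factory=dict)
    #: gene -> True when the generator plants a positive lncRNA correlation
    effect: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        sponged = set(self.sponged_mirnas)
        for mirna, genes in self.target_assignments.items():
            for gene in sorted(genes):
                rows.append(
                    {
                        "mirna_id": mirna,
                        "gene_id": gene,
                        "sponged": mirna in sponged,
                        "planted_effect": self.effect.get(gene, False),
                    }
                )
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "sponged", "planted_effect"])


def sponge_target_correlation(theta: float, beta: float, sigma: float) -> float:
    """Analytic corr(target, lncRNA) of the linear-Gaussian sponge model."""
    if beta == 0.0:
        return 0.0
    return beta * theta / np.sqrt(beta * beta * (1.0 + theta * theta) + sigma * sigma)


def simulate_cerna_dataset(
    config: SpongeSimConfig = SpongeSimConfig(),
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one planted sponge dataset.

    Returns ``(matrix, binding, predictions, truth)``: the expression
    matrix (lncRNA row first), the miRNA→lncRNA binding table, the long
    prediction table over three sources, and the planted ground truth.
    Deterministic under ``config.seed``.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    lnc_id = "LNC01"
    mirnas = [f"mir-{j + 1:03d}" for j in range(c.n_mirnas)]
    sponged = mirnas[: c.n_sponged]

    L = rng.standard_normal(c.n_samples)
    m = rng.standard_normal((c.n_mirnas, c.n_samples))
    a = m.copy()
    a[: c.n_sponged] -= c.sponge_strength * L

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    assignments: dict[str, set[str]] = {}
    effect: dict[str, bool] = {}
    planted = c.sponge_strength > 0 and c.repression > 0
    for j, mirna in enumerate(mirnas):
        targets = set()
        for k in range(c.targets_per_mirna):
            gene = f"tgt-{j + 1:03d}-{k + 1:02d}"
            x = -c.repression * a[j] + rng.normal(0.0, c.noise_sd, c.n_samples)
            gene_ids.append(gene)
            rows.append(x)
            targets.add(gene)
            effect[gene] = planted and mirna in set(sponged)
        assignments[mirna] = targets
    for i in range(c.n_null_genes):
        gene_ids.append(f"null-{i + 1:04d}")
        rows.append(rng.normal(0.0, c.noise_sd, c.n_samples))

    data = pd.DataFrame(
        np.vstack([L] + rows),
        index=[lnc_id] + gene_ids,
        columns=[f"S{s + 1:03d}" for s in range(c.n_samples)],
    )
    matrix = ExpressionMatrix(data=data, lnc_id=lnc_id)

    binding = pd.DataFrame({"mirna_id": mirnas, "lnc_id": lnc_id})

    pred_rows = []
    all_genes = np.asarray(gene_ids)
    true_pairs: set[tuple[str, str]] = set()
    for mirna, targets in assignments.items():
        for gene in sorted(targets):
            true_pairs.add((mirna, gene))
            n_src = 2 + int(rng.random() < 1.0 / 3.0)
            for s in rng.choice(len(SOURCES), size=n_src, replace=False):
                pred_rows.append((mirna, gene, SOURCES[s]))
    # decoys: pairs in exactly one source, twice the true-pair count
    n_decoys = 2 * len(true_pairs)
    used = set(true_pairs)
    made = 0
    while made < n_decoys:
        mirna = mirnas[int(rng.integers(c.n_mirnas))]
        gene = str(all_genes[int(rng.integers(all_genes.size))])
        if (mirna, gene) in used:
            continue
        used.add((mirna, gene))
        pred_rows.append((mirna, gene, SOURCES[int(rng.integers(len(SOURCES)))]))
        made += 1
    predictions = (
        pd.DataFrame(pred_rows, columns=["mirna_id", "gene_id", "source"])
        .drop_duplicates()
        .reset_index(drop=True)
    )

    truth = GroundTruth(
        lnc_id=lnc_id,
        sponged_mirnas=list(sponged),
        target_assignments=assignments,
        effect=effect,
    )
    return matrix, binding, predictions, truth


def simulate_survival(
    n: int,
    theta: float = 0.0,
    hr: float = 4.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Survival table whose hazard jumps by ``hr`` above the planted cutoff.

    expression ~ N(0, 1); event time ~ Exponential(rate =
    baseline_hazard * hr**[expression > theta]). With probability
    ``censor_rate`` a subject is right-censored at a time drawn uniformly
    on (0, event time). Returns ``sample_id, time, event, expression``.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    expr = rng.standard_normal(n)
    rate = baseline_hazard * np.where(expr > theta, hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < censor_rate
    time = np.where(censored, rng.random(n) * t_event, t_event)
    return pd.DataFrame(
        {
            "sample_id": [f"P{i + 1:03d}" for i in range(n)],
            "time": time,
            "event": ~censored,
            "expression": expr,
        }
    )


def simulate_qpcr(
    n_samples: int,
    fold_changes: dict[str, float],
    ref_gene: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    control_group: str = "control",
    treated_group: str = "treated",
) -> pd.DataFrame:
    """CT plate with planted treated/control fold changes.

    CT = sample_offset + gene_baseline - log2(abundance) + N(0, noise_sd^2),
    with abundance = fold change in the treated group and 1 in the control
    group. Random per-sample offsets model loading/pipetting artifacts that
    the ddCT arithmetic must cancel. The reference gene must carry a
    planted fold change of 1.
    """
    if ref_gene not in fold_changes:
        raise ValueError(f"reference gene {ref_gene!r} missing from fold_changes")
    if fold_changes[ref_gene] != 1.0:
        raise ValueError("reference gene must have planted fold change 1")
    if any(fc <= 0 for fc in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    baselines = {g: rng.uniform(18.0, 28.0) for g in fold_changes}
    rows = []
    for group in (control_group, treated_group):
        for i in range(n_samples):
            sample = f"{group}-{i + 1:02d}"
            offset = rng.uniform(-2.0, 2.0)
            for gene, fc in fold_changes.items():
                abundance = fc if group == treated_group else 1.0
                for rep in range(1, n_replicates + 1):
                    ct = (
                        offset + baselines[gene] - np.log2(abundance)
                        + rng.normal(0.0, noise_sd)
                    )
                    rows.append((sample, group, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "replicate", "ct"])


def write_cerna_dataset(
    matrix: ExpressionMatrix,
    binding: pd.DataFrame,
    predictions: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one simulated dataset as the standard TSV files.

    ``expression.tsv``, ``binding.tsv``, ``predictions_<source>.tsv`` (one
    per source) and ``truth.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["expression"] = out / "expression.tsv"
    matrix.data.to_csv(paths["expression"], sep="\t", na_rep="NA", index_label="gene_id")
    paths["binding"] = out / "binding.tsv"
    binding.to_csv(paths["binding"], sep="\t", index=False)
    for source, sub in predictions.groupby("source", sort=True):
        p = out / f"predictions_{source}.tsv"
        sub[["mirna_id", "gene_id"]].to_csv(p, sep="\t", index=False)
        paths[f"predictions_{source}"] = p
    paths["truth"] = out / "truth.tsv"
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
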