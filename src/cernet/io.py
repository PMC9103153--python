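"""Typed readers and writers for the tables the pipeline consumes.

All external interchange is plain tab-delimited text:

* expression matrix — genes in rows, samples in columns, log-scale values,
  ``NA`` marks a missing cell;
* miRNA→gene prediction tables — one file per source database with headers
  ``mirna_id`` and ``gene_id``;
* miRNA→lncRNA binding tables — headers ``mirna_id`` and ``lnc_id``;
* survival tables — ``sample_id``, ``time``, ``event``, ``expression``;
* qPCR CT tables — ``sample_id``, ``group``, ``gene_id``, ``replicate``, ``ct``;
* pipeline configuration — a flat ``key = value`` text file mirroring
  :class:`PipelineConfig`.

Readers never reorder samples: the column order of the expression matrix
defines the sample pairing used by every correlation downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cernet")

__all__ = [
    "ExpressionMatrix",
    "PipelineConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_prediction_tables",
    "read_binding_table",
    "read_survival_table",
    "read_ct_table",
    "write_ct_table",
    "read_config",
    "PREDICTION_COLUMNS",
    "BINDING_COLUMNS",
    "SURVIVAL_COLUMNS",
    "CT_COLUMNS",
]

PREDICTION_COLUMNS = ("mirna_id", "gene_id")
BINDING_COLUMNS = ("mirna_id", "lnc_id")
SURVIVAL_COLUMNS = ("sample_id", "time", "event", "expression")
CT_COLUMNS = ("sample_id", "group", "gene_id", "replicate", "ct")

COLLAPSE_METHODS = ("max-variance", "mean", "first")


@dataclass
class ExpressionMatrix:
    """Log-scale gene × sample expression grid with a designated lncRNA row.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows (index), samples in columns. Float valued; ``NaN``
        flags a missing measurement — never silently zero.
    lnc_id : str
        Identifier of the designated lncRNA row; must be present in the
        index. Duplicate gene rows (array probes mapping to one symbol) are
        permitted until :func:`cernet.assembly.collapse_probes` is applied.
    """

    data: pd.DataFrame
    lnc_id: str

    def __post_init__(self) -> None:
        if self.data.shape[1] == 0 or self.data.shape[0] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise ValueError("expression matrix values must be numeric")
        if self.lnc_id not in self.data.index:
            raise ValueError(
                f"designated lncRNA row {self.lnc_id!r} not found among gene identifiers"
            )
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def has_duplicate_genes(self) -> bool:
        return bool(self.data.index.duplicated().any())

    def lnc_values(self) -> np.ndarray:
        """Expression vector of the designated lncRNA row.

        Raises if the lncRNA identifier is duplicated (collapse first).
        """
        rows = self.data.loc[[self.lnc_id]]
        if len(rows) != 1:
            raise ValueError(
                f"lncRNA row {self.lnc_id!r} is duplicated; collapse probes first"
            )
        return rows.to_numpy(dtype=float)[0]


@dataclass
class PipelineConfig:
    """Tunable thresholds shared across the pipeline stages."""

    min_sources: int = 2
    alpha: float = 0.05
    min_target_set: int = 5
    min_group_frac: float = 0.10
    seed: int = 0
    collapse_method: str = "max-variance"

    def __post_init__(self) -> None:
        if int(self.min_sources) < 1:
            raise ValueError("min_sources must be an integer >= 1")
        self.min_sources = int(self.min_sources)
        if not 0.0 < float(self.alpha) < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.alpha = float(self.alpha)
        if int(self.min_target_set) < 2:
            raise ValueError("min_target_set must be an integer >= 2")
        self.min_target_set = int(self.min_target_set)
        if not 0.0 < float(self.min_group_frac) < 0.5:
            raise ValueError("min_group_frac must lie in (0, 0.5)")
        self.min_group_frac = float(self.min_group_frac)
        if int(self.seed) < 0:
            raise ValueError("seed must be a non-negative integer")
        self.seed = int(self.seed)
        if self.collapse_method not in COLLAPSE_METHODS:
            raise ValueError(
                f"collapse_method must be one of {COLLAPSE_METHODS}, got {self.collapse_method!r}"
            )


def read_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` configuration file.

    Unknown keys are a hard error; ``overrides`` (e.g. from CLI flags) take
    precedence over file values when not ``None``.
    """
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ValueError(
                f"{path}:{lineno}: unknown configuration key {key!r} "
                f"(known keys: {sorted(fields)})"
            )
        values[key] = val
    for key, val in overrides.items():
        if val is not None:
            values[key] = val
    return PipelineConfig(**values)


def read_expression_matrix(path: str | Path, lnc_id: str) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix (first column = gene ids).

    Duplicate gene rows are preserved (collapsing is a separate step) and
    flagged in the log. ``NA`` cells become missing values. Non-numeric
    cells and a missing ``lnc_id`` row are hard errors.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, na_values=["NA"],
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression matrix file: {path}") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression matrix file: {path}")
    raw.index = raw.index.astype(str).str.strip()
    raw.index.name = None

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {raw.iat[r, c]!r} at "
            f"gene {raw.index[r]!r}, sample {raw.columns[c]!r} in {path}"
        )
    if lnc_id not in numeric.index:
        raise ValueError(
            f"designated lncRNA row {lnc_id!r} not found among gene identifiers in {path}"
        )
    if numeric.index.duplicated().any():
        dupes = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.warning(
            "expression matrix %s contains %d duplicated gene identifier(s): %s "
            "(collapse before correlating)", path, len(dupes), dupes[:10],
        )
    return ExpressionMatrix(data=numeric.astype(float), lnc_id=lnc_id)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def _read_pair_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(Path(path), sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty table: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"unknown column layout in {path}: missing {missing}; "
            f"expected tab-delimited headers {list(required)}"
        )
    df = df[list(required)].copy()
    for col in required:
        df[col] = df[col].astype(str).str.strip()
    return df


def read_prediction_tables(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Load miRNA→target-gene prediction tables, one file per source.

    Returns a long table with columns ``mirna_id``, ``gene_id``, ``source``.
    Pairs duplicated within a source are deduplicated; the same pair from
    different sources is kept once per source (that is the evidence the
    intersection step counts).
    """
    frames = []
    for source, p in paths.items():
        df = _read_pair_table(p, PREDICTION_COLUMNS)
        before = len(df)
        df = df.drop_duplicates()
        if len(df) < before:
            logger.info(
                "source %s: removed %d duplicate prediction pair(s)",
                source, before - len(df),
            )
        df["source"] = str(source)
        frames.append(df)
    if not frames:
        raise ValueError("no prediction tables given")
    return pd.concat(frames, ignore_index=True)


def read_binding_table(path: str | Path) -> pd.DataFrame:
    """Load a miRNA→lncRNA binding-prediction table; pairs deduplicated."""
    return _read_pair_table(path, BINDING_COLUMNS).drop_duplicates().reset_index(drop=True)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Load ``(sample_id, time, event, expression)`` triples for cutoff scans."""
    df = _read_pair_table(path, SURVIVAL_COLUMNS)
    df["time"] = pd.to_numeric(df["time"])
    df["expression"] = pd.to_numeric(df["expression"])
    df["event"] = df["event"].str.lower().map(
        {"1": True, "0": False, "true": True, "false": False}
    )
    if df["event"].isna().any():
        raise ValueError(f"event column in {path} must be 0/1 or true/false")
    if (df["time"] < 0).any():
        raise ValueError(f"negative survival time in {path}")
    if df[["time", "expression"]].isna().any().any():
        raise ValueError(f"missing time/expression value in {path}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Load a qPCR CT table with one replicate measurement per row."""
    df = _read_pair_table(path, CT_COLUMNS)
    df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
    df["ct"] = pd.to_numeric(df["ct"])
    if not np.isfinite(df["ct"]).all():
        raise ValueError(f"non-finite CT value in {path}")
    return df


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
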