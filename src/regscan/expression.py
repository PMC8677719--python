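"""Life-stage expression concordance filtering.

The filter keeps genes whose mean FPKM increases strictly along the declared
stage order (default aggregative < filopodic < cystic) after discarding genes
with zero expression in any stage, and reports stage fold changes relative to
a reference stage.  The filter is deterministic: no dispersion modeling, no
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io

DEFAULT_STAGE_ORDER = ("aggregative", "filopodic", "cystic")
ZERO_RULES = ("any-stage", "all-stages")


@dataclass
class ExpressionTable:
    """Long-format gene x stage x replicate FPKM values with a stage order."""

    data: pd.DataFrame  # columns gene_id, stage, replicate, fpkm
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self):
        missing = set(io.EXPRESSION_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"expression data missing columns: {sorted(missing)}")
        if (self.data["fpkm"] < 0).any():
            raise ValueError("FPKM values must be non-negative")
        stages = set(self.data["stage"])
        unknown = stages - set(self.stage_order)
        if unknown:
            raise ValueError(f"stages not in declared order: {sorted(unknown)}")
        reps = self.data.groupby(["gene_id", "stage"]).size()
        if (reps < 1).any() or reps.groupby("gene_id").size().nunique() not in (0, 1):
            raise ValueError("every gene needs at least one replicate per stage")

    def to_tsv(self, path: str | Path) -> None:
        io.write_expression_table(self.data, path)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 stage_order: Sequence[str] = DEFAULT_STAGE_ORDER) -> "ExpressionTable":
        return cls(io.read_expression_table(path), tuple(stage_order))


@dataclass
class ConcordanceResult:
    kept_genes: list[str]
    stage_means: pd.DataFrame           # genes x stages, in stage order
    discarded_zero: list[str] = field(default_factory=list)
    discarded_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        parts = set(self.kept_genes) | set(self.discarded_zero) | set(self.discarded_order)
        total = len(self.kept_genes) + len(self.discarded_zero) + len(self.discarded_order)
        if len(parts) != total or parts != set(self.stage_means.index):
            raise ValueError("kept/discarded lists must partition the input gene set")


def stage_means(table: ExpressionTable | pd.DataFrame,
                stage_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Arithmetic mean FPKM across replicates, genes x stages in stage order."""
    if isinstance(table, ExpressionTable):
        df, order = table.data, table.stage_order
    else:
        df, order = table, stage_order or DEFAULT_STAGE_ORDER
    means = df.groupby(["gene_id", "stage"])["fpkm"].mean().unstack("stage")
    return means.loc[:, list(order)]


def concordance_filter(
    means: pd.DataFrame,
    stage_order: Sequence[str] | None = None,
    zero_rule: str = "any-stage",
    strict: bool = True,
) -> ConcordanceResult:
    """Partition genes into kept / zero-discarded / order-discarded.

    A gene is discarded first when its mean FPKM is 0 in any stage
    (``zero_rule='all-stages'`` instead requires all stages zero), then kept
    only if its means increase along ``stage_order`` (strictly unless
    ``strict=False``, in which case ties survive).
    """
    if zero_rule not in ZERO_RULES:
        raise ValueError(f"zero_rule must be one of {ZERO_RULES}")
    order = list(stage_order) if stage_order is not None else list(means.columns)
    if set(order) != set(means.columns):
        raise ValueError(f"stage order {order} does not match table stages "
                         f"{list(means.columns)}")
    m = means.loc[:, order].to_numpy(dtype=float)
    if zero_rule == "any-stage":
        zero_mask = (m == 0).any(axis=1)
    else:
        zero_mask = (m == 0).all(axis=1)
    diffs = np.diff(m, axis=1)
    increasing = (diffs > 0).all(axis=1) if strict else (diffs >= 0).all(axis=1)
    kept_mask = ~zero_mask & increasing
    order_mask = ~zero_mask & ~increasing
    genes = means.index.to_numpy()
    return ConcordanceResult(
        kept_genes=list(genes[kept_mask]),
        stage_means=means.loc[:, order],
        discarded_zero=list(genes[zero_mask]),
        discarded_order=list(genes[order_mask]),
    )


def fold_changes(means: pd.DataFrame, gene: str, reference_stage: str) -> pd.Series:
    """Ratio of each stage mean to the reference stage mean for one gene."""
    row = means.loc[gene]
    ref = row[reference_stage]
    if ref == 0:
        raise ValueError(f"reference stage {reference_stage!r} has zero mean for {gene}")
    return row / ref
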