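"""RPKM computation and fold-change classification between two strains.

The comparison modeled here is a single RNA-seq profile per strain (wild
type vs. a regulator deletion), normalized as reads per kilobase of gene
per million mapped reads (RPKM), with genes partitioned by a strict
fold-change cutoff. There is no dispersion estimation or significance
testing: with one library per condition the fold change itself is the
screening statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

UP = "up_in_mutant"
DOWN = "down_in_mutant"
UNCHANGED = "unchanged"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used in the reported tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountRecord:
    gene_id: str
    condition: str
    mapped_reads: int
    gene_length: int

    def __post_init__(self) -> None:
        if self.gene_length < 1:
            raise ValueError(f"{self.gene_id}: gene_length must be >= 1")
        if self.mapped_reads < 0:
            raise ValueError(f"{self.gene_id}: negative read count")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    rpkm_wt: float
    rpkm_mut: float

    def __post_init__(self) -> None:
        if self.rpkm_wt < 0 or self.rpkm_mut < 0:
            raise ValueError(f"{self.gene_id}: RPKM must be non-negative")


@dataclass(frozen=True)
class DERecord:
    """Differential-expression summary: symmetric fold change + direction."""

    gene_id: str
    rpkm_wt: float
    rpkm_mut: float
    fold_change: float  # max(r, 1/r), unrounded
    direction: str  # up_in_mutant | down_in_mutant | unchanged

    @property
    def fold_change_2dp(self) -> float:
        return round_half_up(self.fold_change, 2)


def compute_rpkm(count: CountRecord, total_mapped_reads: int) -> float:
    """RPKM = reads / (gene length in kb x library size in millions)."""
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    return count.mapped_reads / ((count.gene_length / 1e3) * (total_mapped_reads / 1e6))


def fold_change(rec: ExpressionRecord, epsilon: float = 0.01) -> DERecord:
    """Symmetric fold change between conditions.

    The ratio r = rpkm_mut/rpkm_wt is folded to max(r, 1/r); a pseudocount
    ``epsilon`` is added to both values only when one of them is zero.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    wt, mut = rec.rpkm_wt, rec.rpkm_mut
    if wt == 0 or mut == 0:
        if epsilon == 0:
            raise ValueError(
                f"{rec.gene_id}: zero RPKM requires a positive pseudocount"
            )
        wt, mut = wt + epsilon, mut + epsilon
    r = mut / wt
    if r > 1:
        direction = UP
    elif r < 1:
        direction = DOWN
    else:
        direction = UNCHANGED
    return DERecord(rec.gene_id, rec.rpkm_wt, rec.rpkm_mut, max(r, 1 / r), direction)


def classify_de(
    records: Iterable[ExpressionRecord],
    threshold: float,
    epsilon: float = 0.01,
) -> dict[str, list[DERecord]]:
    """Partition genes into up / down / unchanged at a strict fold cutoff.

    'More than x-fold' is read strictly: a gene exactly at the threshold
    is left unchanged (and logged). The partition is exhaustive and
    disjoint.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    out: dict[str, list[DERecord]] = {"up": [], "down": [], "unchanged": []}
    for rec in records:
        de = fold_change(rec, epsilon)
        if de.fold_change > threshold and de.direction == UP:
            out["up"].append(de)
        elif de.fold_change > threshold and de.direction == DOWN:
            out["down"].append(de)
        else:
            if de.fold_change == threshold:
                logger.info("%s: fold change exactly at threshold, left unchanged", de.gene_id)
            out["unchanged"].append(de)
    return out


# ---------------------------------------------------------------------------
# table-level plumbing


def load_counts(path) -> pd.DataFrame:
    """Read a count table: gene_id, length_bp, count_WT, count_MUT."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene_id", "length_bp", "count_WT", "count_MUT"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing count columns {missing}")
    return df


def rpkm_table(counts: pd.DataFrame) -> list[ExpressionRecord]:
    """RPKM per gene for both conditions from a wide count table.

    Library sizes are the column totals of mapped reads. Replicate columns
    (count_WT_1, count_WT_2, ...) are averaged as RPKM means.
    """
    wt_cols = [c for c in counts.columns if c == "count_WT" or c.startswith("count_WT_")]
    mut_cols = [c for c in counts.columns if c == "count_MUT" or c.startswith("count_MUT_")]
    if not wt_cols or not mut_cols:
        raise ValueError("count table must have count_WT and count_MUT columns")

    def per_condition(cols: list[str]) -> pd.Series:
        vals = []
        for c in cols:
            total = int(counts[c].sum())
            vals.append(
                counts.apply(
                    lambda row: compute_rpkm(
                        CountRecord(row["gene_id"], c, int(row[c]), int(row["length_bp"])),
                        total,
                    ),
                    axis=1,
                )
            )
        return sum(vals) / len(vals)

    rpkm_wt, rpkm_mut = per_condition(wt_cols), per_condition(mut_cols)
    return [
        ExpressionRecord(g, w, m)
        for g, w, m in zip(counts["gene_id"], rpkm_wt, rpkm_mut)
    ]


def de_frame(
    records: Iterable[ExpressionRecord],
    threshold: float,
    epsilon: float = 0.01,
    min_rpkm: float = 0.0,
) -> pd.DataFrame:
    """Per-gene DE table with 2-dp reported fold changes.

    ``min_rpkm`` optionally suppresses genes whose larger RPKM stays below
    a floor (off by default).
    """
    rows = []
    for rec in records:
        if min_rpkm > 0 and max(rec.rpkm_wt, rec.rpkm_mut) < min_rpkm:
            continue
        de = fold_change(rec, epsilon)
        direction = de.direction if de.fold_change > threshold else UNCHANGED
        rows.append(
            {
                "gene_id": de.gene_id,
                "rpkm_wt": de.rpkm_wt,
                "rpkm_mut": de.rpkm_mut,
                "fold_change": de.fold_change_2dp,
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "rpkm_wt", "rpkm_mut", "fold_change", "direction"]
    )
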