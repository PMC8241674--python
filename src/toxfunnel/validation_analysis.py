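"""Downstream validation arithmetic.

Two small but load-bearing analyses:

* fold-change overlap/reversal across treatments — which genes are
  commonly deregulated by a candidate drug and a cardioprotective control,
  and which of those move in the opposite direction under a cardiotoxic
  control ("reversely deregulated" genes, a cardioprotection signature);
* in-vivo event-rate classification — death/adverse-event rates in a
  treatment group, with rates below a noise threshold (default 10%)
  regarded as experimental error rather than a treatment effect.

Fold changes are consumed as supplied (signed magnitudes, positive =
upregulated); no log transform or magnitude cutoff is applied by default.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "FoldChangeTable",
    "ReversalResult",
    "EventRateSummary",
    "common_deregulated",
    "reversal_detect",
    "event_rate_classify",
    "load_fold_change_csv",
]


@dataclass
class FoldChangeTable:
    treatment: str
    fold_changes: dict[str, float]  # gene -> signed fold change, nonzero

    def __post_init__(self):
        for gene, fc in self.fold_changes.items():
            if not gene:
                raise ValueError("empty gene symbol")
            if fc == 0 or not math.isfinite(fc):
                raise ValueError(f"{self.treatment}: fold change for {gene} must be nonzero")

    def genes(self) -> set[str]:
        return set(self.fold_changes)

    def filtered(self, min_abs_fc: float) -> "FoldChangeTable":
        """Optional magnitude cutoff; default pipeline applies none."""
        return FoldChangeTable(
            self.treatment,
            {g: fc for g, fc in self.fold_changes.items() if abs(fc) >= min_abs_fc},
        )


@dataclass
class ReversalResult:
    common_genes: set[str]
    reversed_genes: set[str]
    triplets: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def common_deregulated(
    tables: Sequence[FoldChangeTable],
) -> tuple[set[str], set[str]]:
    """Genes present in every table, and the subset with one shared sign."""
    if len(tables) < 2:
        raise ValueError("need at least two fold-change tables")
    common = set.intersection(*(t.genes() for t in tables))
    same_direction = {
        g
        for g in common
        if len({math.copysign(1, t.fold_changes[g]) for t in tables}) == 1
    }
    return common, same_direction


def reversal_detect(
    table_a: FoldChangeTable, table_b: FoldChangeTable, table_c: FoldChangeTable
) -> ReversalResult:
    """Genes deregulated the same way by A and B but oppositely by C.

    reversed = {g common to all three : sign A(g) = sign B(g) = -sign C(g)}.
    Symmetric in A and B.
    """
    common = table_a.genes() & table_b.genes() & table_c.genes()
    reversed_genes = set()
    triplets = {}
    for g in common:
        fa, fb, fc = (t.fold_changes[g] for t in (table_a, table_b, table_c))
        triplets[g] = (fa, fb, fc)
        sa, sb, sc = (math.copysign(1, v) for v in (fa, fb, fc))
        if sa == sb and sc == -sa:
            reversed_genes.add(g)
    return ReversalResult(common_genes=common, reversed_genes=reversed_genes, triplets=triplets)


@dataclass
class EventRateSummary:
    events: int
    n: int
    rate_percent: float
    noise_threshold_percent: float
    within_noise: bool


def event_rate_classify(
    events: int, n: int, threshold_percent: float = 10.0
) -> EventRateSummary:
    """Classify an event count against the experimental-noise threshold.

    ``rate_percent`` is 100*events/n rounded to one decimal; ``within_noise``
    compares the exact (unrounded) rate strictly against the threshold.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= events <= n:
        raise ValueError(f"events must be in [0, n], got events={events}, n={n}")
    exact = 100.0 * events / n
    return EventRateSummary(
        events=events,
        n=n,
        rate_percent=round(exact, 1),
        noise_threshold_percent=threshold_percent,
        within_noise=exact < threshold_percent,
    )


def load_fold_change_csv(source: str | os.PathLike, treatment: str) -> FoldChangeTable:
    """Read a per-treatment CSV with columns ``gene,fold_change``."""
    is_path = isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    )
    text = open(source).read() if is_path else str(source)
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or not {"gene", "fold_change"} <= set(reader.fieldnames):
        raise ValueError("fold-change CSV requires columns 'gene' and 'fold_change'")
    fcs: dict[str, float] = {}
    for row in reader:
        gene = row["gene"].strip()
        if gene in fcs:
            raise ValueError(f"duplicate gene symbol {gene!r}")
        fcs[gene] = float(row["fold_change"])
    return FoldChangeTable(treatment, fcs)
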