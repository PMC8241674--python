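"""Correlation-gated descriptor selection.

Two-stage filter used before model training:

1. relevance gate — descriptors whose point-biserial (Pearson) correlation
   with the binary endpoint label has absolute value <= ``t_target``
   (default 0.1) are dropped;
2. collinearity gate — among the survivors, for every pair with pairwise
   |r| > ``t_pair`` (default 0.9) the member with the lower absolute target
   correlation is dropped (ties drop the later descriptor in registry
   order). Pairs are processed in descending |r|, re-evaluating after each
   drop, which makes the procedure deterministic.

Constant descriptor columns have undefined correlation and are routed to
the relevance-dropped list.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CorrelationReport", "SelectionResult", "correlation_report", "select_descriptors"]


@dataclass
class CorrelationReport:
    target_correlations: pd.Series      # descriptor -> Pearson r with label (NaN if undefined)
    pairwise: pd.DataFrame              # symmetric descriptor x descriptor Pearson r
    n_samples: int

    @property
    def descriptors(self) -> list[str]:
        return list(self.target_correlations.index)


@dataclass
class SelectionResult:
    kept: list[str]
    dropped_low_target: list[tuple[str, float]]
    dropped_collinear: list[tuple[str, str, float, float, float]]
    t_target: float = 0.1
    t_pair: float = 0.9

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped_low_target": [
                    {"descriptor": d, "r_target": None if math.isnan(r) else r}
                    for d, r in self.dropped_low_target
                ],
                "dropped_collinear": [
                    {
                        "descriptor": d,
                        "partner": p,
                        "r_pair": rp,
                        "r_target_self": rs,
                        "r_target_partner": rt,
                    }
                    for d, p, rp, rs, rt in self.dropped_collinear
                ],
                "t_target": self.t_target,
                "t_pair": self.t_pair,
            },
            indent=2,
        )


def correlation_report(matrix: pd.DataFrame, labels) -> CorrelationReport:
    """Pearson correlations of each descriptor with the label and pairwise.

    ``labels`` must be binary with both classes present and at least three
    samples. Constant columns get NaN target correlation (undefined) and
    NaN off-diagonal pairwise entries; the diagonal is fixed at 1.
    """
    y = np.asarray(labels, dtype=float)
    if len(y) != len(matrix):
        raise ValueError("labels length does not match descriptor matrix rows")
    if len(y) < 3:
        raise ValueError(f"need at least 3 samples, got {len(y)}")
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"labels must be binary 0/1, got values {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes must be present to correlate against the label")

    X = matrix.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        target = X.apply(lambda col: _pearson(col.to_numpy(), y))
        pairwise = X.corr(method="pearson")  # NaN where a column is constant
    np.fill_diagonal(pairwise.values, 1.0)
    return CorrelationReport(target_correlations=target, pairwise=pairwise, n_samples=len(y))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0 or not np.isfinite(sx):
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def select_descriptors(
    report: CorrelationReport, t_target: float = 0.1, t_pair: float = 0.9
) -> SelectionResult:
    """Apply the relevance and collinearity gates; fully deterministic."""
    order = report.descriptors
    rt = report.target_correlations

    kept: list[str] = []
    dropped_low: list[tuple[str, float]] = []
    for d in order:
        r = rt[d]
        if math.isnan(r) or abs(r) <= t_target:
            dropped_low.append((d, float(r)))
        else:
            kept.append(d)

    dropped_coll: list[tuple[str, str, float, float, float]] = []
    while True:
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                rp = report.pairwise.loc[a, b]
                if math.isnan(rp) or abs(rp) <= t_pair:
                    continue
                if best is None or abs(rp) > best[0]:
                    best = (abs(rp), a, b)
        if best is None:
            break
        _, a, b = best
        ra, rb = abs(rt[a]), abs(rt[b])
        if ra < rb:
            loser, partner = a, b
        elif rb < ra:
            loser, partner = b, a
        else:  # tie: drop the later one in registry order
            loser, partner = (b, a) if order.index(b) > order.index(a) else (a, b)
        kept.remove(loser)
        dropped_coll.append(
            (loser, partner, float(report.pairwise.loc[loser, partner]),
             float(rt[loser]), float(rt[partner]))
        )

    return SelectionResult(
        kept=kept,
        dropped_low_target=dropped_low,
        dropped_collinear=dropped_coll,
        t_target=t_target,
        t_pair=t_pair,
    )
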