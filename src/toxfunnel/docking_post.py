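"""hERG docking-score post-processing.

Takes lowest binding energies (LBE, kcal/mol) from replicate docking runs,
aggregates them per compound, converts binding free energy to a predicted
inhibition constant via the Boltzmann relation

    Ki = exp(deltaG / (R * T)),   R = 1.98719e-3 kcal/(mol K), T = 298.15 K

(the AutoDock4 reporting convention), and ranks compounds against a
cardiotoxic positive control and a cardioprotective negative control.
Weaker binding than the cardiotoxic control (higher, less negative LBE) is
read as a safer hERG profile.

Note ``ki_mean`` is the mean of per-run Ki values, not the Ki of the mean
LBE; by Jensen's inequality the two differ, and the per-run convention is
the one replicate docking reports follow.
"""

from __future__ import annotations

import csv
import io
import math
import os
import re
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE_K",
    "DockingRun",
    "AffinityEstimate",
    "ControlComparison",
    "parse_docking_scores",
    "parse_dlg",
    "ki_from_energy",
    "energy_from_ki",
    "aggregate_runs",
    "rank_vs_controls",
]

GAS_CONSTANT_KCAL = 1.98719e-3     # kcal / (mol K)
STANDARD_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class DockingRun:
    compound_id: str
    run_index: int
    lbe: float  # lowest binding energy, kcal/mol

    def __post_init__(self):
        if not math.isfinite(self.lbe):
            raise ValueError(f"{self.compound_id} run {self.run_index}: LBE not finite")


@dataclass
class AffinityEstimate:
    compound_id: str
    lbe_mean: float
    lbe_sd: float
    ki_mean_uM: float
    ki_sd_uM: float
    n_runs: int


@dataclass
class ControlComparison:
    estimates: list[AffinityEstimate]       # sorted weakest binder first
    positive_control: str
    negative_control: str
    calls: dict[str, str]                   # id -> weaker_than_positive | not_weaker


def ki_from_energy(lbe: float, temperature_K: float = STANDARD_TEMPERATURE_K) -> float:
    """Predicted inhibition constant in molar from binding energy (kcal/mol)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(lbe / (GAS_CONSTANT_KCAL * temperature_K))


def energy_from_ki(ki_molar: float, temperature_K: float = STANDARD_TEMPERATURE_K) -> float:
    """Inverse of :func:`ki_from_energy`."""
    if ki_molar <= 0:
        raise ValueError("Ki must be positive")
    return GAS_CONSTANT_KCAL * temperature_K * math.log(ki_molar)


def parse_docking_scores(source: str | os.PathLike) -> list[DockingRun]:
    """Parse a TSV of docking runs: ``compound_id<TAB>run_index<TAB>lbe_kcal``.

    A header row is optional. Duplicate (compound_id, run_index) pairs are a
    hard error; malformed rows raise with their line number.
    """
    is_path = isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    )
    text = open(source).read() if is_path else str(source)
    runs: list[DockingRun] = []
    seen: set[tuple[str, int]] = set()
    for lineno, row in enumerate(csv.reader(io.StringIO(text), delimiter="\t"), start=1):
        if not row or not "".join(row).strip():
            continue
        if lineno == 1 and row[0].strip().lower() in {"compound_id", "id", "compound"}:
            continue
        if len(row) < 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields, got {row!r}")
        cid = row[0].strip()
        try:
            idx = int(row[1])
            lbe = float(row[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        key = (cid, idx)
        if key in seen:
            raise ValueError(f"duplicate docking run {key}")
        seen.add(key)
        runs.append(DockingRun(cid, idx, lbe))
    return runs


_DLG_ENERGY = re.compile(
    r"Estimated Free Energy of Binding\s*=\s*([-+]?\d+(?:\.\d+)?)\s*kcal/mol"
)


def parse_dlg(
    path: str | os.PathLike, compound_id: str | None = None, run_index: int = 1
) -> DockingRun:
    """Extract the best (lowest) binding energy from an AutoDock4 DLG file."""
    text = open(path).read()
    energies = [float(m) for m in _DLG_ENERGY.findall(text)]
    if not energies:
        raise ValueError(f"no 'Estimated Free Energy of Binding' found in {path}")
    cid = compound_id or os.path.splitext(os.path.basename(path))[0]
    return DockingRun(cid, run_index, min(energies))


def aggregate_runs(
    runs: Iterable[DockingRun], temperature_K: float = STANDARD_TEMPERATURE_K
) -> list[AffinityEstimate]:
    """Per-compound mean/SD of LBE and of the per-run Ki (in µM).

    Sample SD (n-1 denominator); SD = 0 for a single run. Output order
    follows first appearance in the input.
    """
    grouped: dict[str, list[float]] = {}
    for run in runs:
        grouped.setdefault(run.compound_id, []).append(run.lbe)
    out = []
    for cid, lbes in grouped.items():
        kis = [ki_from_energy(e, temperature_K) * 1e6 for e in lbes]
        n = len(lbes)
        out.append(
            AffinityEstimate(
                compound_id=cid,
                lbe_mean=statistics.fmean(lbes),
                lbe_sd=statistics.stdev(lbes) if n > 1 else 0.0,
                ki_mean_uM=statistics.fmean(kis),
                ki_sd_uM=statistics.stdev(kis) if n > 1 else 0.0,
                n_runs=n,
            )
        )
    return out


def rank_vs_controls(
    estimates: Sequence[AffinityEstimate], positive_id: str, negative_id: str
) -> ControlComparison:
    """Rank compounds by binding strength against the control drugs.

    Sorted by mean LBE descending (weakest binder first). A compound is
    called ``weaker_than_positive`` iff its mean LBE is strictly greater
    (less negative) than the cardiotoxic positive control's; a tie is
    conservatively ``not_weaker``.
    """
    by_id = {e.compound_id: e for e in estimates}
    for ctrl in (positive_id, negative_id):
        if ctrl not in by_id:
            raise ValueError(f"control compound {ctrl!r} missing from estimates")
    pos_lbe = by_id[positive_id].lbe_mean
    ranked = sorted(estimates, key=lambda e: e.lbe_mean, reverse=True)
    calls = {
        e.compound_id: ("weaker_than_positive" if e.lbe_mean > pos_lbe else "not_weaker")
        for e in ranked
    }
    return ControlComparison(
        estimates=ranked,
        positive_control=positive_id,
        negative_control=negative_id,
        calls=calls,
    )
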