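"""Three-tier safety filtering funnel and reference-list evaluation.

Tier 1 keeps compounds whose cardiotoxicity endpoint models pass the
configured rule (default: all five endpoints predicted non-toxic). Tier 2
keeps tier-1 survivors with no mutagenicity / tumorigenicity /
reproductive-toxicity alert; tier 3 keeps tier-2 survivors with no
hepatotoxicity / immunotoxicity alert. Survivor sets are strictly nested
and every compound carries an audit trail of the flags that stopped it.

The tier-2/3 predictors behind the original screen are closed software;
here they are pluggable: bundled demonstrative SMARTS alert lists, any
user-supplied alert list, or an externally exported per-compound verdict
table (CSV ``compound_id,category,risk``). Counts obtained with the
bundled lists are therefore illustrative, not a reproduction of any
external tool's output.
"""

from __future__ import annotations

import csv
import io
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import yaml
from rdkit import Chem

from .descriptors import (
    CompoundRecord,
    DescriptorRegistry,
    SubstructurePattern,
    compute_descriptor_panel,
    default_registry,
)

__all__ = [
    "RISK_LEVELS",
    "AUX_CATEGORIES",
    "TIER2_CATEGORIES",
    "TIER3_CATEGORIES",
    "Alert",
    "AlertList",
    "CascadeConfig",
    "CompoundVerdict",
    "FunnelReport",
    "structural_alert_screen",
    "apply_cascade",
    "evaluate_reference_list",
    "load_alert_lists",
    "load_verdict_table",
    "default_alert_lists",
]

RISK_LEVELS = ("none", "low", "high")
TIER2_CATEGORIES = ("mutagenicity", "tumorigenicity", "reproductive")
TIER3_CATEGORIES = ("hepatotoxicity", "immunotoxicity")
AUX_CATEGORIES = TIER2_CATEGORIES + TIER3_CATEGORIES


@dataclass(frozen=True)
class Alert:
    pattern: SubstructurePattern
    level: str  # "low" | "high"

    def __post_init__(self):
        if self.level not in ("low", "high"):
            raise ValueError(f"alert level must be low or high, got {self.level!r}")


@dataclass
class AlertList:
    category: str
    alerts: list[Alert]

    def __post_init__(self):
        if self.category not in AUX_CATEGORIES:
            raise ValueError(
                f"unknown alert category {self.category!r}; expected one of {AUX_CATEGORIES}"
            )


@dataclass
class CascadeConfig:
    """Combination rules for the funnel; recorded verbatim in the report."""

    cardiotox_rule: str = "all_negative"       # or "majority_negative"
    endpoint_threshold: float = 0.5
    aux_fail_rule: str = "any"                  # or "high_only"

    def __post_init__(self):
        if self.cardiotox_rule not in ("all_negative", "majority_negative"):
            raise ValueError(f"unknown cardiotox_rule {self.cardiotox_rule!r}")
        if self.aux_fail_rule not in ("any", "high_only"):
            raise ValueError(f"unknown aux_fail_rule {self.aux_fail_rule!r}")

    def to_dict(self) -> dict:
        return {
            "cardiotox_rule": self.cardiotox_rule,
            "endpoint_threshold": self.endpoint_threshold,
            "aux_fail_rule": self.aux_fail_rule,
            "tier_order": ["cardiotoxicity", list(TIER2_CATEGORIES), list(TIER3_CATEGORIES)],
        }


@dataclass
class CompoundVerdict:
    compound_id: str
    endpoint_probabilities: dict[str, float] = field(default_factory=dict)
    endpoint_labels: dict[str, int] = field(default_factory=dict)
    category_risks: dict[str, str] = field(default_factory=dict)
    tier_reached: str = "passed"  # failed_t1 | failed_t2 | failed_t3 | passed | uncomputable
    aux_flagged: bool = False

    @property
    def cardiotox_positive(self) -> bool:
        return any(v == 1 for v in self.endpoint_labels.values())

    @property
    def overall_toxic(self) -> bool:
        return (
            self.cardiotox_positive
            or self.aux_flagged
            or any(r != "none" for r in self.category_risks.values())
        )


@dataclass
class FunnelReport:
    input_count: int
    tier1_survivors: list[str]
    tier2_survivors: list[str]
    tier3_survivors: list[str]
    verdicts: dict[str, CompoundVerdict]
    config: CascadeConfig
    uncomputable: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.input_count,
            len(self.tier1_survivors),
            len(self.tier2_survivors),
            len(self.tier3_survivors),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "counts": list(self.counts),
                "tier1_survivors": self.tier1_survivors,
                "tier2_survivors": self.tier2_survivors,
                "tier3_survivors": self.tier3_survivors,
                "uncomputable": [list(u) for u in self.uncomputable],
                "config": self.config.to_dict(),
                "verdicts": {
                    cid: {
                        "endpoint_probabilities": v.endpoint_probabilities,
                        "endpoint_labels": v.endpoint_labels,
                        "category_risks": v.category_risks,
                        "tier_reached": v.tier_reached,
                        "overall_toxic": v.overall_toxic,
                    }
                    for cid, v in self.verdicts.items()
                },
            },
            indent=2,
        )


def structural_alert_screen(
    smiles: str, alert_lists: Sequence[AlertList]
) -> dict[str, str]:
    """Per-category risk: the highest level among matched alerts, else none."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    risks: dict[str, str] = {}
    for alist in alert_lists:
        level = "none"
        for alert in alist.alerts:
            if mol.HasSubstructMatch(alert.pattern.query()):
                if alert.level == "high":
                    level = "high"
                    break
                level = "low"
        # categories may appear in several lists; keep the worst
        prev = risks.get(alist.category, "none")
        risks[alist.category] = max(prev, level, key=RISK_LEVELS.index)
    return risks


def _risk_fails(risk: str, rule: str) -> bool:
    return risk == "high" if rule == "high_only" else risk != "none"


def apply_cascade(
    library: Sequence[CompoundRecord],
    suite,
    alert_lists: Sequence[AlertList] = (),
    config: CascadeConfig | None = None,
    registry: DescriptorRegistry | None = None,
    affinities: Mapping[str, float] | None = None,
    aux_verdicts: Mapping[tuple[str, str], str] | None = None,
) -> FunnelReport:
    """Run the full three-tier funnel over a compound library.

    ``suite`` is an :class:`~toxfunnel.model_bench.EndpointModelSuite` or
    any object with ``predict_proba(DataFrame) -> DataFrame`` (per-endpoint
    toxicity probabilities) and a ``threshold`` attribute. ``aux_verdicts``
    maps ``(compound_id, category)`` to a risk level and overrides the
    structural-alert screen for those compounds, letting externally
    exported verdict tables replay the funnel exactly.

    A compound failing an earlier tier is not evaluated at later tiers —
    its verdict carries no flags for them.
    """
    config = config or CascadeConfig()
    threshold = getattr(suite, "threshold", config.endpoint_threshold)
    verdicts: dict[str, CompoundVerdict] = {}
    uncomputable: list[tuple[str, str]] = []

    # Tier 1: cardiotoxicity endpoint models
    computable: list[CompoundRecord] = []
    for rec in library:
        try:
            rec.mol()
            computable.append(rec)
        except ValueError as exc:
            uncomputable.append((rec.id, f"uncomputable: {exc}"))
            verdicts[rec.id] = CompoundVerdict(rec.id, tier_reached="uncomputable")

    tier1: list[str] = []
    if computable:
        X = compute_descriptor_panel(computable, registry or default_registry(), affinities)
        # LE is missing without affinities; models trained without it simply
        # ignore the column via suite.columns selection.
        probs = suite.predict_proba(X)
        for rec in computable:
            p = probs.loc[rec.id].to_dict()
            labels = {ep: int(v >= threshold) for ep, v in p.items()}
            v = CompoundVerdict(rec.id, endpoint_probabilities={k: float(x) for k, x in p.items()},
                                endpoint_labels=labels)
            n_tox = sum(labels.values())
            if config.cardiotox_rule == "all_negative":
                passed = n_tox == 0
            else:  # majority_negative
                passed = n_tox <= len(labels) // 2
            if passed:
                tier1.append(rec.id)
                v.tier_reached = "passed"  # provisional; later tiers may demote
            else:
                v.tier_reached = "failed_t1"
            verdicts[rec.id] = v

    by_id = {r.id: r for r in library}

    def _screen(cid: str, categories: Sequence[str]) -> dict[str, str]:
        rec = by_id[cid]
        if aux_verdicts is not None and any((cid, c) in aux_verdicts for c in categories):
            return {c: aux_verdicts.get((cid, c), "none") for c in categories}
        lists = [al for al in alert_lists if al.category in categories]
        risks = structural_alert_screen(rec.smiles, lists)
        return {c: risks.get(c, "none") for c in categories}

    # Tier 2: mutagenicity / tumorigenicity / reproductive toxicity
    tier2: list[str] = []
    for cid in tier1:
        risks = _screen(cid, TIER2_CATEGORIES)
        verdicts[cid].category_risks.update(risks)
        if any(_risk_fails(r, config.aux_fail_rule) for r in risks.values()):
            verdicts[cid].tier_reached = "failed_t2"
        else:
            tier2.append(cid)

    # Tier 3: hepatotoxicity / immunotoxicity
    tier3: list[str] = []
    for cid in tier2:
        risks = _screen(cid, TIER3_CATEGORIES)
        verdicts[cid].category_risks.update(risks)
        if any(_risk_fails(r, config.aux_fail_rule) for r in risks.values()):
            verdicts[cid].tier_reached = "failed_t3"
        else:
            verdicts[cid].tier_reached = "passed"
            tier3.append(cid)

    return FunnelReport(
        input_count=len(library),
        tier1_survivors=tier1,
        tier2_survivors=tier2,
        tier3_survivors=tier3,
        verdicts=verdicts,
        config=config,
        uncomputable=uncomputable,
    )


def evaluate_reference_list(
    verdicts: Iterable[CompoundVerdict], known_toxic_ids: Sequence[str]
) -> tuple[float, list[dict]]:
    """Combined-verdict success rate on a list of known-toxic compounds.

    success rate = 100 * (# predicted toxic by cardiotoxicity models OR
    flagged by any auxiliary category) / (# known toxic), rounded to one
    decimal. The per-compound table marks aux-only detections with a star.
    """
    vmap = {v.compound_id: v for v in verdicts}
    missing = [cid for cid in known_toxic_ids if cid not in vmap]
    if missing:
        raise ValueError(f"no verdict for known toxic compounds: {missing}")
    table = []
    hits = 0
    for cid in known_toxic_ids:
        v = vmap[cid]
        aux = v.aux_flagged or any(r != "none" for r in v.category_risks.values())
        row = {
            "compound_id": cid,
            "predicted_cardiotoxicity": "Yes" if v.cardiotox_positive else "No",
            "aux_flag": "*" if aux else "",
            "overall_toxic": v.overall_toxic,
        }
        if v.overall_toxic:
            hits += 1
        table.append(row)
    rate = round(100.0 * hits / len(known_toxic_ids), 1)
    return rate, table


# ---------------------------------------------------------------------------
# Alert list / verdict table I/O

def load_alert_lists(source: str | os.PathLike) -> list[AlertList]:
    """Load alert lists from YAML.

    Layout: ``{category: [{name, smarts, level}, ...], ...}``.
    """
    if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(str(source))
    lists = []
    for category, items in raw.items():
        alerts = [
            Alert(SubstructurePattern(it["name"], it["smarts"]), it["level"])
            for it in items
        ]
        for a in alerts:
            a.pattern.query()  # fail fast on bad SMARTS
        lists.append(AlertList(category, alerts))
    return lists


def default_alert_lists() -> list[AlertList]:
    """The bundled demonstrative toxicophore alert lists."""
    from importlib.resources import files

    return load_alert_lists(str(files("toxfunnel.data").joinpath("alert_lists.yaml")))


def load_verdict_table(source: str | os.PathLike) -> dict[tuple[str, str], str]:
    """CSV ``compound_id,category,risk`` -> {(id, category): risk}."""
    text = open(source).read() if os.path.exists(str(source)) else str(source)
    reader = csv.DictReader(io.StringIO(text))
    out: dict[tuple[str, str], str] = {}
    for row in reader:
        risk = row["risk"].strip().lower()
        if risk not in RISK_LEVELS:
            raise ValueError(f"unknown risk level {risk!r} for {row['compound_id']}")
        out[(row["compound_id"].strip(), row["category"].strip())] = risk
    return out
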