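"""Compound ingest and the molecular descriptor panel.

The screening models operate on a small panel of 2D descriptors computed
from SMILES: Crippen logP, a fragment-based drug-likeness score, four
substructure counts (amines, alkyl-amines, aromatic nitrogens, basic
nitrogens) and, when a binding affinity is available, ligand efficiency.
Counts are defined by SMARTS patterns that ship as editable configuration
so they can be tuned against other descriptor software empirically.
"""

from __future__ import annotations

import csv
import io
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen

__all__ = [
    "CompoundRecord",
    "SubstructurePattern",
    "DescriptorVector",
    "DescriptorRegistry",
    "Rejection",
    "parse_compound_library",
    "count_substructure",
    "compute_logp",
    "compute_drug_likeness",
    "compute_ligand_efficiency",
    "compute_descriptor_panel",
    "default_registry",
    "DEFAULT_PATTERNS",
    "DESCRIPTOR_ORDER",
]

# Canonical column order of the descriptor matrix.
DESCRIPTOR_ORDER = (
    "logp",
    "drug_likeness",
    "amines",
    "ligand_efficiency",
    "alkyl_amines",
    "aromatic_nitrogens",
    "basic_nitrogens",
)


@dataclass
class CompoundRecord:
    """One molecule flowing through the pipeline.

    ``labels`` maps an endpoint name (e.g. ``arrhythmia``) to a binary
    toxicity label (1 = toxic).
    """

    id: str
    smiles: str
    name: str | None = None
    labels: dict[str, int] | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"record {self.id!r}: SMILES does not parse: {self.smiles!r}")
        return m


@dataclass(frozen=True)
class SubstructurePattern:
    """A named SMARTS query counted as distinct atom-set matches."""

    name: str
    smarts: str

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"pattern {self.name!r}: SMARTS does not compile: {self.smarts!r}")
        return q


# Pattern semantics (see docs/methods.md for the rationale):
#   amines            sp3 N bonded only to C/H; amides, anilines, N-hetero N excluded
#   alkyl_amines      amines whose carbon substituents are all sp3
#   aromatic_nitrogens any aromatic N (pyridine- or pyrrole-type)
#   basic_nitrogens   amine N plus pyridine-type aromatic N (nH pyrrole excluded)
DEFAULT_PATTERNS: dict[str, SubstructurePattern] = {
    "amines": SubstructurePattern("amines", "[NX3;!$(N~[!#6;!#1]);!$(NC=[O,S,N]);!$(Nc)]"),
    "alkyl_amines": SubstructurePattern("alkyl_amines", "[NX3;!$(N~[!#6;!#1]);!$(N[#6;!X4])]"),
    "aromatic_nitrogens": SubstructurePattern("aromatic_nitrogens", "[n]"),
    "basic_nitrogens": SubstructurePattern(
        "basic_nitrogens",
        "[$([NX3;!$(N~[!#6;!#1]);!$(NC=[O,S,N]);!$(Nc)]),$([nX2H0])]",
    ),
}

# Small demonstrative fragment-score table for the drug-likeness score.
# Positive scores mark fragments over-represented in approved drugs,
# negative ones fragments typical of reactive / non-drug chemistry.
# Absolute values are NOT comparable to other software's proprietary tables.
DEFAULT_DRUGLIKENESS_FRAGMENTS: dict[str, float] = {
    "[OX2H]": 0.6,                      # hydroxyl
    "[NX3;!$(N~[!#6;!#1])]": 0.8,       # aliphatic amine
    "C(=O)[NX3]": 0.9,                  # amide
    "C(=O)[OX2H1]": 0.4,                # carboxylic acid
    "c1ccccc1": 0.5,                    # benzene ring
    "[#6][OX2][#6]": 0.3,               # ether
    "[nX2H0]": 0.7,                     # pyridine-type N
    "[F,Cl,Br]": 0.2,                   # halogen
    "[SX2]": -0.2,                      # thioether
    "[NX3](=O)=O": -1.2,                # nitro (charged form normalised below)
    "[N+](=O)[O-]": -1.2,               # nitro
    "C1OC1": -1.0,                      # epoxide
    "[CX3H1]=O": -0.8,                  # aldehyde
    "N=[N+]=[N-]": -1.5,                # azide
    "[#6]S(=O)(=O)[#6,N]": 0.3,         # sulfone/sulfonamide
}


@dataclass
class DescriptorVector:
    """The descriptor panel for one compound.

    ``ligand_efficiency`` is ``None`` (missing, never zero) when no binding
    affinity was supplied for the compound.
    """

    compound_id: str
    logp: float
    drug_likeness: float
    amines: int
    ligand_efficiency: float | None
    alkyl_amines: int
    aromatic_nitrogens: int
    basic_nitrogens: int
    extras: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | None]:
        row: dict[str, float | None] = {
            "logp": self.logp,
            "drug_likeness": self.drug_likeness,
            "amines": self.amines,
            "ligand_efficiency": self.ligand_efficiency,
            "alkyl_amines": self.alkyl_amines,
            "aromatic_nitrogens": self.aromatic_nitrogens,
            "basic_nitrogens": self.basic_nitrogens,
        }
        row.update(self.extras)
        return row


class DescriptorRegistry:
    """Ordered name -> computation mapping fixing descriptor matrix columns.

    Each handle is called as ``handle(mol, record, affinity)`` where
    ``affinity`` is a binding energy in kcal/mol or ``None``.
    """

    def __init__(self, version: str = "1"):
        self.version = version
        self._handles: dict[str, Callable] = {}

    def register(self, name: str, handle: Callable) -> None:
        if name in self._handles:
            raise ValueError(f"descriptor {name!r} already registered")
        self._handles[name] = handle

    @property
    def names(self) -> list[str]:
        return list(self._handles)

    def compute(self, record: CompoundRecord, affinity: float | None = None) -> dict[str, float | None]:
        mol = record.mol()
        return {name: h(mol, record, affinity) for name, h in self._handles.items()}


@dataclass(frozen=True)
class Rejection:
    line: int
    raw: str
    reason: str


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _finalize(rows: list[tuple[int, str, str, str | None, dict | None]],
              ) -> tuple[list[CompoundRecord], list[Rejection]]:
    """Canonicalize, reject invalid SMILES, enforce unique ids."""
    records: list[CompoundRecord] = []
    rejections: list[Rejection] = []
    seen: dict[str, int] = {}
    for line, cid, smiles, name, labels in rows:
        if not cid:
            rejections.append(Rejection(line, smiles, "empty compound id"))
            continue
        canon = _canonical(smiles)
        if canon is None:
            rejections.append(Rejection(line, smiles, f"invalid SMILES: {smiles!r}"))
            continue
        if cid in seen:
            raise ValueError(
                f"duplicate compound id {cid!r} (lines {seen[cid]} and {line})"
            )
        seen[cid] = line
        records.append(CompoundRecord(id=cid, smiles=canon, name=name, labels=labels))
    return records, rejections


def parse_compound_library(
    source: str | os.PathLike, fmt: str
) -> tuple[list[CompoundRecord], list[Rejection]]:
    """Read a compound library from ``.smi``, SDF or CSV.

    ``source`` may be a path or, for ``smi``/``csv``, raw text. Records with
    unparseable SMILES are listed in the rejection report with their line
    number; input order is preserved. Duplicate ids raise ``ValueError``.
    """
    fmt = fmt.lower()
    if fmt not in {"smi", "sdf", "csv"}:
        raise ValueError(f"unknown library format {fmt!r}; expected smi, sdf or csv")

    is_path = isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    )
    if fmt == "sdf" and not is_path:
        raise IOError(f"SDF source must be a readable file path, got {source!r}")
    if is_path and not os.path.exists(source):
        raise IOError(f"cannot read compound library: {source}")

    rows: list[tuple[int, str, str, str | None, dict | None]] = []
    if fmt == "smi":
        text = open(source).read() if is_path else str(source)
        for i, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            rows.append((i, cid, smiles, None, None))
    elif fmt == "csv":
        text = open(source).read() if is_path else str(source)
        reader = csv.DictReader(io.StringIO(text))
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise ValueError("CSV library requires columns 'id' and 'smiles'")
        label_cols = [c for c in reader.fieldnames if c not in {"id", "smiles", "name"}]
        for i, rec in enumerate(reader, start=2):  # header is line 1
            labels = None
            if label_cols:
                labels = {}
                for c in label_cols:
                    v = rec.get(c, "")
                    if v not in ("", None):
                        labels[c] = int(float(v))
            rows.append((i, rec["id"].strip(), rec["smiles"].strip(),
                         (rec.get("name") or None), labels or None))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(source), sanitize=True)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                rows.append((i, f"sdf{i}", "<unparseable SDF record>", None, None))
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
            rows.append((i, cid, Chem.MolToSmiles(mol), None, None))

    records, rejections = _finalize(rows)
    if not records:
        warnings.warn("compound library contains zero valid records", stacklevel=2)
    return records, rejections


def count_substructure(smiles: str, pattern: SubstructurePattern) -> int:
    """Count distinct atom-set matches of ``pattern`` in ``smiles``.

    Symmetric duplicates (the same atom set matched in a different order)
    are collapsed, so counting is deterministic and representation-invariant.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    matches = mol.GetSubstructMatches(pattern.query(), uniquify=True)
    return len({frozenset(m) for m in matches})


def compute_logp(smiles: str) -> float:
    """Crippen atom-contribution logP (octanol/water partition estimate).

    Atom-additive: each atom is typed against the published contribution
    table and the contributions are summed. The molecule is renumbered to
    canonical atom order first so any SMILES of the same molecule gives a
    bit-identical value (summation order matters at the 1e-15 level).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return float(Crippen.MolLogP(mol))


def compute_drug_likeness(
    smiles: str, fragment_scores: Mapping[str, float] | None = None
) -> float:
    """Fragment-incidence drug-likeness score.

    score = (sum of scores of matched fragments) / sqrt(#matched fragments);
    0.0 when no fragment matches. A fragment counts once no matter how often
    it occurs. The bundled fragment table is demonstrative — swap in a larger
    calibrated table for production scoring.
    """
    if fragment_scores is None:
        fragment_scores = DEFAULT_DRUGLIKENESS_FRAGMENTS
    if not fragment_scores:
        raise ValueError("fragment_scores must be non-empty")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    total = 0.0
    matched = 0
    for smarts, score in fragment_scores.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"fragment SMARTS does not compile: {smarts!r}")
        if mol.HasSubstructMatch(q):
            total += score
            matched += 1
    if matched == 0:
        return 0.0
    return total / math.sqrt(matched)


def compute_ligand_efficiency(binding_energy_kcal_per_mol: float, heavy_atom_count: int) -> float:
    """LE = −ΔG / heavy atoms, in kcal/mol per heavy atom."""
    if heavy_atom_count < 1:
        raise ValueError(f"heavy_atom_count must be >= 1, got {heavy_atom_count}")
    return -binding_energy_kcal_per_mol / heavy_atom_count


def default_registry(
    patterns: Mapping[str, SubstructurePattern] | None = None,
    fragment_scores: Mapping[str, float] | None = None,
) -> DescriptorRegistry:
    """The seven-descriptor panel in canonical column order."""
    patterns = dict(DEFAULT_PATTERNS) if patterns is None else dict(patterns)
    reg = DescriptorRegistry(version="1")
    reg.register("logp", lambda mol, rec, aff: compute_logp(rec.smiles))
    reg.register(
        "drug_likeness",
        lambda mol, rec, aff: compute_drug_likeness(rec.smiles, fragment_scores),
    )
    reg.register(
        "amines", lambda mol, rec, aff: count_substructure(rec.smiles, patterns["amines"])
    )
    reg.register(
        "ligand_efficiency",
        lambda mol, rec, aff: (
            None if aff is None else compute_ligand_efficiency(aff, mol.GetNumHeavyAtoms())
        ),
    )
    reg.register(
        "alkyl_amines",
        lambda mol, rec, aff: count_substructure(rec.smiles, patterns["alkyl_amines"]),
    )
    reg.register(
        "aromatic_nitrogens",
        lambda mol, rec, aff: count_substructure(rec.smiles, patterns["aromatic_nitrogens"]),
    )
    reg.register(
        "basic_nitrogens",
        lambda mol, rec, aff: count_substructure(rec.smiles, patterns["basic_nitrogens"]),
    )
    return reg


def compute_descriptor_panel(
    records: Sequence[CompoundRecord],
    registry: DescriptorRegistry | None = None,
    affinities: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Descriptor matrix: one row per record, columns in registry order.

    ``affinities`` maps compound id -> binding energy (kcal/mol) and feeds
    the ligand-efficiency descriptor; compounds without an affinity get a
    missing (NaN) LE cell, never an imputed zero. Unknown affinity ids
    trigger a warning.
    """
    registry = registry or default_registry()
    affinities = dict(affinities or {})
    known = {r.id for r in records}
    unknown = sorted(set(affinities) - known)
    if unknown:
        warnings.warn(f"affinities given for unknown compound ids: {unknown}", stacklevel=2)
    rows = []
    index = []
    for rec in records:
        vals = registry.compute(rec, affinities.get(rec.id))
        rows.append(vals)
        index.append(rec.id)
    df = pd.DataFrame(rows, index=pd.Index(index, name="compound_id"),
                      columns=registry.names, dtype=float)
    return df


def descriptor_vector(
    record: CompoundRecord,
    registry: DescriptorRegistry | None = None,
    affinity: float | None = None,
) -> DescriptorVector:
    """Compute the panel for a single compound as a typed vector."""
    registry = registry or default_registry()
    vals = registry.compute(record, affinity)
    core = {k: vals[k] for k in DESCRIPTOR_ORDER if k in vals}
    extras = {k: v for k, v in vals.items() if k not in DESCRIPTOR_ORDER}
    return DescriptorVector(
        compound_id=record.id,
        logp=core["logp"],
        drug_likeness=core["drug_likeness"],
        amines=int(core["amines"]),
        ligand_efficiency=core["ligand_efficiency"],
        alkyl_amines=int(core["alkyl_amines"]),
        aromatic_nitrogens=int(core["aromatic_nitrogens"]),
        basic_nitrogens=int(core["basic_nitrogens"]),
        extras=extras,
    )
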