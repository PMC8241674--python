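"""Synthetic labeled compound data with known statistical structure.

The classifier benchmark and the feature-selection rule need labeled
descriptor tables whose ground truth is known exactly. This module
generates them: descriptors are drawn from per-descriptor distributions
(normal for continuous descriptors, Poisson for substructure counts),
pairwise collinearity can be injected to a requested Pearson r via a
shared latent Gaussian factor, and binary endpoint labels are drawn from
a logistic model on the descriptors with user-chosen coefficients.

Labels are generated on descriptors, not structures, because the endpoint
models operate purely on the descriptor table. A separate hand-curated
100-molecule SMILES fixture list (with hand-counted substructure ground
truth for 20 of them) exercises the structure-handling code paths.

All randomness flows from a single spec-level seed through independent
child streams (one for the descriptor block, one per endpoint), so
adding an endpoint never perturbs the descriptor draw.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import CompoundRecord

__all__ = [
    "DescriptorDist",
    "SimulationSpec",
    "SyntheticLibrary",
    "generate_labeled_library",
    "fixture_molecules",
    "fixture_ground_truth",
    "strong_logp_spec",
    "null_spec",
    "DEFAULT_DISTRIBUTIONS",
]


@dataclass(frozen=True)
class DescriptorDist:
    """Marginal distribution of one descriptor.

    kind "normal" uses (loc, scale); kind "poisson" uses loc as the rate.
    """

    kind: str
    loc: float
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("normal", "poisson"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal latents to the marginal (quantile coupling)."""
        if self.kind == "normal":
            return self.loc + self.scale * z
        # Poisson via the Gaussian copula: preserves the latent ordering, so
        # injected latent correlation survives (slightly attenuated).
        return stats.poisson.ppf(stats.norm.cdf(z), mu=self.loc)


# Rough emulation of a small-molecule descriptor table: logP of drug-like
# chemistry, a centred drug-likeness score, LE around typical fragment
# efficiencies, low substructure counts.
DEFAULT_DISTRIBUTIONS: dict[str, DescriptorDist] = {
    "logp": DescriptorDist("normal", 2.5, 1.5),
    "drug_likeness": DescriptorDist("normal", 0.0, 1.0),
    "amines": DescriptorDist("poisson", 1.0),
    "ligand_efficiency": DescriptorDist("normal", 0.3, 0.1),
    "alkyl_amines": DescriptorDist("poisson", 0.7),
    "aromatic_nitrogens": DescriptorDist("poisson", 1.2),
    "basic_nitrogens": DescriptorDist("poisson", 1.0),
}


@dataclass
class SimulationSpec:
    n_compounds: int = 500
    seed: int = 0
    beta0: float = 0.0
    betas: dict[str, float] = field(default_factory=dict)
    distributions: dict[str, DescriptorDist] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS)
    )
    collinearity: list[tuple[str, str, float]] = field(default_factory=list)
    endpoints: tuple[str, ...] = ("cardiotoxicity",)

    def validate(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("n_compounds must be >= 2")
        unknown = set(self.betas) - set(self.distributions)
        if unknown:
            raise ValueError(f"betas refer to unknown descriptors: {sorted(unknown)}")
        for a, b, r in self.collinearity:
            if abs(r) > 1:
                raise ValueError(f"requested correlation |r| > 1 for ({a}, {b}): {r}")
            for d in (a, b):
                if d not in self.distributions:
                    raise ValueError(f"collinearity refers to unknown descriptor {d!r}")


@dataclass
class SyntheticLibrary:
    X: pd.DataFrame
    labels: dict[str, np.ndarray]
    true_beta0: float
    true_betas: dict[str, float]
    spec: SimulationSpec

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_labeled_library(spec: SimulationSpec) -> SyntheticLibrary:
    """Draw a descriptor matrix and logistic endpoint labels per ``spec``.

    Collinearity injections replace descriptor b's latent with
    ``r * z_a + sqrt(1 - r^2) * z_b`` before marginal mapping, achieving
    the requested Pearson r (to within sampling noise; exactly preserved
    for normal marginals, slightly attenuated through the Poisson map).
    Bit-reproducible for a fixed spec + seed.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    desc_ss, *label_ss = root.spawn(1 + len(spec.endpoints))
    rng = np.random.default_rng(desc_ss)

    names = list(spec.distributions)
    n = spec.n_compounds
    Z = {d: rng.standard_normal(n) for d in names}
    for a, b, r in spec.collinearity:
        Z[b] = r * Z[a] + np.sqrt(1.0 - r * r) * Z[b]
    X = pd.DataFrame(
        {d: spec.distributions[d].from_latent(Z[d]) for d in names},
        index=pd.Index([f"synth{i:05d}" for i in range(n)], name="compound_id"),
    )

    logit = np.full(n, spec.beta0, dtype=float)
    for d, beta in spec.betas.items():
        logit += beta * X[d].to_numpy()
    p = _sigmoid(logit)

    labels = {}
    for ep, ss in zip(spec.endpoints, label_ss):
        ep_rng = np.random.default_rng(ss)
        labels[ep] = (ep_rng.random(n) < p).astype(int)
    return SyntheticLibrary(
        X=X, labels=labels, true_beta0=spec.beta0, true_betas=dict(spec.betas), spec=spec
    )


def strong_logp_spec(
    n: int = 300, seed: int = 5, beta_logp: float = 2.0,
    endpoints: tuple[str, ...] = ("cardiotoxicity",),
) -> SimulationSpec:
    """Study condition with a strong lipophilicity-driven toxicity signal.

    The intercept is set to -beta_logp * E[logP] so prevalence stays near
    one half while the effect is strong enough for reliable recovery.
    """
    mean_logp = DEFAULT_DISTRIBUTIONS["logp"].loc
    return SimulationSpec(
        n_compounds=n,
        seed=seed,
        beta0=-beta_logp * mean_logp,
        betas={"logp": beta_logp},
        endpoints=endpoints,
    )


def null_spec(
    n: int = 100, seed: int = 7, endpoints: tuple[str, ...] = ("cardiotoxicity",)
) -> SimulationSpec:
    """Null condition: labels independent of all descriptors (prevalence 1/2)."""
    return SimulationSpec(n_compounds=n, seed=seed, beta0=0.0, betas={}, endpoints=endpoints)


def fixture_molecules() -> list[CompoundRecord]:
    """The bundled hand-curated 100-molecule SMILES fixture list."""
    text = files("toxfunnel.data").joinpath("fixture_molecules.smi").read_text()
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, cid = line.split(None, 1)
        records.append(CompoundRecord(id=cid.strip(), smiles=smiles))
    return records


def fixture_ground_truth() -> dict[str, dict[str, int]]:
    """Hand-counted substructure ground truth for 20 fixture molecules.

    Maps compound id -> {amines, alkyl_amines, aromatic_nitrogens,
    basic_nitrogens}. Counted manually from the structures at curation
    time; used to pin the SMARTS descriptor definitions.
    """
    text = files("toxfunnel.data").joinpath("fixture_ground_truth.csv").read_text()
    out: dict[str, dict[str, int]] = {}
    for row in csv.DictReader(text.splitlines()):
        cid = row.pop("id")
        out[cid] = {k: int(v) for k, v in row.items()}
    return out
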