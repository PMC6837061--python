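"""Synthetic benchmarks with known ground truth.

Two kinds of tasks:

* small drug-like molecule libraries built from hard-coded scaffold
  templates with enumerated substituents, labelled by a documented closed
  form over counted substructures plus input-dependent Gaussian noise —
  the generative model y_i = F(x_i) + eps_i with known F and known
  heteroscedastic sigma(x), so aleatoric-recovery and bias experiments have
  an exact reference;
* conjugate linear-Gaussian regression whose posterior is analytic, the
  exact oracle for particle-based posterior sampling.

Default property: y = 0.3 * heavy_atoms + 1.5 * aromatic_rings
- 0.9 * heteroatoms; default noise: sigma = 0.1 + 0.15 * heteroatoms.
The weights are arbitrary but fixed: the property is learnable by a small
message-passing network yet depends on several distinct graph statistics,
and the noise grows with heteroatom count so that different regions of the
library are intrinsically more variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .molgraph import MolecularGraph, parse_smiles

# Scaffold-cored templates: {0}/{1} are substituent slots. Substituents are
# written as SMILES prefixes, so "{0}c1ccccc1" with "CC" gives ethylbenzene.
SCAFFOLD_TEMPLATES: dict[str, list[str]] = {
    "benzene": ["{0}c1ccccc1", "{0}c1ccc({1})cc1"],
    "pyridine": ["{0}c1ccncc1", "{0}c1cc({1})cnc1"],
    "cyclohexane": ["{0}C1CCCCC1", "{0}C1CCC({1})CC1"],
    "furan": ["{0}c1ccco1", "{0}c1cc({1})co1"],
    "thiophene": ["{0}c1cccs1", "{0}c1cc({1})cs1"],
    "chain": ["{0}CCC{1}", "{0}CCCCC{1}"],
    # larger fused / linked ring systems: a structurally distinct chemotype
    # for out-of-domain probes (cf. steroids vs small bicyclics)
    "naphthalene": ["{0}c1ccc2ccccc2c1", "{0}c1ccc2cc({1})ccc2c1"],
    "decalin": ["{0}C1CCC2CCCCC2C1", "{0}C1CCC2CC({1})CCC2C1"],
    "biphenyl": ["{0}c1ccc(-c2ccccc2)cc1", "{0}c1ccc(-c2ccc({1})cc2)cc1"],
}

SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CC(C)", "N", "O", "OC", "NC", "F", "Cl",
    "C(=O)O", "C(=O)N", "C#N", "OCC", "CCO", "CN",
)

DEFAULT_TRUTH_WEIGHTS = {"heavy_atoms": 0.3, "aromatic_rings": 1.5, "heteroatoms": -0.9}
DEFAULT_NOISE = {"a": 0.1, "b": 0.15}


def graph_statistics(smiles: str) -> dict[str, float]:
    """Counted substructures the synthetic property is built from."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    heavy = mol.GetNumHeavyAtoms()
    arom = rdMolDescriptors.CalcNumAromaticRings(mol)
    hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    return {
        "heavy_atoms": float(heavy),
        "aromatic_rings": float(arom),
        "heteroatoms": float(hetero),
    }


def default_truth_fn(smiles: str) -> float:
    """Deterministic property: weighted counts of graph statistics."""
    stats = graph_statistics(smiles)
    return sum(w * stats[k] for k, w in DEFAULT_TRUTH_WEIGHTS.items())


def default_noise_fn(smiles: str) -> float:
    """Aleatoric standard deviation sigma = a + b * heteroatom count (> 0)."""
    stats = graph_statistics(smiles)
    return DEFAULT_NOISE["a"] + DEFAULT_NOISE["b"] * stats["heteroatoms"]


# Scaffold-specific property offsets (SMARTS core, weight). Real bioactivity
# carries chemotype-specific contributions a model cannot extrapolate from
# other chemotypes; without them a single linear counts->property map is
# learnable from any chemotype and leaves nothing for targeted acquisition
# or domain-shift probes to discover.
SCAFFOLD_SHIFTS: tuple[tuple[str, float], ...] = (
    ("c1ccc2ccccc2c1", 2.2),      # fused aromatic (naphthalene-like)
    ("C1CCC2CCCCC2C1", -1.8),     # fused aliphatic (decalin-like)
    ("c1ccc(-c2ccccc2)cc1", 1.5), # linked biaryl
    ("c1ccncc1", -1.2),           # pyridine core
    ("c1ccoc1", 1.0),             # furan core
    ("c1ccsc1", -1.4),            # thiophene core
)


def scaffold_shift_truth_fn(smiles: str) -> float:
    """Counts-based property plus chemotype-specific scaffold offsets."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    value = default_truth_fn(smiles)
    for smarts, weight in SCAFFOLD_SHIFTS:
        core = Chem.MolFromSmarts(smarts)
        if mol.HasSubstructMatch(core):
            value += weight
    return value


@dataclass
class SyntheticTask:
    """A generated molecule set with its labelling functions."""

    smiles: list[str]
    families: list[str]
    truth_fn: Callable[[str], float]
    noise_fn: Callable[[str], float]
    seed: int


def _enumerate_family(family: str) -> list[str]:
    """All valid template x substituent combinations for one scaffold family.

    Chemically impossible combinations (valence violations) are silently
    skipped; RDKit's error log is muted for the duration of the probe.
    """
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    try:
        out = []
        seen = set()
        for template in SCAFFOLD_TEMPLATES[family]:
            n_slots = template.count("{")
            if n_slots == 1:
                combos = [(s,) for s in SUBSTITUENTS]
            else:
                combos = [(a, b) for a in SUBSTITUENTS for b in SUBSTITUENTS]
            for combo in combos:
                smi = template.format(*combo)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canon = Chem.MolToSmiles(mol)
                if canon in seen:
                    continue
                seen.add(canon)
                out.append(smi)
        return out
    finally:
        RDLogger.EnableLog("rdApp.error")


def generate_molecule_library(
    n: int,
    scaffold_families: tuple[str, ...] = ("benzene", "pyridine", "cyclohexane"),
    seed: int = 0,
    family_weights: tuple[float, ...] | None = None,
) -> tuple[list[str], list[str]]:
    """Draw n valid SMILES from the enumerated scaffold-template space.

    Molecules are sampled without replacement within each family where
    possible, deterministically under the seed, and every entry parses.
    ``family_weights`` sets the library composition (largest-remainder
    apportionment); the default is uniform. Real chemical datasets cluster
    around a few dominant chemotypes, so skewed weights emulate that bias.
    Returns the SMILES and the per-molecule family tags.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = [f for f in scaffold_families if f not in SCAFFOLD_TEMPLATES]
    if unknown:
        raise ValueError(f"unknown scaffold families: {unknown}")
    if family_weights is None:
        weights = np.full(len(scaffold_families), 1.0 / len(scaffold_families))
    else:
        weights = np.asarray(family_weights, dtype=float)
        if len(weights) != len(scaffold_families) or (weights < 0).any():
            raise ValueError("family_weights must be non-negative, one per family")
        weights = weights / weights.sum()
    # largest-remainder apportionment of n over families
    quotas = weights * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    smiles, families = [], []
    for fam, count in zip(scaffold_families, counts):
        cand = _enumerate_family(fam)
        pool = [cand[i] for i in rng.permutation(len(cand))]
        for i in range(count):
            smiles.append(pool[i % len(pool)])
            families.append(fam)
    # deterministic interleave so family blocks do not align with index order
    perm = rng.permutation(len(smiles))
    return [smiles[i] for i in perm], [families[i] for i in perm]


def label_library(
    smiles: list[str],
    truth_fn: Callable[[str], float] = default_truth_fn,
    noise_fn: Callable[[str], float] = default_noise_fn,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy labels y = truth(s) + Normal(0, noise(s)^2), plus the truth table.

    Columns: smiles, y (observed), y_true (noiseless), sigma_true.
    """
    rng = np.random.default_rng(seed)
    y_true = np.array([truth_fn(s) for s in smiles])
    sigma = np.array([noise_fn(s) for s in smiles])
    y = y_true + rng.normal(0.0, 1.0, size=len(smiles)) * sigma
    return pd.DataFrame(
        {"smiles": smiles, "y": y, "y_true": y_true, "sigma_true": sigma}
    )


def make_labelled_dataset(
    n: int,
    scaffold_families: tuple[str, ...] = ("benzene", "pyridine", "cyclohexane"),
    seed: int = 0,
) -> tuple[list[MolecularGraph], pd.DataFrame]:
    """Convenience: generate, label, and parse a library in one call."""
    smiles, families = generate_molecule_library(n, scaffold_families, seed)
    table = label_library(smiles, seed=seed + 1)
    table["family"] = families
    graphs = [parse_smiles(s) for s in smiles]
    return graphs, table


# ---------------------------------------------------------------------------
# conjugate linear-Gaussian oracle


@dataclass
class ConjugateTask:
    """Linear-Gaussian regression with its analytic posterior.

    y = X w + eps, eps ~ N(0, noise_scale^2), w ~ N(0, prior_scale^2 I):
    posterior covariance (X'X / s_n^2 + I / s_p^2)^{-1}, mean Sigma X'y / s_n^2.
    """

    X: np.ndarray
    y: np.ndarray
    w_true: np.ndarray
    prior_scale: float
    noise_scale: float
    post_mean: np.ndarray
    post_cov: np.ndarray

    def analytic_posterior(self) -> tuple[np.ndarray, np.ndarray]:
        """Recompute the conjugate closed form from the stored data."""
        dim = self.X.shape[1]
        prec = self.X.T @ self.X / self.noise_scale**2 + np.eye(dim) / self.prior_scale**2
        cov = np.linalg.inv(prec)
        mean = cov @ (self.X.T @ self.y) / self.noise_scale**2
        return mean, cov

    def validate(self) -> None:
        mean, cov = self.analytic_posterior()
        if not (np.allclose(mean, self.post_mean) and np.allclose(cov, self.post_cov)):
            raise ValueError("stored posterior does not match the conjugate closed form")


def make_conjugate_task(
    dim: int = 3,
    n: int = 50,
    prior_scale: float = 1.0,
    noise_scale: float = 0.5,
    seed: int = 0,
    coef_magnitude_range: tuple[float, float] | None = None,
) -> ConjugateTask:
    """Random design + targets drawn from the generative model; posterior stored.

    ``coef_magnitude_range`` draws |w_true| uniformly in the given interval
    (random signs) instead of from the prior; useful when per-coordinate
    relative errors are measured, which are ill-defined near zero.
    """
    if dim > 10:
        raise ValueError("dim must be <= 10")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    if coef_magnitude_range is None:
        w_true = rng.normal(0.0, prior_scale, size=dim)
    else:
        lo, hi = coef_magnitude_range
        w_true = rng.uniform(lo, hi, size=dim) * rng.choice([-1.0, 1.0], size=dim)
    y = X @ w_true + rng.normal(0.0, noise_scale, size=n)
    prec = X.T @ X / noise_scale**2 + np.eye(dim) / prior_scale**2
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ y) / noise_scale**2
    return ConjugateTask(
        X=X,
        y=y,
        w_true=w_true,
        prior_scale=prior_scale,
        noise_scale=noise_scale,
        post_mean=mean,
        post_cov=cov,
    )
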