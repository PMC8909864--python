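"""Seeded synthetic data: toy SMILES corpora, motif-enriched corpora and
separable fingerprint sets.

These generators stand in for the large public collections a production run
would use (a drug-like training corpus for the general generator, a set of
target ligands for transfer learning, an activity table for the
discriminator), so every pipeline stage is buildable and testable offline.

Toy molecules are assembled atom-by-atom under explicit valence caps
(C:4, N:3, O:2) with single bonds, an optional branch structure, and an
optional single ring closure, then exported as RDKit canonical SMILES —
valid by construction, no rejection sampling.  Motif-enriched corpora graft
random substituents onto a motif scaffold (written in Kekulé form so the
character set stays in upper-case SMILES).  The fingerprint generator emits
two fixed 166-bit class templates with independent per-bit noise, giving a
dataset whose difficulty is controlled by a single flip rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger

from .discriminator import LabeledFingerprintSet

RDLogger.DisableLog("rdApp.*")

_VALENCE = {"C": 4, "N": 3, "O": 2}


class FixtureError(ValueError):
    pass


#: heavy-atom composition of the toy grammar; roughly the element balance of
#: drug-like corpora, where carbon dominates
_ELEMENT_WEIGHTS = {"C": 0.75, "N": 0.15, "O": 0.10}


@dataclass(frozen=True)
class ToyCorpusSpec:
    n: int = 2000
    seed: int = 0
    max_heavy_atoms: int = 12
    alphabet: tuple[str, ...] = ("C", "N", "O")
    ring_fraction: float = 0.35
    branch_fraction: float = 0.25
    double_bond_fraction: float = 0.15
    # geometric size distribution: each additional heavy atom kept with this
    # probability, so sizes are right-skewed like real corpora
    growth_prob: float = 0.82

    def __post_init__(self) -> None:
        if self.n < 1:
            raise FixtureError("n must be >= 1")
        for p in (self.ring_fraction, self.branch_fraction, self.double_bond_fraction):
            if not (0.0 <= p <= 1.0):
                raise FixtureError("fractions must be in [0, 1]")
        if not (0.0 < self.growth_prob < 1.0):
            raise FixtureError("growth_prob must be in (0, 1)")
        if self.max_heavy_atoms < 3:
            raise FixtureError("max_heavy_atoms must be >= 3")
        for el in self.alphabet:
            if el not in _VALENCE:
                raise FixtureError(f"unsupported element {el!r}")

    @property
    def element_probs(self) -> np.ndarray:
        w = np.array([_ELEMENT_WEIGHTS[e] for e in self.alphabet])
        return w / w.sum()


@dataclass(frozen=True)
class MotifSpec:
    motif_smiles: str = "C1=CC=CO1"  # furan, Kekulé spelling
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if Chem.MolFromSmiles(self.motif_smiles) is None:
            raise FixtureError(f"motif does not parse: {self.motif_smiles!r}")
        if not (0.0 < self.enrichment <= 1.0):
            raise FixtureError("enrichment must be in (0, 1]")


def _free_valence(mol: Chem.RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    used = sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds())
    return _VALENCE[atom.GetSymbol()] - used


def _random_molecule(rng: np.random.Generator, spec: ToyCorpusSpec) -> str:
    n_atoms = 3
    while n_atoms < spec.max_heavy_atoms and rng.random() < spec.growth_prob:
        n_atoms += 1
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom("C"))
    last = 0
    for _ in range(n_atoms - 1):
        el = str(rng.choice(spec.alphabet, p=spec.element_probs))
        # chain growth by default; occasional branching from any open atom
        open_atoms = [a.GetIdx() for a in mol.GetAtoms() if _free_valence(mol, a.GetIdx()) > 0]
        if not open_atoms:
            break
        if last in open_atoms and rng.random() >= spec.branch_fraction:
            parent = last
        else:
            parent = int(open_atoms[rng.integers(len(open_atoms))])
        new = mol.AddAtom(Chem.Atom(el))
        double = (
            rng.random() < spec.double_bond_fraction
            and _free_valence(mol, parent) >= 2
            and _VALENCE[el] >= 2
        )
        mol.AddBond(parent, new, Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE)
        last = new
    if rng.random() < spec.ring_fraction:
        # close one ring between two carbons at graph distance >= 2
        carbons = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and _free_valence(mol, a.GetIdx()) > 0
        ]
        pairs = [
            (i, j)
            for i in carbons
            for j in carbons
            if i < j and mol.GetBondBetweenAtoms(i, j) is None
            and len(Chem.GetShortestPath(mol, i, j)) >= 3
        ]
        if pairs:
            i, j = pairs[rng.integers(len(pairs))]
            mol.AddBond(i, j, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    # Kekulé output keeps one spelling convention corpus-wide (a random ring
    # with alternating double bonds can perceive as aromatic)
    Chem.Kekulize(out, clearAromaticFlags=True)
    return Chem.MolToSmiles(out, kekuleSmiles=True)


def toy_smiles_corpus(spec: ToyCorpusSpec) -> list[str]:
    """Seeded corpus of small valid molecules (duplicates allowed)."""
    rng = np.random.default_rng(spec.seed)
    return [_random_molecule(rng, spec) for _ in range(spec.n)]


def _decorated_motif(rng: np.random.Generator, motif: Chem.Mol,
                     alphabet: tuple[str, ...]) -> str:
    """Motif plus a short random single-bond substituent, Kekulé SMILES."""
    mol = Chem.RWMol(motif)
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]
    parent = int(sites[rng.integers(len(sites))])
    for _ in range(int(rng.integers(1, 5))):
        el = str(rng.choice(alphabet))
        new = mol.AddAtom(Chem.Atom(el))
        mol.AddBond(parent, new, Chem.BondType.SINGLE)
        if _VALENCE[el] < 2:
            break
        parent = new
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    Chem.Kekulize(out, clearAromaticFlags=True)
    return Chem.MolToSmiles(out, kekuleSmiles=True)


def motif_enriched_corpus(spec: ToyCorpusSpec, motif: MotifSpec) -> list[str]:
    """Corpus in which >= ``enrichment`` of molecules contain the motif.

    Enriched entries are the motif with a random substituent; the remainder
    come from the plain toy grammar.  Everything is valid by construction.
    """
    motif_mol = Chem.MolFromSmiles(motif.motif_smiles)
    if motif_mol.GetNumAtoms() + 1 > spec.max_heavy_atoms:
        raise FixtureError(
            "motif plus one substituent atom exceeds max_heavy_atoms; "
            "enrichment infeasible at this size limit"
        )
    rng = np.random.default_rng(spec.seed)
    n_motif = int(np.ceil(motif.enrichment * spec.n))
    out = [_decorated_motif(rng, motif_mol, spec.alphabet) for _ in range(n_motif)]
    out.extend(_random_molecule(rng, spec) for _ in range(spec.n - n_motif))
    perm = rng.permutation(spec.n)
    return [out[i] for i in perm]


_TEMPLATE_RNG_SEED = 20_240_915  # class templates are fixed, not per-dataset


def class_templates() -> tuple[np.ndarray, np.ndarray]:
    """The two fixed 166-bit templates used by the separable dataset."""
    rng = np.random.default_rng(_TEMPLATE_RNG_SEED)
    a = rng.integers(0, 2, size=166).astype(np.uint8)
    b = rng.integers(0, 2, size=166).astype(np.uint8)
    return a, b


def separable_fingerprint_dataset(
    n_active: int, n_nonactive: int, flip_rate: float, seed: int = 0
) -> LabeledFingerprintSet:
    """Binary fingerprint rows: class template XOR Bernoulli(flip_rate) bits.

    ``flip_rate`` must be below 0.5 — at 0.5 the rows carry no class signal.
    """
    if not (0.0 <= flip_rate < 0.5):
        raise FixtureError("flip_rate must be in [0, 0.5)")
    if n_active < 1 or n_nonactive < 1:
        raise FixtureError("need at least one row per class")
    tpl_a, tpl_b = class_templates()
    rng = np.random.default_rng(seed)
    rows_a = tpl_a[None, :] ^ (rng.random((n_active, 166)) < flip_rate).astype(np.uint8)
    rows_b = tpl_b[None, :] ^ (rng.random((n_nonactive, 166)) < flip_rate).astype(np.uint8)
    return LabeledFingerprintSet(
        fingerprints=np.vstack([rows_a, rows_b]),
        labels=np.concatenate([np.ones(n_active, dtype=int), np.zeros(n_nonactive, dtype=int)]),
        provenance=["active"] * n_active + ["inactive"] * n_nonactive,
    )
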