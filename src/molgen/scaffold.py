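"""Attachment-site enumeration and rooted scaffold SMILES.

A molecule has many SMILES spellings differing in starting atom and
traversal direction.  To grow a substituent at a chosen scaffold atom with
an autoregressive character model, the scaffold must be spelled so that the
string *ends* at that atom: characters appended after the string then bond
to it.  This module enumerates the attachment sites of a scaffold (every
heavy atom carrying at least one hydrogen, no symmetry reduction) and, for
each site, searches for a Kekulé spelling that passes the methyl-append
verification test:

* the spelling itself parses back to the scaffold, and
* the spelling with ``"C"`` appended parses to the scaffold carrying one
  methyl at the designated atom (canonical-structure comparison, so a
  symmetry-equivalent atom is accepted — the product molecule is identical).

Correctness is defined by that test, not by how candidates are produced:
candidates come from atom-rooted canonical traversals plus seeded random
traversals, and are filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class ScaffoldError(ValueError):
    """Raised for unparseable scaffolds or failed rooted-spelling searches."""


@dataclass(frozen=True)
class AttachmentSite:
    """A heavy atom of the scaffold with >=1 hydrogen, open for substitution."""

    atom_index: int
    element: str
    available_h: int


@dataclass(frozen=True)
class RootedScaffoldSMILES:
    """A scaffold spelling whose final written atom is the attachment site."""

    site: AttachmentSite
    smiles: str
    scaffold_canonical: str


def _parse(scaffold_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise ScaffoldError(f"cannot parse scaffold SMILES {scaffold_smiles!r}")
    return mol


def enumerate_attachment_sites(scaffold_smiles: str) -> list[AttachmentSite]:
    """List every heavy atom with at least one hydrogen, ordered by atom index.

    No symmetry reduction is applied: benzene yields six (equivalent) sites,
    indole yields seven.
    """
    mol = _parse(scaffold_smiles)
    sites = [
        AttachmentSite(a.GetIdx(), a.GetSymbol(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() >= 1
    ]
    if not sites:
        import warnings

        warnings.warn("scaffold has no hydrogen-bearing heavy atoms", stacklevel=2)
    return sites


def _methylated_mol(scaffold: Chem.Mol, atom_index: int) -> Chem.Mol:
    """Scaffold with one methyl bonded at atom_index."""
    rw = Chem.RWMol(scaffold)
    atom = rw.GetAtomWithIdx(atom_index)
    if atom.GetNumExplicitHs() > 0:  # e.g. aromatic [nH]: the methyl replaces one H
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    c = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(atom_index, c, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _methylated(scaffold: Chem.Mol, atom_index: int) -> str:
    return Chem.MolToSmiles(_methylated_mol(scaffold, atom_index))


def verify_rooted(rooted_smiles: str, scaffold_smiles: str, atom_index: int) -> bool:
    """Methyl-append verification of a candidate rooted spelling."""
    scaffold = _parse(scaffold_smiles)
    want = Chem.MolToSmiles(scaffold)
    got = Chem.MolFromSmiles(rooted_smiles)
    if got is None or Chem.MolToSmiles(got) != want:
        return False
    try:
        target = _methylated(scaffold, atom_index)
    except Exception:
        return False
    plus = Chem.MolFromSmiles(rooted_smiles + "C")
    return plus is not None and Chem.MolToSmiles(plus) == target


def _kekule_candidates(mol: Chem.Mol, n_random: int, seed: int) -> list[str]:
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    cands: list[str] = []
    for root in range(kek.GetNumAtoms()):
        try:
            cands.append(
                Chem.MolToSmiles(kek, rootedAtAtom=root, canonical=True, kekuleSmiles=True)
            )
        except Exception:
            pass
    try:
        cands.extend(
            Chem.MolToRandomSmilesVect(kek, n_random, randomSeed=seed, kekuleSmiles=True)
        )
    except Exception:
        pass
    # stable dedup preserving first-seen order
    seen: set[str] = set()
    out = []
    for s in cands:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


_BOND_CHARS = set("=#/\\-:~")


def _methyl_strip_candidates(
    scaffold: Chem.Mol, atom_index: int, n_random: int, seed: int
) -> list[str]:
    """Spellings that end at the site atom, derived from the methylated scaffold.

    A plain traversal can only end at a terminal atom, so mid-chain sites
    need spellings that end with the site atom carrying its other
    substituents in closed branches (e.g. ``OC(C)`` for the middle carbon of
    ethanol).  Those are exactly the spellings of scaffold+methyl that end
    with the methyl ``C``: stripping that final character leaves the
    scaffold written so its last open atom is the attachment site.
    """
    methylated = _methylated_mol(scaffold, atom_index)
    out = []
    for s in _kekule_candidates(methylated, n_random, seed):
        if s.endswith("C") and len(s) > 1 and s[-2] not in _BOND_CHARS:
            out.append(s[:-1])
    return out


def rooted_smiles(
    scaffold_smiles: str,
    site: AttachmentSite,
    n_random: int = 400,
    seed: int = 0,
) -> RootedScaffoldSMILES:
    """Find a Kekulé spelling of the scaffold ending at the given site.

    Candidates come from two sources — direct traversals of the scaffold
    (canonical rooted at every atom plus ``n_random`` seeded random
    traversals) and methyl-strip spellings derived from the methylated
    scaffold — and the first candidate passing the methyl-append
    verification for this site is returned.
    """
    mol = _parse(scaffold_smiles)
    canonical = Chem.MolToSmiles(mol)
    pools = (
        _kekule_candidates(mol, n_random, seed),
        _methyl_strip_candidates(mol, site.atom_index, n_random, seed),
    )
    for pool in pools:
        for cand in pool:
            if verify_rooted(cand, scaffold_smiles, site.atom_index):
                return RootedScaffoldSMILES(site=site, smiles=cand, scaffold_canonical=canonical)
    raise ScaffoldError(
        f"no rooted spelling found for atom {site.atom_index} of {scaffold_smiles!r} "
        f"after {n_random} random traversals"
    )


def enumerate_rooted_library(
    scaffold_smiles: str, n_random: int = 400, seed: int = 0
) -> tuple[list[RootedScaffoldSMILES], list[tuple[AttachmentSite, str]]]:
    """Rooted spellings for every attachment site.

    Returns ``(rooted, failures)`` where failures carry the per-site error
    message; one failed site never blocks the others.
    """
    rooted: list[RootedScaffoldSMILES] = []
    failures: list[tuple[AttachmentSite, str]] = []
    for site in enumerate_attachment_sites(scaffold_smiles):
        try:
            rooted.append(rooted_smiles(scaffold_smiles, site, n_random=n_random, seed=seed))
        except ScaffoldError as exc:
            failures.append((site, str(exc)))
    return rooted, failures
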