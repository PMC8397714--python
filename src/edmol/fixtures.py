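"""Seeded synthetic chemical libraries for desk-scale experiments.

Real campaigns train on tens of thousands of PubChem-class molecules
(MW 200-600).  At desk scale we emulate that library with a seeded
fragment-assembly generator: drug-like scaffolds are decorated with
substituents and linkers drawn from a fixed fragment set, so every product
is chemically valid by construction and the library spans the descriptor
ranges such a sample covers — lipophilic halogenated aromatics, polar
sulfonamide/nitro/polyol chemistry, amines and amides, one to four ring
systems.  Generation is a pure function of :class:`FixtureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem

from .chem_core import Molecule, canonicalize

# ring systems used as assembly cores
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1cncnc1",          # pyrimidine
    "c1ccsc1",           # thiophene
    "c1ccoc1",           # furan
    "c1cc[nH]c1",        # pyrrole
    "c1c[nH]cn1",        # imidazole
    "c1cc[nH]n1",        # pyrazole
    "c1ocnc1",           # oxazole
    "c1scnc1",           # thiazole
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccc2ncccc2c1",    # quinoline
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2[nH]cnc2c1",  # benzimidazole
    "C1CCCCC1",          # cyclohexane
    "C1CCNCC1",          # piperidine
    "C1CNCCN1",          # piperazine
    "C1COCCN1",          # morpholine
    "C1CCOCC1",          # tetrahydropyran
)

# one attachment point each
SUBSTITUENTS: tuple[str, ...] = (
    "[*]C", "[*]CC", "[*]CCC", "[*]C(C)C", "[*]CCCC", "[*]CCCCCC",
    "[*]O", "[*]OC", "[*]OCC",
    "[*]F", "[*]Cl", "[*]Br", "[*]C(F)(F)F",
    "[*]C#N", "[*][N+](=O)[O-]",
    "[*]N", "[*]NC", "[*]N(C)C",
    "[*]C(=O)N", "[*]C(=O)NC", "[*]C(=O)O", "[*]C(=O)OC", "[*]C(=O)C",
    "[*]S(=O)(=O)N", "[*]S(=O)(=O)C",
    "[*]CO", "[*]CCO", "[*]C(O)CO", "[*]OCC(O)CO",
    "[*]N1CCOCC1", "[*]N1CCN(C)CC1",
    "[*]c1ccccc1", "[*]c1ccc(Cl)cc1", "[*]c1ccc(F)cc1",
    "[*]c1ccc(C(F)(F)F)cc1", "[*]c1ccc(Cl)c(Cl)c1", "[*]c1cc(Cl)cc(Cl)c1",
)

# two attachment points each
LINKERS: tuple[str, ...] = (
    "[*]C[*]", "[*]CC[*]", "[*]O[*]", "[*]N[*]",
    "[*]C(=O)N[*]", "[*]S(=O)(=O)N[*]", "[*]C(=O)[*]", "[*]C(=O)O[*]",
    "[*]/C=C/[*]",
)


@dataclass
class FixtureConfig:
    """Parameters of the synthetic library generator."""

    n_molecules: int = 500
    rng_seed: int = 0
    fragment_set: Sequence[str] = SUBSTITUENTS
    scaffold_set: Sequence[str] = SCAFFOLDS
    linker_set: Sequence[str] = LINKERS
    min_heavy_atoms: int = 12
    max_heavy_atoms: int = 40
    max_decorations: int = 4
    #: probability that a decoration step grows a linker + second ring system
    p_linker: float = 0.25
    #: surrogate-oracle output range, eV
    property_range: tuple[float, float] = (1.5, 7.0)

    def __post_init__(self) -> None:
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if self.min_heavy_atoms > self.max_heavy_atoms:
            raise ValueError("min_heavy_atoms > max_heavy_atoms")


def _claim_hydrogen(atom: Chem.Atom) -> None:
    # substitution consumes one hydrogen; explicit Hs (e.g. [nH]) must be
    # decremented by hand or sanitisation rejects the new valence
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)


def _first_dummy(mol: Chem.Mol) -> int | None:
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            return atom.GetIdx()
    return None


def _attach(core: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond ``frag`` (via its dummy atom) to a random open position on ``core``."""
    core_dummy = _first_dummy(core)
    if core_dummy is not None:
        core_site = core.GetAtomWithIdx(core_dummy).GetNeighbors()[0].GetIdx()
    else:
        candidates = [
            a.GetIdx()
            for a in core.GetAtoms()
            if a.GetAtomicNum() in (6, 7) and a.GetTotalNumHs() >= 1
        ]
        if not candidates:
            return None
        core_site = int(rng.choice(candidates))
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    offset = core.GetNumAtoms()
    frag_dummy = None
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() == 0:
            frag_dummy = atom.GetIdx() + offset
            break
    if frag_dummy is None:
        return None
    frag_site = combo.GetAtomWithIdx(frag_dummy).GetNeighbors()[0].GetIdx()
    if core_dummy is None:
        _claim_hydrogen(combo.GetAtomWithIdx(core_site))
    combo.AddBond(core_site, frag_site, Chem.BondType.SINGLE)
    # delete higher index first so the other index stays valid
    to_remove = sorted(
        [frag_dummy] + ([core_dummy] if core_dummy is not None else []), reverse=True
    )
    for idx in to_remove:
        combo.RemoveAtom(idx)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _strip_dummies(mol: Chem.Mol) -> Chem.Mol | None:
    rw = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _assemble_one(cfg: FixtureConfig, rng: np.random.Generator) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(str(rng.choice(cfg.scaffold_set)))
    n_dec = int(rng.integers(1, cfg.max_decorations + 1))
    for _ in range(n_dec):
        if rng.random() < cfg.p_linker:
            linker = Chem.MolFromSmiles(str(rng.choice(cfg.linker_set)))
            grown = _attach(mol, linker, rng)
            if grown is None:
                continue
            ring = Chem.MolFromSmiles(str(rng.choice(cfg.scaffold_set)))
            # give the new ring a dummy handle so _attach bonds it to the
            # linker's open end
            mol2 = _attach(grown, _with_handle(ring, rng), rng)
            mol = mol2 if mol2 is not None else grown
        else:
            frag = Chem.MolFromSmiles(str(rng.choice(cfg.fragment_set)))
            grown = _attach(mol, frag, rng)
            if grown is not None:
                mol = grown
        if mol.GetNumHeavyAtoms() > cfg.max_heavy_atoms:
            return None
    return _strip_dummies(mol)


def _with_handle(ring: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    """Attach a dummy atom to a random CH position of a plain ring system."""
    rw = Chem.RWMol(ring)
    candidates = [
        a.GetIdx()
        for a in rw.GetAtoms()
        if a.GetAtomicNum() in (6, 7) and a.GetTotalNumHs() >= 1
    ]
    site = int(rng.choice(candidates))
    _claim_hydrogen(rw.GetAtomWithIdx(site))
    dummy = rw.AddAtom(Chem.Atom(0))
    rw.AddBond(site, dummy, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def generate_library(cfg: FixtureConfig) -> list[Molecule]:
    """Generate ``cfg.n_molecules`` unique valid molecules, reproducibly.

    Raises ``RuntimeError`` (reporting the count achieved) if the configured
    constraints cannot yield enough unique molecules.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    seen: set[str] = set()
    out: list[Molecule] = []
    max_tries = 200 * cfg.n_molecules
    tries = 0
    while len(out) < cfg.n_molecules and tries < max_tries:
        tries += 1
        raw = _assemble_one(cfg, rng)
        if raw is None:
            continue
        if not (cfg.min_heavy_atoms <= raw.GetNumHeavyAtoms() <= cfg.max_heavy_atoms):
            continue
        smi = Chem.MolToSmiles(raw)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(Molecule(smiles_input=smi, smiles_canonical=smi, is_valid=True))
    if len(out) < cfg.n_molecules:
        raise RuntimeError(
            f"could only generate {len(out)} of {cfg.n_molecules} unique molecules"
        )
    return out


def label_library(
    library: Sequence[Molecule],
    oracle: Callable[[Molecule], object],
) -> list[tuple[Molecule, object]]:
    """Label every molecule with ``oracle``; failing molecules are skipped."""
    out = []
    for mol in library:
        try:
            out.append((mol, oracle(mol)))
        except Exception:
            continue
    return out
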