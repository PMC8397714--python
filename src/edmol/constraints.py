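"""Structural blacklist, property windows and deduplication.

Generated candidates are screened by three structural rules (fused-ring
sizes 4-7, at most six fused rings, alkyl chains of at most six carbons),
a ring-count window around the seed molecule, strict property windows
(e.g. -7.0 eV < HOMO < -5.0 eV and LUMO < 0.0 eV), and removal of
molecules already present in the reference database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem

from .chem_core import Molecule
from .predictor import PropertyVector


@dataclass
class BlacklistConfig:
    fused_ring_size_min: int = 4
    fused_ring_size_max: int = 7
    max_fused_rings: int = 6
    max_alkyl_chain: int = 6
    #: allowed |ring_count(candidate) - ring_count(seed)|; removal triggers
    #: when the difference reaches two, i.e. +/-1 is tolerated
    ring_delta_limit: int = 1

    def __post_init__(self) -> None:
        if self.fused_ring_size_min > self.fused_ring_size_max:
            raise ValueError("fused ring size min > max")
        if min(self.max_fused_rings, self.max_alkyl_chain) <= 0:
            raise ValueError("limits must be positive")


@dataclass(frozen=True)
class PropertyWindow:
    """Strict open interval constraint on a named property."""

    name: str
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window for {self.name!r}: lower must be < upper")

    def contains(self, value: float) -> bool:
        return self.lower < value < self.upper


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()


def _mol_with_rings(mol: Molecule):
    """RDKit mol with verified ring perception.

    Perception can fail spuriously on pathological inputs (and is
    order-dependent within a process); a fresh parse usually recovers, so
    retry before giving up.
    """
    from .chem_core import RingPerceptionError

    for _ in range(3):
        m = mol.rdkit_mol
        try:
            m.GetRingInfo().NumRings()
            return m
        except RuntimeError:
            continue
    raise RingPerceptionError(f"ring perception failed for {mol.smiles_canonical!r}")


@dataclass(frozen=True)
class RingSystem:
    ring_sizes: tuple[int, ...]

    @property
    def n_rings(self) -> int:
        return len(self.ring_sizes)


def fused_ring_systems(mol: Molecule) -> list[RingSystem]:
    """Group SSSR rings into fused systems (rings sharing >= 1 bond).

    Spiro junctions (atom sharing only) do not fuse; each system reports
    its ring sizes.
    """
    if not mol.is_valid:
        raise ValueError(f"invalid molecule {mol.smiles_input!r}")
    m = _mol_with_rings(mol)
    bond_rings = [frozenset(r) for r in m.GetRingInfo().BondRings()]
    n = len(bond_rings)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if bond_rings[i] & bond_rings[j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    atom_rings = m.GetRingInfo().AtomRings()
    return [
        RingSystem(tuple(sorted(len(atom_rings[i]) for i in idxs)))
        for idxs in sorted(groups.values(), key=min)
    ]


def _is_alkyl_carbon(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() != 6 or atom.GetIsAromatic() or atom.IsInRing():
        return False
    if atom.GetHybridization() != Chem.HybridizationType.SP3:
        return False
    return all(nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors())


def longest_alkyl_chain(mol: Molecule) -> int:
    """Longest simple path of acyclic sp3 carbons bonded only to C/H."""
    if not mol.is_valid:
        raise ValueError(f"invalid molecule {mol.smiles_input!r}")
    m = _mol_with_rings(mol)
    eligible = {a.GetIdx() for a in m.GetAtoms() if _is_alkyl_carbon(a)}
    adj = {
        i: [
            nb.GetIdx()
            for nb in m.GetAtomWithIdx(i).GetNeighbors()
            if nb.GetIdx() in eligible
        ]
        for i in eligible
    }
    # eligible atoms are acyclic, so the induced subgraph is a forest:
    # the longest path in each tree is found with two traversals
    best = 0
    seen: set[int] = set()

    def farthest(start: int) -> tuple[int, int]:
        stack = [(start, 1)]
        visited = {start}
        far_node, far_d = start, 1
        while stack:
            node, d = stack.pop()
            if d > far_d:
                far_node, far_d = node, d
            for nb in adj[node]:
                if nb not in visited:
                    visited.add(nb)
                    stack.append((nb, d + 1))
        seen.update(visited)
        return far_node, far_d

    for i in eligible:
        if i in seen:
            continue
        u, _ = farthest(i)
        _, depth = farthest(u)
        best = max(best, depth)
    return best


def ring_count(mol: Molecule) -> int:
    """Number of SSSR rings (cyclomatic number: bonds - atoms + fragments)."""
    m = mol.rdkit_mol
    n_frags = len(Chem.GetMolFrags(m))
    return m.GetNumBonds() - m.GetNumAtoms() + n_frags


def check_structural(
    mol: Molecule, seed: Molecule, cfg: BlacklistConfig | None = None
) -> FilterVerdict:
    """Apply the structural blacklist plus the seed ring-count window."""
    cfg = cfg or BlacklistConfig()
    reasons: list[str] = []
    systems = fused_ring_systems(mol)
    for sys_ in systems:
        if sys_.n_rings >= 2:
            if any(
                s < cfg.fused_ring_size_min or s > cfg.fused_ring_size_max
                for s in sys_.ring_sizes
            ):
                reasons.append("fused_ring_size")
                break
    if any(s.n_rings > cfg.max_fused_rings for s in systems):
        reasons.append("fused_ring_count")
    if longest_alkyl_chain(mol) > cfg.max_alkyl_chain:
        reasons.append("alkyl_chain")
    if abs(ring_count(mol) - ring_count(seed)) > cfg.ring_delta_limit:
        reasons.append("ring_delta")
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def check_property_window(
    props: PropertyVector | dict, windows: Sequence[PropertyWindow]
) -> bool:
    """True iff every strict window holds; missing property raises."""
    for w in windows:
        if w.name not in props:
            raise KeyError(f"property {w.name!r} missing from {sorted(props)}")
        if not w.contains(props[w.name]):
            return False
    return True


def dedup_against(mols: Iterable[Molecule], reference: set[str]) -> list[Molecule]:
    """Drop molecules whose canonical SMILES is in ``reference``; keep order."""
    return [m for m in mols if m.smiles_canonical not in reference]
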