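"""Molecule parsing, ECFP encoding, SMILES validity inspection and similarity.

Molecules are identified by their RDKit-canonical SMILES.  Fingerprints are
Morgan/ECFP bit vectors of fixed length 5000 covering circular neighbourhoods
up to a bond diameter of six (radius 3).  During fingerprint-space evolution
the vectors become real-valued in [0, 1]; every set-based operation
(Tanimoto, lookup) first binarises at 0.5, while neural models consume the
raw real vector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: fingerprint length used throughout (bits)
N_BITS = 5000
#: circular-neighbourhood diameter in bonds (ECFP6 -> Morgan radius 3)
DIAMETER = 6

_MORGAN_CACHE: dict[tuple[int, int], object] = {}


def _morgan_generator(diameter: int, nbits: int):
    key = (diameter, nbits)
    if key not in _MORGAN_CACHE:
        _MORGAN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=diameter // 2, fpSize=nbits
        )
    return _MORGAN_CACHE[key]


class RingPerceptionError(RuntimeError):
    """RDKit could not establish a ring basis for a pathological molecule."""


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule; chemical identity is the canonical SMILES."""

    smiles_input: str
    smiles_canonical: str | None
    is_valid: bool

    @property
    def rdkit_mol(self) -> Chem.Mol:
        if not self.is_valid:
            raise ValueError(f"invalid molecule: {self.smiles_input!r}")
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        if mol is None:  # pathological canonical forms may not round-trip
            mol = Chem.MolFromSmiles(self.smiles_input)
        if mol is None:
            raise ValueError(f"molecule no longer parsable: {self.smiles_canonical!r}")
        # ring perception on heavily fused macrocycles can come back
        # uninitialized (and is not even deterministic about it); try to
        # repair here, but leave failure handling to ring-dependent callers
        try:
            mol.GetRingInfo().NumRings()
        except RuntimeError:
            try:
                Chem.GetSymmSSSR(mol)
            except Exception:
                pass
        return mol

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles_canonical if self.is_valid else f"<invalid {self.smiles_input!r}>"


@dataclass
class Fingerprint:
    """Length-5000 vector in [0, 1]; binary straight after encoding."""

    values: np.ndarray
    is_binary: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("fingerprint must be a 1-D vector")

    def __len__(self) -> int:
        return self.values.shape[0]

    def binarized(self, threshold: float = 0.5) -> np.ndarray:
        """Boolean view at the set-operation threshold (>= 0.5 is 'on')."""
        return self.values >= threshold

    def on_bits(self, threshold: float = 0.5) -> np.ndarray:
        return np.flatnonzero(self.binarized(threshold))


def canonicalize(smiles: str) -> Molecule:
    """Parse ``smiles``; never raises — failure is encoded in ``is_valid``."""
    mol = (
        Chem.MolFromSmiles(smiles) if isinstance(smiles, str) and smiles.strip() else None
    )
    if mol is None:
        return Molecule(smiles_input=smiles, smiles_canonical=None, is_valid=False)
    return Molecule(
        smiles_input=smiles,
        smiles_canonical=Chem.MolToSmiles(mol),
        is_valid=True,
    )


def encode_ecfp(mol: Molecule, diameter: int = DIAMETER, nbits: int = N_BITS) -> Fingerprint:
    """Binary ECFP of ``mol``; invariant to the SMILES spelling.

    Raises ``ValueError`` on an invalid molecule.
    """
    if not mol.is_valid:
        raise ValueError(f"cannot encode invalid molecule {mol.smiles_input!r}")
    fp = _morgan_generator(diameter, nbits).GetFingerprint(mol.rdkit_mol)
    arr = np.zeros(nbits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return Fingerprint(values=arr, is_binary=True)


class InvalidReason(str, Enum):
    PARSE = "parse"
    PARENTHESES = "parentheses"
    RING_CLOSURE = "ring_closure"
    KEKULIZATION = "kekulization"


@dataclass(frozen=True)
class ValidityReport:
    valid: bool
    reason: InvalidReason | None = None


_RING_TOKEN = re.compile(r"%\d{2}|\d")


def _ring_labels_close(smiles: str) -> bool:
    # ring-bond digits must pair up; a digit is reusable once closed
    open_labels: set[str] = set()
    i = 0
    n = len(smiles)
    while i < n:
        c = smiles[i]
        if c in "[":
            j = smiles.find("]", i)
            if j < 0:
                return False  # unclosed bracket atom; parser will also reject
            i = j + 1
            continue
        if c == "%":
            m = _RING_TOKEN.match(smiles, i)
            if not m:
                return False
            label = m.group(0)
            open_labels ^= {label}
            i = m.end()
            continue
        if c.isdigit():
            # a digit not following an atom start is still a ring bond in SMILES
            open_labels ^= {c}
        i += 1
    return not open_labels


def inspect_validity(smiles: str) -> ValidityReport:
    """Grammar/chemistry inspection of a SMILES string.

    Distinguishes unbalanced parentheses, unclosed ring bonds, kekulisation
    failures and general parse failures.  All outcomes are reported, never
    raised.
    """
    if not isinstance(smiles, str) or not smiles:
        return ValidityReport(False, InvalidReason.PARSE)
    depth = 0
    for c in smiles:
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                return ValidityReport(False, InvalidReason.PARENTHESES)
    if depth != 0:
        return ValidityReport(False, InvalidReason.PARENTHESES)
    if not _ring_labels_close(smiles):
        return ValidityReport(False, InvalidReason.RING_CLOSURE)
    # parse without sanitisation first so kekulisation failures are separable
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return ValidityReport(False, InvalidReason.PARSE)
    try:
        Chem.SanitizeMol(mol)
    except Chem.KekulizeException:
        return ValidityReport(False, InvalidReason.KEKULIZATION)
    except Exception:
        return ValidityReport(False, InvalidReason.PARSE)
    return ValidityReport(True, None)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B|/|A∪B| over set bits (binarised at 0.5).

    Both-empty is defined as 1.0.  Raises on length mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    av = a.binarized()
    bv = b.binarized()
    inter = np.count_nonzero(av & bv)
    union = np.count_nonzero(av | bv)
    if union == 0:
        return 1.0
    return inter / union


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path) -> list[Molecule]:
    """One SMILES per line; an optional tab-separated name is ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(canonicalize(line.split("\t")[0].split()[0]))
    return out


def write_smiles_file(path, mols: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write((m.smiles_canonical if m.is_valid else m.smiles_input) + "\n")


def read_smiles_csv(path, smiles_column: str = "smiles") -> pd.DataFrame:
    """CSV with a ``smiles`` column; adds parsed ``molecule`` objects."""
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ValueError(f"CSV has no {smiles_column!r} column")
    df = df.copy()
    df["molecule"] = [canonicalize(s) for s in df[smiles_column]]
    return df


def read_sdf(path) -> list[Molecule]:
    """Read-only SDF convenience; invalid records are returned as invalid."""
    out = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            out.append(Molecule("<sdf record>", None, False))
        else:
            smi = Chem.MolToSmiles(mol)
            out.append(Molecule(smi, smi, True))
    return out
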