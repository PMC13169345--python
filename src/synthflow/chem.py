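"""Molecule identity, fingerprints, similarity, and SMILES tokenization.

All modules in this package funnel molecule handling through here:
molecules are identified by RDKit canonical SMILES, compared by Tanimoto
similarity on Morgan fingerprints (ECFP4: radius 2, 2048 bits by
default), and serialized for the sequence model with a reversible
regex tokenizer that supports a leading reaction-condition token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "canonicalize",
    "mol_from_smiles",
    "ecfp",
    "tanimoto",
    "tokenize",
    "detokenize",
    "Vocabulary",
    "SMILES_TOKEN_RE",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """RDKit canonical SMILES; idempotent, preserves stereo annotations."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@dataclass(frozen=True)
class Molecule:
    """A molecule identified by its canonical SMILES.

    Equality and hashing go through the canonical string, so two
    differently written SMILES of the same structure compare equal.
    """

    smiles: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        return cls(canonicalize(smiles))

    @property
    def rdkit(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    @property
    def num_atoms(self) -> int:
        return self.rdkit.GetNumAtoms()

    def __str__(self) -> str:
        return self.smiles


# ----------------------------------------------------------------------
# fingerprints
# ----------------------------------------------------------------------

_FP_GENS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENS:
        _FP_GENS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _FP_GENS[key]


def ecfp(mol: Molecule | str | Chem.Mol, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Binary Morgan (extended-connectivity) fingerprint as a uint8 array."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if nbits <= 0 or nbits & (nbits - 1):
        raise ValueError("nbits must be a power of two")
    if isinstance(mol, Molecule):
        rd = mol.rdkit
    elif isinstance(mol, str):
        rd = mol_from_smiles(mol)
    else:
        rd = mol
    bv = _fp_generator(radius, nbits).GetFingerprint(rd)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints.

    Two all-zero fingerprints are defined to have similarity 1 (they are
    identical objects; avoids 0/0).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return inter / union


# ----------------------------------------------------------------------
# tokenization
# ----------------------------------------------------------------------

# Standard SMILES regex: bracket atoms, two-letter halogens and the
# organic subset as single tokens, %nn ring closures, bond/branch symbols.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}"
    r"|[BCNOPSFIbcnops]|[0-9]|[=#\-\+\\/\(\)\.@:~\*\$])"
)

_CONDITION_RE = re.compile(r"<RXN_(\d+)>")


class TokenizationError(ValueError):
    pass


def tokenize(smiles: str, condition: int | None = None) -> list[str]:
    """Split a SMILES string into tokens, optionally prepending the
    reaction-condition token ``<RXN_i>`` for template index ``i``."""
    tokens: list[str] = []
    pos = 0
    for m in SMILES_TOKEN_RE.finditer(smiles):
        if m.start() != pos:
            raise TokenizationError(
                f"character {smiles[pos]!r} at position {pos} of {smiles!r} "
                "is outside the SMILES vocabulary"
            )
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"character {smiles[pos]!r} at position {pos} of {smiles!r} "
            "is outside the SMILES vocabulary"
        )
    if condition is not None:
        if condition < 0:
            raise ValueError("condition token index must be >= 0")
        tokens.insert(0, f"<RXN_{condition}>")
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize`; drops a leading condition token."""
    if tokens and _CONDITION_RE.fullmatch(tokens[0]):
        tokens = tokens[1:]
    return "".join(tokens)


@dataclass
class Vocabulary:
    """Token-to-index mapping with reserved specials and condition tokens.

    Layout: ``<PAD> <BOS> <EOS> <UNK>``, then one ``<RXN_i>`` per template
    index, then the SMILES tokens in sorted order.
    """

    tokens: list[str]
    index: dict[str, int] = field(init=False)

    PAD, BOS, EOS, UNK = "<PAD>", "<BOS>", "<EOS>", "<UNK>"

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for special in (self.PAD, self.BOS, self.EOS, self.UNK):
            if special not in self.index:
                raise ValueError(f"vocabulary missing reserved token {special}")

    @classmethod
    def build(cls, corpus: Iterable[str], n_templates: int) -> "Vocabulary":
        seen: set[str] = set()
        for smiles in corpus:
            seen.update(tokenize(smiles))
        toks = [cls.PAD, cls.BOS, cls.EOS, cls.UNK]
        toks += [f"<RXN_{i}>" for i in range(n_templates)]
        toks += sorted(seen)
        return cls(toks)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[self.PAD]

    @property
    def bos_id(self) -> int:
        return self.index[self.BOS]

    @property
    def eos_id(self) -> int:
        return self.index[self.EOS]

    def encode(self, tokens: Sequence[str]) -> list[int]:
        unk = self.index[self.UNK]
        return [self.index.get(t, unk) for t in tokens]

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.tokens[i] for i in ids]

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self.tokens).encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls([line for line in Path(path).read_text().splitlines() if line])
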