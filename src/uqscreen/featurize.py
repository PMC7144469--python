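"""Binary fingerprint representations and Tanimoto similarity.

Compounds are encoded either chemically — Morgan circular fingerprints of
radius 2 (hashed, default 2048 bits) or MACCS structural keys, both computed
with RDKit — or synthetically, as prototype-derived bit patterns from the
:mod:`uqscreen.synth` generator, which lets every downstream stage run
without a chemistry backend.

Similarity is the Tanimoto coefficient |A∧B| / |A∨B| over set bits; the
degenerate all-zero/all-zero pair is defined as 0 ("no shared features").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fingerprint",
    "FingerprintMatrix",
    "ChemistryBackendError",
    "fingerprint",
    "fingerprints_for",
    "tanimoto",
    "tanimoto_matrix",
    "max_similarity_to_set",
    "mean_similarity_to_set",
    "read_fingerprint_csv",
    "write_fingerprint_csv",
]

SCHEMES = ("morgan_r2", "maccs", "synthetic")


class ChemistryBackendError(ImportError):
    """RDKit is unavailable; use precomputed or synthetic fingerprints."""


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # 1-D uint8 array of 0/1
    scheme: str

    def __post_init__(self):
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.ndim != 1 or not np.isin(b, (0, 1)).all():
            raise ValueError("fingerprint bits must be a 1-D 0/1 vector")
        object.__setattr__(self, "bits", b)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]


@dataclass
class FingerprintMatrix:
    """Ordered compounds × bits binary matrix."""

    compound_ids: list[str]
    bits: np.ndarray  # (n_compounds, n_bits) uint8
    scheme: str

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or len(self.compound_ids) != self.bits.shape[0]:
            raise ValueError("row count must match compound_ids")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("entries must be 0/1")

    def __len__(self) -> int:
        return self.bits.shape[0]

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def row(self, i: int) -> Fingerprint:
        return Fingerprint(self.bits[i], self.scheme)

    def subset(self, idx) -> "FingerprintMatrix":
        idx = np.asarray(idx)
        return FingerprintMatrix(
            [self.compound_ids[i] for i in idx], self.bits[idx], self.scheme
        )


def _require_rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

        return Chem, rdFingerprintGenerator, rdMolDescriptors
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ChemistryBackendError(
            "RDKit is not available; supply precomputed fingerprints or use "
            "the synthetic generator (uqscreen.synth)"
        ) from exc


def fingerprint(smiles: str, scheme: str = "morgan_r2", n_bits: int = 2048) -> Fingerprint:
    """Compute a binary fingerprint for one SMILES string.

    ``morgan_r2``: hashed circular fingerprint, radius 2, ``n_bits`` wide.
    ``maccs``: the fixed 167-slot MACCS key set (slot 0 unused by RDKit).
    Deterministic: identical SMILES give identical bit vectors.
    """
    Chem, rdFingerprintGenerator, rdMolDescriptors = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if scheme == "morgan_r2":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        bv = gen.GetFingerprint(mol)
    elif scheme == "maccs":
        bv = rdMolDescriptors.GetMACCSKeysFingerprint(mol)
    else:
        raise ValueError(f"scheme {scheme!r} is not a chemical fingerprint scheme")
    arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    for idx in bv.GetOnBits():
        arr[idx] = 1
    return Fingerprint(arr, scheme)


def fingerprints_for(
    compound_ids: Sequence[str],
    smiles: Sequence[str],
    scheme: str = "morgan_r2",
    n_bits: int = 2048,
) -> FingerprintMatrix:
    """Fingerprint a list of compounds into a FingerprintMatrix.

    An unparseable SMILES raises, naming the offending compound.
    """
    rows = []
    for cid, smi in zip(compound_ids, smiles, strict=True):
        try:
            rows.append(fingerprint(smi, scheme, n_bits).bits)
        except ValueError as exc:
            raise ValueError(f"compound {cid}: {exc}") from exc
    return FingerprintMatrix(list(compound_ids), np.vstack(rows), scheme)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient of two fingerprints of identical scheme/width."""
    if a.scheme != b.scheme or a.n_bits != b.n_bits:
        raise ValueError("fingerprints must share scheme and length")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0", stacklevel=2)
        return 0.0
    return inter / union


def tanimoto_matrix(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Tanimoto between rows of binary matrices a (n×d) and b (m×d).

    With ``b is None`` computes the square self-similarity matrix.
    All-zero/all-zero pairs yield 0.
    """
    a = np.asarray(a, dtype=np.float32)
    b_arr = a if b is None else np.asarray(b, dtype=np.float32)
    inter = a @ b_arr.T
    pa = a.sum(axis=1)[:, None]
    pb = b_arr.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.astype(np.float64)


def max_similarity_to_set(query: Fingerprint, train: FingerprintMatrix) -> float:
    """Maximum Tanimoto between a query and any training compound.

    The standard applicability-domain notion of "similarity to the training
    set"; the mean variant is :func:`mean_similarity_to_set`.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if query.scheme != train.scheme or query.n_bits != train.n_bits:
        raise ValueError("query and training set must share scheme and length")
    sims = tanimoto_matrix(query.bits[None, :], train.bits)
    return float(sims.max())


def mean_similarity_to_set(query: Fingerprint, train: FingerprintMatrix) -> float:
    if len(train) == 0:
        raise ValueError("empty training set")
    sims = tanimoto_matrix(query.bits[None, :], train.bits)
    return float(sims.mean())


def write_fingerprint_csv(fps: FingerprintMatrix, path) -> None:
    df = pd.DataFrame(fps.bits, columns=[f"bit_{i}" for i in range(fps.n_bits)])
    df.insert(0, "compound_id", fps.compound_ids)
    df.insert(1, "scheme", fps.scheme)
    df.to_csv(path, index=False)


def read_fingerprint_csv(path) -> FingerprintMatrix:
    df = pd.read_csv(path)
    scheme = str(df["scheme"].iloc[0]) if "scheme" in df.columns else "synthetic"
    bit_cols = [c for c in df.columns if c.startswith("bit_")]
    return FingerprintMatrix(
        df["compound_id"].astype(str).tolist(),
        df[bit_cols].to_numpy(dtype=np.uint8),
        scheme,
    )
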