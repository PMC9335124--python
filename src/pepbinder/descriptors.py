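"""Peptide sequence descriptors: AAC, DPC, PseAAC, CKSAAGP.

A peptide is encoded as the 519-dimensional concatenation

    AAC (20) | DPC (400) | PseAAC (20 + lambda = 24) | CKSAAGP (25 x 3 = 75)

with a fixed, documented feature order — the order is part of the model
contract because trained submodels store selected feature *indices*.

* AAC: residue frequencies (count / L), alphabetical residue order.
* DPC: dipeptide frequencies (count / (L-1)), alphabetical double loop.
* PseAAC: Chou's type-1 pseudo amino acid composition — residue
  frequencies augmented with ``lam`` sequence-order correlation factors
  built from three standardized residue properties (hydrophobicity,
  hydrophilicity, side-chain mass), weighted by ``w``.
* CKSAAGP: frequencies of physicochemical-group pairs separated by k
  residues (k = 0, 1, 2), with the 20 amino acids partitioned into five
  groups (aliphatic, aromatic, positive-charged, negative-charged,
  uncharged); each k-spaced pair count is divided by L - (k + 1).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from pepbinder.io import AMINO_ACIDS, Peptide, validate_peptide_seq

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Five physicochemical groups; the listing order fixes the CKSAAGP pair order.
AA_GROUPS: tuple[tuple[str, str], ...] = (
    ("ali", "GAVLMI"),   # aliphatic
    ("aro", "FYW"),      # aromatic
    ("pos", "KRH"),      # positive-charged
    ("neg", "DE"),       # negative-charged
    ("unc", "STCPNQ"),   # uncharged polar / small
)
_GROUP_OF = {aa: gi for gi, (_, members) in enumerate(AA_GROUPS) for aa in members}
assert len(_GROUP_OF) == 20

# Residue property tables for type-1 PseAAC (Chou 2001):
# hydrophobicity, hydrophilicity, side-chain mass, keyed alphabetically.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


@lru_cache(maxsize=1)
def _standardized_properties() -> np.ndarray:
    """3 x 20 property matrix, each row zero-mean / unit-variance over the
    20 residues (population statistics)."""
    rows = []
    for table in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDE_CHAIN_MASS):
        v = np.array([table[a] for a in AMINO_ACIDS])
        rows.append((v - v.mean()) / v.std())
    return np.vstack(rows)


@lru_cache(maxsize=1)
def _theta_table() -> np.ndarray:
    """20 x 20 correlation function Theta(Ri, Rj): mean squared difference of
    the three standardized properties."""
    p = _standardized_properties()
    diff = p[:, :, None] - p[:, None, :]
    return np.mean(diff**2, axis=0)


def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies (count / L)."""
    seq = validate_peptide_seq(seq)
    counts = np.zeros(20)
    for ch in seq:
        counts[_AA_INDEX[ch]] += 1
    return counts / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: 400 dipeptide frequencies (count / (L-1))."""
    seq = validate_peptide_seq(seq)
    if len(seq) < 2:
        raise ValueError("DPC requires at least 2 residues")
    counts = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        counts[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
    return counts / (len(seq) - 1)


def cksaagp(seq: str, k_values: tuple[int, ...] = (0, 1, 2)) -> np.ndarray:
    """Composition of k-spaced amino-acid group pairs.

    For each k the count of positions i with groups (g(seq[i]),
    g(seq[i+k+1])) is divided by L-(k+1); the 25-entry blocks are
    concatenated in k order (75 dims at the default k = 0, 1, 2).
    """
    seq = validate_peptide_seq(seq)
    L = len(seq)
    groups = [_GROUP_OF[ch] for ch in seq]
    blocks = []
    for k in k_values:
        n_pairs = L - (k + 1)
        if n_pairs < 1:
            raise ValueError(f"sequence of length {L} too short for k={k}")
        block = np.zeros(25)
        for i in range(n_pairs):
            block[groups[i] * 5 + groups[i + k + 1]] += 1
        blocks.append(block / n_pairs)
    return np.concatenate(blocks)


def pseaac(seq: str, lam: int = 4, w: float = 0.4) -> np.ndarray:
    """Type-1 pseudo amino-acid composition with ``20 + lam`` dimensions.

    The first 20 components carry the residue frequencies, the last ``lam``
    the rank-tau sequence-order correlation factors

        theta_tau = (1 / (L - tau)) * sum_i Theta(R_i, R_{i+tau}),

    all jointly normalized so the vector sums to 1 with the order factors
    weighted by ``w``.
    """
    seq = validate_peptide_seq(seq)
    L = len(seq)
    if L <= lam:
        raise ValueError(f"PseAAC needs L > lambda ({lam}), got L={L}")
    if w <= 0:
        raise ValueError("weight w must be positive")
    theta_tab = _theta_table()
    idx = np.array([_AA_INDEX[ch] for ch in seq])
    f = np.bincount(idx, minlength=20) / L
    thetas = np.array(
        [theta_tab[idx[: L - tau], idx[tau:]].mean() for tau in range(1, lam + 1)]
    )
    denom = f.sum() + w * thetas.sum()
    return np.concatenate([f / denom, w * thetas / denom])


@lru_cache(maxsize=4)
def feature_names(lam: int = 4, k_values: tuple[int, ...] = (0, 1, 2)) -> tuple[str, ...]:
    """Stable names of the full encoding, in concatenation order."""
    names = [f"AAC_{a}" for a in AMINO_ACIDS]
    names += [f"DPC_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    names += [f"PseAAC_{a}" for a in AMINO_ACIDS]
    names += [f"PseAAC_lam{t}" for t in range(1, lam + 1)]
    for k in k_values:
        for ga, _ in AA_GROUPS:
            for gb, _ in AA_GROUPS:
                names.append(f"CKSAAGP_k{k}_{ga}.{gb}")
    return tuple(names)


def encode(seq: str, lam: int = 4, w: float = 0.4, k_values: tuple[int, ...] = (0, 1, 2)) -> np.ndarray:
    """Full descriptor encoding AAC | DPC | PseAAC | CKSAAGP (519 dims at
    defaults).  Sequences shorter than 5 residues cannot satisfy every
    sub-descriptor and are rejected."""
    seq = validate_peptide_seq(seq)
    if len(seq) < max(5, lam + 1, max(k_values) + 2):
        raise ValueError(
            f"sequence {seq!r} too short to encode (need at least 5 residues at defaults)"
        )
    return np.concatenate([aac(seq), dpc(seq), pseaac(seq, lam, w), cksaagp(seq, k_values)])


def encode_many(seqs, lam: int = 4, w: float = 0.4) -> np.ndarray:
    """Encode a sequence collection into an (n, 519) matrix."""
    seqs = [p.seq if isinstance(p, Peptide) else p for p in seqs]
    return np.vstack([encode(s, lam=lam, w=w) for s in seqs])


class PeptideEncoder(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer mapping peptide sequences to descriptor rows.

    Parameters
    ----------
    lam, w : PseAAC order depth and weight.

    ``transform`` accepts an iterable of sequences (or Peptide objects) and
    returns the (n, 519) float matrix; ``get_feature_names_out`` exposes the
    stable column names.
    """

    def __init__(self, lam: int = 4, w: float = 0.4):
        self.lam = lam
        self.w = w

    def fit(self, X, y=None):  # stateless
        return self

    def transform(self, X) -> np.ndarray:
        return encode_many(X, lam=self.lam, w=self.w)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(feature_names(self.lam), dtype=object)
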