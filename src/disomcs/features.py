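"""Per-residue feature assembly: 3 MCS columns + 9 one-hot secondary-structure columns.

Predicted secondary structure is an external input — one symbol per residue
over a nine-letter alphabet (DSSP-style eight states plus '-' for "no
prediction").  Only the cardinality of the alphabet is load-bearing; the
letters are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcs_profile import MCSProfile

N_FEATURES = 12


class FeatureError(ValueError):
    """Raised for unknown symbols or mismatched feature-block lengths."""


@dataclass(frozen=True)
class SSAlphabet:
    """Ordered nine-symbol secondary-structure alphabet, '-' last."""

    symbols: str = "HGIEBTSC-"

    def __post_init__(self) -> None:
        if len(self.symbols) != 9 or len(set(self.symbols)) != 9:
            raise FeatureError("SS alphabet must hold 9 distinct symbols")
        if self.symbols[-1] != "-":
            raise FeatureError("last SS symbol must be '-'")

    def index(self, symbol: str, position: int) -> int:
        i = self.symbols.find(symbol)
        if i < 0:
            raise FeatureError(
                f"unknown secondary-structure symbol {symbol!r} at position {position + 1}"
            )
        return i


DEFAULT_SS_ALPHABET = SSAlphabet()


@dataclass(frozen=True)
class FeatureMatrix:
    """L x 12 features: columns 0-2 the MCS profile (O, N, D), 3-11 one-hot SS."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise FeatureError(f"feature matrix must have {N_FEATURES} columns")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def mcs_block(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def ss_block(self) -> np.ndarray:
        return self.values[:, 3:]


def encode_ss(ss_string: str, alphabet: SSAlphabet = DEFAULT_SS_ALPHABET) -> np.ndarray:
    """One-hot encode a secondary-structure string as an L x 9 block."""
    block = np.zeros((len(ss_string), 9), dtype=np.float64)
    for p, sym in enumerate(ss_string):
        block[p, alphabet.index(sym, p)] = 1.0
    return block


def assemble(mcs: MCSProfile, ss_block: np.ndarray) -> FeatureMatrix:
    """Concatenate the MCS profile and the SS one-hot block, MCS first."""
    if len(mcs.values) != len(ss_block):
        raise FeatureError(
            f"MCS length {len(mcs.values)} != SS length {len(ss_block)}"
        )
    return FeatureMatrix(np.hstack([mcs.values, ss_block]))


def read_ss_fasta(path, alphabet: SSAlphabet = DEFAULT_SS_ALPHABET) -> dict[str, str]:
    """Read per-chain secondary-structure strings from FASTA-like records."""
    out: dict[str, str] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        for p, sym in enumerate(s):
            alphabet.index(sym, p)  # validate early, naming the position
        out[rec.id] = s
    return out
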