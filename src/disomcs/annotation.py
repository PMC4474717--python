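"""Residue-level disorder annotation.

Disordered residues are defined operationally, CASP-style: a residue is
disordered when its backbone C-alpha atom is missing from the deposited
structure.  The two-state order/disorder labeling derived from that mask is
the ground truth for all evaluation.

For training and inference a third state is introduced: the *near-disorder*
region, the K residues at each terminus of an ordered region.  Relabeling
those boundary residues softens the heavy order/disorder class imbalance and
absorbs the boundary errors that otherwise dominate the loss.  Near-disorder
is a modeling device only — it never enters evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

ORDER = "O"
NEAR = "N"
DISORDER = "D"

#: the fixed three-state alphabet, in canonical order
STATES = (ORDER, NEAR, DISORDER)

#: 20 standard residues plus X for unknown
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_K = 5


class AnnotationError(ValueError):
    """Raised for inconsistent chain annotations or label strings."""


@dataclass(frozen=True)
class ChainAnnotation:
    """A protein chain with its per-residue resolved mask.

    ``resolved[i]`` is True when residue ``i`` has a backbone C-alpha atom
    in the reference structure (i.e. the residue is ordered).
    """

    chain_id: str
    sequence: str
    resolved: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise AnnotationError("chain_id must be non-empty")
        if len(self.sequence) < 1:
            raise AnnotationError(f"{self.chain_id}: empty sequence")
        if len(self.resolved) != len(self.sequence):
            raise AnnotationError(
                f"{self.chain_id}: resolved mask length {len(self.resolved)} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise AnnotationError(
                f"{self.chain_id}: unexpected sequence letters {sorted(bad)}"
            )
        object.__setattr__(self, "resolved", tuple(bool(b) for b in self.resolved))


@dataclass(frozen=True)
class LabeledChain:
    """A chain with a three-state {O,N,D} label string of matching length."""

    chain_id: str
    sequence: str
    labels: str
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise AnnotationError(
                f"{self.chain_id}: labels length {len(self.labels)} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.labels) - set(STATES)
        if bad:
            raise AnnotationError(f"{self.chain_id}: unexpected labels {sorted(bad)}")
        if self.k < 0:
            raise AnnotationError("near-disorder width K must be >= 0")


def two_state_labels(chain: ChainAnnotation) -> str:
    """Map a resolved mask to a two-state {O,D} label string.

    Position ``i`` is D iff ``resolved[i]`` is False, else O.
    """
    return "".join(ORDER if r else DISORDER for r in chain.resolved)


def add_near_disorder(labels: str, k: int = DEFAULT_K) -> str:
    """Relabel the K boundary residues of every ordered run as near-disorder.

    For each maximal run of O of length m: if m > 2K the first K and last K
    positions become N; if m <= 2K the whole run becomes N (the two boundary
    windows would overlap, so the run has no interior).  D positions are
    never touched, and K=0 is the identity.  Runs abutting the chain termini
    are treated like any other ordered run.
    """
    bad = set(labels) - {ORDER, DISORDER}
    if bad:
        raise AnnotationError(f"two-state labels expected, got {sorted(bad)}")
    if k < 0:
        raise AnnotationError("near-disorder width K must be >= 0")
    if k == 0:
        return labels
    out = list(labels)
    for m in re.finditer(rf"{ORDER}+", labels):
        start, end = m.span()
        run = end - start
        if run <= 2 * k:
            out[start:end] = NEAR * run
        else:
            out[start : start + k] = NEAR * k
            out[end - k : end] = NEAR * k
    return "".join(out)


def label_chain(chain: ChainAnnotation, k: int = DEFAULT_K) -> LabeledChain:
    """Derive the three-state labeling of a chain from its resolved mask."""
    return LabeledChain(
        chain_id=chain.chain_id,
        sequence=chain.sequence,
        labels=add_near_disorder(two_state_labels(chain), k),
        k=k,
    )


def class_composition(chains: Iterable[LabeledChain]) -> tuple[int, int, int]:
    """Count (n_O, n_N, n_D) residues over a collection of labeled chains."""
    n_o = n_n = n_d = 0
    for c in chains:
        n_o += c.labels.count(ORDER)
        n_n += c.labels.count(NEAR)
        n_d += c.labels.count(DISORDER)
    return n_o, n_n, n_d


def composition_ratio(
    counts: Sequence[float], unit: int = -1
) -> tuple[float, ...]:
    """Normalize class counts so that ``counts[unit]`` equals 1.

    With two-state counts (n_O, n_D) and ``unit=-1`` this yields the
    order:disorder ratio as (r, 1.0); with three-state counts and ``unit=1``
    the near-disorder class is the unit, e.g. (6.9, 1.0, 0.6).
    """
    base = counts[unit]
    if base <= 0:
        raise AnnotationError("cannot normalize to a zero-count class")
    return tuple(c / base for c in counts)


# ---------------------------------------------------------------------------
# file input: query FASTA + resolved-index TSV


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AnnotationError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_resolved_tsv(path) -> dict[str, tuple[int, ...]]:
    """Read a two-column TSV of (chain_id, comma-separated 1-based resolved indices).

    An empty second column means no residue is resolved (fully disordered).
    """
    out: dict[str, tuple[int, ...]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AnnotationError(f"{path}:{ln}: expected 2 tab-separated columns")
            cid, idx = parts
            if cid in out:
                raise AnnotationError(f"{path}:{ln}: duplicate chain id {cid!r}")
            out[cid] = tuple(int(t) for t in idx.split(",") if t) if idx else ()
    return out


def annotations_from_files(fasta_path, resolved_path) -> list[ChainAnnotation]:
    """Pair a query FASTA with a resolved-index TSV into ChainAnnotations."""
    seqs = read_fasta(fasta_path)
    resolved = read_resolved_tsv(resolved_path)
    missing = set(seqs) - set(resolved)
    if missing:
        raise AnnotationError(f"no resolved-index entry for chains {sorted(missing)}")
    chains = []
    for cid, seq in seqs.items():
        mask = [False] * len(seq)
        for i in resolved[cid]:
            if not 1 <= i <= len(seq):
                raise AnnotationError(f"{cid}: resolved index {i} out of range 1..{len(seq)}")
            mask[i - 1] = True
        chains.append(ChainAnnotation(cid, seq, tuple(mask)))
    return chains


def write_resolved_tsv(chains: Iterable[ChainAnnotation], path) -> None:
    """Write the resolved-index TSV consumed by :func:`annotations_from_files`."""
    with open(path, "w") as fh:
        for c in chains:
            idx = ",".join(str(i + 1) for i, r in enumerate(c.resolved) if r)
            fh.write(f"{c.chain_id}\t{idx}\n")
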