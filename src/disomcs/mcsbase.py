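"""The MCSbase knowledge database: sequences paired with {O,N,D} state strings.

The on-disk dialect keeps the file a plain FASTA readable by any standard
parser: each record is two FASTA entries, ``>id`` with the amino-acid
sequence and ``>id|labels`` with the equal-length three-state label string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

from .annotation import AMINO_ALPHABET, STATES, LabeledChain

LABEL_SUFFIX = "|labels"
_WRAP = 60


class MCSFormatError(ValueError):
    """Raised for malformed MCSbase files or records."""


@dataclass(frozen=True)
class MCSRecord:
    """One database entry: a chain sequence and its per-residue state string."""

    id: str
    sequence: str
    labels: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise MCSFormatError(f"invalid record id {self.id!r}")
        if len(self.sequence) != len(self.labels):
            raise MCSFormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} "
                f"!= labels length {len(self.labels)}"
            )
        bad = set(self.labels) - set(STATES)
        if bad:
            raise MCSFormatError(f"record {self.id!r}: unexpected state symbols {sorted(bad)}")


class MCSDatabase:
    """An ordered collection of :class:`MCSRecord` with unique ids."""

    def __init__(self, records: Iterable[MCSRecord] = ()):
        self._records: list[MCSRecord] = []
        self._by_id: dict[str, MCSRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: MCSRecord) -> None:
        if rec.id in self._by_id:
            raise MCSFormatError(f"duplicate record id {rec.id!r}")
        self._records.append(rec)
        self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[MCSRecord]:
        return iter(self._records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    def __getitem__(self, rec_id: str) -> MCSRecord:
        try:
            return self._by_id[rec_id]
        except KeyError:
            raise KeyError(f"unknown record id {rec_id!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MCSDatabase):
            return NotImplemented
        return self._records == other._records

    @property
    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self._records)


def _wrap(s: str) -> str:
    return "\n".join(s[i : i + _WRAP] for i in range(0, len(s), _WRAP))


def write_mcsbase(db: MCSDatabase, path) -> None:
    """Serialize the database as paired FASTA entries with 60-column wrapping."""
    with open(path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.id}\n{_wrap(rec.sequence)}\n")
            fh.write(f">{rec.id}{LABEL_SUFFIX}\n{_wrap(rec.labels)}\n")


def read_mcsbase(path) -> MCSDatabase:
    """Read an MCSbase file, pairing ``id`` / ``id|labels`` entries by id.

    The two entries of a record may appear in either adjacent order; a
    missing partner, a length mismatch, or a duplicate id is an error naming
    the offending id.
    """
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    order: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id.endswith(LABEL_SUFFIX):
            rid = entry.id[: -len(LABEL_SUFFIX)]
            if rid in labels:
                raise MCSFormatError(f"duplicate labels entry for id {rid!r}")
            labels[rid] = str(entry.seq)
        else:
            rid = entry.id
            if rid in seqs:
                raise MCSFormatError(f"duplicate sequence entry for id {rid!r}")
            seqs[rid] = str(entry.seq).upper()
        if rid not in order:
            order.append(rid)
    db = MCSDatabase()
    for rid in order:
        if rid not in seqs:
            raise MCSFormatError(f"labels entry without sequence for id {rid!r}")
        if rid not in labels:
            raise MCSFormatError(f"sequence entry without labels for id {rid!r}")
        db.add(MCSRecord(rid, seqs[rid], labels[rid]))
    return db


def exclude_matches(db: MCSDatabase, queries: Iterable[str]) -> MCSDatabase:
    """Drop every record whose sequence exactly equals any query sequence.

    The comparison is case-insensitive and full-length; homologs that are
    merely similar are retained.  Used to keep evaluation fair when queries
    themselves were deposited in the database.
    """
    qset = {q.upper() for q in queries}
    return MCSDatabase(r for r in db if r.sequence.upper() not in qset)


def database_from_chains(chains: Iterable[LabeledChain]) -> MCSDatabase:
    """Build a database directly from three-state labeled chains."""
    return MCSDatabase(MCSRecord(c.chain_id, c.sequence, c.labels) for c in chains)
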