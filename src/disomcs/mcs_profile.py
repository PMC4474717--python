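"""Multi-Class Conservative Score (MCS) profiles.

For a query, local-alignment hits against the MCSbase are filtered by
e-value, ranked ascending, and the top S retained.  Walking each retained
alignment, the three-state label of every aligned subject residue is counted
into one of three boxes at the corresponding query position.  Normalizing
the boxes per position yields the MCS profile: an L x 3 matrix of
order/near-disorder/disorder probabilities, a PSSM-like summary of the
structural state of the query's homologs.

Positions never covered by a hit carry (0, 0, 0) rather than a uniform
distribution, so downstream models can distinguish "no homology signal"
from "balanced evidence".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import STATES
from .mcsbase import MCSDatabase

GAP = "-"
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


class HitError(ValueError):
    """Raised for inconsistent alignment hits."""


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment (HSP) between a query and a database subject.

    Coordinates are 1-based inclusive, BLAST tabular style; the aligned
    strings carry '-' for gaps and have equal length.
    """

    query_id: str
    subject_id: str
    e_value: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise HitError("e-value must be non-negative")
        if len(self.aligned_query) != len(self.aligned_subject):
            raise HitError(
                f"{self.query_id}/{self.subject_id}: aligned strings differ in length"
            )
        q_res = len(self.aligned_query) - self.aligned_query.count(GAP)
        s_res = len(self.aligned_subject) - self.aligned_subject.count(GAP)
        if q_res != self.query_end - self.query_start + 1:
            raise HitError(
                f"{self.query_id}/{self.subject_id}: query span "
                f"{self.query_start}-{self.query_end} != {q_res} aligned residues"
            )
        if s_res != self.subject_end - self.subject_start + 1:
            raise HitError(
                f"{self.query_id}/{self.subject_id}: subject span "
                f"{self.subject_start}-{self.subject_end} != {s_res} aligned residues"
            )


@dataclass(frozen=True)
class HitSelectionParams:
    """e-value cutoff and top-S truncation for hit selection."""

    e_threshold: float = 10.0
    s: int = 10

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.s < 1:
            raise ValueError("S must be >= 1")


@dataclass
class StateCounts:
    """Per-position integer boxes (O, N, D) accumulated over hits."""

    counts: np.ndarray  # (L, 3) int64

    @classmethod
    def zeros(cls, length: int) -> "StateCounts":
        return cls(np.zeros((length, 3), dtype=np.int64))


@dataclass(frozen=True)
class MCSProfile:
    """L x 3 per-position state probabilities with per-position hit coverage.

    Rows with coverage > 0 sum to 1; rows with coverage 0 are all zeros.
    """

    values: np.ndarray  # (L, 3) float64
    coverage: np.ndarray  # (L,) int64


def select_hits(
    hits: Iterable[AlignmentHit], params: HitSelectionParams | None = None
) -> list[AlignmentHit]:
    """Filter hits strictly below the e-value threshold and keep the top S.

    Survivors are sorted by ascending e-value; ties are broken by
    (subject_id, query_start) so selection is deterministic.  If fewer than
    S hits survive the filter, all of them are retained.
    """
    params = params or HitSelectionParams()
    kept = [h for h in hits if h.e_value < params.e_threshold]
    kept.sort(key=lambda h: (h.e_value, h.subject_id, h.query_start))
    return kept[: params.s]


def accumulate_counts(
    hit: AlignmentHit, subject_labels: str, counts: StateCounts
) -> StateCounts:
    """Add one hit's subject-state observations into the per-position boxes.

    Alignment columns are walked left to right with residue cursors starting
    at (query_start, subject_start).  A column where both symbols are
    residues contributes one count of the subject residue's state at the
    query position; a column with a gap on either side advances only the
    non-gap cursor and contributes nothing.
    """
    if len(subject_labels) < hit.subject_end:
        raise HitError(
            f"{hit.subject_id}: labels length {len(subject_labels)} "
            f"< subject_end {hit.subject_end}"
        )
    qpos = hit.query_start - 1  # 0-based
    spos = hit.subject_start - 1
    arr = counts.counts
    for qc, sc in zip(hit.aligned_query, hit.aligned_subject):
        if qc != GAP and sc != GAP:
            if qpos >= arr.shape[0]:
                raise HitError(
                    f"{hit.query_id}/{hit.subject_id}: query position "
                    f"{qpos + 1} beyond profile length {arr.shape[0]}"
                )
            arr[qpos, _STATE_INDEX[subject_labels[spos]]] += 1
            qpos += 1
            spos += 1
        elif qc != GAP:
            qpos += 1
        elif sc != GAP:
            spos += 1
    return counts


def compute_profile(counts: StateCounts) -> MCSProfile:
    """Normalize the per-position boxes to probabilities.

    MCS(p, s) = c(p, s) / sum_s' c(p, s') wherever the denominator is
    positive; zero-coverage rows stay (0, 0, 0).
    """
    arr = counts.counts
    coverage = arr.sum(axis=1)
    values = np.zeros(arr.shape, dtype=np.float64)
    covered = coverage > 0
    values[covered] = arr[covered] / coverage[covered, None]
    return MCSProfile(values=values, coverage=coverage)


def mcs_for_query(
    sequence: str,
    db: MCSDatabase,
    hits: Iterable[AlignmentHit],
    params: HitSelectionParams | None = None,
) -> MCSProfile:
    """Select hits, accumulate their subject states, and normalize."""
    counts = StateCounts.zeros(len(sequence))
    for hit in select_hits(hits, params):
        if hit.subject_id not in db:
            raise KeyError(f"hit subject {hit.subject_id!r} not in database")
        accumulate_counts(hit, db[hit.subject_id].labels, counts)
    return compute_profile(counts)


# ---------------------------------------------------------------------------
# PSI-BLAST tabular adapter
#
# Expected columns (outfmt "6 qseqid sseqid evalue qstart qend sstart send
# qseq sseq").  The documented external search mirrors the intended protocol
# (six PSI-BLAST iterations, 500 maximum target sequences against the
# MCSbase), but nothing in this package ever invokes BLAST itself.

_TAB_COLUMNS = 9


def read_hits_tsv(path) -> list[AlignmentHit]:
    """Parse BLAST-style tabular hits (9 columns, see module notes)."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _TAB_COLUMNS:
                raise HitError(
                    f"{path}:{ln}: expected {_TAB_COLUMNS} columns, got {len(parts)}"
                )
            qid, sid, ev, qs, qe, ss, se, qseq, sseq = parts
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    e_value=float(ev),
                    query_start=int(qs),
                    query_end=int(qe),
                    subject_start=int(ss),
                    subject_end=int(se),
                    aligned_query=qseq,
                    aligned_subject=sseq,
                )
            )
    return hits


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits in the same 9-column tabular layout the adapter reads."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        format(h.e_value, ".6g"),
                        str(h.query_start),
                        str(h.query_end),
                        str(h.subject_start),
                        str(h.subject_end),
                        h.aligned_query,
                        h.aligned_subject,
                    ]
                )
                + "\n"
            )
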