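"""Self-contained synthetic corpora for exercising every pipeline stage.

The generator emulates the salient statistics of crystallographic disorder
data: chains of 80-300 residues with roughly 5% disordered residues
concentrated in terminal and occasional internal segments, a composition
bias in disordered segments (enriched in P, E, S, K, G, Q; depleted in the
hydrophobic/aromatic W, C, F, I, Y, V), families of mutated homologs whose
copied state labels carry flip noise, a label-correlated but noisy
secondary-structure oracle, and local-alignment hits from a built-in
Smith-Waterman-style aligner (match +2, mismatch -1, gap open -5, extend
-1) with a pseudo e-value that orders hits by score.

Everything is reproducible from (config, seed), and the corpus writers emit
the exact file formats the production parsers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align

from .annotation import (
    DEFAULT_K,
    ChainAnnotation,
    add_near_disorder,
    two_state_labels,
    write_resolved_tsv,
)
from .mcsbase import MCSDatabase, MCSRecord, write_mcsbase
from .mcs_profile import AlignmentHit, write_hits_tsv
from .features import DEFAULT_SS_ALPHABET, SSAlphabet

AMINO = "ACDEFGHIKLMNPQRSTVWY"

# background residue frequencies, roughly UniProt-wide
_BASE_FREQ = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.0, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.3, "V": 6.9, "W": 1.1, "Y": 2.9,
}
_DISORDER_ENRICHED = set("PESKGQ")
_DISORDER_DEPLETED = set("WCFIYV")


def _composition_tables() -> tuple[np.ndarray, np.ndarray]:
    order = np.array([_BASE_FREQ[a] for a in AMINO])
    order /= order.sum()
    dis = np.array(
        [
            _BASE_FREQ[a] * (2.5 if a in _DISORDER_ENRICHED else 0.3 if a in _DISORDER_DEPLETED else 1.0)
            for a in AMINO
        ]
    )
    dis /= dis.sum()
    return order, dis


_ORDER_TABLE, _DISORDER_TABLE = _composition_tables()


@dataclass
class SynthConfig:
    """Knobs of the synthetic study conditions (defaults are the conditions)."""

    n_families: int = 30
    length_range: tuple[int, int] = (80, 300)
    disorder_target: float = 0.05
    terminal_disorder_prob: float = 0.6
    internal_segment_rate: float = 0.0008
    segment_length_mean: float = 8.0
    n_homologs: int = 15
    substitution_prob: float = 0.15
    indel_prob: float = 0.01
    label_flip_prob: float = 0.05
    ss_noise: float = 0.2
    k: int = DEFAULT_K
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not lo < hi:
            raise ValueError("length_range must satisfy min < max")
        for name in (
            "disorder_target",
            "terminal_disorder_prob",
            "internal_segment_rate",
            "substitution_prob",
            "indel_prob",
            "label_flip_prob",
            "ss_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ToyAlignParams:
    """Scoring of the built-in local aligner and its reporting threshold."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    min_score: float = 10.0


@dataclass
class SynthCorpus:
    """A full synthetic study: queries + database + SS strings + hits."""

    queries: list[ChainAnnotation]
    db: MCSDatabase
    ss: dict[str, str]
    hits: list[AlignmentHit]
    config: SynthConfig = field(default_factory=SynthConfig)

    def truth(self, chain_id: str) -> str:
        for q in self.queries:
            if q.chain_id == chain_id:
                return two_state_labels(q)
        raise KeyError(chain_id)


def generate_chain(rng: np.random.Generator, config: SynthConfig) -> tuple[str, str]:
    """One chain: sequence plus two-state {O,D} truth labels.

    Terminal disordered segments appear at each end with
    ``terminal_disorder_prob`` and geometric length; internal segments start
    at each residue with ``internal_segment_rate`` (a marked point process).
    Residue identities follow the ordered or disordered composition table.
    """
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    p_len = 1.0 / config.segment_length_mean
    mask = np.zeros(length, dtype=bool)
    if rng.random() < config.terminal_disorder_prob:
        mask[: min(length, int(rng.geometric(p_len)))] = True
    if rng.random() < config.terminal_disorder_prob:
        seg = min(length, int(rng.geometric(p_len)))
        mask[length - seg :] = True
    if config.internal_segment_rate > 0:
        for i in np.flatnonzero(rng.random(length) < config.internal_segment_rate):
            mask[i : i + int(rng.geometric(p_len))] = True
    aa_idx = np.where(
        mask,
        rng.choice(len(AMINO), size=length, p=_DISORDER_TABLE),
        rng.choice(len(AMINO), size=length, p=_ORDER_TABLE),
    )
    seq = "".join(AMINO[i] for i in aa_idx)
    labels = "".join("D" if m else "O" for m in mask)
    return seq, labels


def generate_family(
    rng: np.random.Generator, chain_id: str, sequence: str, labels: str, config: SynthConfig
) -> list[MCSRecord]:
    """Mutated homologs of a chain, with noisy copied labels, three-stated.

    Each homolog applies per-residue substitutions, rare single-residue
    indels (deletion or duplication, equally likely), and two-state label
    flips; the resulting labels are then widened with near-disorder at the
    configured K, exactly as real database entries would be.
    """
    records = []
    for j in range(config.n_homologs):
        s_chars: list[str] = []
        l_chars: list[str] = []
        for i, aa in enumerate(sequence):
            if rng.random() < config.indel_prob:
                if rng.random() < 0.5:
                    continue  # deletion
                s_chars.append(aa)  # duplication insertion, same label
                l_chars.append(labels[i])
            if rng.random() < config.substitution_prob:
                aa = AMINO[(AMINO.index(aa) + 1 + int(rng.integers(len(AMINO) - 1))) % len(AMINO)]
            lab = labels[i]
            if rng.random() < config.label_flip_prob:
                lab = "O" if lab == "D" else "D"
            s_chars.append(aa)
            l_chars.append(lab)
        if not s_chars:  # pathological all-deleted homolog
            s_chars, l_chars = list(sequence), list(labels)
        records.append(
            MCSRecord(
                id=f"{chain_id}_h{j}",
                sequence="".join(s_chars),
                labels=add_near_disorder("".join(l_chars), config.k),
            )
        )
    return records


def generate_ss(
    rng: np.random.Generator,
    labels: str,
    config: SynthConfig,
    alphabet: SSAlphabet = DEFAULT_SS_ALPHABET,
) -> str:
    """A noisy label-correlated secondary-structure string.

    Ordered runs emit blocks of H/E/T with geometric block lengths;
    disordered residues emit '-' or C.  Each symbol is then corrupted to a
    uniformly random alphabet symbol with probability ``ss_noise``.
    """
    out: list[str] = []
    i = 0
    length = len(labels)
    while i < length:
        if labels[i] == "D":
            out.append("-" if rng.random() < 0.5 else "C")
            i += 1
        else:
            elem = "HET"[int(rng.integers(3))]
            block = int(rng.geometric(1.0 / 6.0))
            while i < length and labels[i] == "O" and block > 0:
                out.append(elem)
                i += 1
                block -= 1
    noisy = [
        alphabet.symbols[int(rng.integers(9))] if rng.random() < config.ss_noise else s
        for s in out
    ]
    return "".join(noisy)


def _make_aligner(params: ToyAlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def pseudo_e_value(score: float, query_len: int, db_residues: int) -> float:
    """A monotone score-to-e-value map: e = m * n * 2^(-score/4).

    This preserves the ordering the hit-selection stage needs and scales
    with search-space size, without the full extreme-value statistics of a
    real sequence search.
    """
    return float(query_len) * float(db_residues) * 2.0 ** (-score / 4.0)


def toy_align(
    query_id: str,
    query: str,
    db: MCSDatabase,
    params: ToyAlignParams | None = None,
) -> list[AlignmentHit]:
    """Best local alignment per database subject, scored and e-valued.

    Alignments scoring at or below ``min_score`` are dropped.  The dynamic
    programming itself is delegated to Biopython's pairwise aligner
    configured with the scoring above.
    """
    params = params or ToyAlignParams()
    aligner = _make_aligner(params)
    n_db = db.total_residues
    hits: list[AlignmentHit] = []
    for rec in db:
        score = aligner.score(query, rec.sequence)
        if score <= params.min_score:
            continue
        aln = aligner.align(query, rec.sequence)[0]
        q_blocks, s_blocks = (np.asarray(b, dtype=int) for b in aln.aligned)
        aq: list[str] = []
        asub: list[str] = []
        prev_q, prev_s = int(q_blocks[0][0]), int(s_blocks[0][0])
        for (q0, q1), (s0, s1) in zip(q_blocks, s_blocks):
            if q0 > prev_q:  # residues of the query opposite a subject gap
                aq.append(query[prev_q:q0])
                asub.append("-" * (q0 - prev_q))
            if s0 > prev_s:
                aq.append("-" * (s0 - prev_s))
                asub.append(rec.sequence[prev_s:s0])
            aq.append(query[q0:q1])
            asub.append(rec.sequence[s0:s1])
            prev_q, prev_s = int(q1), int(s1)
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=rec.id,
                e_value=pseudo_e_value(float(score), len(query), n_db),
                query_start=int(q_blocks[0][0]) + 1,
                query_end=int(q_blocks[-1][1]),
                subject_start=int(s_blocks[0][0]) + 1,
                subject_end=int(s_blocks[-1][1]),
                aligned_query="".join(aq),
                aligned_subject="".join(asub),
            )
        )
    return hits


def generate_corpus(config: SynthConfig | None = None) -> SynthCorpus:
    """Compose chains, families, SS strings and hits into one corpus.

    Byte-identical output for identical (config, seed): all randomness flows
    through one seeded generator.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    queries: list[ChainAnnotation] = []
    db = MCSDatabase()
    ss: dict[str, str] = {}
    for i in range(config.n_families):
        cid = f"q{i:03d}"
        seq, labels = generate_chain(rng, config)
        queries.append(
            ChainAnnotation(cid, seq, tuple(c == "O" for c in labels))
        )
        for rec in generate_family(rng, cid, seq, labels, config):
            db.add(rec)
        ss[cid] = generate_ss(rng, labels, config)
    hits: list[AlignmentHit] = []
    for q in queries:
        hits.extend(toy_align(q.chain_id, q.sequence, db))
    return SynthCorpus(queries=queries, db=db, ss=ss, hits=hits, config=config)


def write_corpus(corpus: SynthCorpus, outdir) -> dict[str, Path]:
    """Write the corpus in the formats the production parsers read.

    Emits: queries.fasta, resolved.tsv (1-based resolved indices),
    mcsbase.fa (paired-FASTA dialect), ss.fasta, hits.tsv (BLAST-style
    9-column tabular).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "queries": outdir / "queries.fasta",
        "resolved": outdir / "resolved.tsv",
        "mcsbase": outdir / "mcsbase.fa",
        "ss": outdir / "ss.fasta",
        "hits": outdir / "hits.tsv",
    }
    with open(paths["queries"], "w") as fh:
        for q in corpus.queries:
            fh.write(f">{q.chain_id}\n")
            for i in range(0, len(q.sequence), 60):
                fh.write(q.sequence[i : i + 60] + "\n")
    write_resolved_tsv(corpus.queries, paths["resolved"])
    write_mcsbase(corpus.db, paths["mcsbase"])
    with open(paths["ss"], "w") as fh:
        for cid, s in corpus.ss.items():
            fh.write(f">{cid}\n{s}\n")
    write_hits_tsv(corpus.hits, paths["hits"])
    return paths
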