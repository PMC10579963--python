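"""Peptide corpora: FASTA I/O, validation, redundancy reduction and encoding.

A :class:`Corpus` is an ordered collection of short peptides over the 20
canonical amino acids.  Sequences are prepared for the character-level
language model by greedy identity-based clustering (CD-HIT style), padding
with the token ``X`` and appending an end-of-sequence token ``$``, giving a
22-symbol vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: Padding token, doubling as the start-of-sequence primer.
PAD = "X"
#: End-of-sequence token.
END = "$"

_CANONICAL_SET = frozenset(CANONICAL)


class CorpusError(ValueError):
    """Malformed corpus input (bad residue, duplicate id, parse failure)."""


@dataclass(frozen=True)
class Peptide:
    """A single peptide sequence with provenance.

    Parameters
    ----------
    id : str
        Unique identifier within a corpus.
    sequence : str
        Residues over the canonical 20-letter alphabet, upper case.
    provenance : str
        One of ``training``, ``generated``, ``random``, ``helical``,
        ``external``.
    """

    id: str
    sequence: str
    provenance: str = "external"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CorpusError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise CorpusError(
                f"peptide {self.id!r}: non-canonical residue(s) "
                f"{sorted(bad)!r} in sequence {self.sequence!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Corpus:
    """Ordered list of peptides with unique ids."""

    peptides: list[Peptide] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise CorpusError(f"duplicate peptide id {p.id!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def min_len(self) -> int:
        return min((len(p) for p in self.peptides), default=0)

    @property
    def max_len(self) -> int:
        return max((len(p) for p in self.peptides), default=0)


@dataclass(frozen=True)
class Vocabulary:
    """22-token vocabulary: 20 amino acids + pad/start ``X`` + end ``$``."""

    symbols: tuple[str, ...] = tuple(CANONICAL) + (PAD, END)

    def __post_init__(self) -> None:
        if len(self.symbols) != 22 or len(set(self.symbols)) != 22:
            raise ValueError("vocabulary must contain exactly 22 distinct symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def pad_index(self) -> int:
        return self.symbols.index(PAD)

    @property
    def end_index(self) -> int:
        return self.symbols.index(END)

    def index_of(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def encode_sequence(self, seq: str, window: int) -> list[int]:
        """Render ``X`` + seq + ``$`` padded with ``X`` to *window* tokens."""
        tokens = [PAD] + list(seq) + [END]
        if len(tokens) > window:
            raise CorpusError(
                f"window {window} too small for sequence of length {len(seq)}"
            )
        tokens += [PAD] * (window - len(tokens))
        return [self.index_of(t) for t in tokens]

    def decode_indices(self, indices: Iterable[int]) -> str:
        """Strip start/pad framing and return the residue string."""
        out = []
        for i, idx in enumerate(indices):
            sym = self.symbols[idx]
            if sym == END:
                break
            if sym == PAD:
                if i == 0:
                    continue  # start token
                break  # trailing padding
            out.append(sym)
        return "".join(out)


@dataclass
class EncodedBatch:
    """Token matrix plus loss mask for next-token training.

    ``loss_mask`` is False exactly at positions whose token is the padding
    symbol, so that when the matrix is shifted into (input, target) pairs the
    padding targets (and the initial start token) do not contribute to the
    loss.
    """

    token_matrix: np.ndarray  # (n_sequences, window) int
    loss_mask: np.ndarray  # (n_sequences, window) bool
    vocabulary: Vocabulary

    def __len__(self) -> int:
        return self.token_matrix.shape[0]

    @property
    def window(self) -> int:
        return self.token_matrix.shape[1]


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, provenance: str = "external") -> Corpus:
    """Read a FASTA file into a :class:`Corpus`.

    Headers become ids, sequences are upper-cased, record order is preserved.
    Raises :class:`CorpusError` for non-canonical residues, naming the record.
    """
    path = Path(path)
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        peptides.append(
            Peptide(id=record.id, sequence=str(record.seq).upper(), provenance=provenance)
        )
    if not peptides:
        logger.warning("read_fasta: no records found in %s", path)
    return Corpus(peptides)


def write_fasta(corpus: Corpus, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in corpus
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# Filtering and redundancy reduction


def length_filter(corpus: Corpus, min_len: int, max_len: int) -> Corpus:
    """Keep peptides with ``min_len <= length <= max_len`` (order preserved)."""
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length bounds ({min_len}, {max_len})")
    kept = [p for p in corpus if min_len <= len(p) <= max_len]
    logger.info("length_filter: %d -> %d peptides", len(corpus), len(kept))
    return Corpus(kept)


def _make_aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = 0.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap)
    aligner.extend_gap_score = -abs(gap)
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    gap_penalty: float = 0.0,
    denominator: str = "shorter",
) -> float:
    """Global-alignment sequence identity in ``[0, 1]``.

    Identity is the number of identically aligned positions in the optimal
    global alignment (match +1, mismatch 0, linear gap ``-gap_penalty``)
    divided by the length of the shorter sequence (CD-HIT convention) or by
    the alignment length when ``denominator='alignment'``.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aligner = _make_aligner(gap=gap_penalty)
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    if denominator == "shorter":
        denom = min(len(a), len(b))
    elif denominator == "alignment":
        denom = alignment.length
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return identities / denom


def redundancy_reduce(corpus: Corpus, threshold: float = 0.9) -> Corpus:
    """Greedy incremental clustering; returns cluster representatives.

    Peptides are visited in order of decreasing length (ties broken by id).
    A peptide joins the first existing cluster whose representative exceeds
    *threshold* identity, otherwise it founds a new cluster.  Mirrors the
    CD-HIT longest-first greedy strategy.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(corpus, key=lambda p: (-len(p), p.id))
    representatives: list[Peptide] = []
    for p in ordered:
        if not any(
            pairwise_identity(p.sequence, rep.sequence) > threshold
            for rep in representatives
        ):
            representatives.append(p)
    keep_ids = {p.id for p in representatives}
    kept = [p for p in corpus if p.id in keep_ids]
    logger.info(
        "redundancy_reduce: %d -> %d representatives at identity > %.2f",
        len(corpus), len(kept), threshold,
    )
    return Corpus(kept)


# ---------------------------------------------------------------------------
# Encoding


def encode(corpus: Corpus, vocabulary: Vocabulary | None = None,
           window: int | None = None, mask_padding: bool = True) -> EncodedBatch:
    """Encode a corpus into a padded token matrix with a loss mask.

    Each sequence becomes ``X`` (start) + residues + ``$`` + ``X``-padding to
    *window* tokens.  The default window is the longest sequence plus two
    (start and end tokens).
    """
    vocabulary = vocabulary or Vocabulary()
    needed = corpus.max_len + 2
    if window is None:
        window = needed
    if corpus.peptides and window < needed:
        longest = max(corpus, key=len)
        raise CorpusError(
            f"window {window} < {needed} required by peptide {longest.id!r}"
        )
    if not corpus.peptides:
        return EncodedBatch(
            token_matrix=np.zeros((0, window), dtype=np.int64),
            loss_mask=np.zeros((0, window), dtype=bool),
            vocabulary=vocabulary,
        )
    matrix = np.array(
        [vocabulary.encode_sequence(p.sequence, window) for p in corpus],
        dtype=np.int64,
    )
    if mask_padding:
        mask = matrix != vocabulary.pad_index
    else:
        mask = np.ones_like(matrix, dtype=bool)
        mask[:, 0] = False  # start token is never a prediction target
    return EncodedBatch(token_matrix=matrix, loss_mask=mask, vocabulary=vocabulary)


def decode(batch: EncodedBatch) -> list[str]:
    """Inverse of :func:`encode`: recover the residue strings."""
    return [batch.vocabulary.decode_indices(row) for row in batch.token_matrix]
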