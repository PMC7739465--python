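"""One-hot encoding of amino-acid sequences.

Every protein is represented as a fixed-size ``max_len x 21`` binary
matrix: the 20 canonical residues occupy channels 0-19 in alphabetical
order and channel 20 collects every non-canonical symbol (X, B, Z, U, O,
J, ``*``, ...). Sequences longer than ``max_len`` keep their first
``max_len`` residues; shorter ones are zero-padded at the tail, so a row
sums to one inside the encoded span and to zero in the padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical residues, alphabetical; channel 20 is the unknown channel.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
N_CHANNELS = len(ALPHABET) + 1
UNKNOWN_CHANNEL = len(ALPHABET)
MAX_LEN_DEFAULT = 2000

_CHANNEL_OF = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class SequenceEncoding:
    """Fixed-size one-hot matrix for one protein."""

    protein: str
    matrix: np.ndarray

    @property
    def length(self) -> int:
        """Number of encoded (non-padding) positions."""
        return int(self.matrix.sum())


def sequence_to_channels(seq: str, max_len: int = MAX_LEN_DEFAULT) -> np.ndarray:
    """Integer channel indices for the first ``max_len`` residues."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    seq = seq.upper()[:max_len]
    return np.fromiter(
        (_CHANNEL_OF.get(aa, UNKNOWN_CHANNEL) for aa in seq),
        dtype=np.int64,
        count=len(seq),
    )


def encode_sequence(
    seq: str, max_len: int = MAX_LEN_DEFAULT, protein: str = ""
) -> SequenceEncoding:
    """One-hot encode a sequence into a ``max_len x 21`` binary matrix."""
    channels = sequence_to_channels(seq, max_len=max_len)
    m = np.zeros((max_len, N_CHANNELS), dtype=np.float32)
    m[np.arange(len(channels)), channels] = 1.0
    return SequenceEncoding(protein=protein, matrix=m)


def decode_encoding(enc: SequenceEncoding) -> str:
    """Argmax-decode the nonzero rows; unknown channel decodes to ``X``."""
    letters = ALPHABET + "X"
    rows = enc.matrix[enc.matrix.sum(axis=1) > 0]
    return "".join(letters[i] for i in rows.argmax(axis=1))


def encode_batch(
    records, max_len: int = MAX_LEN_DEFAULT
) -> tuple[list, np.ndarray]:
    """Stack one-hot encodings for ``(id, sequence)`` pairs.

    Returns the id list and an ``(n, max_len, 21)`` float32 array.
    """
    ids = []
    mats = []
    for pid, seq in records:
        ids.append(pid)
        mats.append(encode_sequence(seq, max_len=max_len, protein=pid).matrix)
    return ids, np.stack(mats) if mats else np.zeros((0, max_len, N_CHANNELS), "f4")


def read_fasta(path) -> list:
    """Read FASTA records as ``(id, sequence)`` pairs.

    The id is the first whitespace token of the header; sequences are
    uppercased with gap characters removed. Records with empty sequences
    are skipped with a warning.
    """
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("-", "").replace(".", "")
        if not seq:
            logger.warning("skipping FASTA record %s: empty sequence", record.id)
            continue
        out.append((record.id, seq))
    return out
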