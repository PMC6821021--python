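"""Alignment input/output and serialisation of fitted Potts parameters.

Sequences are stored integer-encoded over a fixed 21-letter alphabet: the 20
standard amino acids in alphabetical one-letter-code order followed by the gap
symbol ``-`` (code 20).  Nonstandard residue letters (B, Z, X, J, U, O, and
anything else unrecognised) are mapped to the gap code rather than rejected,
treating the gap as just another symbol of the model.  Internal indices are
0-based throughout; file output (CASP RR) is 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
GAP_CODE = ALPHABET.index(GAP)

_ENCODE_LUT = np.full(256, GAP_CODE, dtype=np.int8)
for _code, _sym in enumerate(ALPHABET):
    _ENCODE_LUT[ord(_sym)] = _code
_ENCODE_LUT[ord(".")] = GAP_CODE


class MalformedAlignmentError(ValueError):
    """Raised when an alignment file is ragged, empty or unparseable."""


class ParameterFormatError(ValueError):
    """Raised when a parameter file is corrupted or inconsistent."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string into integer codes (gap/unknown -> 20)."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw].copy()


def decode_sequence(codes: np.ndarray, alphabet: str = ALPHABET) -> str:
    return "".join(alphabet[c] for c in np.asarray(codes))


@dataclass
class Alignment:
    """Integer-encoded multiple sequence alignment (M sequences x L columns).

    Attributes
    ----------
    sequences : ndarray of shape (M, L), int8
        Symbol codes in ``{0, ..., len(alphabet) - 1}``.
    ids : list of str
        Sequence identifiers, one per row.
    query_index : int
        Row index of the query sequence (default 0).
    alphabet : str
        Ordered symbol list; the production alphabet has 21 symbols with the
        gap last.
    """

    sequences: np.ndarray
    ids: list = field(default_factory=list)
    query_index: int = 0
    alphabet: str = ALPHABET

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise MalformedAlignmentError("alignment matrix must be 2-D")
        m, l = self.sequences.shape
        if m < 1 or l < 2:
            raise MalformedAlignmentError(
                f"alignment needs M >= 1 and L >= 2, got M={m}, L={l}"
            )
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(m)]
        if len(self.ids) != m:
            raise MalformedAlignmentError("number of ids does not match rows")
        q = len(self.alphabet)
        if len(set(self.alphabet)) != q:
            raise MalformedAlignmentError("alphabet symbols must be distinct")
        if self.sequences.min() < 0 or self.sequences.max() >= q:
            raise MalformedAlignmentError("symbol code outside alphabet range")
        if not 0 <= self.query_index < m:
            raise MalformedAlignmentError("query_index out of range")

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def row_string(self, m: int) -> str:
        return decode_sequence(self.sequences[m], self.alphabet)


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".a3m") or p.endswith(".a2m"):
        return "a3m"
    if p.endswith((".fa", ".fasta", ".afa", ".mfa", ".fas")):
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "flat"
    raise MalformedAlignmentError(f"empty alignment file: {path}")


def read_alignment(path, fmt: str | None = None, query_index: int = 0) -> Alignment:
    """Read an alignment file into an :class:`Alignment`.

    Parameters
    ----------
    path : path-like
        Input file.
    fmt : {"fasta", "a3m", "flat", None}
        File format; ``None`` infers from the extension / first character.
        ``a3m`` removes lowercase insert-state columns so every row matches
        the query's match-column length.  ``flat`` is one sequence per line.
    """
    fmt = fmt or _infer_format(path)
    ids, rows = [], []
    if fmt in ("fasta", "a3m"):
        for rec in SeqIO.parse(str(path), "fasta"):
            s = str(rec.seq)
            if fmt == "a3m":
                s = "".join(c for c in s if not c.islower() and c != ".")
            ids.append(rec.id)
            rows.append(s)
    elif fmt == "flat":
        with open(path) as fh:
            for k, line in enumerate(fh):
                line = line.strip()
                if line:
                    ids.append(f"seq{k}")
                    rows.append(line)
    else:
        raise ValueError(f"unknown alignment format: {fmt!r}")

    if not rows:
        raise MalformedAlignmentError(f"empty alignment file: {path}")
    length = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != length:
            raise MalformedAlignmentError(
                f"ragged alignment: record {rid!r} has length {len(row)}, "
                f"expected {length}"
            )
    mat = np.stack([encode_sequence(r) for r in rows])
    return Alignment(mat, ids=ids, query_index=query_index)


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i in range(aln.n_sequences):
            fh.write(f">{aln.ids[i]}\n{aln.row_string(i)}\n")


# ---------------------------------------------------------------------------
# CASP RR contact lists
# ---------------------------------------------------------------------------

def write_contacts_rr(contacts, length: int, path) -> None:
    """Write contacts as CASP RR-style lines ``i j 0 8 score`` (1-based, i<j).

    Lines are emitted in descending score order with a deterministic
    lexicographic ``(i, j)`` tie-break.  ``contacts`` is a ContactSet or any
    iterable of 0-based ``(i, j, score)`` triples.
    """
    entries = getattr(contacts, "entries", contacts)
    rows = []
    for i, j, s in entries:
        if not (0 <= i < j < length):
            raise ValueError(
                f"contact ({i}, {j}) out of range for length {length}"
            )
        rows.append((int(i), int(j), float(s)))
    rows.sort(key=lambda t: (-t[2], t[0], t[1]))
    with open(path, "w") as fh:
        for i, j, s in rows:
            fh.write(f"{i + 1} {j + 1} 0 8 {s:.6f}\n")


def read_contacts_rr(path):
    """Read a CASP RR-style file back into a list of 0-based (i, j, score)."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] in ("PFRMAT", "TARGET", "MODEL", "END"):
                continue
            if len(parts) < 5:
                raise ValueError(f"malformed RR line: {line.rstrip()!r}")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            out.append((i, j, float(parts[4])))
    return out


# ---------------------------------------------------------------------------
# Potts parameter container (plain text, exact round trip)
# ---------------------------------------------------------------------------

_PARAM_MAGIC = "# clmdca potts parameters v1"


def save_parameters(params, path) -> None:
    """Serialise Potts parameters to a self-describing plain-text file.

    Layout: a versioned header declaring L, q and the alphabet, then L lines
    of q field values h_i(a), then for every pair i<j (lexicographic order)
    q lines of q coupling values e_ij(a, b).  Values are printed with 17
    significant digits so the round trip is bit-exact for float64.
    """
    if params.q <= len(ALPHABET):
        alpha = ALPHABET[: params.q]
    else:
        raise ValueError("cannot serialise alphabets larger than 21 symbols")
    buf = io.StringIO()
    buf.write(f"{_PARAM_MAGIC}\n")
    buf.write(f"# L {params.length} q {params.q}\n")
    buf.write(f"# alphabet {alpha}\n")
    np.savetxt(buf, params.h, fmt="%.17g")
    np.savetxt(buf, params.e.reshape(-1, params.q), fmt="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_parameters(path):
    """Load a parameter file written by :func:`save_parameters`."""
    from .potts_model import PottsParameters

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _PARAM_MAGIC:
        raise ParameterFormatError(f"not a clmdca parameter file: {path}")
    try:
        header = lines[1].split()
        length, q = int(header[2]), int(header[4])
    except (IndexError, ValueError) as exc:
        raise ParameterFormatError("malformed parameter header") from exc
    body = [ln for ln in lines[2:] if ln and not ln.startswith("#")]
    n_pairs = length * (length - 1) // 2
    expected = length + n_pairs * q
    if len(body) != expected:
        raise ParameterFormatError(
            f"parameter file declares L={length}, q={q} "
            f"({expected} value rows) but contains {len(body)}"
        )
    try:
        mat = np.array([[float(v) for v in ln.split()] for ln in body])
    except ValueError as exc:
        raise ParameterFormatError("non-numeric value in parameter file") from exc
    if mat.shape[1] != q:
        raise ParameterFormatError("row width does not match declared q")
    h = mat[:length]
    e = mat[length:].reshape(n_pairs, q, q)
    return PottsParameters(h=h, e=e)
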