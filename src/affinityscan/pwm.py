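"""Position weight matrices and background base composition.

A PWM here is a probability matrix: for each of its ``l`` positions, the
probability of observing A, C, G or T.  Matrices arrive either as JASPAR-style
count matrices (counts of each base in an alignment of known sites) or as
probability matrices; both are converted to strictly positive probability
columns so that likelihood ratios are always finite.

Zero handling follows common motif-database practice: zero *counts* become a
count of one before normalization, while zero *probabilities* receive a fixed
1e-6 pseudocount (chosen to be smaller than the smallest non-zero probability
found in public collections) followed by column renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# complement in index space: A<->T, C<->G
COMPLEMENT_IDX = np.array([3, 2, 1, 0])

PROB_PSEUDOCOUNT = 1e-6
COLUMN_SUM_ATOL = 1e-9


class PWMParseError(ValueError):
    """Raised when a matrix file cannot be parsed into a valid 4 x l matrix."""


@dataclass(frozen=True)
class PWM:
    """A probability matrix over A/C/G/T at each of ``l`` motif positions.

    ``matrix`` has shape (4, l); rows are A, C, G, T in that order.  Every
    entry is strictly positive and every column sums to 1 (within 1e-9).
    ``source_kind`` records whether the matrix was built from counts or from
    probabilities, which determines the pseudocount policy that was applied.
    """

    name: str
    matrix: np.ndarray
    source_kind: str = "probabilities"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be 4 x l with l >= 1, got shape {m.shape}")
        if not np.all(m > 0):
            raise ValueError(f"PWM {self.name!r}: all probabilities must be strictly positive")
        colsums = m.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=COLUMN_SUM_ATOL, rtol=0):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1, got {colsums}")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def information_content(self) -> float:
        """Mean per-position information content in bits (2 + sum p log2 p)."""
        m = self.matrix
        return float(np.mean(2.0 + np.sum(m * np.log2(m), axis=0)))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=0))


@dataclass(frozen=True)
class Background:
    """Genome-wide (or intergenic) mono-nucleotide frequencies A, C, G, T."""

    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError(f"Background needs 4 frequencies, got shape {f.shape}")
        if not np.all(f > 0):
            raise ValueError("Background frequencies must be strictly positive")
        if not np.isclose(f.sum(), 1.0, atol=COLUMN_SUM_ATOL, rtol=0):
            raise ValueError(f"Background frequencies must sum to 1, got {f.sum()}")
        f.flags.writeable = False
        object.__setattr__(self, "freqs", f)


def _normalize_columns(matrix: np.ndarray) -> np.ndarray:
    return matrix / matrix.sum(axis=0, keepdims=True)


def _parse_matrix_lines(lines: list[str], path: str) -> tuple[str, np.ndarray]:
    """Parse a JASPAR-style block: optional '>' header plus 4 numeric rows.

    Rows may be bare numbers or the bracketed dialect ``A [ 4 19 0 ... ]``.
    Returns (name, 4 x l array) with rows in A/C/G/T order.
    """
    name = Path(path).stem
    rows: list[tuple[str | None, np.ndarray]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else name
            continue
        label: str | None = None
        body = line
        head = line.split(None, 1)[0]
        if head.rstrip(":").upper() in BASE_INDEX and (len(head) == 1 or head.endswith(":")):
            label = head.rstrip(":").upper()
            body = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
        body = body.replace("[", " ").replace("]", " ")
        try:
            values = np.array([float(tok) for tok in body.split()], dtype=float)
        except ValueError as exc:
            raise PWMParseError(f"{path}:{lineno}: cannot parse numeric row: {raw.rstrip()!r}") from exc
        if values.size == 0:
            raise PWMParseError(f"{path}:{lineno}: empty matrix row: {raw.rstrip()!r}")
        if np.any(values < 0):
            raise PWMParseError(f"{path}:{lineno}: negative entry in row: {raw.rstrip()!r}")
        rows.append((label, values))

    if len(rows) != 4:
        raise PWMParseError(f"{path}: expected 4 base rows, found {len(rows)}")
    lengths = {r[1].size for r in rows}
    if len(lengths) != 1:
        raise PWMParseError(f"{path}: rows have unequal lengths {sorted(lengths)}")

    labels = [r[0] for r in rows]
    matrix = np.vstack([r[1] for r in rows])
    if all(lbl is not None for lbl in labels):
        if sorted(labels) != list(BASES):
            raise PWMParseError(f"{path}: row labels must be A, C, G, T; got {labels}")
        order = [labels.index(b) for b in BASES]
        matrix = matrix[order]
    return name, matrix


def read_pwm_counts(path: str | Path) -> PWM:
    """Read a JASPAR-format count matrix and convert it to probabilities.

    Zero counts are replaced by one (so no base is ever impossible), then each
    column is normalized to sum to 1.
    """
    lines = Path(path).read_text().splitlines()
    name, counts = _parse_matrix_lines(lines, str(path))
    if not np.allclose(counts, np.round(counts)):
        raise PWMParseError(f"{path}: count matrix has non-integer entries")
    counts = np.where(counts == 0, 1.0, counts)
    return PWM(name=name, matrix=_normalize_columns(counts), source_kind="counts")


def read_pwm_probs(path: str | Path) -> PWM:
    """Read a probability matrix (TSV rows labeled A/C/G/T, or JASPAR layout).

    Exact zeroes get a 1e-6 pseudocount and columns are renormalized.  A
    warning is emitted when the pseudocount is not smaller than the smallest
    non-zero probability of the matrix (the pseudocount is then distorting
    rather than just regularizing).
    """
    lines = Path(path).read_text().splitlines()
    name, probs = _parse_matrix_lines(lines, str(path))
    colsums = probs.sum(axis=0)
    bad = np.abs(colsums - 1.0) > 0.01
    if np.any(bad):
        raise PWMParseError(
            f"{path}: probability columns {np.flatnonzero(bad).tolist()} sum to "
            f"{colsums[bad].tolist()}, expected 1 within 0.01"
        )
    nonzero = probs[probs > 0]
    if nonzero.size and nonzero.min() <= PROB_PSEUDOCOUNT:
        warnings.warn(
            f"{path}: smallest non-zero probability {nonzero.min():g} is not larger "
            f"than the pseudocount {PROB_PSEUDOCOUNT:g}",
            stacklevel=2,
        )
    probs = np.where(probs == 0, PROB_PSEUDOCOUNT, probs)
    return PWM(name=name, matrix=_normalize_columns(probs), source_kind="probabilities")


def shuffle_pwm(pwm: PWM, seed: int) -> PWM:
    """Randomly permute the PWM's positions (columns).

    The column multiset -- hence the base composition of the motif -- is
    preserved; only the positional structure is destroyed.  Used as a negative
    control for motif-specific predictive power.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.length)
    return PWM(name=f"{pwm.name}_shuf", matrix=pwm.matrix[:, perm], source_kind=pwm.source_kind)


def background_from_fasta(path: str | Path) -> Background:
    """Estimate background base frequencies from FASTA sequence.

    Counts A/C/G/T case-insensitively across all records, skipping N and other
    ambiguity codes; a base never observed is floored at a count of one.
    """
    counts = np.zeros(4, dtype=float)
    n_records = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                n_records += 1
                continue
            for ch in line.upper():
                idx = BASE_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
    if n_records == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if counts.sum() == 0:
        raise ValueError(f"{path}: no unambiguous A/C/G/T bases found")
    counts = np.where(counts == 0, 1.0, counts)
    return Background(freqs=counts / counts.sum())
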