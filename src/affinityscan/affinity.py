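"""Window scores, total binding affinity (TBA) and cutoff occupancy.

The model scores every length-``l`` window of a sequence against a PWM as the
likelihood ratio of the motif model to a background composition, taking the
better of the two orientations (the factor can bind either strand).  In log
space (natural log throughout):

    score(window) = log max( prod_j P(w_j, r_j) / P(b, r_j),
                             prod_j P(w_{l-j+1}, r'_j) / P(b, r_j) )

where r'_j is the complementary base.  Note the background term always uses
the plus-strand base, so the score is a ratio of two models of the *observed*
plus-strand window.

TBA is the log of the sum of the exponentiated window scores over all
L - l + 1 windows -- a cutoff-free, sequence-level affinity in which weak
sites contribute proportionally to their likelihood ratio.  Occupancy
restricts the sum to windows scoring at least ``C * S_max`` where S_max is
the best score the PWM can achieve; at C = 1 only top-scoring sites remain.

Windows containing N or masked positions are skipped entirely; a sequence
with no scorable window is an error for TBA (distinct from a low affinity),
while an occupancy sum with no passing window is the -inf sentinel (log 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from affinityscan.pwm import BASE_INDEX, COMPLEMENT_IDX, PWM, Background

# Relative tolerance on the C * S_max threshold: guarantees the top-scoring
# window itself passes at C = 1 despite floating-point rounding.
CUTOFF_RTOL = 1e-9

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


class NoScorableWindowError(ValueError):
    """Sequence has no window free of N/masked bases: affinity is undefined."""


class UnscorableWindowError(ValueError):
    """A single window passed to window_score contains N or masked bases."""


@dataclass
class SequenceRecord:
    """A DNA sequence with an optional set of masked (unscorable) positions."""

    id: str
    bases: str
    mask: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.mask = frozenset(self.mask)
        if self.mask and (min(self.mask) < 0 or max(self.mask) >= len(self.bases)):
            raise ValueError(f"sequence {self.id!r}: mask positions out of bounds")

    def __len__(self) -> int:
        return len(self.bases)

    def codes(self) -> np.ndarray:
        """Sequence as int codes A=0 C=1 G=2 T=3; N/masked positions are -1."""
        codes = _ENCODE[np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)].copy()
        if self.mask:
            codes[list(self.mask)] = -1
        return codes

    def reverse_complement(self) -> "SequenceRecord":
        comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
        n = len(self.bases)
        return SequenceRecord(
            id=self.id,
            bases=self.bases.translate(comp)[::-1],
            mask=frozenset(n - 1 - p for p in self.mask),
        )


@dataclass(frozen=True)
class AffinityValue:
    """A log-scale affinity/occupancy with bookkeeping on the windows used."""

    value: float
    n_windows_used: int
    n_sites_passing: int | None = None


@dataclass(frozen=True)
class CutoffGrid:
    """Ordered score-cutoff fractions C in (0, 1]; default 0.1, 0.2, ..., 1."""

    values: tuple[float, ...] = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))

    def __post_init__(self) -> None:
        v = tuple(float(c) for c in self.values)
        if not v:
            raise ValueError("cutoff grid is empty")
        if any(not 0 < c <= 1 for c in v):
            raise ValueError(f"cutoffs must lie in (0, 1]: {v}")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError(f"cutoffs must be strictly increasing: {v}")
        object.__setattr__(self, "values", v)

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _log_odds(pwm: PWM, bg: Background) -> tuple[np.ndarray, np.ndarray]:
    """Per-position log-odds for both orientations, indexed by plus-strand base.

    fwd[j, b] = log P(w_j, b) - log P(bg, b)
    rev[j, b] = log P(w_{l-j+1}, comp(b)) - log P(bg, b)

    so a window's orientation scores are plain sums over its plus-strand codes.
    """
    logm = np.log(pwm.matrix)  # (4, l)
    logbg = np.log(bg.freqs)  # (4,)
    fwd = (logm - logbg[:, None]).T  # (l, 4)
    rev = (logm[COMPLEMENT_IDX, ::-1] - logbg[:, None]).T
    return fwd, rev


def _window_scores(pwm: PWM, seq: SequenceRecord, bg: Background) -> np.ndarray:
    """Scores of all L - l + 1 windows; NaN where a window is unscorable."""
    l = pwm.length
    codes = seq.codes()
    L = codes.size
    if L < l:
        return np.empty(0)
    fwd, rev = _log_odds(pwm, bg)
    safe = np.where(codes < 0, 0, codes)
    windows = np.lib.stride_tricks.sliding_window_view(safe, l)  # (L-l+1, l)
    pos = np.arange(l)
    scores = np.maximum(fwd[pos, windows].sum(axis=1), rev[pos, windows].sum(axis=1))
    invalid = np.lib.stride_tricks.sliding_window_view(codes < 0, l).any(axis=1)
    scores[invalid] = np.nan
    return scores


def window_score(pwm: PWM, window: str | SequenceRecord, bg: Background | None = None) -> float:
    """Log-likelihood-ratio score of a single window of length l.

    The score is the max over the two orientations; natural log.
    """
    bg = bg or Background()
    if isinstance(window, str):
        window = SequenceRecord(id="window", bases=window)
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    scores = _window_scores(pwm, window, bg)
    if np.isnan(scores[0]):
        raise UnscorableWindowError(f"window {window.bases!r} contains N or masked bases")
    return float(scores[0])


def s_max(pwm: PWM, bg: Background | None = None) -> float:
    """Maximum achievable window score for a PWM against a background.

    Each orientation's score is a sum of independent per-position terms, so
    its maximum is the sum of per-position maxima; the overall maximum takes
    the better orientation.  (With a non-uniform background the two can
    differ, since the background term follows the plus strand.)
    """
    bg = bg or Background()
    fwd, rev = _log_odds(pwm, bg)
    return float(max(fwd.max(axis=1).sum(), rev.max(axis=1).sum()))


def tba(pwm: PWM, seq: SequenceRecord, bg: Background | None = None) -> AffinityValue:
    """Total binding affinity: log sum over usable windows of exp(score)."""
    bg = bg or Background()
    scores = _window_scores(pwm, seq, bg)
    usable = scores[~np.isnan(scores)]
    if usable.size == 0:
        raise NoScorableWindowError(
            f"sequence {seq.id!r} (length {len(seq)}) has no scorable window for "
            f"PWM {pwm.name!r} (length {pwm.length})"
        )
    return AffinityValue(value=float(logsumexp(usable)), n_windows_used=int(usable.size))


def occupancy(pwm: PWM, seq: SequenceRecord, bg: Background | None = None, cutoff: float = 0.8) -> AffinityValue:
    """TBA restricted to windows scoring at least ``cutoff * s_max``.

    Returns -inf (empty sum) when no window passes; this is a legitimate
    "no predicted site" value, not an error.
    """
    bg = bg or Background()
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    scores = _window_scores(pwm, seq, bg)
    usable = scores[~np.isnan(scores)]
    if usable.size == 0:
        raise NoScorableWindowError(
            f"sequence {seq.id!r} has no scorable window for PWM {pwm.name!r}"
        )
    threshold = cutoff * s_max(pwm, bg)
    passing = usable[usable >= threshold - CUTOFF_RTOL * max(1.0, abs(threshold))]
    value = float(logsumexp(passing)) if passing.size else float("-inf")
    return AffinityValue(
        value=value,
        n_windows_used=int(usable.size),
        n_sites_passing=int(passing.size),
    )


def sum_of_scores(pwm: PWM, seq: SequenceRecord, bg: Background | None = None, cutoff: float = 0.8) -> float:
    """Sum of raw window log-scores above the cutoff (site-list style baseline).

    Unlike occupancy this adds log scores arithmetically instead of summing
    likelihood ratios; it emulates scoring a sequence by the sum of its
    called sites' scores.  Returns 0.0 when no window passes.
    """
    bg = bg or Background()
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    scores = _window_scores(pwm, seq, bg)
    usable = scores[~np.isnan(scores)]
    if usable.size == 0:
        raise NoScorableWindowError(
            f"sequence {seq.id!r} has no scorable window for PWM {pwm.name!r}"
        )
    threshold = cutoff * s_max(pwm, bg)
    passing = usable[usable >= threshold - CUTOFF_RTOL * max(1.0, abs(threshold))]
    return float(passing.sum()) if passing.size else 0.0


@dataclass
class ScoreMatrix:
    """Regions x PWMs table of affinity values plus per-cell failure reasons.

    ``values`` is a DataFrame indexed by sequence id with one column per PWM;
    cells that could not be scored are NaN and the reason is recorded in
    ``missing`` keyed by (sequence id, PWM name).  -inf is a real value
    (empty occupancy), not a missing cell.
    """

    values: pd.DataFrame
    mode: str
    cutoff: float | None = None
    missing: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sequence_id", float_format="%.10g")

    @staticmethod
    def read_tsv(path, mode: str = "tba", cutoff: float | None = None) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sequence_id")
        return ScoreMatrix(values=df, mode=mode, cutoff=cutoff)


_MODES = ("tba", "occupancy", "sum_of_scores")


def score_matrix(
    pwms: list[PWM],
    seqs: list[SequenceRecord],
    bg: Background | None = None,
    mode: str = "tba",
    cutoff: float | None = None,
) -> ScoreMatrix:
    """Score every sequence against every PWM into a regions x PWMs table."""
    bg = bg or Background()
    if not pwms:
        raise ValueError("empty PWM list")
    if not seqs:
        raise ValueError("empty sequence list")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode != "tba" and cutoff is None:
        raise ValueError(f"mode {mode!r} requires a cutoff")

    values = np.full((len(seqs), len(pwms)), np.nan)
    missing: dict[tuple[str, str], str] = {}
    for j, pwm in enumerate(pwms):
        for i, seq in enumerate(seqs):
            try:
                if mode == "tba":
                    values[i, j] = tba(pwm, seq, bg).value
                elif mode == "occupancy":
                    values[i, j] = occupancy(pwm, seq, bg, cutoff).value
                else:
                    values[i, j] = sum_of_scores(pwm, seq, bg, cutoff)
            except NoScorableWindowError as exc:
                missing[(seq.id, pwm.name)] = str(exc)
    df = pd.DataFrame(values, index=[s.id for s in seqs], columns=[p.name for p in pwms])
    return ScoreMatrix(values=df, mode=mode, cutoff=cutoff, missing=missing)
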