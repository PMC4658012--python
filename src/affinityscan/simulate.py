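"""Synthetic fixtures: PWMs, planted-motif benchmarks, segmentations, expression.

Everything downstream of the scoring core is exercised offline with data
generated here.  The binding benchmark emulates the statistical structure of
a ChIP-seq evaluation: positive sequences are background DNA with k motif
instances planted at random non-overlapping positions and orientations,
negatives are pure background of the same length.  Site instances are drawn
from the PWM itself under a sampling temperature, so the benchmark contains
the mixture of strong and weak sites that makes cutoff-free scoring matter.
Expression is simulated forward from the log-linear model so the full
normalize -> fit path can be tested end to end.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from affinityscan.affinity import ScoreMatrix, SequenceRecord
from affinityscan.pwm import BASES, PWM, Background
from affinityscan.regions import ChromatinSegment

#: the 13 open + 2 closed labels of the 15-state chromatin vocabulary
OPEN_STATE_LABELS = (
    "Active Promoter",
    "Weak Promoter",
    "Poised Promoter",
    "Strong Enhancer",
    "Strong Enhancer 2",
    "Weak Enhancer",
    "Weak Enhancer 2",
    "Insulator",
    "Txn Transition",
    "Txn Elongation",
    "Weak Txn",
    "Repetitive/CNV",
    "Repetitive/CNV 2",
)
CLOSED_STATE_LABELS = ("Polycomb repressed", "Heterochrom; low signal")


@dataclass
class SimConfig:
    """Study conditions for a planted-motif binding benchmark.

    ``site_strength`` is the sampling temperature for drawing site instances
    from the PWM: 1 samples faithfully from the motif's position
    distributions, 0 always inserts the consensus, and values between
    sharpen the distribution toward the consensus.
    """

    seed: int = 0
    n_pos: int = 300
    n_neg: int = 300
    L: int = 500
    k: int = 3
    site_strength: float = 1.0
    bg: Background = field(default_factory=Background)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("sequence counts must be >= 1")
        if not 0 <= self.site_strength:
            raise ValueError("site_strength must be >= 0")


def _column_ic(p: np.ndarray) -> float:
    return float(2.0 + np.sum(p * np.log2(p)))


def make_pwm(seed: int, l: int, information_content_target: float) -> PWM:
    """Random PWM with a given mean per-position information content (bits).

    Each column is a Dirichlet draw sharpened toward a random consensus base;
    the sharpening weight is bisected per column so the mean per-position
    information content lands within 0.1 bits of the target.  Targets at or
    above 2 bits are unreachable with strictly positive probabilities.
    """
    if l < 1:
        raise ValueError("PWM length must be >= 1")
    if not 0 <= information_content_target < 2.0:
        raise ValueError(
            f"information content target must be in [0, 2) bits, got {information_content_target}"
        )
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(l):
        base_col = rng.dirichlet(np.full(4, 5.0))
        consensus = np.zeros(4)
        consensus[rng.integers(4)] = 1.0
        uniform = np.full(4, 0.25)
        # blend toward the consensus to raise IC, or toward uniform to lower it
        target_dir = consensus if _column_ic(base_col) < information_content_target else uniform

        def ic_at(t: float) -> float:
            p = (1 - t) * base_col + t * target_dir
            p = np.maximum(p, 1e-9)
            return _column_ic(p / p.sum())

        lo, hi = 0.0, 1.0 - 1e-9
        for _ in range(60):
            mid = (lo + hi) / 2
            if (ic_at(mid) < information_content_target) == (target_dir is consensus):
                lo = mid
            else:
                hi = mid
        t = hi
        p = (1 - t) * base_col + t * target_dir
        p = np.maximum(p, 1e-9)
        cols.append(p / p.sum())
    return PWM(name=f"sim_pwm_s{seed}_l{l}", matrix=np.column_stack(cols))


def _sample_background(rng: np.random.Generator, n: int, L: int, bg: Background) -> list[str]:
    codes = rng.choice(4, size=(n, L), p=bg.freqs)
    lookup = np.array(list(BASES))
    return ["".join(lookup[row]) for row in codes]


def sample_site(rng: np.random.Generator, pwm: PWM, site_strength: float = 1.0) -> str:
    """Draw one site instance from the PWM under a sampling temperature."""
    out = []
    for j in range(pwm.length):
        p = pwm.matrix[:, j]
        if site_strength == 0:
            idx = int(np.argmax(p))
        else:
            w = p ** (1.0 / site_strength)
            idx = int(rng.choice(4, p=w / w.sum()))
        out.append(BASES[idx])
    return "".join(out)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def plant_sites(
    rng: np.random.Generator,
    sequence: str,
    pwm: PWM,
    k: int,
    site_strength: float = 1.0,
) -> tuple[str, list[int]]:
    """Insert k non-overlapping PWM instances (random orientation) into a sequence."""
    L, l = len(sequence), pwm.length
    if k * l > L:
        raise ValueError(f"cannot fit {k} sites of length {l} in {L} bp")
    starts: list[int] = []
    attempts = 0
    while len(starts) < k:
        attempts += 1
        if attempts > 10000 * k:
            raise ValueError(f"failed to place {k} non-overlapping sites of length {l} in {L} bp")
        pos = int(rng.integers(0, L - l + 1))
        if all(pos + l <= s or pos >= s + l for s in starts):
            starts.append(pos)
    seq = list(sequence)
    for pos in sorted(starts):
        site = sample_site(rng, pwm, site_strength)
        if rng.random() < 0.5:
            site = _revcomp(site)
        seq[pos : pos + pwm.length] = site
    return "".join(seq), sorted(starts)


def make_binding_benchmark(
    cfg: SimConfig, pwm: PWM
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, list[int]]]:
    """Planted-motif positives and length-matched background negatives.

    Returns (positives, negatives, site coordinates per positive id).
    """
    if cfg.L < pwm.length:
        raise ValueError(f"sequence length {cfg.L} < PWM length {pwm.length}")
    rng = np.random.default_rng(cfg.seed)
    negatives = [
        SequenceRecord(id=f"neg_{i}", bases=s)
        for i, s in enumerate(_sample_background(rng, cfg.n_neg, cfg.L, cfg.bg))
    ]
    positives = []
    coords: dict[str, list[int]] = {}
    for i, s in enumerate(_sample_background(rng, cfg.n_pos, cfg.L, cfg.bg)):
        planted, starts = plant_sites(rng, s, pwm, cfg.k, cfg.site_strength)
        rec = SequenceRecord(id=f"pos_{i}", bases=planted)
        positives.append(rec)
        coords[rec.id] = starts
    return positives, negatives, coords


def make_expression(
    design: ScoreMatrix | pd.DataFrame,
    coefficients: np.ndarray | pd.Series,
    intercept: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    name: str = "sim",
) -> pd.DataFrame:
    """Simulate raw expression from the log-linear model over a design matrix.

    Log2 expression is design @ coefficients + intercept + Normal(0, sd); the
    returned table is on the raw scale, shifted so its minimum is exactly zero
    (one gene at the detection floor).  Passing the table through
    normalize_expression recovers the simulated log2 values up to the small
    distortion of the pseudo-count, which is the second-smallest raw value.
    """
    X = design.values if isinstance(design, ScoreMatrix) else design
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (X.shape[1],):
        raise ValueError(f"need {X.shape[1]} coefficients, got shape {c.shape}")
    rng = np.random.default_rng(seed)
    e = X.to_numpy() @ c + intercept + rng.normal(0.0, noise_sd, size=len(X))
    raw = np.maximum(np.exp2(e) - np.exp2(e).min(), 0.0)
    return pd.DataFrame({name: raw}, index=X.index)


def noise_sd_for_snr(design: ScoreMatrix | pd.DataFrame, coefficients, snr: float = 1.0) -> float:
    """Noise standard deviation giving Var(signal)/Var(noise) = snr."""
    X = design.values if isinstance(design, ScoreMatrix) else design
    signal = X.to_numpy() @ np.asarray(coefficients, dtype=float)
    return float(signal.std(ddof=0) / np.sqrt(snr))


def make_chromatin(
    seed: int, chrom_len: int, mean_seg_len: int, closed_fraction: float, chrom: str = "chrSim"
) -> list[ChromatinSegment]:
    """Random chromatin segmentation tiling [0, chrom_len) exactly.

    Segment lengths are exponential with the given mean (floored at 1 bp);
    each segment is closed with probability ``closed_fraction`` (one of the 2
    closed labels) and open otherwise (one of the 13 open labels), so closed
    states cover about that fraction of the chromosome.
    """
    if chrom_len < mean_seg_len:
        raise ValueError("chrom_len must be >= mean_seg_len")
    if not 0 <= closed_fraction <= 1:
        raise ValueError("closed_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    segments: list[ChromatinSegment] = []
    pos = 0
    while pos < chrom_len:
        length = max(1, int(rng.exponential(mean_seg_len)))
        end = min(pos + length, chrom_len)
        if rng.random() < closed_fraction:
            state = CLOSED_STATE_LABELS[int(rng.integers(2))]
            openness = "closed"
        else:
            state = OPEN_STATE_LABELS[int(rng.integers(13))]
            openness = "open"
        segments.append(ChromatinSegment(chrom=chrom, start=pos, end=end, state=state, openness=openness))
        pos = end
    return segments


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.bases), 70):
                fh.write(r.bases[i : i + 70] + "\n")


def write_segmentation_bed(segments: list[ChromatinSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\n")
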