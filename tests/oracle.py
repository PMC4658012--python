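"""Independent brute-force reference for window scores, TBA and occupancy.

Deliberately written with explicit Python loops and dictionary lookups --
no numpy vectorization, no code shared with the implementation -- so that
agreement between the two is meaningful evidence of correctness.
"""

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def _window_ratio(pwm_matrix, window, bg_freqs):
    """Max over orientations of the likelihood-ratio product for one window."""
    l = len(window)
    fwd = 1.0
    rev = 1.0
    for j in range(l):
        base = window[j]
        if base not in BASE_ROW:
            return None
        denom = bg_freqs[BASE_ROW[base]]
        fwd *= pwm_matrix[BASE_ROW[base]][j] / denom
        rev *= pwm_matrix[BASE_ROW[COMPLEMENT[base]]][l - j - 1] / denom
    return max(fwd, rev)


def brute_window_scores(pwm, seq, bg):
    """Log window scores for every window; None where unscorable."""
    matrix = [[float(v) for v in row] for row in pwm.matrix]
    freqs = [float(v) for v in bg.freqs]
    bases = seq.bases.upper()
    l = pwm.length
    out = []
    for i in range(len(bases) - l + 1):
        if any((i + j) in seq.mask for j in range(l)):
            out.append(None)
            continue
        ratio = _window_ratio(matrix, bases[i : i + l], freqs)
        out.append(None if ratio is None else math.log(ratio))
    return out


def brute_s_max(pwm, bg):
    """Exhaustive per-position maximization over both orientations."""
    matrix = [[float(v) for v in row] for row in pwm.matrix]
    freqs = [float(v) for v in bg.freqs]
    l = pwm.length
    best_fwd = 0.0
    best_rev = 0.0
    for j in range(l):
        best_fwd += max(
            math.log(matrix[BASE_ROW[b]][j] / freqs[BASE_ROW[b]]) for b in "ACGT"
        )
        best_rev += max(
            math.log(matrix[BASE_ROW[COMPLEMENT[b]]][l - j - 1] / freqs[BASE_ROW[b]])
            for b in "ACGT"
        )
    return max(best_fwd, best_rev)


def brute_tba(pwm, seq, bg):
    total = 0.0
    n = 0
    for s in brute_window_scores(pwm, seq, bg):
        if s is not None:
            total += math.exp(s)
            n += 1
    if n == 0:
        raise ValueError("no scorable window")
    return math.log(total)


def brute_occupancy(pwm, seq, bg, cutoff):
    threshold = cutoff * brute_s_max(pwm, bg)
    tol = 1e-9 * max(1.0, abs(threshold))
    total = 0.0
    n_pass = 0
    for s in brute_window_scores(pwm, seq, bg):
        if s is not None and s >= threshold - tol:
            total += math.exp(s)
            n_pass += 1
    return (math.log(total) if n_pass else float("-inf")), n_pass


def brute_sum_of_scores(pwm, seq, bg, cutoff):
    threshold = cutoff * brute_s_max(pwm, bg)
    tol = 1e-9 * max(1.0, abs(threshold))
    return sum(
        s
        for s in brute_window_scores(pwm, seq, bg)
        if s is not None and s >= threshold - tol
    )


def brute_auc(positives, negatives):
    """AUC by direct enumeration of all (positive, negative) pairs."""
    wins = 0.0
    for p in positives:
        for n in negatives:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(positives) * len(negatives))
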