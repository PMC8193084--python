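"""Independent reference implementations used only by the tests.

These are deliberately naive (loop-based, no vectorisation, no shared
code with the package) so they can serve as oracles for the optimised
implementations.
"""

import numpy as np


def naive_dfa_fluctuation(x, sizes):
    """Loop-based DFA fluctuation function (forward/backward averaged)."""
    x = np.asarray(x, dtype=float)
    n_samp = len(x)
    y = np.zeros(n_samp)
    acc = 0.0
    xbar = sum(x) / n_samp
    for i in range(n_samp):
        acc += x[i] - xbar
        y[i] = acc
    out = []
    for n in sizes:
        n = int(n)
        n_boxes = n_samp // n
        covered = n_boxes * n
        f_dirs = []
        for direction in ("fwd", "bwd"):
            seg = y[:covered] if direction == "fwd" else y[n_samp - covered:]
            ssr = 0.0
            for b in range(n_boxes):
                box = seg[b * n:(b + 1) * n]
                t = np.arange(n, dtype=float)
                # per-box least-squares line
                a_mat = np.vstack([t, np.ones(n)]).T
                coef, *_ = np.linalg.lstsq(a_mat, box, rcond=None)
                resid = box - (coef[0] * t + coef[1])
                ssr += float((resid ** 2).sum())
            f_dirs.append(np.sqrt(ssr / covered))
        out.append(0.5 * (f_dirs[0] + f_dirs[1]))
    return np.array(out)


def naive_dfa_exponent(x, sizes):
    f = naive_dfa_fluctuation(x, sizes)
    slope, _ = np.polyfit(np.log2(sizes), np.log2(f), 1)
    return slope


def periodogram_hurst(x):
    """Spectral-slope Hurst estimate for fGn: PSD ~ f^(1-2H).

    Fits the low-frequency half of the periodogram; independent of any
    DFA machinery.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    freqs = np.fft.rfftfreq(n)
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    keep = (freqs > 0) & (freqs < 0.25)
    beta = -np.polyfit(np.log(freqs[keep]), np.log(power[keep]), 1)[0]
    return (beta + 1.0) / 2.0


def binomial_tail_threshold(n, alpha):
    """Brute-force smallest k with P(X >= k | Bin(n, 1/2)) <= alpha."""
    from math import comb

    tail = 0.0
    # walk k downward accumulating the upper tail
    for k in range(n, -1, -1):
        tail += comb(n, k) * 0.5 ** n
        if tail > alpha:
            return k + 1
    return 0
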