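"""Independent brute-force oracles used by the feature and filter tests."""

import numpy as np


def sampen_bruteforce(x, m, r):
    """O(n^2) sample entropy by explicit template counting.

    Both template lengths are restricted to the first n-m starting points so
    the counts are comparable; self-matches excluded; Chebyshev distance.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    tol = r * x.std()
    nb = n - m
    b = a = 0
    for i in range(nb - 1):
        for j in range(i + 1, nb):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= tol:
                a += 1
    if a == 0 or b == 0:
        return 0.0
    return -np.log(a / b)


def zc_bruteforce(x, eps=0.0):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps:
            count += 1
    return count


def ssc_bruteforce(x, eps=0.0):
    count = 0
    for i in range(1, len(x) - 1):
        d1 = x[i] - x[i - 1]
        d2 = x[i] - x[i + 1]
        if d1 * d2 > 0 and abs(d1) >= eps and abs(d2) >= eps:
            count += 1
    return count


def yule_walker_coeffs(x, order):
    """Prediction-error coefficients a_k from a direct Toeplitz solve
    (independent of the Levinson-Durbin recursion under test)."""
    from scipy.linalg import toeplitz
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = len(xc)
    r = np.array([xc[:n - k] @ xc[k:] for k in range(order + 1)]) / n
    phi = np.linalg.solve(toeplitz(r[:order]), r[1:order + 1])
    return -phi           # A(z) = 1 + a_1 z^-1 + ...


def cepstra_from_ar(a):
    """Direct cepstral recursion on known prediction-error coefficients."""
    p = len(a)
    c = np.zeros(p)
    c[0] = -a[0]
    for n in range(2, p + 1):
        c[n - 1] = -a[n - 1] - sum((1 - k / n) * a[k - 1] * c[n - k - 1]
                                   for k in range(1, n))
    return c


def sine_rms_ratio_db(filter_fn, freq, fs, seconds=3.0):
    """Steady-state attenuation of a pure sine through ``filter_fn`` (dB)."""
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = filter_fn(x)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return 20 * np.log10(np.sqrt(np.mean(y[mid] ** 2))
                         / np.sqrt(np.mean(x[mid] ** 2)))
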