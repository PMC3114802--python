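"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written the slow, obvious way (explicit
loops, stdlib statistics) and kept free of imports from the code paths it
checks, so a test comparing the two routes is a genuine dual computation.
"""

from __future__ import annotations

import itertools
import statistics

import numpy as np


# --- least median of squares ------------------------------------------------

def _median_sq_residual(xs, ys, b0, b1):
    return statistics.median((y - b0 - b1 * x) ** 2 for x, y in zip(xs, ys))


def _band_intercept(ts):
    ts = sorted(ts)
    n = len(ts)
    h = n // 2 + 1
    best_i, best_w = 0, None
    for i in range(n - h + 1):
        w = ts[i + h - 1] - ts[i]
        if best_w is None or w < best_w:
            best_i, best_w = i, w
    return 0.5 * (ts[best_i] + ts[best_i + h - 1])


def _ols(xs, ys):
    n = len(xs)
    xm = sum(xs) / n
    ym = sum(ys) / n
    sxx = sum((x - xm) ** 2 for x in xs)
    sxy = sum((x - xm) * (y - ym) for x, y in zip(xs, ys))
    b1 = sxy / sxx
    return ym - b1 * xm, b1


def lms_bruteforce(xs, ys):
    """Exhaustive pair-enumeration LMS line (plus the OLS safeguard
    candidates): returns (beta0, beta1, objective)."""
    xs = [float(v) for v in xs]
    ys = [float(v) for v in ys]
    n = len(xs)
    best = None
    for i, j in itertools.combinations(range(n), 2):
        if xs[i] == xs[j]:
            continue
        slope = (ys[j] - ys[i]) / (xs[j] - xs[i])
        b0 = _band_intercept([y - slope * x for x, y in zip(xs, ys)])
        obj = _median_sq_residual(xs, ys, b0, slope)
        if best is None or obj < best[0]:
            best = (obj, b0, slope)
    if max(xs) > min(xs):
        ob0, ob1 = _ols(xs, ys)
        for b0, b1 in ((_band_intercept([y - ob1 * x
                                         for x, y in zip(xs, ys)]), ob1),
                       (ob0, ob1)):
            obj = _median_sq_residual(xs, ys, b0, b1)
            if best is None or obj < best[0]:
                best = (obj, b0, b1)
    obj, b0, b1 = best
    return b0, b1, obj


# --- motif scanning ---------------------------------------------------------

def parse_pattern_text(text):
    """Pattern text -> list of allowed-base sets, None for spacer slots."""
    iupac = {"A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "R": {"A", "G"}}
    slots = []
    i = 0
    while i < len(text):
        if text[i] == "{":
            close = text.index("}", i)
            slots.extend([None] * int(text[i + 1:close]))
            i = close + 1
        else:
            slots.append(iupac[text[i]])
            i += 1
    return slots


def hamming_scan_bruteforce(seq, pattern_text, max_mismatch):
    """Sliding-window scan; returns [(offset, mismatches), ...]."""
    slots = parse_pattern_text(pattern_text)
    w = len(slots)
    hits = []
    for off in range(len(seq) - w + 1):
        mism = 0
        for rel, allowed in enumerate(slots):
            if allowed is None:
                continue
            if seq[off + rel] not in allowed:
                mism += 1
        if mism <= max_mismatch:
            hits.append((off, mism))
    return hits


# --- detection chain --------------------------------------------------------

def detection_chain_oracle(z_matrix, alpha, lms_fit):
    """Up-calls of the full chain, recomputed step by step.

    ``lms_fit`` supplies the (beta0, beta1) of the LMS line -- the candidate
    sample is part of the estimator's definition -- but everything else
    (summaries, OLS, averaging, scale, p-values, step-up) is recomputed
    independently here.
    """
    from scipy.stats import norm

    z = np.asarray(z_matrix, dtype=float)
    z0 = z[0]
    zavg = z[1:].mean(axis=0)
    ob0, ob1 = _ols(list(z0), list(zavg))
    lb0, lb1 = lms_fit
    b0 = (ob0 + lb0) / 2.0
    b1 = (ob1 + lb1) / 2.0
    raw = zavg - (b0 + b1 * z0)
    s = np.percentile(np.abs(raw), 75) / 1.15
    r = raw / s
    p = norm.sf(r)
    m = p.size
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / (m * c_m):
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject & (r > 0)


# --- set algebra ------------------------------------------------------------

def venn_bruteforce(a, b, c, removed, universe):
    a, b, c = set(a), set(b), set(c)
    removed = set(removed)
    universe = set(universe)
    counts = {"qa_only": 0, "starvation_only": 0, "qa1f_only": 0,
              "qa&starvation": 0, "qa&qa1f": 0, "starvation&qa1f": 0,
              "qa&starvation&qa1f": 0, "none": 0}
    for f in universe - removed:
        ina, inb, inc = f in a, f in b, f in c
        if ina and inb and inc:
            counts["qa&starvation&qa1f"] += 1
        elif ina and inb:
            counts["qa&starvation"] += 1
        elif ina and inc:
            counts["qa&qa1f"] += 1
        elif inb and inc:
            counts["starvation&qa1f"] += 1
        elif ina:
            counts["qa_only"] += 1
        elif inb:
            counts["starvation_only"] += 1
        elif inc:
            counts["qa1f_only"] += 1
        else:
            counts["none"] += 1
    return counts
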