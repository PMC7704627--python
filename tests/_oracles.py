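"""Independent brute-force oracles used only by the test suite.

Everything here is written from the definitions in plain Python (lists,
Fractions, math), deliberately sharing no code with the package kernels
it checks.
"""

from fractions import Fraction
from itertools import product
from math import factorial, log

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Match-style scoring, one window at a time

def freqs(counts, pseudocount=0.0):
    out = []
    for row in counts:
        total = sum(row) + 4 * pseudocount
        out.append([(c + pseudocount) / total for c in row])
    return out


def info(f_rows):
    return [sum(fb * log(4 * fb) for fb in row if fb > 0) for row in f_rows]


def core_positions(counts, pseudocount=0.0, core_len=5):
    I = info(freqs(counts, pseudocount))
    w = min(core_len, len(I))
    sums = [sum(I[i:i + w]) for i in range(len(I) - w + 1)]
    best = max(sums)
    start = sums.index(best)  # leftmost max
    return list(range(start, start + w))


def window_score(counts, window, positions=None, pseudocount=0.0):
    """(Current - Min) / (Max - Min) over the given positions (default all)."""
    f = freqs(counts, pseudocount)
    I = info(f)
    if positions is None:
        positions = range(len(f))
    cur = sum(I[i] * f[i][BASES.index(window[i])] for i in positions)
    lo = sum(I[i] * min(f[i]) for i in positions)
    hi = sum(I[i] * max(f[i]) for i in positions)
    return (cur - lo) / (hi - lo)


def brute_scan(counts, matrix_id, species_id, seq, mode, mss_cutoff,
               core_cutoff=1.0, both_strands=True, pseudocount=0.0):
    """Score every window independently; return (matrix_id, species_id,
    offset, strand, mss, css_or_None) tuples sorted by offset/strand.

    Per-matrix terms (frequencies, information, core, Min/Max) are
    precomputed once from the definitions; each window is then scored by
    an explicit per-position loop.
    """
    L = len(counts)
    n = len(seq)
    f = freqs(counts, pseudocount)
    I = info(f)
    core = core_positions(counts, pseudocount)
    weighted = [{b: I[i] * f[i][k] for k, b in enumerate(BASES)}
                for i in range(L)]
    lo = sum(I[i] * min(f[i]) for i in range(L))
    hi = sum(I[i] * max(f[i]) for i in range(L))
    core_lo = sum(I[i] * min(f[i]) for i in core)
    core_hi = sum(I[i] * max(f[i]) for i in core)
    hits = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        s = seq if strand == "+" else rc(seq)
        for j in range(n - L + 1):
            w = s[j:j + L]
            if "N" in w:
                continue
            cur = 0.0
            for i in range(L):
                cur += weighted[i][w[i]]
            mss = (cur - lo) / (hi - lo)
            if mss < mss_cutoff:
                continue
            core_cur = 0.0
            for i in core:
                core_cur += weighted[i][w[i]]
            css = (core_cur - core_lo) / (core_hi - core_lo)
            if mode == "match" and css < core_cutoff:
                continue
            start = j if strand == "+" else n - L - j
            hits.append((matrix_id, species_id, start - n, strand, mss,
                         css if mode == "match" else None))
    hits.sort(key=lambda h: (h[2], 0 if h[3] == "+" else 1))
    return hits


# ---------------------------------------------------------------------------
# Fisher exact test by direct enumeration (factorial-based, all Fractions)

def fisher_enum(a, b, c, d):
    """Two-tailed Fisher p for [[a, b], [c, d]], sum-of-small-p rule."""
    def C(n, k):
        return factorial(n) // (factorial(k) * factorial(n - k))

    n1, n2, k, n = a + b, c + d, a + c, a + b + c + d
    denom = C(n, k)
    probs = {}
    for x in range(0, k + 1):
        if x <= n1 and k - x <= n2:
            probs[x] = Fraction(C(n1, x) * C(n2, k - x), denom)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


# ---------------------------------------------------------------------------
# Three-way bootstrap by exhaustive resample enumeration

def bootstrap_enum(active, inactive):
    """Exact (p_greater, p_equal, p_less) Fractions over all equiprobable
    with-replacement resample pairs (feasible for group sizes <= 3)."""
    n_a, n_i = len(active), len(inactive)
    total = Fraction(0)
    tallies = {"greater": Fraction(0), "equal": Fraction(0), "less": Fraction(0)}
    weight = Fraction(1, n_a ** n_a * n_i ** n_i)
    for pick_a in product(range(n_a), repeat=n_a):
        s_a = sum(active[i] for i in pick_a)
        for pick_i in product(range(n_i), repeat=n_i):
            s_i = sum(inactive[i] for i in pick_i)
            lhs, rhs = s_i * n_a, s_a * n_i  # inactive mean vs active mean
            key = "greater" if lhs > rhs else ("equal" if lhs == rhs else "less")
            tallies[key] += weight
            total += weight
    assert total == 1
    return tallies["greater"], tallies["equal"], tallies["less"]
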