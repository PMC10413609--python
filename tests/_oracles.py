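"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive expected results from first principles (full
enumeration, no seeding, no shared code paths with the package) so the
miners can be checked by exact set equality.
"""

import numpy as np

from plastotype._util import revcomp, smallest_period
from plastotype.repeat_mining import DEFAULT_SSR_THRESHOLDS


def random_seq(seed, n, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), n))


def at_rich_seq(seed, n, gc=0.39):
    """Random background at plastome-like base composition."""
    rng = np.random.default_rng(seed)
    return "".join(
        rng.choice(list("ACGT"), n, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )


def ssr_oracle(s, thresholds=DEFAULT_SSR_THRESHOLDS):
    """Test every (start, unit) pair directly; O(L * 6) but trivially correct."""
    hits = set()
    L = len(s)
    for u, min_copies in thresholds.items():
        for start in range(0, L - u):
            unit = s[start : start + u]
            if "N" in unit or smallest_period(unit) != u:
                continue
            # left-maximality at character level
            if start > 0 and s[start - 1] == s[start - 1 + u] and s[start - 1] != "N":
                continue
            k = start + u
            while k < L and s[k] == s[k - u] and s[k] != "N":
                k += 1
            copies = (k - start) // u
            if copies >= min_copies:
                hits.add((start, u, copies))
    return hits


def _oracle_windows(mism, lo, hi, max_mm, min_len):
    """Inclusion-maximal windows with <= max_mm mismatches, trimmed to match
    endpoints — straight from the definition, over a full diagonal."""
    bounds = [lo - 1] + list(mism) + [hi]
    mism_set = set(mism)
    span = max_mm + 1
    out = set()
    n = len(bounds)
    for i in range(max(0, n - span - 1) + 1):
        j = min(i + span, n - 1)
        ws, we = bounds[i] + 1, bounds[j]
        while ws < we and ws in mism_set:
            ws += 1
        while we > ws and (we - 1) in mism_set:
            we -= 1
        if we - ws >= min_len:
            mm = sum(1 for m in mism if ws <= m < we)
            out.add((ws, we, mm))
    return out


def repeat_oracle(s, min_len=30, max_mm=3):
    """All-pairs Hamming oracle: every diagonal and anti-diagonal in full."""
    N = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    t = np.frombuffer(revcomp(s).encode(), dtype=np.uint8)
    hits = set()
    for d in range(1, N - min_len + 1):
        mism = (np.flatnonzero(arr[: N - d] != arr[d:])).tolist()
        for ws, we, mm in _oracle_windows(mism, 0, N - d, max_mm, min_len):
            length = we - ws
            if length > d:
                continue  # overlapping copies
            hits.add(("direct", ws, ws + d, length, mm))
    for e in range(-(N - min_len), N - min_len + 1):
        x0, x1 = max(0, -e), min(N, N - e)
        if x1 - x0 < min_len:
            continue
        mism = (x0 + np.flatnonzero(arr[x0:x1] != t[x0 + e : x1 + e])).tolist()
        for ws, we, mm in _oracle_windows(mism, x0, x1, max_mm, min_len):
            length = we - ws
            b = N - e - we
            lo_s, hi_s = min(ws, b), max(ws, b)
            if hi_s - lo_s < length:  # overlapping arms (hairpin)
                continue
            hits.add(("palindromic", lo_s, hi_s, length, mm))
    return hits


def impl_repeat_keys(hits):
    return {
        (h.kind, h.interval_a.start, h.interval_b.start, h.length, h.mismatches)
        for h in hits
    }


def plant_pairs(seed, n):
    """Random sequence with planted direct and palindromic pairs (0-3 mm)."""
    rng = np.random.default_rng(seed)
    s = list(random_seq(seed + 1000, n))
    for k, kind in enumerate(["direct", "palindromic", "direct"]):
        length = int(rng.integers(30, 80))
        core = random_seq(seed + 2000 + k, length)
        mate = list(core if kind == "direct" else revcomp(core))
        for _ in range(int(rng.integers(0, 4))):
            pos = int(rng.integers(0, length))
            mate[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mate[pos]]
        a = int(rng.integers(50, n // 2 - 100))
        b = int(rng.integers(n // 2 + 50, n - 100))
        s[a : a + length] = core
        s[b : b + length] = mate
    return "".join(s)


def plant_ssr_arrays(seed, n):
    """AT-rich sequence with a few planted SSR arrays above threshold."""
    rng = np.random.default_rng(seed)
    s = at_rich_seq(seed + 500, n)
    for k in range(4):
        u = int(rng.integers(1, 7))
        unit = "".join(rng.choice(list("ACGT"), u))
        while smallest_period(unit) != u:
            unit = "".join(rng.choice(list("ACGT"), u))
        copies = int(rng.integers(DEFAULT_SSR_THRESHOLDS[u], DEFAULT_SSR_THRESHOLDS[u] + 5))
        pos = 200 + k * (n - 400) // 4 + int(rng.integers(0, 50))
        arr = unit * copies
        s = s[:pos] + arr + s[pos + len(arr):]
    return s
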