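"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double loops, quadratic scans) and
shares no code with the package internals beyond reverse complementation.
"""

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def rc(s: str) -> str:
    return "".join(COMP.get(b, "N") for b in reversed(s))


def brute_scan(bases, arm, smin, smax, max_mm=0):
    """Enumerate every (position, spacer, mismatches) hit directly."""
    hits = []
    n = len(bases)
    for s in range(smin, smax + 1):
        for i in range(n - (2 * arm + s) + 1):
            left = bases[i : i + arm]
            right = bases[i + arm + s : i + 2 * arm + s]
            window = bases[i : i + 2 * arm + s]
            if "N" in window:
                continue
            mm = sum(1 for a, b in zip(left, rc(right)) if a != b)
            if mm <= max_mm:
                hits.append((i, s, mm))
    return sorted(hits)


def brute_foldback(t, max_loop=None):
    """Best intramolecular stem: maximize length, then minimize loop.

    Returns (stem_len, a, b) with t[a:a+k] == rc(t[b:b+k]) and loop
    b - a - k >= 0, found by quadratic scan with greedy extension.
    """
    n = len(t)
    best = (0, 0, 0)  # (stem_len, a, b) with loop = b - a - stem_len
    best_loop = n + 1
    # choose the unpaired central loop [i, j) and extend the stem outward
    for i in range(n + 1):
        jmax = n if max_loop is None else min(n, i + max_loop)
        for j in range(i, jmax + 1):
            k = 0
            while i - 1 - k >= 0 and j + k < n and t[i - 1 - k] == COMP.get(t[j + k], "?"):
                k += 1
            loop = j - i
            if k > best[0] or (k == best[0] and k > 0 and loop < best_loop):
                best = (k, i - k, j)
                best_loop = loop
    return best


def brute_foldback_result(t, max_loop=None):
    """(stem_len, loop_len) of the optimal fold-back."""
    k, a, j = brute_foldback(t, max_loop)
    if k == 0:
        return (0, 0)
    return (k, j - a - k)


def brute_coverage(d):
    """Per-base ancestor copy number by direct counting."""
    cov = [0] * len(d.ancestor)
    for p in d.pieces:
        if hasattr(p, "strand"):
            for x in range(p.start, p.end):
                cov[x] += 1
    return cov


def brute_common_substrings(a, b, min_len):
    """All maximal (i, j, length >= min_len) common substrings, O(n*m)."""
    out = set()
    for i in range(len(a)):
        for j in range(len(b)):
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not maximal on the left
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k >= min_len:
                out.add((i, j, k))
    return sorted(out)
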