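"""Independent oracles used across the test suite.

These deliberately take a different route from the implementation they
check: the motif oracle translates PROSITE syntax to Python regular
expressions, and the Fisher oracle enumerates hypergeometric tables in
exact rational arithmetic.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction

from solscore.motifs import MotifPattern

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def pattern_to_regex(pattern: MotifPattern) -> re.Pattern:
    """Translate a parsed pattern into a non-greedy regular expression."""
    parts = []
    for elem in pattern.elements:
        if elem.kind == "wildcard":
            body = "."
        elif elem.kind == "set":
            body = "[" + "".join(sorted(elem.residues)) + "]"
        else:
            body = "[^" + "".join(sorted(elem.residues)) + "]"
        if elem.min_repeat == elem.max_repeat:
            rep = "" if elem.min_repeat == 1 else f"{{{elem.min_repeat}}}"
        else:
            rep = f"{{{elem.min_repeat},{elem.max_repeat}}}?"
        parts.append(body + rep)
    core = "".join(parts)
    if pattern.anchored_end:
        core += "$"
    return re.compile(core)


def regex_scan(residues: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """Leftmost-shortest matches per start position, 1-based inclusive."""
    rx = pattern_to_regex(pattern)
    starts = (0,) if pattern.anchored_start else range(len(residues))
    out = []
    for start in starts:
        m = rx.match(residues, start)
        if m is not None and m.end() > start:
            out.append((start + 1, m.end()))
    return out


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided Fisher p via exact enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k)
        for k in range(k_min, k_max + 1)
    }
    num = sum(w for w in weights.values() if w <= weights[a])
    return float(Fraction(num, math.comb(n, c1)))
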