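"""Brute-force Shannon-entropy oracle, independent of the library.

Builds its own count dictionary with an explicit loop and evaluates
-sum f log2 f with exact fractions, sharing no code with
sefkit.entropy.  Used to cross-check the library implementation.
"""

import math
from fractions import Fraction


def oracle_entropy(tokens) -> float:
    """-sum_i f_i log2 f_i over the token list, in bits."""
    if not tokens:
        raise ValueError("empty token list")
    counts = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    n_total = len(tokens)
    acc = 0.0
    for c in counts.values():
        f = Fraction(c, n_total)
        acc -= float(f) * math.log2(float(f))
    return acc
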