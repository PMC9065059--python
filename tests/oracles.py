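"""Independent brute-force oracles shared by unit and acceptance tests.

Leftmost-longest full-regex matching over candidate substrings — a
deliberately naive quadratic reference, structurally unrelated to the
run-chaining scanner it checks. Loops may contain G/C in their interior
but cannot start or end with one: runs absorb adjacent bases greedily,
so a loop base touching a run would extend the run instead.
"""

import re

_LOOP_G = r"(?:[ACTN][ACGTN]{0,5}[ACTN]|[ACTN])"
_LOOP_C = r"(?:[AGTN][ACGTN]{0,5}[AGTN]|[AGTN])"
PLUS_G4 = re.compile(rf"G{{3,}}(?:{_LOOP_G}G{{3,}}){{3,}}")
MINUS_G4 = re.compile(rf"C{{3,}}(?:{_LOOP_C}C{{3,}}){{3,}}")
PLUS_RUNS = re.compile(rf"G{{3,}}(?:{_LOOP_G}G{{3,}})*")
MINUS_RUNS = re.compile(rf"C{{3,}}(?:{_LOOP_C}C{{3,}})*")


def oracle_scan(seq, pattern, seed_char):
    """Non-overlapping leftmost-longest matches of ``pattern``."""
    out = []
    i, n = 0, len(seq)
    triple = seed_char * 3
    while i < n:
        if not seq.startswith(triple, i):
            i += 1
            continue
        best = None
        for end in range(n, i, -1):
            if pattern.fullmatch(seq, i, end):
                best = end
                break
        if best is None:
            i += 1
        else:
            out.append((i, best))
            i = best
    return out


def oracle_both_strands(seq, kind):
    if kind == "g4":
        plus = oracle_scan(seq, PLUS_G4, "G")
        minus = oracle_scan(seq, MINUS_G4, "C")
    else:
        plus = oracle_scan(seq, PLUS_RUNS, "G")
        minus = oracle_scan(seq, MINUS_RUNS, "C")
    return {(s, e, "+") for s, e in plus} | {(s, e, "-") for s, e in minus}
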