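"""Independent brute-force oracles shared across test modules.

These deliberately re-derive behaviour from first principles (slicing
plus ``re.fullmatch`` on substrings) rather than reusing the package's
scanning code, so that agreement is a real cross-check.
"""

import re


def brute_force_matches(pattern, sequence):
    """Leftmost-longest non-overlapping matches: try every start position
    in order, and for each start every end from the right."""
    cre = re.compile(pattern)
    out = []
    i = 0
    while i < len(sequence):
        found = None
        for start in range(i, len(sequence)):
            for end in range(len(sequence), start, -1):
                if cre.fullmatch(sequence[start:end]):
                    found = (start, end)
                    break
            if found:
                break
        if not found:
            break
        out.append(sequence[found[0]:found[1]])
        i = found[1]
    return out


def brute_force_weight(pattern, train, db, threshold):
    """Re-derivation of the weight-training equation: enumerate every
    (sequence, match) pair via the brute-force scanner and sum
    +/- cest * len over the motif database."""
    total = 0.0
    for rec in train.records:
        for motif in brute_force_matches(pattern, rec.sequence):
            entry = db.lookup(motif)
            if entry is None:
                continue
            term = entry.cest * len(motif)
            total += term if entry.cest >= threshold else -term
    return total
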