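"""Independent naive oracles used to cross-check the package's entropy code.

Everything here is a deliberate double-loop / term-by-term reimplementation
with no shared code path with ordent: plain ``math.log`` summations over
Python lists. Tests freeze values computed with these functions and assert
the package agrees.
"""

import math


def naive_entropy(counts, base=None):
    """−Σ p log p over positive counts, term by term."""
    total = sum(counts)
    s = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            s -= p * math.log(p)
    return s / math.log(base) if base is not None else s


def naive_row_entropies(table, base=None):
    return [naive_entropy(row, base) if sum(row) > 0 else 0.0 for row in table]


def naive_conditional_entropy(table, base=None):
    total = sum(sum(row) for row in table)
    s = 0.0
    for row in table:
        n_row = sum(row)
        if n_row > 0:
            s += (n_row / total) * naive_entropy(row, base)
    return s


def naive_ratio(table):
    cols = [sum(row[j] for row in table) for j in range(len(table[0]))]
    return naive_conditional_entropy(table) / naive_entropy(cols)


def transpose(table):
    return [[row[j] for row in table] for j in range(len(table[0]))]


def naive_mce(table):
    return 0.5 * (naive_ratio(table) + naive_ratio(transpose(table)))
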