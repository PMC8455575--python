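"""Brute-force oracles: expand pattern tables to explicit fragment lists and
compute every statistic by direct enumeration, independently of the
implementation's weighted-count arithmetic."""

from __future__ import annotations

import math


def expand_complete(table) -> list[str]:
    out = []
    for pat in sorted(table.patterns):
        if "N" not in pat:
            out.extend([pat] * table.patterns[pat])
    return out


def oracle_epipolymorphism(table) -> float:
    frags = expand_complete(table)
    n = len(frags)
    freqs = {}
    for f in frags:
        freqs[f] = freqs.get(f, 0) + 1
    return 1.0 - sum((c / n) ** 2 for c in freqs.values())


def oracle_spectrum(table) -> list[float]:
    frags = expand_complete(table)
    n = len(frags)
    props = [0.0] * (table.n_cpgs + 1)
    for f in frags:
        props[f.count("M")] += 1.0 / n
    return props


def oracle_linkage(table):
    """Pairwise Pearson correlation by naive fragment-level sums; NaN for
    pairs with a constant site."""
    frags = expand_complete(table)
    n = len(frags)
    k = table.n_cpgs
    x = [[1.0 if f[j] == "M" else 0.0 for j in range(k)] for f in frags]
    means = [sum(row[j] for row in x) / n for j in range(k)]
    r = [[math.nan] * k for _ in range(k)]
    for j in range(k):
        for l in range(k):
            cov = sum((row[j] - means[j]) * (row[l] - means[l]) for row in x) / n
            vj = sum((row[j] - means[j]) ** 2 for row in x) / n
            vl = sum((row[l] - means[l]) ** 2 for row in x) / n
            if vj > 0 and vl > 0:
                r[j][l] = cov / math.sqrt(vj * vl)
    vals = [r[j][l] for j in range(k) for l in range(k) if j != l and not math.isnan(r[j][l])]
    mean_r = sum(vals) / len(vals) if vals else math.nan
    return r, mean_r
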