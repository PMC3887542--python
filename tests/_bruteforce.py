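"""Independent brute-force oracles used to cross-check the library.

Everything here is written directly from definitions (loops, no reuse of
package code paths) so statistic tests compare two independent routes.
"""

from __future__ import annotations

import math
from itertools import groupby

import numpy as np


def bf_mean(xs):
    return sum(xs) / len(xs)


def bf_sample_sd(xs):
    m = bf_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def bf_cell_stats(rows, chooser, partner, value):
    """Per-(chooser, partner) n/mean/sd from a list of dict rows."""
    out = {}
    keys = sorted({(r[chooser], r[partner]) for r in rows})
    for key in keys:
        vals = [r[value] for r in rows if (r[chooser], r[partner]) == key]
        out[key] = {
            "n": len(vals),
            "mean": bf_mean(vals),
            "sd": bf_sample_sd(vals) if len(vals) >= 2 else None,
        }
    return out


def bf_responsiveness(cell_means_for_line):
    return bf_mean(cell_means_for_line)


def bf_choosiness_sd(cell_means_for_line):
    return bf_sample_sd(cell_means_for_line)


def bf_choosiness_cv(cell_means_for_line):
    return bf_sample_sd(cell_means_for_line) / bf_mean(cell_means_for_line)


def bf_strength_total_sd(cell_means_for_line, all_trial_values_for_line):
    num = max(cell_means_for_line) - bf_mean(cell_means_for_line)
    return num / bf_sample_sd(all_trial_values_for_line)


def bf_strength_max_sd(cell_means_for_line, trials_by_cell):
    """trials_by_cell: list of per-cell trial-value lists, aligned with
    cell_means_for_line."""
    num = max(cell_means_for_line) - bf_mean(cell_means_for_line)
    imax = cell_means_for_line.index(max(cell_means_for_line))
    return num / bf_sample_sd(trials_by_cell[imax])


def bf_ranks(values):
    """Average ranks, 1 = smallest."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def bf_kendalls_w(rank_rows):
    """12 S / (m^2 (n^3 - n) - m sum T), T the tie correction per row."""
    m = len(rank_rows)
    n = len(rank_rows[0])
    col_sums = [sum(row[j] for row in rank_rows) for j in range(n)]
    mean_sum = bf_mean(col_sums)
    s = sum((c - mean_sum) ** 2 for c in col_sums)
    tie = 0.0
    for row in rank_rows:
        for _, grp in groupby(sorted(row)):
            t = len(list(grp))
            tie += t ** 3 - t
    denom = m ** 2 * (n ** 3 - n) - m * tie
    return 12.0 * s / denom if denom > 0 else 0.0


def bf_bh_adjust(pvals):
    """Benjamini-Hochberg step-up by definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj
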