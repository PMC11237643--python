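"""Independent brute-force oracles, coded separately from the pipeline.

These deliberately avoid the package's own code paths (and numpy where
practical) so they can serve as references: a step-by-step TMM factor
computation in plain loops, and exhaustive enumeration of every
admissible piecewise-constant segmentation.
"""

from __future__ import annotations

import math
from itertools import combinations


def _quantile_type7(sorted_values: list[float], p: float) -> float:
    n = len(sorted_values)
    h = (n - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_values[lo] + (h - lo) * (sorted_values[hi] - sorted_values[lo])


def _average_ranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based average rank of the tie block
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_tmm_factors(
    counts: list[list[float]], trim_m: float = 0.30, trim_a: float = 0.05
) -> list[float]:
    """Step-by-step TMM factors for a samples-by-attributes count matrix."""
    n_samples = len(counts)
    libs = [sum(row) for row in counts]
    f75 = [
        _quantile_type7(sorted(row), 0.75) / lib for row, lib in zip(counts, libs)
    ]
    mean_f75 = sum(f75) / n_samples
    ref_idx = min(range(n_samples), key=lambda i: abs(f75[i] - mean_f75))
    ref, ref_lib = counts[ref_idx], libs[ref_idx]

    factors = []
    for row, lib in zip(counts, libs):
        ms, as_, ws = [], [], []
        for x, r in zip(row, ref):
            if x > 0 and r > 0:
                p, q = x / lib, r / ref_lib
                ms.append(math.log2(p / q))
                as_.append(0.5 * math.log2(p * q))
                ws.append((lib - x) / (lib * x) + (ref_lib - r) / (ref_lib * r))
        if not ms:
            raise ValueError("no shared positive attributes with reference")
        if max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = _average_ranks(ms)
        rank_a = _average_ranks(as_)
        num = den = 0.0
        for m, rm, ra, w in zip(ms, rank_m, rank_a, ws):
            if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
                num += m / w
                den += 1.0 / w
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)

    log_mean = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_mean) for f in factors]


def _rss(values: list[float], start: int, end: int) -> float:
    seg = values[start:end]
    mean = sum(seg) / len(seg)
    return sum((v - mean) ** 2 for v in seg)


def exhaustive_segmentations(
    values: list[float],
    h: float = 0.01,
    min_segment: int = 2,
    max_breaks: int = 5,
) -> dict:
    """Enumerate every admissible segmentation; return per-break-count
    optimum and the BIC-chosen break count (smaller count wins ties)."""
    values = [float(v) for v in values]
    n = len(values)
    min_len = max(min_segment, math.ceil(h * n))
    feasible = min(max_breaks, n // min_len - 1)
    scale = (max(values) - min(values)) or 1.0
    floor = n * scale * scale * 1e-12

    best: dict[int, tuple[float, tuple[int, ...]]] = {0: (_rss(values, 0, n), ())}
    for m in range(1, max(feasible, 0) + 1):
        best_rss, best_breaks = math.inf, None
        for breaks in combinations(range(min_len, n - min_len + 1), m):
            bounds = (0, *breaks, n)
            if any(b - a < min_len for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            rss = sum(_rss(values, a, b) for a, b in zip(bounds[:-1], bounds[1:]))
            if rss < best_rss:
                best_rss, best_breaks = rss, breaks
        if best_breaks is None:
            break
        best[m] = (best_rss, best_breaks)

    def bic(rss: float, m: int) -> float:
        return n * math.log(max(rss, floor) / n) + (2 * m + 2) * math.log(n)

    chosen = 0
    if best[0][0] > floor:
        for m in sorted(best):
            if m == 0:
                continue
            if bic(best[m][0], m) < bic(best[chosen][0], chosen) - 1e-9 * (
                1.0 + abs(bic(best[chosen][0], chosen))
            ):
                chosen = m
    return {
        "per_breaks": best,
        "chosen": chosen,
        "chosen_breaks": best[chosen][1],
        "chosen_rss": best[chosen][0],
    }
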