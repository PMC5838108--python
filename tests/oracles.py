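"""Independent brute-force reference implementations.

Deliberately written as plain Python loops over lists, with no numpy
vectorization and no reuse of the package's code paths, so agreement with
the package is a meaningful cross-check.
"""

from __future__ import annotations

import math


def _present(xs):
    return [x for x in xs if x == x]


def summary_at_node(values: list[float]) -> tuple[int, float, float, float]:
    """(n, mean, sd, se) of the non-missing values; NaN where undefined."""
    xs = _present(values)
    n = len(xs)
    if n == 0:
        return 0, math.nan, math.nan, math.nan
    mean = sum(xs) / n
    if n < 2:
        return n, mean, math.nan, math.nan
    var = sum((x - mean) ** 2 for x in xs) / (n - 1)
    sd = math.sqrt(var)
    return n, mean, sd, sd / math.sqrt(n)


def profile_summary(rows: list[list[float]]) -> dict[str, list[float]]:
    """Column-wise summary of a members x nodes table."""
    n_nodes = len(rows[0])
    out = {"n": [], "mean": [], "sd": [], "se": []}
    for v in range(n_nodes):
        n, mean, sd, se = summary_at_node([row[v] for row in rows])
        out["n"].append(n)
        out["mean"].append(mean)
        out["sd"].append(sd)
        out["se"].append(se)
    return out


def zscores(x: list[float], ref_rows: list[list[float]]) -> list[float]:
    """Node-wise (x - mean_ref) / sd_ref; NaN where x or sd missing or sd==0."""
    out = []
    for v in range(len(x)):
        _, mean, sd, _ = summary_at_node([row[v] for row in ref_rows])
        if x[v] != x[v] or mean != mean or sd != sd or sd == 0:
            out.append(math.nan)
        else:
            out.append((x[v] - mean) / sd)
    return out


def peak_z(z: list[float], start: int, end: int) -> tuple[float, int]:
    """Signed z at the node of max |z| in [start, end]; ties -> lowest node."""
    best_v, best = None, -1.0
    for v in range(start, end + 1):
        if z[v] != z[v]:
            continue
        if abs(z[v]) > best:
            best, best_v = abs(z[v]), v
    if best_v is None:
        raise ValueError("all missing")
    return z[best_v], best_v


def mean_z(z: list[float], start: int, end: int) -> float:
    xs = _present(z[start : end + 1])
    if not xs:
        raise ValueError("all missing")
    return sum(xs) / len(xs)


def fraction_deviant(
    group_rows: dict[str, list[float]],
    ref_rows: list[list[float]],
    threshold: float,
    start: int,
    end: int,
    direction: str = "absolute",
) -> float:
    deviant = 0
    for _, x in sorted(group_rows.items()):
        z = zscores(x, ref_rows)
        hit = False
        for v in range(start, end + 1):
            if z[v] != z[v]:
                continue
            if direction == "absolute" and abs(z[v]) > threshold:
                hit = True
            elif direction == "positive" and z[v] > threshold:
                hit = True
            elif direction == "negative" and -z[v] > threshold:
                hit = True
        deviant += hit
    return deviant / len(group_rows)


def quantile_bins(pairs: list[tuple[str, float]], k: int) -> dict[str, int]:
    """Sort by (value, subject ID), split into k contiguous near-equal chunks."""
    order = sorted(pairs, key=lambda sv: (sv[1], sv[0]))
    n = len(order)
    base, extra = divmod(n, k)
    out: dict[str, int] = {}
    pos = 0
    for g in range(k):
        size = base + (1 if g < extra else 0)
        for s, _ in order[pos : pos + size]:
            out[s] = g
        pos += size
    return out


def union_mask(n_nodes: int, ranges: list[tuple[int, int]]) -> list[bool]:
    covered = set()
    for start, end in ranges:
        covered |= set(range(start, end + 1))
    return [v in covered for v in range(n_nodes)]
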