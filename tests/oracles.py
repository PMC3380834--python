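"""Independent brute-force reference implementations used as test oracles.

Everything here is written position-by-position / all-pairs, with no code
shared with the package internals, so that agreement is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, special


def oracle_ratio_values(
    ip: np.ndarray, inp: np.ndarray, step: int, adjust_mode: str = "log2"
) -> list[float | None]:
    """Per-grid-position log2 ratio with flooring and depth adjustment."""
    mu_ip = sum(ip) / len(ip)
    mu_in = sum(inp) / len(inp)
    if adjust_mode == "log2":
        adj = math.log2(mu_ip) - math.log2(mu_in)
    else:
        adj = mu_ip - mu_in
    out: list[float | None] = []
    for p in range(0, len(ip), step):
        if ip[p] >= mu_ip:
            floored = inp[p] if inp[p] >= mu_in else mu_in
            out.append(math.log2(ip[p]) - math.log2(floored) - adj)
        else:
            out.append(None)
    return out


def oracle_median_smooth(
    values: list[float | None], step: int, window: int, min_points: int
) -> list[float | None]:
    """Centered median in windows of +/- window/2 bp around each grid point."""
    half_bp = window / 2.0
    n = len(values)
    reach = int(half_bp // step) + 2  # safely covers every in-window index
    out: list[float | None] = []
    for i in range(n):
        inside = [
            values[j]
            for j in range(max(0, i - reach), min(n, i + reach + 1))
            if abs(j * step - i * step) <= half_bp and values[j] is not None
        ]
        if len(inside) < min_points:
            out.append(None)
        else:
            s = sorted(inside)
            m = len(s)
            out.append(
                s[m // 2] if m % 2 else (s[m // 2 - 1] + s[m // 2]) / 2.0
            )
    return out


def oracle_call_regions(
    values: list[float | None],
    step: int,
    threshold: float,
    min_len: int,
    max_gap: int,
    span_includes_bin: bool = True,
) -> list[tuple[int, int]]:
    """Greedy left-to-right clustering of above-threshold grid positions."""
    above = [
        i * step for i, v in enumerate(values) if v is not None and v >= threshold
    ]
    clusters: list[list[int]] = []
    for p in above:
        if clusters and p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    regions = []
    for c in clusters:
        span = (c[-1] + step - c[0]) if span_includes_bin else (c[-1] - c[0])
        if span >= min_len:
            regions.append((c[0], c[-1] + step))
    return regions


def oracle_score(
    values: list[float | None], step: int, start: int, end: int, k: int
) -> tuple[float, int]:
    """Best mean over k consecutive present values in [start, end)."""
    present = [
        (i * step, v)
        for i, v in enumerate(values)
        if v is not None and start <= i * step < end
    ]
    if not present:
        raise ValueError("no present values")
    if len(present) < k:
        vals = [v for _, v in present]
        return sum(vals) / len(vals), present[(len(present) - 1) // 2][0]
    best_mean, best_center = -math.inf, -1
    for i in range(len(present) - k + 1):
        window = present[i: i + k]
        m = sum(v for _, v in window) / k
        if m > best_mean:
            best_mean, best_center = m, window[k // 2][0]
    return best_mean, best_center


def oracle_percent_overlap(query, target) -> float:
    """All-pairs >=1-nt overlap fraction; query counted once per region."""
    hits = 0
    for q in query:
        if any(
            q[0] == t[0] and q[1] < t[2] and t[1] < q[2] for t in target
        ):
            hits += 1
    return 100.0 * hits / len(query)


def t_density(x: float, df: float) -> float:
    """Student t probability density, written out from the gamma function."""
    lognorm = (
        special.gammaln((df + 1) / 2.0)
        - special.gammaln(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )
    return math.exp(lognorm - (df + 1) / 2.0 * math.log1p(x * x / df))


def oracle_two_tailed_p(t: float, df: float) -> float:
    """Two-tailed p by numerical integration of the t density tail."""
    tail, _ = integrate.quad(t_density, abs(t), np.inf, args=(df,))
    return 2.0 * tail


def oracle_welch(a, b) -> tuple[float, float, float]:
    """Welch statistic, Welch-Satterthwaite df, and quadrature p."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sa, sb = va / na, vb / nb
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return t, df, oracle_two_tailed_p(t, df)
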