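"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, textbook formulas)
kept separate from the package so they share no code path with it.
"""

from __future__ import annotations

import numpy as np


def splitplot_ss_bruteforce(y: np.ndarray) -> dict:
    """Textbook split-plot sums of squares via explicit marginal-mean loops.

    ``y`` has shape (g, n, a, b).  Returns {term: SS}.
    """
    g, n, a, b = y.shape
    grand = 0.0
    for gi in range(g):
        for si in range(n):
            for ai in range(a):
                for bi in range(b):
                    grand += y[gi, si, ai, bi]
    grand /= g * n * a * b

    def mean_over(fix):
        """Mean of all cells matching the partial index dict ``fix``."""
        total, count = 0.0, 0
        for gi in range(g):
            if "g" in fix and gi != fix["g"]:
                continue
            for si in range(n):
                if "s" in fix and si != fix["s"]:
                    continue
                for ai in range(a):
                    if "a" in fix and ai != fix["a"]:
                        continue
                    for bi in range(b):
                        if "b" in fix and bi != fix["b"]:
                            continue
                        total += y[gi, si, ai, bi]
                        count += 1
        return total / count

    ss = {}
    ss["G"] = sum(
        n * a * b * (mean_over({"g": gi}) - grand) ** 2 for gi in range(g)
    )
    ss["S(G)"] = sum(
        a * b * (mean_over({"g": gi, "s": si}) - mean_over({"g": gi})) ** 2
        for gi in range(g)
        for si in range(n)
    )
    ss["A"] = sum(
        g * n * b * (mean_over({"a": ai}) - grand) ** 2 for ai in range(a)
    )
    ss["GA"] = sum(
        n * b
        * (
            mean_over({"g": gi, "a": ai})
            - mean_over({"g": gi})
            - mean_over({"a": ai})
            + grand
        ) ** 2
        for gi in range(g)
        for ai in range(a)
    )
    # A x subject-within-group residual
    ss["AS(G)"] = sum(
        b
        * (
            mean_over({"g": gi, "s": si, "a": ai})
            - mean_over({"g": gi, "s": si})
            - mean_over({"g": gi, "a": ai})
            + mean_over({"g": gi})
        ) ** 2
        for gi in range(g)
        for si in range(n)
        for ai in range(a)
    )
    if b > 1:
        ss["B"] = sum(
            g * n * a * (mean_over({"b": bi}) - grand) ** 2 for bi in range(b)
        )
        ss["GB"] = sum(
            n * a
            * (
                mean_over({"g": gi, "b": bi})
                - mean_over({"g": gi})
                - mean_over({"b": bi})
                + grand
            ) ** 2
            for gi in range(g)
            for bi in range(b)
        )
        ss["BS(G)"] = sum(
            a
            * (
                mean_over({"g": gi, "s": si, "b": bi})
                - mean_over({"g": gi, "s": si})
                - mean_over({"g": gi, "b": bi})
                + mean_over({"g": gi})
            ) ** 2
            for gi in range(g)
            for si in range(n)
            for bi in range(b)
        )
        ss["AB"] = sum(
            g * n
            * (
                mean_over({"a": ai, "b": bi})
                - mean_over({"a": ai})
                - mean_over({"b": bi})
                + grand
            ) ** 2
            for ai in range(a)
            for bi in range(b)
        )
        ss["GAB"] = sum(
            n
            * (
                mean_over({"g": gi, "a": ai, "b": bi})
                - mean_over({"g": gi, "a": ai})
                - mean_over({"g": gi, "b": bi})
                - mean_over({"a": ai, "b": bi})
                + mean_over({"g": gi})
                + mean_over({"a": ai})
                + mean_over({"b": bi})
                - grand
            ) ** 2
            for gi in range(g)
            for ai in range(a)
            for bi in range(b)
        )
        ss_total = sum(
            (y[gi, si, ai, bi] - grand) ** 2
            for gi in range(g)
            for si in range(n)
            for ai in range(a)
            for bi in range(b)
        )
        ss["ABS(G)"] = ss_total - sum(ss.values())
    return ss


def truncated_normal_mean_rejection(
    mean: float, sd: float, lo: float, hi: float, rng, n_keep: int = 200_000
) -> float:
    """Mean of Normal(mean, sd) truncated to [lo, hi] by rejection sampling."""
    kept = []
    while len(kept) < n_keep:
        draws = rng.normal(mean, sd, size=n_keep)
        kept.extend(draws[(draws >= lo) & (draws <= hi)])
    return float(np.mean(kept[:n_keep]))
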