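"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive expected results by brute force or closed
form, independently of the library's implementation paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def copied_visits_bruteforce(
    visits: pd.DataFrame,
    window: tuple[float, float],
    threshold: float,
    reference: str = "exit",
) -> set[tuple]:
    """Exhaustive pair scan: every ordered visit pair is tested for (same
    cage and corner, different animal, no intervening visit at that corner,
    latency in [0, threshold)).  Returns a set of
    (cage, leader, follower, corner, follower_entry) tuples."""
    w0, w1 = window
    out = set()
    sel = visits[(visits["entry"] >= w0) & (visits["entry"] < w1)]
    arr = sel[["cage", "animal", "corner", "entry", "exit"]].to_numpy(dtype=object)
    n = len(arr)
    entries = sel["entry"].to_numpy(dtype=float)
    for i in range(n):
        for j in range(n):
            ci, ai, ki, ent_i, ext_i = arr[i]
            cj, aj, kj, ent_j, ext_j = arr[j]
            if ci != cj or ki != kj or ai == aj or not ent_i < ent_j:
                continue
            same_corner = (sel["cage"] == ci).to_numpy() & (sel["corner"] == ki).to_numpy()
            if np.any(same_corner & (entries > ent_i) & (entries < ent_j)):
                continue  # an intervening visit re-demonstrated the corner
            ref = ext_i if reference == "exit" else ent_i
            lat = ent_j - ref
            if 0 <= lat < threshold:
                out.add((ci, ai, aj, ki, float(ent_j)))
    return out


def pearson_chi2_cellwise(table) -> float:
    """Sum over cells of (O - E)^2 / E under independence margins."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    e = row * col / t.sum()
    return float(((t - e) ** 2 / e).sum())
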