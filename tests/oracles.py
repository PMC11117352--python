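"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's seed-and-extend / greedy code
paths: the repeat oracle compares every pair of fixed windows directly, and
the clustering oracle follows the textual definition on a precomputed
identity matrix.
"""

from __future__ import annotations

import numpy as np


def brute_force_best_repeat(
    residues: str,
    window: int = 200,
    stride: int = 25,
    min_sep: int = 2500,
    max_sep: int = 10000,
) -> tuple[int, int, float] | None:
    """Best direct-repeat pair by exhaustive window comparison.

    Compares Hamming identity of every pair of ``window``-bp windows whose
    separation lies in [min_sep, max_sep]; returns (start1, start2,
    identity%) of the best pair or None.  O(n^2 / stride^2) — fixture scale
    only.
    """
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    starts = list(range(0, len(arr) - window + 1, stride))
    best = None
    for i, s1 in enumerate(starts):
        w1 = arr[s1 : s1 + window]
        for s2 in starts[i + 1 :]:
            sep = s2 - s1
            if sep < min_sep:
                continue
            if sep > max_sep:
                break
            ident = 100.0 * float((w1 == arr[s2 : s2 + window]).mean())
            if best is None or ident > best[2]:
                best = (s1, s2, ident)
    return best


def greedy_cluster_oracle(
    ids: list[str], lengths: dict[str, int], identity: dict[tuple[str, str], float], threshold: float
) -> list[list[str]]:
    """Greedy centroid clustering straight from the definition: longest
    first (ties by id), join the first centroid at >= threshold."""
    order = sorted(ids, key=lambda i: (-lengths[i], i))
    clusters: list[list[str]] = []
    for sid in order:
        for cl in clusters:
            pair = (min(sid, cl[0]), max(sid, cl[0]))
            if identity[pair] >= threshold:
                cl.append(sid)
                break
        else:
            clusters.append([sid])
    return clusters
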