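"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values from first principles
(exhaustive enumeration, parity arguments) without reusing any of the
package's algorithmic shortcuts.
"""

from __future__ import annotations

import numpy as np


def n50_bruteforce(lengths: list[int]) -> int:
    """Largest L such that sequences of length >= L sum to >= half the total."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = max(best, L)
    return best


def min_crossovers_bruteforce(M: np.ndarray) -> int:
    """Minimum switches over all 2^m per-site phase assignments.

    Enumerates every phase vector explicitly (vectorised over the 2^m
    assignments); no min(d, n-d) shortcut is used.
    """
    m, n = M.shape
    flips = ((np.arange(2 ** m)[:, None] >> np.arange(m)) & 1).astype(M.dtype)
    painted = M[None, :, :] ^ flips[:, :, None]
    costs = (painted[:, 1:, :] != painted[:, :-1, :]).sum(axis=(1, 2))
    return int(costs.min())


def hot_segments_bruteforce(
    df, rho_bp_min: float = 0.2, total_rho_min: float = 500.0, merge_gap: int = 0
) -> list[tuple[str, int, int]]:
    """All maximal threshold-passing runs, by direct enumeration.

    A run is a set of consecutive intervals (per chromosome, sorted),
    every one with rho/bp > rho_bp_min, with inter-interval track gaps
    <= merge_gap, that cannot be extended on either side; it passes if
    its summed rho (rate x length) > total_rho_min.
    """
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        rows = list(sub.itertuples(index=False))
        k = len(rows)

        def hot(i):
            return rows[i].rho_per_bp > rho_bp_min

        def joined(i):  # interval i-1 and i belong to the same run
            return rows[i].start - rows[i - 1].end <= merge_gap

        for i in range(k):
            for j in range(i, k):
                if not all(hot(t) for t in range(i, j + 1)):
                    continue
                if not all(joined(t) for t in range(i + 1, j + 1)):
                    continue
                # maximality
                if i > 0 and hot(i - 1) and joined(i):
                    continue
                if j + 1 < k and hot(j + 1) and joined(j + 1):
                    continue
                total = sum(
                    r.rho_per_bp * (r.end - r.start) for r in rows[i : j + 1]
                )
                if total > total_rho_min:
                    out.append((chrom, rows[i].start, rows[j].end))
    return sorted(out)


def min_chain_partition_bruteforce(valid_pair) -> "callable":
    """Return a DP computing the minimum number of co-linear runs.

    ``valid_pair(b1, b2)`` says whether block b2 may directly follow b1
    within one run.  Blocks must be pre-sorted; runs are consecutive.
    """

    def count(blocks: list) -> int:
        k = len(blocks)
        if k == 0:
            return 0
        best = [None] * (k + 1)
        best[0] = 0
        for j in range(1, k + 1):
            for i in range(j):
                run = blocks[i:j]
                if all(valid_pair(a, b) for a, b in zip(run, run[1:])):
                    if best[i] is not None and (best[j] is None or best[i] + 1 < best[j]):
                        best[j] = best[i] + 1
        return best[k]

    return count
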