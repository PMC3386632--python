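"""Independent brute-force oracle for cysteine-flanked motif scanning.

Enumerates every (left cysteine, tripeptide occurrence, right cysteine)
triple directly from the residue string and reduces to the innermost
flanks per occurrence.  Deliberately naive and independent of the package
implementation.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_scan(
    residues: str,
    tripeptides,
    max_left: int = 16,
    max_right: int = 16,
) -> set[tuple[str, int, int, int, int, int]]:
    """All flanked matches as (tri, motif_start, left_cys, right_cys, ls, rs).

    All coordinates 1-based; innermost qualifying cysteine on each side.
    """
    n = len(residues)
    out = set()
    for tri in tripeptides:
        for i in range(n - 2):
            if residues[i : i + 3] != tri:
                continue
            m = i + 1  # 1-based motif start
            lefts = [
                p
                for p in range(1, n + 1)
                if residues[p - 1] == "C" and p < m and (m - p - 1) <= max_left
            ]
            rights = [
                q
                for q in range(1, n + 1)
                if residues[q - 1] == "C" and q > m + 2 and (q - (m + 2) - 1) <= max_right
            ]
            if lefts and rights:
                left, right = max(lefts), min(rights)
                out.add((tri, m, left, right, m - left - 1, right - (m + 2) - 1))
    return out


def random_protein(rng: np.random.Generator, length: int, cys_freq: float = 0.08) -> str:
    """Random residue string with elevated cysteine frequency."""
    w = np.full(20, (1.0 - cys_freq) / 19)
    w[AA.index("C")] = cys_freq
    return "".join(rng.choice(list(AA), size=length, p=w))
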