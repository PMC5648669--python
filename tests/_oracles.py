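"""Brute-force reference implementations, independent of the package.

Flood-fill patch labelling and all-pairs minimum-distance joined-pair
counting, written as plainly as possible so they can serve as oracles
for the fast implementations.
"""

import numpy as np


def flood_fill_labels(grid: np.ndarray, class_value, rule: int) -> tuple[np.ndarray, int]:
    """Label connected components of ``class_value`` by explicit flood fill."""
    rows, cols = grid.shape
    if rule == 4:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    labels = np.zeros((rows, cols), dtype=int)
    n = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if grid[r0, c0] != class_value or labels[r0, c0]:
                continue
            n += 1
            stack = [(r0, c0)]
            labels[r0, c0] = n
            while stack:
                r, c = stack.pop()
                for dr, dc in moves:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < rows and 0 <= cc < cols
                            and grid[rr, cc] == class_value
                            and not labels[rr, cc]):
                        labels[rr, cc] = n
                        stack.append((rr, cc))
    return labels, n


def connect_bruteforce(grid: np.ndarray, class_value, rule: int,
                       threshold: float) -> float:
    """CONNECT by exhaustive all-pairs minimum cell-centre distance."""
    labels, n = flood_fill_labels(grid, class_value, rule)
    if n <= 1:
        return 0.0
    coords = [np.argwhere(labels == i).astype(float) for i in range(1, n + 1)]
    joined = 0
    for i in range(n):
        for j in range(i + 1, n):
            dmin = min(
                float(np.hypot(*(a - b)))
                for a in coords[i]
                for b in coords[j]
            )
            if dmin <= threshold:
                joined += 1
    return 100.0 * joined / (n * (n - 1) / 2)
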