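"""Independent re-implementations used as test oracles.

These deliberately avoid the library routines used by the package
(vectorised numpy reductions, skimage labelling, FFT filters) so that
agreement is informative.
"""

from __future__ import annotations

import math

import numpy as np


def naive_grid_epoch_counts(
    z_stack: np.ndarray,
    cell_px: int,
    onsets: list[int],
    post_frames: int,
    threshold: float,
) -> np.ndarray:
    """Triple-loop re-implementation of grid/epoch response counting."""
    t, h, w = z_stack.shape
    n_rows, n_cols = h // cell_px, w // cell_px
    counts = np.zeros((n_rows, n_cols), dtype=int)
    for r in range(n_rows):
        for c in range(n_cols):
            pix = [
                (r * cell_px + i, c * cell_px + j)
                for i in range(cell_px)
                for j in range(cell_px)
            ]
            for onset in onsets:
                hit = False
                for f in range(onset + 1, min(t, onset + post_frames + 1)):
                    mean = sum(z_stack[f, y, x] for (y, x) in pix) / len(pix)
                    if mean >= threshold:
                        hit = True
                        break
                counts[r, c] += hit
    return counts


def flood_fill_components(binary: np.ndarray, connectivity: int = 8):
    """BFS connected components; returns a list of sorted cell-coordinate lists."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary)
    comps = []
    for y in range(h):
        for x in range(w):
            if not binary[y, x] or seen[y, x]:
                continue
            stack, comp = [(y, x)], []
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                comp.append((cy, cx))
                for dy, dx in nbrs:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(sorted(comp))
    return comps


def max_tail_probability(threshold: float, n_samples: int) -> float:
    """P(max of n iid standard normals >= threshold), closed form."""
    phi = 0.5 * (1.0 + math.erf(threshold / math.sqrt(2.0)))
    return 1.0 - phi**n_samples


def gaussian_transfer(sigma: float, omega: float, truncate: float = 4.0) -> float:
    """Amplitude response of the discrete truncated Gaussian kernel at
    angular frequency omega (radians per sample), matching scipy's
    gaussian_filter1d kernel construction."""
    radius = int(truncate * sigma + 0.5)
    k = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (k / sigma) ** 2)
    w /= w.sum()
    return float(np.sum(w * np.cos(omega * k)))
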