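"""Scoring recovered structures against simulator ground truth."""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = ["match_hotspots", "match_centroids"]


def match_hotspots(
    detected_masks: list,
    truth_masks: list,
    min_overlap: float = 0.5,
) -> dict:
    """Greedy one-to-one matching of detected vs ground-truth hotspot masks.

    A pair matches when their intersection covers at least ``min_overlap`` of
    the smaller mask.  Returns precision, recall and the matched index pairs.
    """
    if not (0.0 < min_overlap <= 1.0):
        raise ParameterError("min_overlap must be in (0, 1]")
    det = [np.asarray(m, dtype=bool) for m in detected_masks]
    tru = [np.asarray(m, dtype=bool) for m in truth_masks]
    pairs = []
    used_t: set[int] = set()
    for i, d in enumerate(det):
        best_j, best_ov = -1, 0.0
        for j, t in enumerate(tru):
            if j in used_t:
                continue
            inter = int(np.count_nonzero(d & t))
            denom = min(int(d.sum()), int(t.sum()))
            ov = inter / denom if denom else 0.0
            if ov > best_ov:
                best_ov, best_j = ov, j
        if best_j >= 0 and best_ov >= min_overlap:
            pairs.append((i, best_j))
            used_t.add(best_j)
    precision = len(pairs) / len(det) if det else (1.0 if not tru else 0.0)
    recall = len(pairs) / len(tru) if tru else 1.0
    return {"precision": precision, "recall": recall, "pairs": pairs}


def match_centroids(
    detected_centroids: np.ndarray,
    truth_centroids: np.ndarray,
    max_distance_px: float = 2.0,
) -> dict:
    """Greedy nearest-centroid matching within ``max_distance_px``.

    Returns the fraction of detected centroids matched to a distinct truth
    centroid and the matched pairs.
    """
    det = np.atleast_2d(np.asarray(detected_centroids, dtype=float))
    tru = np.atleast_2d(np.asarray(truth_centroids, dtype=float))
    if det.size and det.shape[1] != 2:
        raise ParameterError("centroids must be (n, 2) arrays")
    if det.size == 0:
        return {"matched_fraction": 0.0 if tru.size else 1.0, "pairs": []}
    if tru.size == 0:
        return {"matched_fraction": 0.0, "pairs": []}
    dists = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    pairs = []
    used_t: set[int] = set()
    # match closest pairs first so a stray detection cannot steal a centroid
    order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
    used_d: set[int] = set()
    for i, j in order:
        i, j = int(i), int(j)
        if i in used_d or j in used_t or dists[i, j] > max_distance_px:
            continue
        pairs.append((i, j))
        used_d.add(i)
        used_t.add(j)
    return {"matched_fraction": len(pairs) / len(det), "pairs": pairs}
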