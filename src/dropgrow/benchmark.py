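"""Score quantification output against synthetic ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_detections", "detection_scores"]


def match_detections(
    result: pd.DataFrame, truth: pd.DataFrame, max_center_dist: float = 5.0
) -> pd.DataFrame:
    """Greedily match detected droplets to ground-truth droplets.

    ``result`` is a table from :func:`dropgrow.quantify.quantify`; ``truth``
    is the ``droplets`` table of a :class:`SyntheticImageTruth`.  Pairs are
    matched closest-first, one-to-one, within ``max_center_dist`` pixels.
    Returns one row per match with center/radius errors and both signals.
    """
    if len(result) == 0 or len(truth) == 0:
        return pd.DataFrame(
            columns=["det_index", "truth_index", "center_dist", "radius_err_frac",
                     "n_cells", "true_signal", "fluor_sum"]
        )
    det_xy = result[["center_x", "center_y"]].to_numpy(float)
    tru_xy = truth[["center_x", "center_y"]].to_numpy(float)
    dist = np.hypot(
        det_xy[:, None, 0] - tru_xy[None, :, 0],
        det_xy[:, None, 1] - tru_xy[None, :, 1],
    )
    pairs = []
    used_d, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for i, j in order:
        if dist[i, j] > max_center_dist:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        r_true = float(truth["radius_px"].iloc[j])
        pairs.append(
            {
                "det_index": int(i),
                "truth_index": int(j),
                "center_dist": float(dist[i, j]),
                "radius_err_frac": abs(float(result["radius_px"].iloc[i]) - r_true) / r_true,
                "n_cells": int(truth["n_cells"].iloc[j]),
                "true_signal": float(truth["true_signal"].iloc[j]),
                "fluor_sum": float(result["fluor_sum"].iloc[i]),
            }
        )
    return pd.DataFrame(pairs)


def detection_scores(
    result: pd.DataFrame, truth: pd.DataFrame, max_center_dist: float = 5.0
) -> tuple[float, float, pd.DataFrame]:
    """(recall, precision, matches) of a detection run against ground truth."""
    matches = match_detections(result, truth, max_center_dist)
    recall = len(matches) / len(truth) if len(truth) else 1.0
    precision = len(matches) / len(result) if len(result) else 1.0
    return recall, precision, matches
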