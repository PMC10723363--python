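"""Scan-level quality control: head-motion filtering and FC-based outliers."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["qc_fd_filter", "qc_fc_pca_outliers"]

#: conventional mean framewise-displacement exclusion threshold (mm)
DEFAULT_FD_THRESHOLD_MM = 0.55


def qc_fd_filter(manifest: pd.DataFrame,
                 threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> pd.DataFrame:
    """Flag scans whose mean framewise displacement exceeds the threshold.

    ``manifest`` needs a ``mean_fd`` column (mm).  Returns a report with the
    FD value, a pass flag, and an exclusion reason for every failed scan.
    """
    if "mean_fd" not in manifest.columns:
        raise ValueError("manifest has no 'mean_fd' column")
    fd = manifest["mean_fd"]
    missing = fd.index[fd.isna()].tolist()
    if missing:
        raise ValueError(f"scans with missing mean FD: {missing}")
    passed = fd <= threshold_mm
    report = pd.DataFrame(
        {
            "mean_fd": fd,
            "fd_pass": passed,
            "reason": np.where(
                passed, "", f"mean FD > {threshold_mm} mm"
            ),
        },
        index=manifest.index,
    )
    return report


def qc_fc_pca_outliers(fc_edges: np.ndarray) -> dict:
    """Flag scans with outlying FC patterns by PCA on stacked edge vectors.

    The first principal component of the scans-by-edges matrix captures the
    dominant shared FC pattern deviation; scans scoring more than 1 sd above
    the mean are flagged.  The component sign is oriented so the largest-
    magnitude score is positive, making flags invariant to row order.
    """
    X = np.asarray(fc_edges, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 scans of FC edges")
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    if np.abs(scores).max() > 0 and scores[np.argmax(np.abs(scores))] < 0:
        scores = -scores
    cut = scores.mean() + scores.std()
    flags = scores > cut
    return {"flags": flags, "pc1_scores": scores, "threshold": float(cut)}
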