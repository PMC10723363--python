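"""Per-subject eigenmode readouts: cumulative gradient amplitudes and pairwise
phase angles, and their cohort-level correspondence with gradient moments.

A gradient's cumulative amplitude sums, over eigenmodes, the quantity
``sqrt((b - a)^2 + (a + b)^2) = sqrt(2) |a + ib|`` where ``a + ib`` is the
gradient's complex eigenvector component on that mode (scaled by the mode's
excitation weight when one has been resolved from data; the weight-times-
component product is gauge-invariant).  The phase angle between two gradients
is the circular mean of their per-mode angle differences, weighted by the
product of the two gradients' per-mode amplitudes; 90 deg means temporally
orthogonal (uncorrelated) gradients, and departures from 90 deg ("collapse")
translate into between-gradient correlation ~ cos(angle).
"""

from __future__ import annotations

import numpy as np

from .oscillator import EigenmodeSet

__all__ = [
    "cumulative_gradient_amplitude",
    "pairwise_phase_angle",
    "eigen_metrics_vector",
    "metrics_variance_correlation",
    "moment_vector",
]


def cumulative_gradient_amplitude(modes: EigenmodeSet, gradient: int) -> float:
    """Summed oscillation magnitude of one gradient across all eigenmodes.

    ``gradient`` is a 0-based index into the K gradients.
    """
    K = modes.n_gradients
    if not 0 <= gradient < K:
        raise IndexError(f"gradient index {gradient} out of range for K={K}")
    total = 0.0
    for m in modes.modes:
        a, b = m.components[gradient].real, m.components[gradient].imag
        total += m.weight * np.sqrt((b - a) ** 2 + (a + b) ** 2)
    return float(total)


def pairwise_phase_angle(modes: EigenmodeSet, g1: int, g2: int) -> float:
    """Amplitude-weighted circular mean phase-angle difference (degrees).

    Per mode the difference ``arg(a1 + i b1) - arg(a2 + i b2)`` is wrapped,
    then averaged on the circle with weights proportional to the product of the
    two gradients' amplitudes on that mode (weights normalized per subject).
    Output lies in (-180, 180].
    """
    K = modes.n_gradients
    if not (0 <= g1 < K and 0 <= g2 < K):
        raise IndexError(f"gradient indices ({g1}, {g2}) out of range for K={K}")
    amps = modes.gradient_amplitudes()            # (n_modes, K)
    weights = amps[:, g1] * amps[:, g2]
    if not np.any(weights > 0):
        raise ValueError(
            f"gradients {g1} and {g2} share no mode with nonzero amplitude; "
            "phase angle undefined"
        )
    weights = weights / weights.sum()
    comp = np.array([m.components for m in modes.modes])
    diffs = np.angle(comp[:, g1]) - np.angle(comp[:, g2])
    mean_angle = np.angle(np.sum(weights * np.exp(1j * diffs)))
    deg = float(np.degrees(mean_angle))
    if deg <= -180.0:
        deg += 360.0
    return deg


def eigen_metrics_vector(modes: EigenmodeSet, fold_angles: bool = True) -> np.ndarray:
    """Per-subject metric vector: K amplitudes then K(K-1)/2 pairwise angles.

    Angles are folded to [0, 180] by default so that cohort comparisons are
    insensitive to the sign convention of the circular difference (``cos`` of
    the angle, which carries the correlation content, is unchanged).
    Pair order is row-major upper triangle (i < j).
    """
    K = modes.n_gradients
    amps = [cumulative_gradient_amplitude(modes, g) for g in range(K)]
    angles = []
    for i in range(K):
        for j in range(i + 1, K):
            ang = pairwise_phase_angle(modes, i, j)
            angles.append(abs(ang) if fold_angles else ang)
    return np.array(amps + angles)


def moment_vector(gts: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Gradient temporal moments: K variances then K(K-1)/2 covariances.

    Pair order matches :func:`eigen_metrics_vector`.
    """
    G = np.asarray(gts, dtype=float)
    sigma = np.cov(G, rowvar=False, ddof=ddof)
    K = sigma.shape[0]
    iu = np.triu_indices(K, k=1)
    return np.concatenate([np.diag(sigma), sigma[iu]])


def metrics_variance_correlation(
    cohort_metrics: np.ndarray, cohort_moments: np.ndarray
) -> dict:
    """Correlate eigenmode metrics with gradient moments across a cohort.

    Both inputs are (subjects, K + K(K-1)/2) with identical column ordering
    (amplitudes/variances first, then angles/covariances).  Returns the full
    Pearson correlation table (metrics x moments) plus the median absolute
    correlation over corresponding (diagonal) and non-corresponding entries.
    Constant columns yield NaN entries and are excluded from the medians.
    """
    M = np.asarray(cohort_metrics, dtype=float)
    V = np.asarray(cohort_moments, dtype=float)
    if M.shape != V.shape:
        raise ValueError("metrics and moments tables must have identical shape")
    if M.shape[0] < 25:
        raise ValueError(f"need at least 25 subjects, got {M.shape[0]}")
    p = M.shape[1]
    table = np.full((p, p), np.nan)
    m_sd = M.std(axis=0)
    v_sd = V.std(axis=0)
    ok_m = m_sd > 0
    ok_v = v_sd > 0
    if np.any(ok_m) and np.any(ok_v):
        zm = (M[:, ok_m] - M[:, ok_m].mean(axis=0)) / m_sd[ok_m]
        zv = (V[:, ok_v] - V[:, ok_v].mean(axis=0)) / v_sd[ok_v]
        sub = (zm.T @ zv) / M.shape[0]
        table[np.ix_(ok_m, ok_v)] = sub
    diag = np.abs(np.diag(table))
    off = np.abs(table[~np.eye(p, dtype=bool)])
    return {
        "correlation": table,
        "median_corresponding_abs_r": float(np.nanmedian(diag)),
        "median_noncorresponding_abs_r": float(np.nanmedian(off)),
        "constant_metric_columns": np.flatnonzero(~ok_m),
        "constant_moment_columns": np.flatnonzero(~ok_v),
    }
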