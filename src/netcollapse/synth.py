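"""Synthetic cohort generation with planted ground truth.

Generates everything the analysis pipeline consumes — a gradient spatial basis
with a unipolar first gradient, per-subject gradient timeseries from a
noise-driven linear coupled damped harmonic-oscillator system, regional atrophy
maps built from a global-severity factor plus focal patterns, and behavior
scores linear in the planted factors — while recording every planted truth so
downstream estimators can be tested for parameter recovery.

Each subject's dynamical system is assembled by direct modal construction: K
eigenmodes with specified eigenvalues ``-gamma_k + i omega_k`` and eigenvector
position parts ``v_k`` (gradient k dominant, small cross-components on the
other gradients whose complex phases encode the planted pairwise phase
angles).  The state matrix ``A = Re(W L W^-1)`` then has exactly those modes,
is stable by construction, and automatically has companion form because every
eigenvector has the shape ``[v; lambda v]``.

Atrophy severity perturbs the dynamics in two planted ways:

* amplitude loss — gradient 1's timeseries is scaled by
  ``1 - atrophy_amplitude_effect * severity`` (times per-subject lognormal
  jitter applied to every gradient), so its temporal variance shrinks
  quadratically with severity;
* phase collapse — the planted gradient 1-4 phase angle moves away from 90 deg
  (temporal orthogonality) by ``atrophy_phase_effect * severity`` degrees.
  Every other gradient pair receives its own jittered target near 90 deg,
  giving the across-subject variation in all pairwise moments that
  cohort-level correspondence analyses require.

The generative system is the same linear second-order model the estimator
fits, driven by white-noise forcing (Euler-Maruyama with an inner step of
TR/10) with a burn-in discarded so the recorded series are stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .oscillator import StabilityError

__all__ = [
    "SyntheticConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "StructureFunctionCohort",
    "default_baseline_coupling",
    "make_synthetic_basis",
    "build_modal_system",
    "build_pair_coupled_system",
    "simulate_noise_driven",
    "simulate_oscillator_subject",
    "make_cohort",
    "make_structure_function_cohort",
]


def build_modal_system(
    omega: np.ndarray,
    damping: np.ndarray,
    cross_amp: float | np.ndarray = 0.15,
    angle_targets_deg: np.ndarray | None = None,
) -> np.ndarray:
    """State matrix with one planted eigenmode per gradient.

    Mode k has eigenvalue ``-damping[k] + i omega[k]`` (rad/TR) and an
    eigenvector position part with unit weight on gradient k and modulus
    ``cross_amp`` on every other gradient g, at complex phase
    ``angle_targets_deg[g, k]`` (antisymmetric; entry [i, j] with i < j is the
    planted phase-angle difference arg(v[i]) - arg(v[j]) for the pair, so 90
    deg means temporal quadrature/orthogonality).  Returns the real 2K x 2K
    companion-form matrix ``A = Re(W L W^-1)``.
    """
    omega = np.asarray(omega, dtype=float)
    damping = np.asarray(damping, dtype=float)
    K = omega.shape[0]
    if np.any(damping <= 0):
        raise StabilityError("all modal dampings must be positive")
    if angle_targets_deg is None:
        angle_targets_deg = np.full((K, K), 90.0)
        angle_targets_deg[np.tril_indices(K)] = -90.0
        np.fill_diagonal(angle_targets_deg, 0.0)
    theta = np.radians(np.asarray(angle_targets_deg, dtype=float))
    eps = np.broadcast_to(np.asarray(cross_amp, dtype=float), (K, K))
    lams = []
    cols = []
    for k in range(K):
        lam = complex(-damping[k], omega[k])
        v = np.full(K, 0j)
        v[k] = 1.0
        for g in range(K):
            if g != k:
                v[g] = eps[g, k] * np.exp(1j * theta[g, k])
        for lam_c, v_c in ((lam, v), (np.conj(lam), np.conj(v))):
            lams.append(lam_c)
            cols.append(np.concatenate([v_c, lam_c * v_c]))
    W = np.array(cols).T
    A = np.real(W @ np.diag(lams) @ np.linalg.inv(W))
    if not (np.allclose(A[:K, :K], 0.0, atol=1e-8)
            and np.allclose(A[:K, K:], np.eye(K), atol=1e-8)):
        raise ValueError(
            "modal construction lost companion structure (cross_amp too large?)"
        )
    A[:K, :K] = 0.0
    A[:K, K:] = np.eye(K)
    return A


def default_baseline_coupling(
    n_gradients: int = 6,
    omega_range: tuple[float, float] = (0.15, 0.45),
    damping_ratio: float = 0.15,
    cross_amp: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline position/velocity coupling blocks for K healthy gradients.

    Natural frequencies ``omega_k`` (rad/TR) ascend over ``omega_range`` so
    gradient 1 has the slowest dynamics and, under equal forcing, the largest
    stationary variance; every pair sits at 90 deg (temporally orthogonal).
    Returned as the (position, velocity) blocks of the companion matrix.
    """
    omega = np.linspace(omega_range[0], omega_range[1], n_gradients)
    A = build_modal_system(omega, damping_ratio * omega, cross_amp)
    K = n_gradients
    return A[K:, :K].copy(), A[K:, K:].copy()


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``noise_sd`` is measurement-side noise (regional residual after basis
    mixing, atrophy residual, behavior residual); ``forcing_sd`` is the
    white-noise process forcing that keeps the oscillator system stationary.
    ``atrophy_amplitude_effect`` is the fractional gradient-1 amplitude loss
    per unit severity; ``atrophy_phase_effect`` the degrees of gradient 1-4
    collapse away from 90 deg per unit severity.
    """

    n_subjects: int = 100
    n_regions: int = 60
    n_gradients: int = 6
    n_timepoints: int = 500
    tr_seconds: float = 2.0
    omega_range: tuple[float, float] = (0.15, 0.45)
    damping_ratio: float = 0.3
    cross_amp: float = 0.15
    atrophy_amplitude_effect: float = 0.25
    atrophy_phase_effect: float = 13.0
    amplitude_jitter_sd: float = 0.2
    angle_jitter_sd: float = 20.0
    noise_sd: float = 0.2
    forcing_sd: float = 1.0
    burn_in: int = 200
    substeps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gradients > self.n_regions:
            raise ValueError("K must not exceed R")
        if self.n_timepoints < 4 * self.n_gradients:
            raise ValueError("need T >= 4K timepoints")
        if self.noise_sd < 0 or self.forcing_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        # baseline must exist and be stable (guaranteed by modal construction,
        # but validated here so bad parameter choices fail loudly at config time)
        A = build_modal_system(self.omega, self.damping, self.cross_amp)
        _check_stability(A)

    @property
    def omega(self) -> np.ndarray:
        return np.linspace(*self.omega_range, self.n_gradients)

    @property
    def damping(self) -> np.ndarray:
        return self.damping_ratio * self.omega

    @property
    def forcing_profile(self) -> np.ndarray:
        """Per-gradient forcing amplitudes, scaled ~omega^1.5 so every mode is
        comparably excited (gradient 1 keeps a modest variance edge)."""
        omega = self.omega
        return self.forcing_sd * (omega / omega[0]) ** 1.5

    @property
    def baseline_coupling(self) -> tuple[np.ndarray, np.ndarray]:
        """(position, velocity) blocks of the zero-severity baseline system."""
        A = build_modal_system(self.omega, self.damping, self.cross_amp)
        K = self.n_gradients
        return A[K:, :K].copy(), A[K:, K:].copy()


def _check_stability(A: np.ndarray, tol: float = 1e-8) -> None:
    eigvals = np.linalg.eigvals(A)
    worst = eigvals[np.argmax(eigvals.real)]
    if worst.real > tol:
        raise StabilityError(
            f"unstable system: eigenvalue {worst:.5g} has positive real part"
        )


@dataclass
class SyntheticSubject:
    severity: float
    focal_scores: tuple[float, float]
    atrophy: np.ndarray | None            # (R,) W-scores; filled by make_cohort
    timeseries: np.ndarray                # (T, R)
    true_gradient_timeseries: np.ndarray  # (T, K)
    true_amplitudes: np.ndarray           # (K,) planted scaling factors
    true_phase_targets: np.ndarray        # (K, K) planted pair angles, deg
    behavior: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    basis: np.ndarray                     # (R, K)
    atrophy: pd.DataFrame                 # subjects x regions
    behavior: pd.DataFrame
    metadata: pd.DataFrame                # severity, focal scores
    truths: dict
    config: SyntheticConfig


def make_synthetic_basis(n_regions: int, n_gradients: int, seed: int = 0) -> np.ndarray:
    """Orthonormal R x K gradient basis whose first column is unipolar.

    Column 1 has strictly positive weights (all regions load with the same
    sign, as the sensory-to-association gradient does); the remaining columns
    are a random orthonormal completion.  Deterministic given the seed.
    """
    if n_gradients > n_regions:
        raise ValueError(f"K={n_gradients} exceeds R={n_regions}")
    rng = np.random.default_rng([seed, 11])
    col1 = np.abs(rng.normal(size=n_regions)) + 0.3
    M = np.column_stack([col1, rng.normal(size=(n_regions, n_gradients - 1))])
    Q, _ = np.linalg.qr(M)
    Q = Q[:, :n_gradients]
    if Q[0, 0] * col1[0] < 0:
        Q[:, 0] = -Q[:, 0]
    # reproducible signs for the free columns
    for j in range(1, n_gradients):
        i = np.argmax(np.abs(Q[:, j]))
        if Q[i, j] < 0:
            Q[:, j] = -Q[:, j]
    return Q


def build_pair_coupled_system(
    theta_deg: float,
    omega: float = 0.25,
    damping: float = 0.01,
    omega2: float = 0.5,
    damping2: float = 0.3,
    cross_amp: float = 0.05,
) -> np.ndarray:
    """Two-gradient state matrix with a planted dominant-mode phase offset.

    The dominant, lightly damped mode carries both gradients with equal
    amplitude and a relative phase of ``theta_deg`` (gradient 2 lagging
    gradient 1); a second, strongly damped mode is localized on gradient 2
    (with a small ``cross_amp`` on gradient 1) so the system is identifiable.
    Under noise forcing the two gradient timeseries correlate at approximately
    ``cos(theta_deg)``.
    """
    theta = np.radians(theta_deg)
    lam1 = complex(-damping, omega)
    lam2 = complex(-damping2, omega2)
    v1 = np.array([1.0, np.exp(-1j * theta)]) / np.sqrt(2)
    v2 = np.array([cross_amp + 0.0j, 1.0 + 0.0j])
    v2 /= np.linalg.norm(v2)
    cols = []
    lams = []
    for lam, v in ((lam1, v1), (np.conj(lam1), np.conj(v1)),
                   (lam2, v2), (np.conj(lam2), np.conj(v2))):
        lams.append(lam)
        cols.append(np.concatenate([v, lam * v]))
    W = np.array(cols).T
    A = np.real(W @ np.diag(lams) @ np.linalg.inv(W))
    A[:2, :2] = 0.0
    A[:2, 2:] = np.eye(2)
    return A


def simulate_noise_driven(
    A: np.ndarray,
    n_timepoints: int,
    forcing_sd: float | np.ndarray = 1.0,
    tr_substeps: int = 10,
    burn_in: int = 200,
    rng: np.random.Generator | int | None = 0,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Stationary gradient timeseries from a stochastically forced system.

    Integrates ``dx = A x dt + [0, forcing] dW`` by Euler-Maruyama with
    ``tr_substeps`` inner steps per TR, discards ``burn_in`` TRs, and returns
    the position coordinates sampled on the TR grid, shape (T, K).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    A = np.asarray(A, dtype=float)
    K = A.shape[0] // 2
    forcing = np.broadcast_to(np.asarray(forcing_sd, dtype=float), (K,))
    dt = 1.0 / tr_substeps
    x = np.zeros(2 * K) if initial_state is None else np.asarray(initial_state, float).copy()
    out = np.empty((n_timepoints, K))
    n_total = (burn_in + n_timepoints) * tr_substeps
    if np.any(forcing > 0):
        noise = rng.normal(size=(n_total, K)) * (forcing * np.sqrt(dt))
    else:
        noise = np.zeros((n_total, K))
    step = 0
    for t in range(burn_in + n_timepoints):
        for _ in range(tr_substeps):
            x = x + dt * (A @ x)
            x[K:] += noise[step]
            step += 1
        if t >= burn_in:
            out[t - burn_in] = x[:K]
    return out


def _subject_system(
    config: SyntheticConfig, severity: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble one subject's state matrix and planted truths."""
    K = config.n_gradients
    targets = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            t = 90.0 + rng.normal(0.0, config.angle_jitter_sd)
            if (i, j) == (0, 3):
                t -= config.atrophy_phase_effect * severity
            # random quadrature sign: the folded angle |t| is what is planted,
            # and randomizing the sign makes the cross-mode contamination of
            # every other pair's angle zero-mean instead of systematic
            t *= rng.choice([-1.0, 1.0])
            targets[i, j] = t
            targets[j, i] = -t
    A = build_modal_system(config.omega, config.damping, config.cross_amp,
                           angle_targets_deg=targets)
    amps = np.exp(rng.normal(0.0, config.amplitude_jitter_sd, size=K))
    amps[0] *= max(1.0 - config.atrophy_amplitude_effect * severity, 0.05)
    return A, targets, amps


def simulate_oscillator_subject(
    config: SyntheticConfig,
    severity: float,
    seed: int,
    basis: np.ndarray | None = None,
) -> SyntheticSubject:
    """One synthetic subject: planted dynamics, mixed to regions, plus noise."""
    rng = np.random.default_rng([config.seed, int(seed)])
    if basis is None:
        basis = make_synthetic_basis(config.n_regions, config.n_gradients,
                                     config.seed)
    A, targets, amps = _subject_system(config, severity, rng)
    _check_stability(A)
    G = simulate_noise_driven(
        A,
        config.n_timepoints,
        forcing_sd=config.forcing_profile,
        tr_substeps=config.substeps,
        burn_in=config.burn_in,
        rng=rng,
    )
    G = G * amps
    if config.noise_sd > 0:
        region_noise = config.noise_sd * rng.normal(
            size=(config.n_timepoints, config.n_regions)
        )
    else:
        region_noise = 0.0
    ts = G @ basis.T + region_noise
    return SyntheticSubject(
        severity=float(severity),
        focal_scores=(0.0, 0.0),
        atrophy=None,
        timeseries=ts,
        true_gradient_timeseries=G,
        true_amplitudes=amps,
        true_phase_targets=targets,
        seed=int(seed),
    )


def _atrophy_patterns(config: SyntheticConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng([config.seed, 13])
    R = config.n_regions
    global_pat = np.abs(rng.normal(size=R)) * 0.4 + 0.3
    focal2 = np.zeros(R)
    focal3 = np.zeros(R)
    idx = rng.permutation(R)
    k = max(R // 5, 2)
    focal2[idx[:k]] = np.abs(rng.normal(size=k)) + 0.5
    focal3[idx[k : 2 * k]] = np.abs(rng.normal(size=k)) + 0.5
    # center the focal maps (bipolar patterns, like syndrome-contrast
    # components) so per-subject mean atrophy tracks the severity factor alone
    focal2 -= focal2.mean()
    focal3 -= focal3.mean()
    return {"global": global_pat, "focal2": focal2, "focal3": focal3}


def make_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Full synthetic cohort with atrophy, timeseries, and behavior tables.

    Severity is uniform on [0, 2]; focal factors are standard normal.  Atrophy
    is ``s * global + f2 * focal2 + f3 * focal3 + noise`` and behavior scores
    are noisy linear combinations of (s, f2, f3).
    """
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng([config.seed, 17])
    basis = make_synthetic_basis(config.n_regions, config.n_gradients, config.seed)
    patterns = _atrophy_patterns(config)
    sev = rng.uniform(0.0, 2.0, size=config.n_subjects)
    f2 = rng.normal(size=config.n_subjects)
    f3 = rng.normal(size=config.n_subjects)
    behavior_weights = {
        "global_cognition": (-1.0, -0.2, -0.2),
        "language": (-0.5, -0.8, 0.1),
        "executive": (-0.5, 0.1, -0.8),
    }
    subjects = []
    atrophy_rows = []
    behav_rows = []
    for i in range(config.n_subjects):
        subj = simulate_oscillator_subject(config, sev[i], seed=1000 + i,
                                           basis=basis)
        subj.focal_scores = (float(f2[i]), float(f3[i]))
        subj.atrophy = (
            sev[i] * patterns["global"]
            + f2[i] * patterns["focal2"]
            + f3[i] * patterns["focal3"]
            + config.noise_sd * rng.normal(size=config.n_regions)
        )
        subj.behavior = {
            name: w[0] * sev[i] + w[1] * f2[i] + w[2] * f3[i]
            + config.noise_sd * rng.normal()
            for name, w in behavior_weights.items()
        }
        subjects.append(subj)
        atrophy_rows.append(subj.atrophy)
        behav_rows.append(subj.behavior)
    ids = [f"sub-{i:04d}" for i in range(config.n_subjects)]
    regions = [f"region_{r:03d}" for r in range(config.n_regions)]
    # scan-level covariates for QC and stratification: plausible head motion
    # (gamma, mean 0.2 mm, occasional large movers) and a severity-band label
    mean_fd = rng.gamma(shape=4.0, scale=0.05, size=config.n_subjects)
    diagnosis = pd.cut(
        sev, bins=[-np.inf, 0.5, 1.0, 1.5, np.inf],
        labels=["CN", "mild", "moderate", "severe"],
    ).astype(str)
    metadata = pd.DataFrame(
        {
            "subject": ids,
            "severity": sev,
            "focal2": f2,
            "focal3": f3,
            "mean_fd": mean_fd,
            "diagnosis": diagnosis,
        }
    ).set_index("subject")
    return SyntheticCohort(
        subjects=subjects,
        basis=basis,
        atrophy=pd.DataFrame(atrophy_rows, index=ids, columns=regions),
        behavior=pd.DataFrame(behav_rows, index=ids),
        metadata=metadata,
        truths={
            "patterns": patterns,
            "behavior_weights": behavior_weights,
            "severity": sev,
            "focal2": f2,
            "focal3": f3,
        },
        config=config,
    )


@dataclass
class StructureFunctionCohort:
    """Directly planted low-rank atrophy / FC-edge cohort.

    Used to test structure-function component extraction: atrophy is a linear
    combination of spatial patterns (the first one global/all-positive) and the
    FC edge table is a linear combination of edge patterns whose subject scores
    correlate with the corresponding atrophy factors at the planted
    ``coupling_r``.
    """

    atrophy: pd.DataFrame                 # S x R
    fc_edges: np.ndarray                  # S x E
    factors: np.ndarray                   # S x C planted structure factors
    function_factors: np.ndarray          # S x C planted function latents
    structure_patterns: np.ndarray        # R x C
    edge_patterns: np.ndarray             # E x C
    labels: np.ndarray                    # pseudo-syndrome labels
    coupling_r: np.ndarray


def make_structure_function_cohort(
    n_subjects: int = 300,
    n_regions: int = 100,
    n_components: int = 3,
    coupling_r: float | tuple = 0.6,
    factor_scales: tuple = (2.4, 1.0, 0.7, 0.5, 0.4),
    atrophy_noise_sd: float = 0.3,
    edge_noise_sd: float = 0.3,
    seed: int = 0,
) -> StructureFunctionCohort:
    """Plant a C-component structure-function cohort.

    Factor variances decrease with component index so component order is
    identifiable; the first structure pattern is all-positive (global
    severity), so component-1 scores track per-subject mean atrophy.
    """
    rng = np.random.default_rng([seed, 19])
    C = n_components
    R = n_regions
    E = R * (R - 1) // 2
    r = np.broadcast_to(np.asarray(coupling_r, dtype=float), (C,)).copy()
    scales = np.asarray(factor_scales[:C], dtype=float)
    F = rng.normal(size=(n_subjects, C)) * scales
    # structure patterns: an all-positive global-severity map plus focal maps
    # orthogonal to it AND exactly mean-zero, so per-subject mean atrophy
    # tracks factor 1 alone
    # lognormal map: strictly positive but spatially heterogeneous; split-half
    # loading comparisons are Pearson correlations of CENTERED loadings, and a
    # near-constant positive map would carry almost no centered signal
    g = np.exp(rng.normal(0.0, 0.75, size=R))
    g /= np.linalg.norm(g)
    span, _ = np.linalg.qr(np.column_stack([g, np.ones(R)]))
    focal = rng.normal(size=(R, C - 1))
    focal -= span @ (span.T @ focal)
    focal, _ = np.linalg.qr(focal)
    P = np.column_stack([g, focal[:, : C - 1]]) * np.sqrt(R)
    Q = rng.normal(size=(E, C))
    Q, _ = np.linalg.qr(Q)
    Q = Q[:, :C] * np.sqrt(E) / 10.0
    zF = (F - F.mean(axis=0)) / F.std(axis=0)
    U = r * zF + np.sqrt(1.0 - r**2) * rng.normal(size=(n_subjects, C))
    atrophy = F @ P.T + atrophy_noise_sd * rng.normal(size=(n_subjects, R))
    fc_edges = (U * scales) @ Q.T + edge_noise_sd * rng.normal(size=(n_subjects, E))
    labels = np.array(["grp%d" % (i % 4) for i in rng.permutation(n_subjects)])
    ids = [f"sub-{i:04d}" for i in range(n_subjects)]
    regions = [f"region_{j:03d}" for j in range(R)]
    return StructureFunctionCohort(
        atrophy=pd.DataFrame(atrophy, index=ids, columns=regions),
        fc_edges=fc_edges,
        factors=F,
        function_factors=U,
        structure_patterns=P,
        edge_patterns=Q,
        labels=labels,
        coupling_r=r,
    )
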