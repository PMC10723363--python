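"""Linear coupled damped harmonic-oscillator model of gradient dynamics.

Each gradient timeseries ``G_k(t)`` is modeled as a second-order linear ODE whose
acceleration depends on every gradient's position and velocity::

    G_k'' = b_k0 + sum_j P[k, j] G_j + sum_j V[k, j] G_j'

Coefficients are estimated by ordinary least squares of the finite-difference
second derivative on positions and first derivatives.  Rewriting the K coupled
second-order equations as 2K first-order equations gives ``dY/dt = A Y + b``
with the companion-form state matrix

    A = [[0, I], [P, V]]      (state ordering: K positions, then K velocities)

whose complex eigenvalues ``alpha + i beta`` carry per-mode damping (``alpha``,
per TR) and angular frequency (``beta``, rad/TR), and whose eigenvectors carry
each gradient's amplitude and phase on that mode.  All fitting is done in TR
time units; frequencies are converted to Hz only for reporting (beta / 2pi / TR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import ttest_rel
from sklearn.base import BaseEstimator

__all__ = [
    "CouplingModel",
    "StateMatrix",
    "Eigenmode",
    "EigenmodeSet",
    "SimulatedTrajectory",
    "OscillatorModel",
    "StabilityError",
    "finite_difference_derivatives",
    "fit_coupling_parameters",
    "build_state_matrix",
    "compute_eigenmodes",
    "simulate_gradients",
    "simulate_subject_fc",
    "fc_identifiability",
]

#: eigenvalues with |imag| below this (per TR) are treated as real (overdamped)
_IMAG_TOL = 1e-9


class StabilityError(ValueError):
    """Raised when a state matrix has an eigenvalue with positive real part."""


@dataclass
class CouplingModel:
    """Fitted second-order coupling coefficients, one equation per gradient.

    Row ``k`` of :attr:`position_coeffs` / :attr:`velocity_coeffs` holds the
    regression weights of ``G_k''`` on all positions / velocities.  Units:
    positions per TR^2, velocities per TR.
    """

    intercepts: np.ndarray            # (K,)
    position_coeffs: np.ndarray       # (K, K)
    velocity_coeffs: np.ndarray       # (K, K)
    r_squared: np.ndarray | None = None  # (K,) fit diagnostics

    @property
    def n_gradients(self) -> int:
        return self.intercepts.shape[0]


@dataclass
class StateMatrix:
    """Companion-form first-order system ``dY/dt = A Y + offset``."""

    A: np.ndarray                # (2K, 2K)
    offset: np.ndarray           # (2K,) affine term from the fitted intercepts

    @property
    def n_gradients(self) -> int:
        return self.A.shape[0] // 2

    def fixed_point(self) -> np.ndarray:
        """Affine fixed point ``-A^{-1} offset`` (least-squares if singular)."""
        if not np.any(self.offset):
            return np.zeros(self.A.shape[0])
        try:
            return -linalg.solve(self.A, self.offset)
        except linalg.LinAlgError:
            return -linalg.lstsq(self.A, self.offset)[0]


@dataclass
class Eigenmode:
    """One oscillatory mode of the state matrix (conjugate pair collapsed).

    ``components[g] = a + ib`` is gradient *g*'s complex coefficient, read from
    the position rows of the eigenvector.  The gauge is fixed by normalizing the
    position subvector to unit modulus-norm and rotating so gradient 1 (or the
    largest-amplitude gradient when gradient 1 is silent) has phase 0.
    ``weight`` is the mode's excitation resolved from observed data (1.0 when no
    data has been attached); the product ``weight * |components|`` is invariant
    to the eigenvector gauge.
    """

    eigenvalue: complex               # alpha + i beta, per TR
    frequency_hz: float
    damping: float                    # alpha, per TR
    components: np.ndarray            # (K,) complex, gauge-normalized
    weight: float = 1.0
    overdamped: bool = False
    position_norm: float = 1.0        # raw-eigenvector position-subvector norm


@dataclass
class EigenmodeSet:
    """Collapsed eigenmodes plus the full raw eigenstructure of one system."""

    modes: list[Eigenmode]
    eigenvalues: np.ndarray           # all 2K eigenvalues
    raw_eigenvectors: np.ndarray      # (2K, 2K) as returned by the solver
    mode_indices: np.ndarray          # column index of each kept mode's raw vector
    state: StateMatrix
    tr_seconds: float
    eigenvector_condition: float = 1.0
    degenerate: bool = False

    @property
    def n_gradients(self) -> int:
        return self.state.n_gradients

    def is_stable(self, tol: float = 1e-8) -> bool:
        return bool(np.max(self.eigenvalues.real) <= tol)

    def resolve_weights(self, states: np.ndarray) -> "EigenmodeSet":
        """Set per-mode excitation weights from an observed state trajectory.

        ``states`` is (T, 2K): positions then velocities.  Each state is
        decomposed onto the raw eigenvectors; a mode's weight is the rms modulus
        of its coefficient timeseries scaled by its raw position-subvector norm
        (and doubled for conjugate pairs, which contribute twice to the real
        signal), making ``weight * |components|`` gauge-invariant.
        """
        dev = states - self.state.fixed_point()
        coeffs = linalg.solve(self.raw_eigenvectors, dev.T)  # (2K, T)
        for mode, idx in zip(self.modes, self.mode_indices):
            rms = float(np.sqrt(np.mean(np.abs(coeffs[idx]) ** 2)))
            pair_factor = 1.0 if mode.overdamped else 2.0
            mode.weight = pair_factor * rms * mode.position_norm
        return self

    def gradient_amplitudes(self) -> np.ndarray:
        """(n_modes, K) per-mode per-gradient amplitude ``weight*sqrt(2)*|a+ib|``."""
        comp = np.array([m.components for m in self.modes])
        w = np.array([m.weight for m in self.modes])
        return np.sqrt(2.0) * w[:, None] * np.abs(comp)


@dataclass
class SimulatedTrajectory:
    gradients: np.ndarray             # (T, K)
    states: np.ndarray                # (T, 2K)
    method: str
    initial_state: np.ndarray


def finite_difference_derivatives(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second finite-difference derivatives of gradient scores.

    Central differences in the interior, one-sided at the endpoints; the time
    unit is 1 TR.  ``scores`` is (T, K) with T >= 3.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < 3:
        raise ValueError(f"need at least 3 timepoints, got {scores.shape[0]}")
    d1 = np.gradient(scores, axis=0)
    d2 = np.gradient(d1, axis=0)
    return d1, d2


def fit_coupling_parameters(
    G: np.ndarray, d1: np.ndarray, d2: np.ndarray, drop_endpoints: int = 0
) -> CouplingModel:
    """Least-squares fit of each gradient's acceleration on all positions and
    velocities plus an intercept (2K+1 coefficients per equation).

    ``drop_endpoints`` excludes that many rows at each end of the series from
    the regression: the one-sided endpoint differences carry O(h) error (which
    the second differencing propagates one row inward), and on clean data
    those few rows can dominate the bias of small coefficients.  The default
    keeps every row, matching finite-differencing of the full series.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    T, K = G.shape
    if T - 2 - 2 * drop_endpoints <= 2 * K + 1:
        raise ValueError(f"too few timepoints ({T}) to fit {2 * K + 1} terms per equation")
    if drop_endpoints:
        sl = slice(drop_endpoints, T - drop_endpoints)
        G, d1, d2 = G[sl], d1[sl], d2[sl]
        T = G.shape[0]
    X = np.column_stack([np.ones(T), G, d1])
    cond = np.linalg.cond(X)
    if not np.isfinite(cond):
        raise linalg.LinAlgError("singular regressor matrix (collinear gradients)")
    if cond > 1e8:
        warnings.warn(
            f"ill-conditioned coupling regression (cond={cond:.3g})", RuntimeWarning
        )
    beta, _, _, _ = np.linalg.lstsq(X, d2, rcond=None)  # (2K+1, K)
    resid = d2 - X @ beta
    ss_tot = np.sum((d2 - d2.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - np.sum(resid**2, axis=0) / ss_tot, 0.0)
    return CouplingModel(
        intercepts=beta[0].copy(),
        position_coeffs=beta[1 : K + 1].T.copy(),
        velocity_coeffs=beta[K + 1 :].T.copy(),
        r_squared=r2,
    )


def build_state_matrix(cm: CouplingModel) -> StateMatrix:
    """Companion form: position rows [0 | I], velocity rows [P | V]."""
    K = cm.n_gradients
    A = np.zeros((2 * K, 2 * K))
    A[:K, K:] = np.eye(K)
    A[K:, :K] = cm.position_coeffs
    A[K:, K:] = cm.velocity_coeffs
    offset = np.concatenate([np.zeros(K), cm.intercepts])
    return StateMatrix(A=A, offset=offset)


def compute_eigenmodes(
    state: StateMatrix | np.ndarray, tr_seconds: float
) -> EigenmodeSet:
    """Eigendecompose the state matrix and collapse conjugate pairs.

    Modes with positive imaginary eigenvalue part are kept (one per conjugate
    pair); real eigenvalues are kept individually and flagged overdamped.  Modes
    are sorted by ascending frequency; frequencies are reported in Hz via
    ``beta / (2 pi TR)``.
    """
    if isinstance(state, np.ndarray):
        state = StateMatrix(A=np.asarray(state, dtype=float),
                            offset=np.zeros(state.shape[0]))
    A = state.A
    if not np.all(np.isfinite(A)):
        raise ValueError("state matrix contains non-finite entries")
    K = state.n_gradients
    eigvals, eigvecs = linalg.eig(A)
    cond = np.linalg.cond(eigvecs)
    degenerate = cond > 1e8
    if degenerate:
        warnings.warn(
            f"near-degenerate eigenvectors (cond={cond:.3g}); "
            "mode decomposition unreliable",
            RuntimeWarning,
        )
    scale = max(1.0, float(np.max(np.abs(eigvals))))
    keep: list[int] = [
        i for i, lam in enumerate(eigvals)
        if lam.imag > _IMAG_TOL * scale or abs(lam.imag) <= _IMAG_TOL * scale
    ]
    modes = []
    for i in keep:
        lam = eigvals[i]
        overdamped = abs(lam.imag) <= _IMAG_TOL * scale
        v_pos = eigvecs[:K, i]
        pnorm = float(np.linalg.norm(v_pos))
        comp = v_pos / pnorm if pnorm > 0 else v_pos
        anchor = 0 if abs(comp[0]) >= 1e-8 else int(np.argmax(np.abs(comp)))
        comp = comp * np.exp(-1j * np.angle(comp[anchor]))
        beta = 0.0 if overdamped else lam.imag
        modes.append(
            Eigenmode(
                eigenvalue=complex(lam),
                frequency_hz=beta / (2.0 * np.pi * tr_seconds),
                damping=float(lam.real),
                components=comp,
                overdamped=overdamped,
                position_norm=pnorm,
            )
        )
    order = np.argsort([m.frequency_hz for m in modes], kind="stable")
    modes = [modes[i] for i in order]
    mode_indices = np.array([keep[i] for i in order])
    return EigenmodeSet(
        modes=modes,
        eigenvalues=eigvals,
        raw_eigenvectors=eigvecs,
        mode_indices=mode_indices,
        state=state,
        tr_seconds=tr_seconds,
        eigenvector_condition=float(cond),
        degenerate=bool(degenerate),
    )


def _check_horizon(eigvals: np.ndarray, n_steps: int) -> None:
    growth = float(np.max(eigvals.real)) * n_steps
    if growth > 50.0:
        raise OverflowError(
            f"unstable system: max Re(lambda)={np.max(eigvals.real):.4g} per TR "
            f"would grow by e^{growth:.1f} over {n_steps} steps"
        )


def simulate_gradients(
    modes_or_state: EigenmodeSet | StateMatrix | np.ndarray,
    initial_state: np.ndarray,
    n_steps: int,
    method: str = "closed_form",
    substeps: int = 20,
    tr_seconds: float = 2.0,
) -> SimulatedTrajectory:
    """Integrate ``dY/dt = A Y + offset`` from an initial state.

    ``closed_form`` evaluates the eigenmode solution ``Y(t) = V e^{L t} V^{-1}
    Y0`` (deviations from the affine fixed point); ``numerical`` runs classical
    RK4 with ``substeps`` sub-intervals per TR.  Both return samples on the TR
    grid, first sample = initial state.
    """
    if isinstance(modes_or_state, EigenmodeSet):
        ms = modes_or_state
    else:
        ms = compute_eigenmodes(modes_or_state, tr_seconds)
    state = ms.state
    K = state.n_gradients
    x0 = np.asarray(initial_state, dtype=float)
    if x0.shape != (2 * K,):
        raise ValueError(f"initial state must have shape ({2 * K},)")
    _check_horizon(ms.eigenvalues, n_steps)
    fp = state.fixed_point()
    if method == "closed_form":
        c0 = linalg.solve(ms.raw_eigenvectors, x0 - fp)
        t = np.arange(n_steps)
        # (T, 2K) complex growth factors; real part is exact for real A
        E = np.exp(np.outer(t, ms.eigenvalues))
        states = np.real((E * c0) @ ms.raw_eigenvectors.T) + fp
    elif method == "numerical":
        A, b = state.A, state.offset
        h = 1.0 / substeps
        states = np.empty((n_steps, 2 * K))
        x = x0.copy()
        states[0] = x
        for n in range(1, n_steps):
            for _ in range(substeps):
                k1 = A @ x + b
                k2 = A @ (x + 0.5 * h * k1) + b
                k3 = A @ (x + 0.5 * h * k2) + b
                k4 = A @ (x + h * k3) + b
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            states[n] = x
    else:
        raise ValueError(f"unknown method {method!r}")
    return SimulatedTrajectory(
        gradients=states[:, :K], states=states, method=method, initial_state=x0
    )


class OscillatorModel(BaseEstimator):
    """Fit the coupled damped harmonic-oscillator model to gradient scores.

    Parameters
    ----------
    tr_seconds : float
        Repetition time of the input timeseries (seconds per sample); used only
        to convert eigenmode angular frequencies to Hz.
    resolve_weights : bool
        If True, per-mode excitation weights are resolved from the training
        trajectory after the eigendecomposition (required for data-scale
        amplitude metrics).

    Attributes
    ----------
    coupling_ : CouplingModel
    state_matrix_ : StateMatrix
    modes_ : EigenmodeSet
    """

    def __init__(self, tr_seconds: float = 2.0, resolve_weights: bool = True,
                 drop_endpoints: int = 0):
        self.tr_seconds = tr_seconds
        self.resolve_weights = resolve_weights
        self.drop_endpoints = drop_endpoints

    def fit(self, X: np.ndarray, y=None) -> "OscillatorModel":
        G = np.asarray(X, dtype=float)
        d1, d2 = finite_difference_derivatives(G)
        self.coupling_ = fit_coupling_parameters(
            G, d1, d2, drop_endpoints=self.drop_endpoints
        )
        self.state_matrix_ = build_state_matrix(self.coupling_)
        self.modes_ = compute_eigenmodes(self.state_matrix_, self.tr_seconds)
        self._states = np.column_stack([G, d1])
        if self.resolve_weights:
            self.modes_.resolve_weights(self._states)
        return self

    def simulate(
        self,
        n_steps: int | None = None,
        initial_state: np.ndarray | None = None,
        method: str = "closed_form",
    ) -> SimulatedTrajectory:
        if initial_state is None:
            initial_state = self._states[0]
        if n_steps is None:
            n_steps = self._states.shape[0]
        return simulate_gradients(
            self.modes_, initial_state, n_steps, method=method,
            tr_seconds=self.tr_seconds,
        )

    def simulate_fc(self, basis: np.ndarray, mode: str = "ensemble") -> np.ndarray:
        """Simulate region FC from the fitted system (see simulate_subject_fc)."""
        return _simulate_fc_from_fit(self, np.asarray(basis, dtype=float), mode)


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _simulate_fc_from_fit(model: OscillatorModel, basis: np.ndarray,
                          mode: str) -> np.ndarray:
    ms = model.modes_
    states = model._states
    T = states.shape[0]
    K = ms.n_gradients
    # a marginally positive fitted eigenvalue is tolerable as long as the
    # trajectory cannot grow appreciably over the simulation horizon
    stable = float(np.max(ms.eigenvalues.real)) * T < 5.0
    if not stable and mode == "ensemble":
        warnings.warn(
            "unstable fitted system; falling back to a single short-horizon "
            "simulation",
            RuntimeWarning,
        )
        mode = "single"
    fp = ms.state.fixed_point()
    V = ms.raw_eigenvectors
    lam = ms.eigenvalues
    if mode == "ensemble":
        # one trajectory per observed timepoint's state, per-trajectory FC averaged
        C0 = linalg.solve(V, (states - fp).T)      # (2K, T)
        t = np.arange(T)
        E = np.exp(np.outer(t, lam))               # (T, 2K)
        Vpos = V[:K].T                              # (2K, K)
        fc_sum = np.zeros((basis.shape[0], basis.shape[0]))
        for j in range(T):
            traj = np.real((E * C0[:, j]) @ Vpos) + fp[:K]
            sigma = np.cov(traj, rowvar=False)
            fc_sum += _corr_from_cov(basis @ sigma @ basis.T)
        return fc_sum / T
    horizon = T if stable else min(T, 50)
    traj = model.simulate(n_steps=horizon, method="closed_form").gradients
    sigma = np.cov(traj, rowvar=False)
    return _corr_from_cov(basis @ sigma @ basis.T)


def simulate_subject_fc(
    gts: np.ndarray,
    basis: np.ndarray,
    mode: str = "ensemble",
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Fit a subject's oscillator model and return the simulated region FC.

    Ensemble mode launches one closed-form trajectory from every observed
    timepoint's (position, velocity) state, computes region FC for each, and
    averages the correlation matrices; single mode uses one trajectory from the
    first observed state.
    """
    model = OscillatorModel(tr_seconds=tr_seconds).fit(np.asarray(gts, dtype=float))
    return model.simulate_fc(basis, mode=mode)


def fc_identifiability(
    actual_fcs: list[np.ndarray], simulated_fcs: list[np.ndarray]
) -> dict:
    """Compare each subject's actual FC with every subject's simulated FC.

    Returns the full similarity table (upper-triangle Pearson r, actual x
    simulated), median self- and other-similarity, a paired t statistic on
    self vs mean-other per subject, and the fraction of subjects whose own
    simulation ranks first.
    """
    if len(actual_fcs) != len(simulated_fcs):
        raise ValueError("actual and simulated FC lists differ in length")
    S = len(actual_fcs)
    R = actual_fcs[0].shape[0]
    iu = np.triu_indices(R, k=1)
    act = np.array([fc[iu] for fc in actual_fcs])
    sim = np.array([fc[iu] for fc in simulated_fcs])
    table = np.corrcoef(act, sim)[:S, S:]
    self_r = np.diag(table)
    other = table[~np.eye(S, dtype=bool)].reshape(S, S - 1)
    tstat, pval = ttest_rel(self_r, other.mean(axis=1))
    return {
        "similarity": table,
        "self_r": self_r,
        "median_self_r": float(np.median(self_r)),
        "median_other_r": float(np.median(other)),
        "t_statistic": float(tstat),
        "p_value": float(pval),
        "self_rank_first_fraction": float(
            np.mean(self_r >= table.max(axis=1) - 1e-12)
        ),
    }
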