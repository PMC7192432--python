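"""Maximum-likelihood dynamic factor analysis (DFA) for multivariate time series.

The model is a linear-Gaussian state-space model with latent random-walk
"common trends"::

    x_t = x_{t-1} + w_t,          w_t ~ MVN(0, I_m)
    y_t = Z x_t + D d_t + v_t,    v_t ~ MVN(0, R)

where ``y_t`` is an n-vector of (z-scored) observations at time t, ``x_t``
holds the m latent trends, ``Z`` is the n x m loading matrix, ``d_t`` an
optional covariate and ``D`` its effect (one shared value or one per series).
The observation level is fixed at zero (the data are z-scored) and the state
covariance Q is fixed to the identity; both are identifiability conventions,
as is the constraint z_ij = 0 for column j > row i on the loading matrix.
The initial state is x_0 ~ MVN(0, kappa * I) with x_1 = x_0 + w_1, so the
filter starts from Var(x_1) = (kappa + 1) * I.

Estimation maximises the marginal likelihood by EM: the E-step is an exact
Kalman filter/smoother (missing observations are dropped from each update;
their moments are reconstructed for the M-step), and the M-step updates the
free loadings, covariate effects and the structured observation covariance R
in closed form.  The updates are conditional (Z, D given the previous R,
then R given the new Z, D), so every iteration is guaranteed not to decrease
the log-likelihood.  Multiple random starts guard against local maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "DFAParams",
    "DFAFit",
    "RotatedFit",
    "R_STRUCTURES",
    "COVARIATE_MODES",
    "count_parameters",
    "kalman_filter_smoother",
    "SmootherResult",
    "em_step",
    "fit_dfa",
    "varimax_rotate",
    "fitted_values",
]

R_STRUCTURES = (
    "diagonal-equal",
    "diagonal-unequal",
    "equal-variance-covariance",
    "grouped-by-class",
    "grouped-by-station",
)
COVARIATE_MODES = ("none", "shared", "unique")

#: variance floor applied in M-step updates of R, to keep likelihoods finite
_R_FLOOR = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Hypothesis object: trend count, R structure and covariate handling.

    ``m = 0`` denotes the trend-free model (pure covariate regression), which
    therefore requires a covariate.  Grouped R structures need series
    metadata (class or station labels) at fit time.
    """

    m: int
    r_structure: str = "diagonal-unequal"
    covariate_mode: str = "none"
    covariate_name: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.m, (int, np.integer)) or self.m < 0:
            raise ValueError(f"trend count m must be a non-negative integer, got {self.m}")
        if self.r_structure not in R_STRUCTURES:
            raise ValueError(
                f"unknown R structure {self.r_structure!r}; choose from {R_STRUCTURES}"
            )
        if self.covariate_mode not in COVARIATE_MODES:
            raise ValueError(f"unknown covariate mode {self.covariate_mode!r}")
        if self.m == 0 and self.covariate_mode == "none":
            raise ValueError("m=0 (trend-free regression) requires a covariate")

    @property
    def label(self) -> str:
        cov = "" if self.covariate_mode == "none" else (
            f"+{self.covariate_name or 'covariate'}({self.covariate_mode})"
        )
        return f"{self.r_structure}/m={self.m}{cov}"


def count_parameters(
    spec: ModelSpec,
    n: int,
    n_classes: int | None = None,
    n_stations: int | None = None,
) -> int:
    """Number of free parameters of a DFA specification on ``n`` series.

    Free loadings: ``n*m - m*(m-1)/2`` (upper-triangle cells of Z are pinned
    to zero for identifiability; Q = I and the level a = 0 are fixed, not
    counted).  R contributes 1 (diagonal-equal), n (diagonal-unequal),
    2 (equal variance-covariance), one per class or one per station for the
    grouped structures.  The covariate effect contributes 0, 1 or n.
    """
    m = spec.m
    if m > n:
        raise ValueError(f"m={m} exceeds the number of series n={n}")
    k = n * m - m * (m - 1) // 2
    rs = spec.r_structure
    if rs == "diagonal-equal":
        k += 1
    elif rs == "diagonal-unequal":
        k += n
    elif rs == "equal-variance-covariance":
        k += 2
    elif rs == "grouped-by-class":
        if n_classes is None:
            raise ValueError("grouped-by-class requires n_classes")
        k += n_classes
    elif rs == "grouped-by-station":
        if n_stations is None:
            raise ValueError("grouped-by-station requires n_stations")
        k += n_stations
    k += {"none": 0, "shared": 1, "unique": n}[spec.covariate_mode]
    return k


@dataclass
class DFAParams:
    """Concrete parameter values of the state-space model.

    ``D`` is stored as an n-vector of per-series covariate effects (all equal
    under the shared mode) or ``None`` when the model has no covariate.
    ``kappa`` is the initial-state prior variance on z-scored data.
    """

    Z: np.ndarray
    R: np.ndarray
    D: np.ndarray | None = None
    kappa: float = 5.0

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    def validate(self) -> None:
        n = self.Z.shape[0]
        if self.R.shape != (n, n):
            raise ValueError("R must be n x n")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if np.linalg.eigvalsh(self.R).min() < -1e-8:
            raise ValueError("R must be positive semi-definite")
        if self.D is not None and self.D.shape != (n,):
            raise ValueError("D must be an n-vector")


@dataclass
class SmootherResult:
    """Output of the Kalman smoother E-step."""

    x_smooth: np.ndarray  # (m, T) smoothed state means
    V_smooth: np.ndarray  # (T, m, m) smoothed state variances
    V_cross: np.ndarray  # (T-1, m, m) Cov(x_t, x_{t+1} | all data)
    loglik: float


def _offset(params: DFAParams, covariates: np.ndarray | None, T: int) -> np.ndarray:
    """Per-cell mean offset D * d_t, shape (n, T)."""
    n = params.n
    if params.D is None or covariates is None:
        return np.zeros((n, T))
    d = np.asarray(covariates, dtype=float)
    if d.shape != (T,):
        raise ValueError(f"covariate series must have length T={T}")
    if np.isnan(d).any():
        raise ValueError("covariate series cannot have missing data")
    return np.outer(params.D, d)


def kalman_filter_smoother(
    params: DFAParams,
    Y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> SmootherResult:
    """Exact linear-Gaussian inference for the DFA model with missing data.

    ``Y`` is (n, T) with NaN marking missing cells.  At each time step the
    rows of Z and R belonging to missing observations are dropped from the
    update, and the log-likelihood accumulates the prediction-error
    decomposition over the non-missing data only.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-d (series x time)")
    n, T = Y.shape
    if params.n != n:
        raise ValueError("params dimension does not match Y")
    obs = ~np.isnan(Y)
    if not obs.any():
        raise ValueError("panel is entirely missing")
    m = params.m
    mu = _offset(params, covariates, T)
    Z, R = params.Z, params.R
    log2pi = np.log(2.0 * np.pi)

    if m == 0:
        ll = 0.0
        for t in range(T):
            o = obs[:, t]
            if not o.any():
                continue
            v = Y[o, t] - mu[o, t]
            F = R[np.ix_(o, o)]
            L = np.linalg.cholesky(F)
            alpha = np.linalg.solve(L, v)
            ll -= 0.5 * (o.sum() * log2pi + 2.0 * np.log(np.diag(L)).sum() + alpha @ alpha)
        empty = np.zeros((0, T))
        return SmootherResult(empty, np.zeros((T, 0, 0)), np.zeros((max(T - 1, 0), 0, 0)), ll)

    I_m = np.eye(m)
    x_pred = np.empty((T, m))
    P_pred = np.empty((T, m, m))
    x_filt = np.empty((T, m))
    P_filt = np.empty((T, m, m))
    ll = 0.0
    x, P = np.zeros(m), (params.kappa + 1.0) * I_m
    # The model is time-invariant, so for stretches with a constant missing
    # pattern the gain and covariances reach a steady state; once reached we
    # reuse them and only propagate the means, which is exact to rounding.
    prev_key: bytes | None = None
    steady = False
    K = Finv = None
    half_logdet = 0.0
    idx_cache: dict[bytes, np.ndarray] = {}
    for t in range(T):
        x_pred[t], P_pred[t] = x, P
        o = obs[:, t]
        key = o.tobytes()
        if key != prev_key:
            steady = False
        if o.any():
            io = idx_cache.get(key)
            if io is None:
                io = idx_cache[key] = np.where(o)[0]
            Zo = Z[io]
            v = Y[io, t] - mu[io, t] - Zo @ x
            if steady:
                Pf = P_filt[t - 1]
            else:
                PZ = P @ Zo.T
                F = Zo @ PZ + R[np.ix_(io, io)]
                try:
                    L = np.linalg.cholesky(F)
                except np.linalg.LinAlgError as exc:
                    raise np.linalg.LinAlgError(
                        "innovation covariance not positive definite (check R)"
                    ) from exc
                half_logdet = np.log(np.diag(L)).sum()
                Linv = np.linalg.inv(L)
                Finv = Linv.T @ Linv
                K = PZ @ Finv
                Pf = P - K @ PZ.T
                Pf = 0.5 * (Pf + Pf.T)
                if key == prev_key and abs(Pf - P_filt[t - 1]).max() < 1e-12:
                    steady = True
            ll -= 0.5 * (io.size * log2pi) + half_logdet + 0.5 * (v @ Finv @ v)
            x = x + K @ v
        else:
            Pf = P
        x_filt[t], P_filt[t] = x, Pf
        P = Pf + I_m  # random-walk prediction
        prev_key = key

    # Rauch-Tung-Striebel smoother (transition = identity); the gain and
    # covariance recursions likewise freeze once both the filter quantities
    # and the smoothed variance have converged within a constant-pattern run.
    x_smooth = np.empty((T, m))
    V_smooth = np.empty((T, m, m))
    V_cross = np.empty((max(T - 1, 0), m, m))
    x_smooth[-1], V_smooth[-1] = x_filt[-1], P_filt[-1]
    J = None
    steady = False
    for t in range(T - 2, -1, -1):
        if steady and (
            abs(P_filt[t] - P_filt[t + 1]).max() > 1e-12
            or abs(V_smooth[t + 1] - V_smooth[t + 2]).max() > 1e-12
        ):
            steady = False
        if not steady:
            J = np.linalg.solve(P_pred[t + 1].T, P_filt[t].T).T  # P_filt P_pred^{-1}
            V = P_filt[t] + J @ (V_smooth[t + 1] - P_pred[t + 1]) @ J.T
            V_smooth[t] = 0.5 * (V + V.T)
            if (
                t + 2 < T
                and abs(P_filt[t] - P_filt[t + 1]).max() < 1e-12
                and abs(V_smooth[t] - V_smooth[t + 1]).max() < 1e-12
            ):
                steady = True
        else:
            V_smooth[t] = V_smooth[t + 1]
        x_smooth[t] = x_filt[t] + J @ (x_smooth[t + 1] - x_pred[t + 1])
        V_cross[t] = J @ V_smooth[t + 1]
    return SmootherResult(x_smooth.T, V_smooth, V_cross, ll)


def _free_gamma_positions(n: int, m: int, covariate_mode: str) -> list[list[int]]:
    """Free-parameter map for the stacked coefficient matrix Gamma = [Z D].

    Returns, per free parameter, the list of positions it occupies in
    vec(Gamma) (column-major).  Z cells with column > row are fixed at zero;
    a shared covariate effect ties all n cells of the D column together.
    """
    groups: list[list[int]] = []
    for j in range(m):
        for i in range(j, n):  # rows i >= column j are free
            groups.append([j * n + i])
    if covariate_mode == "shared":
        groups.append([m * n + i for i in range(n)])
    elif covariate_mode == "unique":
        groups.extend([[m * n + i] for i in range(n)])
    return groups


def _project_R(S: np.ndarray, structure: str, groups: np.ndarray | None) -> np.ndarray:
    """Closed-form M-step for R constrained to the given structure.

    ``S`` is the expected residual outer-product matrix (already divided by
    T).  For diagonal structures the update averages diagonal entries within
    each sharing group; for the equal variance-covariance (compound-symmetry)
    structure the exact MLE follows from the fixed eigenstructure
    R = c1 * J/n + c2 * (I - J/n).
    """
    n = S.shape[0]
    if structure == "diagonal-equal":
        return max(np.mean(np.diag(S)), _R_FLOOR) * np.eye(n)
    if structure == "diagonal-unequal":
        return np.diag(np.maximum(np.diag(S), _R_FLOOR))
    if structure == "equal-variance-covariance":
        c1 = max(S.sum() / n, _R_FLOOR)
        c2 = max((np.trace(S) - S.sum() / n) / (n - 1), _R_FLOOR)
        alpha = (c1 + (n - 1) * c2) / n
        beta = (c1 - c2) / n
        return alpha * np.eye(n) + beta * (np.ones((n, n)) - np.eye(n))
    if structure in ("grouped-by-class", "grouped-by-station"):
        if groups is None:
            raise ValueError(f"{structure} requires series group labels")
        var = np.empty(n)
        for g in np.unique(groups):
            sel = groups == g
            var[sel] = max(np.mean(np.diag(S)[sel]), _R_FLOOR)
        return np.diag(var)
    raise ValueError(f"unknown R structure {structure!r}")


def _estep_moments(
    params: DFAParams,
    Y: np.ndarray,
    covariates: np.ndarray | None,
    smooth: SmootherResult,
):
    """Expected complete-data sufficient statistics for the M-step.

    With w_t = [x_t; d_t] the stacked regressor, returns the per-panel sums
    of E[w w'], E[y w'] and E[y y'] under the smoothing distribution.
    Missing observations are latent: their conditional moments given the
    observed rows and the smoothed state are reconstructed exactly,
    including the R-coupling term for non-diagonal R.
    """
    n, T = Y.shape
    m = params.m
    p = 0 if params.D is None else 1
    q = m + p
    obs = ~np.isnan(Y)
    d = None
    if p:
        d = np.asarray(covariates, dtype=float)
    Z, R = params.Z, params.R
    Dvec = params.D if p else np.zeros(n)

    sum_ww = np.zeros((q, q))
    sum_yw = np.zeros((n, q))
    sum_yy = np.zeros((n, n))

    xs = smooth.x_smooth  # (m, T)
    Vs = smooth.V_smooth  # (T, m, m)

    # group time steps by missing pattern and vectorize within each group
    patterns: dict[bytes, list[int]] = {}
    for t in range(T):
        patterns.setdefault(obs[:, t].tobytes(), []).append(t)

    for key, ts_list in patterns.items():
        ts = np.asarray(ts_list)
        o = np.frombuffer(key, dtype=bool)
        io = np.where(o)[0]
        im = np.where(~o)[0]
        k = ts.size
        X = xs[:, ts]  # (m, k)
        Vsum = Vs[ts].sum(axis=0) if m else np.zeros((0, 0))
        Exx_sum = Vsum + X @ X.T
        dk = d[ts] if p else None

        # E[y | data] for the group, (n, k): observed rows are the data,
        # missing rows use the conditional given states and observed rows
        Ey = np.empty((n, k))
        Ey[io] = Y[np.ix_(io, ts)]
        if im.size:
            if io.size:
                Roo = R[np.ix_(io, io)]
                C = np.linalg.solve(Roo.T, R[np.ix_(im, io)].T).T
                Sigma_M = R[np.ix_(im, im)] - C @ R[np.ix_(io, im)]
            else:
                C = np.zeros((im.size, 0))
                Sigma_M = R[np.ix_(im, im)]
            G = (Z[im] - C @ Z[io]) if m else np.zeros((im.size, 0))
            c_blk = np.zeros((im.size, k))
            if p:
                c_blk += np.outer(Dvec[im], dk)
            if io.size:
                resid_o = Y[np.ix_(io, ts)] - (np.outer(Dvec[io], dk) if p else 0.0)
                c_blk += C @ resid_o
            Ey[im] = c_blk + (G @ X if m else 0.0)

        # E[y x'] summed over the group
        if m:
            Eyx_sum = np.empty((n, m))
            Eyx_sum[io] = Y[np.ix_(io, ts)] @ X.T
            if im.size:
                Eyx_sum[im] = c_blk @ X.T + G @ Exx_sum
        # E[y y'] summed
        sum_yy += Ey @ Ey.T
        if im.size:
            extra = k * Sigma_M + (G @ Vsum @ G.T if m else 0.0)
            sum_yy[np.ix_(im, im)] += extra

        if p:
            sum_ww[:m, :m] += Exx_sum
            xd = X @ dk
            sum_ww[:m, m] += xd
            sum_ww[m, :m] += xd
            sum_ww[m, m] += dk @ dk
            if m:
                sum_yw[:, :m] += Eyx_sum
            sum_yw[:, m] += Ey @ dk
        else:
            sum_ww += Exx_sum
            sum_yw += Eyx_sum
    return sum_ww, sum_yw, sum_yy


def em_step(
    params: DFAParams,
    smooth: SmootherResult,
    Y: np.ndarray,
    covariates: np.ndarray | None,
    spec: ModelSpec,
    groups: np.ndarray | None = None,
) -> DFAParams:
    """One (E)CM update of the free parameters given smoother output.

    Solves the constrained weighted least-squares problem for the free cells
    of Z and the covariate effects (weighting by the current R^{-1}), then
    updates R in closed form under its structure, holding Z and D at their
    new values.  Constrained loading cells remain exactly zero.  Each call
    cannot decrease the marginal log-likelihood.
    """
    n, T = Y.shape
    m = params.m
    p = 0 if params.D is None else 1
    q = m + p
    sum_ww, sum_yw, sum_yy = _estep_moments(params, Y, covariates, smooth)

    if q > 0:
        Rinv = np.linalg.inv(params.R)
        groups_free = _free_gamma_positions(n, m, spec.covariate_mode)
        nfree = len(groups_free)
        M = np.zeros((n * q, nfree))
        for j, pos in enumerate(groups_free):
            M[pos, j] = 1.0
        A = np.kron(sum_ww, Rinv)
        b = (Rinv @ sum_yw).flatten(order="F")
        beta = np.linalg.solve(M.T @ A @ M, M.T @ b)
        gamma = (M @ beta).reshape((n, q), order="F")
        Z_new = gamma[:, :m]
        D_new = gamma[:, m] if p else None
    else:
        gamma = np.zeros((n, 0))
        Z_new, D_new = params.Z[:, :0], None

    S = (sum_yy - sum_yw @ gamma.T - gamma @ sum_yw.T + gamma @ sum_ww @ gamma.T) / T
    S = 0.5 * (S + S.T)
    R_new = _project_R(S, spec.r_structure, groups)
    return DFAParams(Z=Z_new, R=R_new, D=D_new, kappa=params.kappa)


def _run_em(
    params: DFAParams,
    Y: np.ndarray,
    covariates: np.ndarray | None,
    spec: ModelSpec,
    groups: np.ndarray | None,
    tol: float,
    max_iter: int,
) -> tuple[DFAParams, SmootherResult, bool, int]:
    """Iterate (accelerated) EM from ``params`` until the absolute
    log-likelihood improvement drops below ``tol`` or ``max_iter`` is hit.

    Acceleration over-relaxes along the EM direction with an adaptive step
    and keeps an extrapolated iterate only if the next likelihood evaluation
    confirms it; otherwise it falls back to the plain EM iterate, so the
    accepted log-likelihood sequence never decreases.
    """
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    smooth = None
    fallback: DFAParams | None = None
    step = 1.0
    for n_iter in range(1, max_iter + 1):
        smooth = kalman_filter_smoother(params, Y, covariates)
        if smooth.loglik < ll_prev - 1e-9:
            if fallback is not None:
                params, fallback, step = fallback, None, 1.0
                continue
            if smooth.loglik < ll_prev - 1e-6:
                warnings.warn(
                    f"log-likelihood decreased by {ll_prev - smooth.loglik:.2e} "
                    f"at EM iteration {n_iter} ({spec.label})"
                )
        if abs(smooth.loglik - ll_prev) < tol:
            converged = True
            break
        ll_prev = smooth.loglik
        base = em_step(params, smooth, Y, covariates, spec, groups)
        step = min(step * 1.4, 16.0)
        accel = _extrapolate(params, base, step) if step > 1.0 else None
        if accel is not None:
            fallback, params = base, accel
        else:
            fallback, params, step = None, base, 1.0
    if not converged:
        if fallback is not None:
            # the last state is an unconfirmed extrapolation; return the
            # plain EM iterate instead, whose likelihood cannot have dropped
            params = fallback
        smooth = kalman_filter_smoother(params, Y, covariates)
    return params, smooth, converged, n_iter


def _extrapolate(params: DFAParams, base: DFAParams, step: float) -> DFAParams | None:
    """Over-relaxed iterate params + step * (base - params), or None if the
    extrapolated R leaves the positive-definite cone (all R structures here
    are closed under linear combinations, so only positivity can fail)."""
    R = params.R + step * (base.R - params.R)
    if np.diag(R).min() <= 0:
        return None
    off = R - np.diag(np.diag(R))
    if np.any(off) and np.linalg.eigvalsh(R).min() <= 0:
        return None
    Z = params.Z + step * (base.Z - params.Z)
    D = None
    if base.D is not None:
        D = params.D + step * (base.D - params.D)
    return DFAParams(Z=Z, R=R, D=D, kappa=params.kappa)


def _init_params(
    spec: ModelSpec, n: int, rng: np.random.Generator, kappa: float
) -> DFAParams:
    """Random start: free loadings ~ U(-1, 1), R variances ~ U(0.1, 1)."""
    m = spec.m
    Z = np.zeros((n, m))
    for j in range(m):
        Z[j:, j] = rng.uniform(-1.0, 1.0, size=n - j)
    if spec.r_structure == "diagonal-equal":
        R = rng.uniform(0.1, 1.0) * np.eye(n)
    elif spec.r_structure == "equal-variance-covariance":
        R = rng.uniform(0.1, 1.0) * np.eye(n)
    elif spec.r_structure == "diagonal-unequal":
        R = np.diag(rng.uniform(0.1, 1.0, size=n))
    else:
        R = np.diag(rng.uniform(0.1, 1.0, size=n))
    D = np.zeros(n) if spec.covariate_mode != "none" else None
    return DFAParams(Z=Z, R=R, D=D, kappa=kappa)


def _groups_from_metadata(spec: ModelSpec, metadata) -> np.ndarray | None:
    if spec.r_structure == "grouped-by-class":
        col = "class"
    elif spec.r_structure == "grouped-by-station":
        col = "station"
    else:
        return None
    if metadata is None or col not in metadata:
        raise ValueError(f"{spec.r_structure} requires series metadata column {col!r}")
    labels = np.asarray(metadata[col])
    _, codes = np.unique(labels, return_inverse=True)
    return codes


@dataclass
class DFAFit:
    """A converged maximum-likelihood fit plus bookkeeping for model selection."""

    spec: ModelSpec
    params: DFAParams
    x_smooth: np.ndarray  # (m, T)
    x_var: np.ndarray  # (T, m, m)
    loglik: float
    n_data: int
    k: int
    aicc: float
    converged: bool
    n_iter: int
    n_starts: int
    start_logliks: list = field(default_factory=list)
    seed: int | None = None


def fit_dfa(
    Y,
    spec: ModelSpec,
    covariates: np.ndarray | None = None,
    metadata=None,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 5000,
    kappa: float = 5.0,
    screen_iter: int = 100,
) -> DFAFit:
    """Fit a DFA specification by EM with multiple random starts.

    Parameters
    ----------
    Y
        (n, T) array of z-scored anomalies (NaN = missing), or a
        :class:`~dfakit.preprocess.SeriesPanel`, whose metadata then feeds
        the grouped R structures.
    spec
        The model hypothesis to fit.
    covariates
        Length-T covariate series, required when the spec includes one;
        must be complete (no missing values).
    n_starts, seed
        Number of randomized starts and master seed; each start draws its
        initial values from an independent seeded stream, so a fit is fully
        reproducible.
    tol, max_iter
        EM stops when the absolute log-likelihood improvement over one
        iteration falls below ``tol``, or at ``max_iter``.
    screen_iter
        Length of the short screening run given to every start before the
        best start is iterated to convergence.
    """
    metadata_df = metadata
    if hasattr(Y, "to_array"):
        if metadata_df is None:
            metadata_df = Y.meta
        Y = Y.to_array()
    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    if spec.covariate_mode != "none":
        if covariates is None:
            raise ValueError("spec includes a covariate but none was provided")
        covariates = np.asarray(covariates, dtype=float)
        if np.isnan(covariates).any():
            raise ValueError("covariate series cannot have missing data")
    groups = _groups_from_metadata(spec, metadata_df)

    # Screen all random starts with a short EM run, then iterate only the
    # most promising one to convergence (the usual strategy for EM-based
    # factor models, where full runs from every start would be wasteful).
    screen = min(screen_iter, max_iter)
    best = None
    start_lls: list[float] = []
    master = np.random.SeedSequence([int(seed), spec.m, R_STRUCTURES.index(spec.r_structure)])
    for child in master.spawn(n_starts):
        rng = np.random.default_rng(child)
        params = _init_params(spec, n, rng, kappa)
        params, smooth, converged, n_iter = _run_em(
            params, Y, covariates, spec, groups, tol, screen
        )
        start_lls.append(smooth.loglik)
        if best is None or smooth.loglik > best[0]:
            best = (smooth.loglik, params, smooth, converged, n_iter)

    if best is None:
        raise RuntimeError("no EM start produced a fit")
    _, params, smooth, converged, n_iter = best
    if not converged and max_iter > screen:
        params, smooth, converged, extra = _run_em(
            params, Y, covariates, spec, groups, tol, max_iter - screen
        )
        n_iter += extra
    loglik = smooth.loglik
    n_data = int((~np.isnan(Y)).sum())
    n_classes = n_stations = None
    if metadata_df is not None:
        if "class" in metadata_df:
            n_classes = len(np.unique(np.asarray(metadata_df["class"])))
        if "station" in metadata_df:
            n_stations = len(np.unique(np.asarray(metadata_df["station"])))
    k = count_parameters(spec, n, n_classes=n_classes, n_stations=n_stations)
    from .selection import aicc  # deferred: selection imports this module

    return DFAFit(
        spec=spec,
        params=params,
        x_smooth=smooth.x_smooth,
        x_var=smooth.V_smooth,
        loglik=loglik,
        n_data=n_data,
        k=k,
        aicc=aicc(loglik, k, n_data),
        converged=converged,
        n_iter=n_iter,
        n_starts=n_starts,
        start_logliks=start_lls,
        seed=seed,
    )


@dataclass
class RotatedFit:
    """Varimax-rotated presentation of a fit; fitted values are unchanged."""

    Z_rot: np.ndarray
    x_rot: np.ndarray
    H: np.ndarray  # orthogonal rotation with Z_rot = Z @ H, x_rot = H' x


def varimax_rotate(fit: DFAFit) -> RotatedFit:
    """Varimax-rotate loadings and apply the inverse rotation to the trends.

    The rotation is a reporting convention only: ``Z_rot @ x_rot`` equals
    ``Z @ x_smooth`` exactly.  Each rotated trend is sign-flipped, if
    needed, so that the sum of its loadings is non-negative (the sign of a
    trend/loading pair is not identified).
    """
    Z = fit.params.Z
    m = Z.shape[1]
    if m == 0:
        raise ValueError("varimax rotation requires at least one trend")
    if m == 1:
        H = np.eye(1)
    else:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        _, H = rotate_factors(Z, "varimax")
    Z_rot = Z @ H
    signs = np.where(Z_rot.sum(axis=0) >= 0, 1.0, -1.0)
    H = H * signs
    return RotatedFit(Z_rot=Z @ H, x_rot=H.T @ fit.x_smooth, H=H)


def fitted_values(fit: DFAFit, covariates: np.ndarray | None = None) -> np.ndarray:
    """Model predictions Z x_hat + D d for every cell, including missing ones."""
    T = fit.x_smooth.shape[1]
    pred = np.zeros((fit.params.n, T))
    if fit.params.m:
        pred += fit.params.Z @ fit.x_smooth
    if fit.params.D is not None:
        pred += _offset(fit.params, covariates, T)
    return pred
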