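"""Multivariate Curve Resolution – Alternating Least Squares.

Bilinear decomposition ``D ~ C @ S`` of a hyperspectral cube into
non-negative concentration maps ``C`` (pixels x k) and endmember spectra
``S`` (k x channels), alternating non-negative least squares with an
optional contribution-contrast step that shrinks each pixel's
concentration vector toward its dominant component while preserving the
pixel's total concentration.

MCR solutions are inherently permutation- and scale-ambiguous (and, more
generally, rotation-ambiguous); all diagnostics here therefore use
invariant quantities — lack of fit, signal fractions, and matched cosine
similarities via :func:`match_components` — never raw elementwise
comparison.  The scale convention is unit-L2 spectra with concentrations
carrying the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .core import HSImage

__all__ = [
    "MCRConfig",
    "ComponentSet",
    "init_purest_variables",
    "mcr_als",
    "contrast_step",
    "signal_fractions",
    "high_intensity_fraction",
    "match_components",
]


@dataclass(frozen=True)
class MCRConfig:
    n_components: int = 10
    init: str = "purest_variables"      # purest_variables | random | provided
    max_iter: int = 200
    tol_lof: float = 1e-6               # relative change in lack of fit
    nonneg_C: bool = True
    nonneg_S: bool = True
    contrast_weight: float = 0.0
    noise_percent: float = 5.0          # SIMPLISMA offset, % of max mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol_lof <= 0:
            raise ValueError("tol_lof must be positive")
        if not 0.0 <= self.contrast_weight <= 1.0:
            raise ValueError("contrast_weight must lie in [0, 1]")
        if self.init not in ("purest_variables", "random", "provided"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ComponentSet:
    """Fitted MCR model: spectra, concentration maps and diagnostics."""

    S: np.ndarray                       # (k, channels), unit L2 rows
    C: np.ndarray                       # (pixels, k)
    image_shape: tuple[int, int] | None
    lof_percent: float
    signal_fraction_percent: np.ndarray  # (k,)
    residual_percent: float
    iterations_run: int
    converged: bool
    lof_history: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.S.shape[0]

    def concentration_image(self, k: int) -> np.ndarray:
        if self.image_shape is None:
            raise ValueError("component set was fitted on a flat matrix")
        return self.C[:, k].reshape(self.image_shape)

    def reconstruct(self) -> np.ndarray:
        return self.C @ self.S


def _as_matrix(cube) -> tuple[np.ndarray, tuple[int, int] | None]:
    if isinstance(cube, HSImage):
        return cube.flatten(), cube.shape[:2]
    arr = np.asarray(cube, dtype=float)
    if arr.ndim == 3:
        return arr.reshape(-1, arr.shape[2]), arr.shape[:2]
    if arr.ndim == 2:
        return arr, None
    raise ValueError("expected a cube or a pixels-by-channels matrix")


def init_purest_variables(cube, k: int, noise_percent: float = 5.0
                          ) -> tuple[np.ndarray, list[int]]:
    """SIMPLISMA-style initial spectra from the purest channels.

    Purity of channel j is std_j / (mean_j + offset), weighted at every
    selection round by a determinant-based independence factor so that a
    channel (or an exact duplicate of one) is never selected twice.  The
    selected channels' intensity images form an initial concentration
    estimate; the returned initial ``S`` is its non-negative least-squares
    projection onto the data.  Deterministic for fixed input.

    Returns ``(S_init, selected_channel_indices)``.
    """
    D, _ = _as_matrix(cube)
    n_pix, n_chan = D.shape
    if k > n_chan:
        raise ValueError("k exceeds the number of channels")
    mu = D.mean(axis=0)
    sigma = D.std(axis=0)
    offset = noise_percent / 100.0 * (mu.max() if mu.max() > 0 else 1.0)
    purity = sigma / (mu + offset)
    # length-scaled columns for the determinant (independence) weights
    lam = np.sqrt(mu**2 + (sigma + offset) ** 2)
    lam[lam == 0] = 1.0
    Z = D / lam
    G = (Z.T @ Z) / n_pix           # channel correlation-around-origin
    rank = np.linalg.matrix_rank(D)
    selected: list[int] = []
    for step in range(k):
        if not selected:
            score = purity.copy()          # first pick: pure purity criterion
        else:
            weights = np.empty(n_chan)
            for j in range(n_chan):
                idx = selected + [j]
                weights[j] = max(np.linalg.det(G[np.ix_(idx, idx)]), 0.0)
            score = purity * weights
            score[selected] = -np.inf
        j_best = int(np.argmax(score))
        selected.append(j_best)
    if k > rank:
        import warnings

        warnings.warn(f"k={k} exceeds numerical rank {rank} of the data",
                      stacklevel=2)
    C0 = D[:, selected]             # (pixels, k) intensity columns
    S0 = np.empty((k, n_chan))
    for j in range(n_chan):
        S0[:, j], _ = nnls(C0, D[:, j])
    # guard against all-zero rows (degenerate channel selection)
    for i in range(k):
        if not S0[i].any():
            S0[i] = D[np.argmax(C0[:, i])]
    return S0, selected


def contrast_step(C: np.ndarray, weight: float) -> np.ndarray:
    """Contribution-contrast operator.

    Shrinks each pixel's concentration vector toward a vector with all of
    the pixel's total concentration on its dominant component:
    ``C' = (1 - w) * C + w * proj_dominant(C)``.  Per-pixel sums are
    preserved exactly; ``weight=0`` is the identity; ties on the dominant
    component break toward the lowest component index.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    C = np.asarray(C, dtype=float)
    if weight == 0.0:
        return C.copy()
    dominant = np.argmax(C, axis=1)
    proj = np.zeros_like(C)
    proj[np.arange(C.shape[0]), dominant] = C.sum(axis=1)
    return (1.0 - weight) * C + weight * proj


def _fnnls(G: np.ndarray, f: np.ndarray, max_outer: int | None = None
           ) -> np.ndarray:
    """Active-set NNLS on the normal equations (Bro & de Jong fast NNLS).

    Solves min ||A x - b||, x >= 0, given G = A^T A and f = A^T b.  The
    passive set grows by the most violated coordinate (deterministic
    tie-break by lowest index via argmax), so repeated calls are
    reproducible.
    """
    k = f.size
    x = np.zeros(k)
    passive = np.zeros(k, dtype=bool)
    w = f.copy()
    tol = 1e-12 * max(float(np.abs(f).max()), 1.0)
    outer = 0
    limit = max_outer or 3 * k + 10
    while not passive.all() and np.any(w[~passive] > tol) and outer < limit:
        outer += 1
        cand = np.where(~passive, w, -np.inf)
        passive[int(np.argmax(cand))] = True
        while True:
            idx = np.flatnonzero(passive)
            try:
                s_p = np.linalg.solve(G[np.ix_(idx, idx)], f[idx])
            except np.linalg.LinAlgError:
                s_p = np.linalg.lstsq(G[np.ix_(idx, idx)], f[idx],
                                      rcond=None)[0]
            if np.all(s_p > tol):
                x = np.zeros(k)
                x[idx] = s_p
                break
            s = np.zeros(k)
            s[idx] = s_p
            bad = passive & (s <= tol)
            denom = x[bad] - s[bad]
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(denom > 0, x[bad] / denom, np.inf)
            alpha = float(np.min(alphas)) if alphas.size else 0.0
            x = x + alpha * (s - x)
            passive[x <= tol] = False
            if not passive.any():
                x = np.zeros(k)
                break
        w = f - G @ x
    return x


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_i - b_i|| s.t. x_i >= 0 for every column b_i of B.

    Returns X with shape (A.shape[1], B.shape[1]).  Uses Gram-based
    active-set NNLS per column (column order fixes tie-breaking
    deterministically), with a Lawson–Hanson fallback on ill-conditioned
    columns.
    """
    k = A.shape[1]
    G = A.T @ A
    F = A.T @ B
    # fast path: columns whose unconstrained solution is already feasible
    # satisfy the KKT conditions and need no active-set work
    try:
        X = np.linalg.solve(G, F)
        needs_work = np.flatnonzero(np.any(X < 0, axis=0))
        X[:, needs_work] = 0.0
    except np.linalg.LinAlgError:
        X = np.zeros((k, B.shape[1]))
        needs_work = np.arange(B.shape[1])
    for i in needs_work:
        xi = _fnnls(G, F[:, i])
        if not np.all(np.isfinite(xi)):
            xi, _ = nnls(A, B[:, i])
        X[:, i] = xi
    return X


def mcr_als(cube, config: MCRConfig = MCRConfig(),
            S_init: np.ndarray | None = None) -> ComponentSet:
    """Run alternating least squares on a cube (or pixel matrix).

    Each iteration updates C given S and S given C (non-negatively when
    configured), applies the contrast step when ``contrast_weight > 0``,
    renormalises rows of S to unit L2 norm (scale absorbed into C), and
    evaluates the lack of fit LOF(%) = 100 * sqrt(sum(resid^2)/sum(D^2)).
    Stops when the relative LOF change drops below ``tol_lof`` or after
    ``max_iter`` iterations; non-convergence is reported in the result,
    not raised.
    """
    D, image_shape = _as_matrix(cube)
    if not np.all(np.isfinite(D)):
        raise ValueError("cube contains non-finite values")
    k = config.n_components
    if k > D.shape[0]:
        raise ValueError("more components than pixels")
    total_ss = float(np.sum(D**2))
    if total_ss == 0.0:
        raise ValueError("zero-signal cube")

    if config.init == "provided":
        if S_init is None:
            raise ValueError("init='provided' requires S_init")
        S = np.asarray(S_init, dtype=float).copy()
    elif config.init == "random":
        rng = np.random.default_rng(config.seed)
        S = rng.random((k, D.shape[1]))
    else:
        S, _ = init_purest_variables(D, k, config.noise_percent)
    S = _unit_rows(S)

    lof_history: list[float] = []
    converged = False
    C = np.zeros((D.shape[0], k))
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        # C update: rows of D against current S
        if config.nonneg_C:
            C = _nnls_rows(S.T, D.T).T
        else:
            C = np.linalg.lstsq(S.T, D.T, rcond=None)[0].T
        if config.contrast_weight > 0:
            C = contrast_step(C, config.contrast_weight)
        # S update: columns of D against current C
        if config.nonneg_S:
            S = _nnls_rows(C, D)
        else:
            S = np.linalg.lstsq(C, D, rcond=None)[0]
        S, C = _renormalise(S, C)
        resid = D - C @ S
        lof = 100.0 * np.sqrt(np.sum(resid**2) / total_ss)
        lof_history.append(lof)
        # LOF of the zero model is 100%, which serves as the pre-iteration
        # reference, so a huge tolerance stops after the first iteration.
        prev = lof_history[-2] if len(lof_history) >= 2 else 100.0
        if abs(prev - lof) / max(prev, 1e-300) < config.tol_lof:
            converged = True
            break

    recon = C @ S
    fractions = np.array([
        100.0 * np.sum(np.outer(C[:, i], S[i]) ** 2) / total_ss
        for i in range(k)
    ])
    residual_pct = 100.0 * np.sum((D - recon) ** 2) / total_ss
    return ComponentSet(
        S=S, C=C, image_shape=image_shape, lof_percent=lof_history[-1],
        signal_fraction_percent=fractions, residual_percent=residual_pct,
        iterations_run=iterations, converged=converged,
        lof_history=lof_history,
    )


def _unit_rows(S: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return S / norms


def _renormalise(S: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(S, axis=1)
    norms[norms == 0] = 1.0
    return S / norms[:, None], C * norms[None, :]


def signal_fractions(component_set: ComponentSet, cube) -> tuple[np.ndarray, float]:
    """Per-component sum-squared-signal percentages of the total signal.

    fraction_k = 100 * sum((C_k S_k^T)^2) / sum(D^2); also returns the
    residual percentage.
    """
    D, _ = _as_matrix(cube)
    total_ss = float(np.sum(D**2))
    if total_ss == 0.0:
        raise ValueError("zero-signal cube")
    C, S = component_set.C, component_set.S
    fractions = np.array([
        100.0 * np.sum(np.outer(C[:, i], S[i]) ** 2) / total_ss
        for i in range(S.shape[0])
    ])
    residual = 100.0 * np.sum((D - C @ S) ** 2) / total_ss
    return fractions, residual


def high_intensity_fraction(concentration_map: np.ndarray, mask: np.ndarray,
                            threshold_rule: str = "percentile",
                            value: float | None = None,
                            pooled: np.ndarray | None = None) -> float:
    """Percent of in-mask pixels whose concentration exceeds a threshold.

    ``threshold_rule`` is one of:

    - ``"absolute"``: threshold is ``value``;
    - ``"percentile"``: threshold is the ``value``-th percentile (default
      60) of ``pooled`` (e.g. both classes' concentrations pooled) or, if
      no pool is given, of the in-mask values;
    - ``"otsu"``: Otsu's threshold on the in-mask values (rejected when
      all values are equal — the split is undefined).
    """
    cmap = np.asarray(concentration_map, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    vals = cmap[m]
    if threshold_rule == "absolute":
        if value is None:
            raise ValueError("absolute rule requires a value")
        thr = float(value)
    elif threshold_rule == "percentile":
        q = 60.0 if value is None else float(value)
        ref = np.asarray(pooled, dtype=float).ravel() if pooled is not None else vals
        thr = float(np.percentile(ref, q))
    elif threshold_rule == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(vals) == 0:
            raise ValueError("Otsu threshold undefined on an all-equal map")
        thr = float(threshold_otsu(vals))
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return 100.0 * float(np.mean(vals > thr))


def match_components(S_est: np.ndarray, S_true: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one component assignment by total cosine similarity.

    Returns ``(permutation, cosines)`` where ``permutation[i]`` is the row
    of ``S_true`` matched to row i of ``S_est`` (Hungarian assignment on
    the negative cosine matrix; scale-invariant).  With unequal counts the
    smaller set is matched and the rest reported as -1.
    """
    A = np.asarray(S_est, dtype=float)
    B = np.asarray(S_true, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("channel grids differ")
    An = _unit_rows(A)
    Bn = _unit_rows(B)
    cosines = An @ Bn.T
    rows, cols = linear_sum_assignment(-cosines)
    perm = np.full(A.shape[0], -1, dtype=int)
    matched = np.zeros(A.shape[0])
    for r, c in zip(rows, cols):
        perm[r] = c
        matched[r] = cosines[r, c]
    return perm, matched
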