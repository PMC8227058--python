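"""REML/BLUP linear mixed model with separable AR1xAR1 spatial residuals.

Model for one trait y over the trial's plots:

    y = X B + Z1 b + Z2 g + e,
    b ~ N(0, Vb I),  g ~ N(0, Vg I),  e ~ N(0, Ve R),

with fixed effects B (intercept, replication contrasts, one column per check
genotype), random block-within-replication effects b, random full-sib family
effects g, and residuals whose correlation R is separable over the field grid:
R_ij = rho_row^|row_i - row_j| * rho_col^|col_i - col_j|, built on occupied
plot coordinates only.

Variance components (Vb, Vg, Ve, rho_row, rho_col) are estimated by restricted
maximum likelihood using Average-Information (AI) Newton updates with
step-halving, falling back to a derivative-free simplex search on a
transformed scale when an AI step cannot improve the criterion. The REML
criterion is evaluated through the Henderson mixed-model-equation (MME)
factorization rather than by inverting the full n x n covariance.

From the fitted model: family BLUPs g_hat, their prediction-error covariance
(PEV, the family block of the inverse MME coefficient matrix), the mean
pairwise prediction-error variance mean_{i<j} var(g_hat_i - g_hat_j), and the
PEV-based (Cullis) broad-sense heritability

    H = 1 - PEV_pairwise / (2 Vg),

which may legitimately be negative when family prediction is worse than
useless. The approximate genetic correlation between two traits is the Pearson
correlation of their family BLUP vectors from separate single-trait fits.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, toeplitz

logger = logging.getLogger(__name__)

_RHO_BOUND = 0.99


# ---------------------------------------------------------------------------
# correlation structures
# ---------------------------------------------------------------------------

def ar1_correlation(rho: float, n: int) -> np.ndarray:
    """AR1 correlation matrix of size n: entry (i, j) = rho^|i-j|."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return toeplitz(rho ** np.arange(n))


def ar1_kron_ar1(rho_row: float, rho_col: float, rows, cols) -> np.ndarray:
    """Separable AR1xAR1 correlation over occupied plots at (rows, cols).

    Exact exponent-of-distance entries, so missing grid cells need no phantom
    plots. Symmetric with unit diagonal; positive definite for |rho| < 1.
    """
    for name, r in (("rho_row", rho_row), ("rho_col", rho_col)):
        if not abs(r) < 1:
            raise ValueError(f"|{name}| must be < 1, got {r}")
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    if rows.shape != cols.shape:
        raise ValueError("rows and cols must align")
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    return rho_row**dr * rho_col**dc


def _ar1_kron_ar1_drho(rho: float, d_own: np.ndarray, other_factor: np.ndarray) -> np.ndarray:
    # d/drho of rho^d is d * rho^(d-1); zero where d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dpow = np.where(d_own > 0, d_own * np.where(d_own > 0, rho, 1.0) ** (d_own - 1), 0.0)
    return dpow * other_factor


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarComponents:
    Vb: float
    Vg: float
    Ve: float
    rho_row: float = 0.0
    rho_col: float = 0.0

    def validate(self) -> None:
        for name in ("Vb", "Vg", "Ve"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_row", "rho_col"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")


@dataclass
class MixedModelSpec:
    """Design matrices and residual coordinates for one trait."""

    y: np.ndarray
    X: np.ndarray
    Z1: np.ndarray  # block-within-rep incidence (may have 0 columns)
    Z2: np.ndarray  # family incidence; all-zero rows for check plots
    rows: np.ndarray  # field row per plot (residual coordinates)
    cols: np.ndarray
    fixed_labels: list[str] = field(default_factory=list)
    block_labels: list[str] = field(default_factory=list)
    family_labels: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.y)


def build_design(table: pd.DataFrame, values, include_blocks: bool = True) -> MixedModelSpec:
    """Assemble X, Z1, Z2 from a plot table.

    ``table`` needs columns plot_id, field_row, field_col, rep, block,
    genotype_id, genotype_class; ``values`` is the per-plot trait vector
    aligned with the table. X carries an intercept, treatment-coded
    replication contrasts and one indicator per check/genitor genotype, so
    family plots are the reference level and family effects (Z2) are
    deviations from the family-population mean.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != len(table):
        raise ValueError("one trait value per plot required")
    if not np.isfinite(y).all():
        raise ValueError("missing/non-finite trait values are not supported here")
    if table.plot_id.duplicated().any():
        dupes = table.plot_id[table.plot_id.duplicated()].tolist()
        raise ValueError(f"duplicated plot_id: {dupes[:5]}")

    n = len(table)
    reps = np.asarray(table.rep)
    rep_levels = np.unique(reps)
    is_family = np.asarray(table.genotype_class == "family")
    gids = np.asarray(table.genotype_id)

    cols_X = [np.ones(n)]
    fixed_labels = ["intercept"]
    for r in rep_levels[1:]:
        cols_X.append((reps == r).astype(float))
        fixed_labels.append(f"rep_{r}")
    check_ids = sorted(set(gids[~is_family]))
    for cid in check_ids:
        cols_X.append((gids == cid).astype(float))
        fixed_labels.append(f"check_{cid}")
    X = np.column_stack(cols_X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient fixed-effects design (labels: {fixed_labels})")

    block_keys = sorted({(r, b) for r, b in zip(table.rep, table.block)}) if include_blocks else []
    block_index = {k: j for j, k in enumerate(block_keys)}
    Z1 = np.zeros((n, len(block_keys)))
    if include_blocks:
        for i, (r, b) in enumerate(zip(table.rep, table.block)):
            Z1[i, block_index[(r, b)]] = 1.0

    family_ids = sorted(set(gids[is_family]))
    fam_index = {f: j for j, f in enumerate(family_ids)}
    Z2 = np.zeros((n, len(family_ids)))
    for i, (gid, fam) in enumerate(zip(gids, is_family)):
        if fam:
            Z2[i, fam_index[gid]] = 1.0

    return MixedModelSpec(
        y=y,
        X=X,
        Z1=Z1,
        Z2=Z2,
        rows=np.asarray(table.field_row, dtype=float),
        cols=np.asarray(table.field_col, dtype=float),
        fixed_labels=fixed_labels,
        block_labels=[f"rep{r}_blk{b}" for r, b in block_keys],
        family_labels=list(family_ids),
    )


# ---------------------------------------------------------------------------
# REML criterion (Henderson MME route)
# ---------------------------------------------------------------------------

def _mme_pieces(spec: MixedModelSpec, theta: VarComponents, var_floor: float):
    """Factorized MME quantities at theta; shared by loglik and BLUP extraction."""
    n, p = spec.n, spec.X.shape[1]
    nb, nf = spec.Z1.shape[1], spec.Z2.shape[1]
    Vb = max(theta.Vb, var_floor) if nb else 0.0
    Vg = max(theta.Vg, var_floor)
    Ve = max(theta.Ve, var_floor)

    R = ar1_kron_ar1(theta.rho_row, theta.rho_col, spec.rows, spec.cols)
    cR = cho_factor(R, lower=True)
    logdet_R = 2.0 * float(np.log(np.diag(cR[0])).sum())

    W = np.hstack([spec.X, spec.Z1, spec.Z2])
    RiW = cho_solve(cR, W) / Ve
    Riy = cho_solve(cR, spec.y) / Ve
    WtRiW = W.T @ RiW
    WtRiy = W.T @ Riy

    g_var = np.concatenate([np.full(nb, Vb), np.full(nf, Vg)])
    C = WtRiW.copy()
    C[p:, p:] += np.diag(1.0 / g_var)
    cC = cho_factor(C, lower=True)
    sol = cho_solve(cC, WtRiy)
    logdet_C = 2.0 * float(np.log(np.diag(cC[0])).sum())

    M = WtRiW[p:, p:] + np.diag(1.0 / g_var)
    cM = cho_factor(M, lower=True)
    logdet_M = 2.0 * float(np.log(np.diag(cM[0])).sum())

    yPy = float(spec.y @ Riy - WtRiy @ sol)
    logdet_V = n * math.log(Ve) + logdet_R + float(np.log(g_var).sum()) + logdet_M
    logdet_XtViX = logdet_C - logdet_M
    return {
        "sol": sol, "cC": cC, "p": p, "nb": nb, "nf": nf,
        "yPy": yPy, "logdet_V": logdet_V, "logdet_XtViX": logdet_XtViX,
        "Vb": Vb, "Vg": Vg, "Ve": Ve, "R": R,
    }


def restricted_loglik(spec: MixedModelSpec, theta: VarComponents,
                      var_floor: float = 0.0) -> float:
    """Restricted log-likelihood l_R at the given variance components.

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| - log|X'X| + y'Py ].

    The log|X'X| normalization makes the value invariant to the fixed-effects
    parameterization (treatment vs sum coding give identical l_R).
    """
    theta.validate()
    pieces = _mme_pieces(spec, theta, var_floor)
    n, p = spec.n, pieces["p"]
    sign, logdet_XtX = np.linalg.slogdet(spec.X.T @ spec.X)
    if sign <= 0:
        raise ValueError("singular X'X")
    return -0.5 * (
        (n - p) * math.log(2.0 * math.pi)
        + pieces["logdet_V"]
        + pieces["logdet_XtViX"]
        - logdet_XtX
        + pieces["yPy"]
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    theta: VarComponents
    beta: np.ndarray
    fixed_labels: list[str]
    b_hat: np.ndarray
    g_hat: np.ndarray
    family_labels: list[str]
    pev_g: np.ndarray  # nf x nf prediction-error covariance of family BLUPs
    mean_pairwise_pev: float
    mean_diag_pev: float
    loglik: float
    converged: bool
    n_iter: int
    H: float  # NaN when Vg pinned at the floor
    loglik_trace: list[float] = field(default_factory=list)
    vg_at_floor: bool = False


def _dense_P_and_derivs(spec: MixedModelSpec, theta: VarComponents, active: list[str]):
    """Dense P, Py and dV/dtheta_i for the AI score and information."""
    n = spec.n
    R = ar1_kron_ar1(theta.rho_row, theta.rho_col, spec.rows, spec.cols)
    V = theta.Ve * R
    if spec.Z1.shape[1]:
        V = V + theta.Vb * (spec.Z1 @ spec.Z1.T)
    V = V + theta.Vg * (spec.Z2 @ spec.Z2.T)
    cV = cho_factor(V, lower=True)
    Vinv = cho_solve(cV, np.eye(n))
    ViX = Vinv @ spec.X
    XtViX = spec.X.T @ ViX
    P = Vinv - ViX @ np.linalg.solve(XtViX, ViX.T)
    Py = P @ spec.y

    dr = np.abs(spec.rows[:, None] - spec.rows[None, :])
    dc = np.abs(spec.cols[:, None] - spec.cols[None, :])
    Rr = theta.rho_row**dr
    Rc = theta.rho_col**dc
    dV = {}
    for name in active:
        if name == "Vb":
            dV[name] = spec.Z1 @ spec.Z1.T
        elif name == "Vg":
            dV[name] = spec.Z2 @ spec.Z2.T
        elif name == "Ve":
            dV[name] = R
        elif name == "rho_row":
            dV[name] = theta.Ve * _ar1_kron_ar1_drho(theta.rho_row, dr, Rc)
        elif name == "rho_col":
            dV[name] = theta.Ve * _ar1_kron_ar1_drho(theta.rho_col, dc, Rr)
    return P, Py, dV


def _theta_to_vec(theta: VarComponents, active: list[str]) -> np.ndarray:
    return np.array([getattr(theta, a) for a in active])


def _vec_to_theta(vec: np.ndarray, active: list[str], base: VarComponents) -> VarComponents:
    d = {a: float(v) for a, v in zip(active, vec)}
    return VarComponents(
        Vb=d.get("Vb", base.Vb),
        Vg=d.get("Vg", base.Vg),
        Ve=d.get("Ve", base.Ve),
        rho_row=d.get("rho_row", base.rho_row),
        rho_col=d.get("rho_col", base.rho_col),
    )


def _project(vec: np.ndarray, active: list[str], var_floor: float) -> np.ndarray:
    out = vec.copy()
    for i, a in enumerate(active):
        if a.startswith("rho"):
            out[i] = float(np.clip(out[i], -_RHO_BOUND, _RHO_BOUND))
        else:
            out[i] = max(out[i], var_floor)
    return out


def reml_fit(spec: MixedModelSpec, init: VarComponents | None = None,
             fit_rho: bool = True, max_iter: int = 100,
             tol_loglik: float = 1e-6, tol_params: float = 1e-4,
             pev_mode: str = "pairwise") -> MixedModelFit:
    """Maximize the REML criterion and extract BLUPs, PEV and heritability.

    AI-REML with step-halving; a Nelder-Mead polish on (log-variance,
    atanh-correlation) scale takes over if an AI step cannot improve the
    criterion. Variances are kept above a soft floor of 1e-8 * var(y);
    correlations inside [-0.99, 0.99]. Non-convergence returns a fit with
    ``converged=False`` and a warning rather than raising.
    """
    if spec.n <= spec.X.shape[1]:
        raise ValueError("more fixed-effect parameters than observations")
    vy = float(np.var(spec.y))
    if vy == 0:
        raise ValueError("trait has zero variance")
    var_floor = 1e-8 * vy

    active = []
    if spec.Z1.shape[1]:
        active.append("Vb")
    active += ["Vg", "Ve"]
    if fit_rho:
        active += ["rho_row", "rho_col"]

    theta = init or VarComponents(Vb=vy / 3, Vg=vy / 3, Ve=vy / 3, rho_row=0.0, rho_col=0.0)
    vec = _project(_theta_to_vec(theta, active), active, var_floor)
    theta = _vec_to_theta(vec, active, theta)

    ll = restricted_loglik(spec, theta, var_floor)
    trace = [ll]
    converged = False
    stalled = False
    it = 0
    for it in range(1, max_iter + 1):
        P, Py, dV = _dense_P_and_derivs(spec, theta, active)
        k = len(active)
        score = np.empty(k)
        q = [dV[a] @ Py for a in active]
        for i, a in enumerate(active):
            score[i] = -0.5 * (float(np.sum(P * dV[a])) - float(Py @ q[i]))
        AI = np.empty((k, k))
        Pq = [P @ qi for qi in q]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(q[i] @ Pq[j])
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(k) * np.trace(AI), score)
        except np.linalg.LinAlgError:
            stalled = True
            break

        step = 1.0
        improved = False
        for _ in range(15):
            cand_vec = _project(vec + step * delta, active, var_floor)
            cand_theta = _vec_to_theta(cand_vec, active, theta)
            try:
                cand_ll = restricted_loglik(spec, cand_theta, var_floor)
            except (np.linalg.LinAlgError, ValueError):
                cand_ll = -np.inf
            if cand_ll >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            stalled = True
            break

        rel_change = float(np.max(np.abs(cand_vec - vec) / np.maximum(np.abs(vec), var_floor)))
        dll = cand_ll - ll
        vec, theta, ll = cand_vec, cand_theta, cand_ll
        trace.append(ll)
        if abs(dll) < tol_loglik and rel_change < tol_params:
            converged = True
            break

    if stalled or not converged:
        # simplex polish on an unconstrained scale
        def to_x(v):
            return np.array([
                math.atanh(v[i] / _RHO_BOUND) if a.startswith("rho") else math.log(max(v[i], var_floor))
                for i, a in enumerate(active)
            ])

        def from_x(x):
            return np.array([
                _RHO_BOUND * math.tanh(x[i]) if a.startswith("rho") else math.exp(x[i])
                for i, a in enumerate(active)
            ])

        def negll(x):
            try:
                return -restricted_loglik(spec, _vec_to_theta(from_x(x), active, theta), var_floor)
            except (np.linalg.LinAlgError, ValueError):
                return np.inf

        res = optimize.minimize(negll, to_x(vec), method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if -res.fun >= ll:
            vec = _project(from_x(res.x), active, var_floor)
            theta = _vec_to_theta(vec, active, theta)
            new_ll = restricted_loglik(spec, theta, var_floor)
            converged = converged or (new_ll - ll < max(10 * tol_loglik, 1e-4))
            ll = new_ll
            trace.append(ll)
    if not converged:
        warnings.warn("REML did not reach the convergence tolerances", stacklevel=2)

    pieces = _mme_pieces(spec, theta, var_floor)
    p, nb, nf = pieces["p"], pieces["nb"], pieces["nf"]
    sol = pieces["sol"]
    beta = sol[:p]
    b_hat = sol[p : p + nb]
    g_hat = sol[p + nb :]
    Cinv = cho_solve(pieces["cC"], np.eye(p + nb + nf))
    pev_g = Cinv[p + nb :, p + nb :]

    d = np.diag(pev_g)
    if nf > 1:
        ssum = float(pev_g.sum())
        sdiag = float(d.sum())
        npairs = nf * (nf - 1) / 2
        # var(gi - gj) = PEV_ii + PEV_jj - 2 PEV_ij averaged over unordered pairs
        mean_pairwise = ((nf - 1) * sdiag - (ssum - sdiag)) / npairs
    else:
        mean_pairwise = float(2.0 * d[0]) if nf else float("nan")
    mean_diag = float(d.mean()) if nf else float("nan")

    vg_at_floor = pieces["Vg"] <= var_floor * (1 + 1e-6)
    if vg_at_floor:
        H = float("nan")
        warnings.warn("Vg estimated at the variance floor; heritability undefined", stacklevel=2)
    else:
        pev_stat = mean_pairwise if pev_mode == "pairwise" else 2.0 * mean_diag
        H = 1.0 - pev_stat / (2.0 * pieces["Vg"])

    return MixedModelFit(
        theta=VarComponents(pieces["Vb"], pieces["Vg"], pieces["Ve"],
                            theta.rho_row, theta.rho_col),
        beta=beta,
        fixed_labels=spec.fixed_labels,
        b_hat=b_hat,
        g_hat=g_hat,
        family_labels=spec.family_labels,
        pev_g=pev_g,
        mean_pairwise_pev=float(mean_pairwise),
        mean_diag_pev=mean_diag,
        loglik=ll,
        converged=bool(converged),
        n_iter=it,
        H=float(H),
        loglik_trace=trace,
        vg_at_floor=vg_at_floor,
    )


def pev_at(spec: MixedModelSpec, theta: VarComponents) -> tuple[float, float]:
    """Mean pairwise family PEV and Cullis H at fixed variance components.

    No optimization: useful for the design's expected (long-run) heritability
    under known parameters.
    """
    theta.validate()
    pieces = _mme_pieces(spec, theta, var_floor=0.0)
    p, nb, nf = pieces["p"], pieces["nb"], pieces["nf"]
    Cinv = cho_solve(pieces["cC"], np.eye(p + nb + nf))
    pev_g = Cinv[p + nb :, p + nb :]
    d = np.diag(pev_g)
    sdiag = float(d.sum())
    ssum = float(pev_g.sum())
    npairs = nf * (nf - 1) / 2
    mean_pairwise = ((nf - 1) * sdiag - (ssum - sdiag)) / npairs
    return mean_pairwise, 1.0 - mean_pairwise / (2.0 * theta.Vg)


def cullis_H(fit: MixedModelFit | float, Vg: float | None = None) -> float:
    """PEV-based broad-sense heritability H = 1 - PEV_pairwise / (2 Vg).

    Accepts a fit, or (mean pairwise PEV, Vg) as two scalars. H can be
    negative; Vg <= 0 makes it undefined.
    """
    if isinstance(fit, MixedModelFit):
        pev, Vg = fit.mean_pairwise_pev, fit.theta.Vg
    else:
        pev = float(fit)
    if Vg is None or Vg <= 0:
        raise ValueError("H undefined for Vg <= 0")
    return 1.0 - pev / (2.0 * Vg)


def genetic_correlation(fit_real: MixedModelFit, fit_htp: MixedModelFit) -> float:
    """Approximate genetic correlation: Pearson r of the two family BLUP vectors."""
    if fit_real.family_labels != fit_htp.family_labels:
        raise ValueError("fits must share the same family set and ordering")
    a, b = fit_real.g_hat, fit_htp.g_hat
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero-variance BLUP vector; genetic correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class GeneticSummary:
    """Per-trait genetic parameters consumed by the selection-response formulas."""

    trait: str
    Vg: float
    H: float
    r: float = 1.0  # vs the paired real trait; 1 for the real trait itself

    @property
    def h(self) -> float:
        """sqrt(H); NaN when H is negative (flagged, not clamped)."""
        return math.sqrt(self.H) if self.H >= 0 else float("nan")

    @property
    def v(self) -> float:
        return math.sqrt(self.Vg)


# ---------------------------------------------------------------------------
# sklearn-style estimator facade
# ---------------------------------------------------------------------------

class SpatialMixedModel:
    """Estimator interface over :func:`reml_fit`.

    Parameters mirror the fitting options; ``fit(X, y)`` takes the plot table
    (DataFrame with plot_id, field_row, field_col, rep, block, genotype_id,
    genotype_class) as X and the trait vector as y. Fitted state lands in
    trailing-underscore attributes (Vb_, Vg_, Ve_, rho_row_, rho_col_, H_,
    blup_family_, ...).
    """

    def __init__(self, fit_rho: bool = True, max_iter: int = 100,
                 tol_loglik: float = 1e-6, tol_params: float = 1e-4,
                 pev_mode: str = "pairwise", init: VarComponents | None = None):
        self.fit_rho = fit_rho
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_params = tol_params
        self.pev_mode = pev_mode
        self.init = init

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "fit_rho": self.fit_rho,
            "max_iter": self.max_iter,
            "tol_loglik": self.tol_loglik,
            "tol_params": self.tol_params,
            "pev_mode": self.pev_mode,
            "init": self.init,
        }

    def set_params(self, **params) -> "SpatialMixedModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "SpatialMixedModel":
        spec = build_design(X, y)
        fit = reml_fit(spec, init=self.init, fit_rho=self.fit_rho,
                       max_iter=self.max_iter, tol_loglik=self.tol_loglik,
                       tol_params=self.tol_params, pev_mode=self.pev_mode)
        self.fit_ = fit
        self.Vb_ = fit.theta.Vb
        self.Vg_ = fit.theta.Vg
        self.Ve_ = fit.theta.Ve
        self.rho_row_ = fit.theta.rho_row
        self.rho_col_ = fit.theta.rho_col
        self.beta_ = fit.beta
        self.blup_block_ = fit.b_hat
        self.blup_family_ = fit.g_hat
        self.family_labels_ = fit.family_labels
        self.H_ = fit.H
        self.mean_pairwise_pev_ = fit.mean_pairwise_pev
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        return self

    def summary(self, trait: str = "trait", r: float = 1.0) -> GeneticSummary:
        if not hasattr(self, "fit_"):
            raise RuntimeError("model is not fitted")
        return GeneticSummary(trait=trait, Vg=self.Vg_, H=self.H_, r=r)
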