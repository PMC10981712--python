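"""Uncertainty-weighted positive matrix factorization (receptor model).

The sample × element concentration matrix X is decomposed into nonnegative
source contributions G (samples × factors) and profiles F (factors ×
elements),

    x_ij = Σ_k g_ik f_kj + e_ij,

by minimizing the uncertainty-scaled objective

    Q = Σ_ij (e_ij / u_ij)²

with per-cell uncertainties u_ij.  The solver uses alternating weighted
multiplicative updates (monotone in Q) with multiple random restarts, and
an optional robust mode that inflates the uncertainty of outlying cells
(|e/u| > 4) so single extreme samples do not dominate the fit; both the
robust and the plain objective are reported (Q_robust ≤ Q_true).

The uncertainty matrix follows the receptor-modelling convention: for
detected values u = sqrt((error_fraction·c)² + (0.5·MDL)²); non-detects are
set to 5/6·MDL with u = 5/6·MDL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import NONDETECT_FRACTION, SamplePanel, ValidationError

_EPS = 1e-12
ROBUST_CUTOFF = 4.0


@dataclass
class UncertaintyMatrix:
    """Per-cell measurement uncertainties (same units as concentration)."""

    u: pd.DataFrame
    error_fraction: float

    def __post_init__(self) -> None:
        if not (self.u.to_numpy() > 0).all():
            raise ValidationError("all uncertainties must be positive")


@dataclass
class PMFSolution:
    """A fitted factorization plus the data it was fitted to."""

    g: pd.DataFrame              # samples × factors
    f: pd.DataFrame              # factors × elements
    q_true: float
    q_robust: float
    r2: pd.Series                # per element, plus "overall"
    scaled_residuals: pd.DataFrame
    factor_count: int
    restart_seed: int
    converged: bool
    n_iterations: int
    x: pd.DataFrame = field(repr=False, default=None)
    u: pd.DataFrame = field(repr=False, default=None)
    q_history: np.ndarray | None = field(repr=False, default=None)

    @property
    def reconstruction(self) -> pd.DataFrame:
        rec = self.g.to_numpy() @ self.f.to_numpy()
        return pd.DataFrame(rec, index=self.g.index, columns=self.f.columns)


def build_uncertainty(
    panel: SamplePanel,
    error_fraction: float = 0.10,
    mdl: pd.Series | dict | None = None,
) -> UncertaintyMatrix:
    """Per-cell uncertainties from an error fraction and detection limits.

    ``mdl`` gives per-element method detection limits; where absent, the
    panel's own cell-level detection limits are used, and censored cells
    without either raise an error.
    """
    if error_fraction < 0:
        raise ValidationError("error_fraction must be >= 0")
    elements = list(panel.elements)
    conc = panel.concentration.to_numpy(dtype=float)
    cens = panel.censored.to_numpy()
    dl = panel.detection_limit.to_numpy(dtype=float)
    if mdl is not None:
        mdl_vec = pd.Series(mdl).reindex(elements).to_numpy(dtype=float)
        dl = np.where(np.isnan(dl), np.broadcast_to(mdl_vec, dl.shape), dl)
    if np.isnan(dl[cens]).any():
        raise ValidationError("censored cells need a detection limit (mdl)")
    if (dl[cens] <= 0).any():
        raise ValidationError("detection limits must be positive")
    # detected cells without an MDL contribute no DL term
    dl_term = np.where(np.isnan(dl), 0.0, 0.5 * dl)
    c = np.where(cens, NONDETECT_FRACTION * dl, conc)
    if np.isnan(c).any():
        raise ValidationError("panel has missing uncensored concentrations")
    u = np.sqrt((error_fraction * c) ** 2 + dl_term**2)
    u[cens] = NONDETECT_FRACTION * dl[cens]
    if not (u > 0).all():
        raise ValidationError(
            "zero uncertainty produced; provide an error fraction or MDLs"
        )
    u_df = pd.DataFrame(u, index=panel.sample_ids, columns=elements)
    return UncertaintyMatrix(u=u_df, error_fraction=error_fraction)


def _q_value(x, gf, u):
    return float((((x - gf) / u) ** 2).sum())


def _robust_u(x, gf, u):
    """Inflate uncertainties of outlier cells per the |r| > 4 convention."""
    r = (x - gf) / u
    absr = np.abs(r)
    scale = np.where(absr > ROBUST_CUTOFF, np.sqrt(absr / ROBUST_CUTOFF), 1.0)
    return u * scale


def _fit_single(
    x: np.ndarray,
    u: np.ndarray,
    k: int,
    rng: np.random.Generator,
    robust: bool,
    tol: float,
    max_iter: int,
    track: bool,
    reweight_every: int = 10,
):
    n, m = x.shape
    scale = np.sqrt(max(x.mean(), _EPS) / k)
    g = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    f = rng.uniform(0.1, 1.0, size=(k, m)) * scale

    u_eff = u
    w = 1.0 / u_eff**2
    history = [] if track else None
    q_prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gf = g @ f
        if robust and (it - 1) % reweight_every == 0:
            u_eff = _robust_u(x, gf, u)
            w = 1.0 / u_eff**2
        wx = w * x
        g *= (wx @ f.T) / ((w * gf) @ f.T + _EPS)
        gf = g @ f
        f *= (g.T @ wx) / (g.T @ (w * gf) + _EPS)
        gf = g @ f
        q = _q_value(x, gf, u_eff)
        if track:
            assert (g >= 0).all() and (f >= 0).all()
            history.append(q)
        if q <= x.size * _EPS or (
            q_prev < np.inf and abs(q_prev - q) <= tol * max(q_prev, _EPS)
        ):
            converged = True
            break
        q_prev = q
    gf = g @ f
    u_final = _robust_u(x, gf, u) if robust else u
    q_true = _q_value(x, gf, u)
    q_robust = _q_value(x, gf, u_final)
    return g, f, q_true, q_robust, converged, it, history


def fit_pmf(
    panel: SamplePanel,
    u: UncertaintyMatrix,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    robust: bool = True,
    tol: float = 1e-8,
    max_iter: int = 5000,
    track_history: bool = False,
) -> PMFSolution:
    """Best-of-restarts weighted nonnegative factorization.

    ``restarts`` independent random initialisations are run (default 20);
    the solution with the lowest Q_robust (or Q_true when ``robust=False``)
    is kept.  Non-convergence within ``max_iter`` is flagged on the result,
    not raised.
    """
    x = panel.values()
    n, m = x.shape
    if not 1 <= k < min(n, m):
        raise ValidationError(
            f"factor count k={k} must satisfy 1 <= k < min(samples, elements)"
            f" = {min(n, m)}"
        )
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    uu = u.u.to_numpy(dtype=float)
    if uu.shape != x.shape:
        raise ValidationError("uncertainty matrix shape does not match panel")

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        g, f, q_true, q_robust, conv, n_it, hist = _fit_single(
            x, uu, k, rng, robust, tol, max_iter, track_history
        )
        key = q_robust if robust else q_true
        if best is None or key < best[0]:
            best = (key, g, f, q_true, q_robust, conv, n_it, hist)

    _, g, f, q_true, q_robust, conv, n_it, hist = best
    if not conv:
        warnings.warn("PMF did not converge within max_iter; result flagged")
    gf = g @ f
    resid = (x - gf) / uu
    factors = [f"F{i + 1}" for i in range(k)]
    elements = list(panel.elements)
    r2 = _r_squared(x, gf, elements)
    return PMFSolution(
        g=pd.DataFrame(g, index=panel.sample_ids, columns=factors),
        f=pd.DataFrame(f, index=factors, columns=elements),
        q_true=q_true,
        q_robust=q_robust,
        r2=r2,
        scaled_residuals=pd.DataFrame(
            resid, index=panel.sample_ids, columns=elements
        ),
        factor_count=k,
        restart_seed=seed,
        converged=conv,
        n_iterations=n_it,
        x=pd.DataFrame(x, index=panel.sample_ids, columns=elements),
        u=u.u.copy(),
        q_history=None if hist is None else np.asarray(hist),
    )


def _r_squared(x: np.ndarray, gf: np.ndarray, elements) -> pd.Series:
    out = {}
    for j, el in enumerate(elements):
        ss_res = float(((x[:, j] - gf[:, j]) ** 2).sum())
        ss_tot = float(((x[:, j] - x[:, j].mean()) ** 2).sum())
        out[el] = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    ss_res = float(((x - gf) ** 2).sum())
    ss_tot = float(((x - x.mean()) ** 2).sum())
    out["overall"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return pd.Series(out)


@dataclass
class FitDiagnostics:
    """Summary diagnostics for a fitted factorization."""

    residual_fraction_in_3: float
    r2: pd.Series
    q_true: float
    q_robust: float
    q_ratio: float
    residual_ok: bool
    r2_ok: bool
    converged: bool

    @property
    def passed(self) -> bool:
        return self.residual_ok and self.r2_ok


def diagnose_fit(
    sol: PMFSolution,
    residual_fraction_threshold: float = 0.955,
    r2_threshold: float = 0.98,
) -> FitDiagnostics:
    """Check scaled residuals and goodness of fit against the customary
    receptor-model acceptance thresholds."""
    resid = sol.scaled_residuals.to_numpy()
    frac = float((np.abs(resid) <= 3.0).mean())
    r2_overall = float(sol.r2["overall"])
    return FitDiagnostics(
        residual_fraction_in_3=frac,
        r2=sol.r2,
        q_true=sol.q_true,
        q_robust=sol.q_robust,
        q_ratio=sol.q_robust / sol.q_true if sol.q_true > 0 else 1.0,
        residual_ok=frac >= residual_fraction_threshold,
        r2_ok=r2_overall >= r2_threshold,
        converged=sol.converged,
    )


def contribution_percentages(
    sol: PMFSolution,
) -> tuple[pd.DataFrame, pd.Series]:
    """Percent source shares per element, and mass-weighted overall shares.

    For element j, factor k's share is the factor's mean reconstructed mass
    over the element's total mean reconstructed mass, ×100; overall shares
    weight elements by reconstructed mass so they also sum to 100.
    """
    g = sol.g.to_numpy()
    f = sol.f.to_numpy()
    # mean reconstructed mass of element j from factor k
    mass = np.mean(g, axis=0)[:, None] * f          # factors × elements
    totals = mass.sum(axis=0)                       # per element
    if (totals <= 0).any():
        bad = [el for el, t in zip(sol.f.columns, totals) if t <= 0]
        warnings.warn(f"zero reconstructed concentration for {bad}; shares undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_el = 100.0 * mass / totals
    per_element = pd.DataFrame(per_el, index=sol.f.index, columns=sol.f.columns)
    overall = pd.Series(
        100.0 * mass.sum(axis=1) / mass.sum(), index=sol.f.index
    )
    return per_element, overall


def label_factors(sol: PMFSolution, top_n: int = 2) -> dict[str, list[str]]:
    """Marker-element heuristic: the ``top_n`` elements with the highest
    share in each factor.  Analyst metadata only — source identities (e.g.
    asbestos vs coal combustion) are assigned by the analyst, never
    inferred as ground truth."""
    shares, _ = contribution_percentages(sol)
    return {
        fk: shares.loc[fk].sort_values(ascending=False).head(top_n).index.tolist()
        for fk in shares.index
    }


def match_factors(
    estimated: pd.DataFrame,
    reference: pd.DataFrame,
    scale: np.ndarray | pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one factor matching (Hungarian assignment on cosine
    similarity), resolving the permutation ambiguity of the factorization.

    Profiles are compared after dividing each element by ``scale`` (for
    example the element's mean concentration) so high-mass species do not
    dominate the similarity; with ``scale=None`` raw profiles are used.
    Returns (order, cosines): ``estimated.iloc[order]`` aligns with
    ``reference``, with the matched cosine similarities alongside.
    """
    from scipy.optimize import linear_sum_assignment

    a = reference.to_numpy(dtype=float)
    b = estimated.to_numpy(dtype=float)
    if scale is not None:
        s = np.asarray(scale, dtype=float)
        a = a / s
        b = b / s
    a = a / np.linalg.norm(a, axis=1, keepdims=True)
    b = b / np.linalg.norm(b, axis=1, keepdims=True)
    sim = a @ b.T
    rows, cols = linear_sum_assignment(-sim)
    order = cols[np.argsort(rows)]
    return order, sim[rows, cols][np.argsort(rows)]


def select_factor_count(
    panel: SamplePanel,
    u: UncertaintyMatrix,
    k_range=range(3, 7),
    restarts: int = 20,
    seed: int = 0,
    robust: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Best-of-restarts Q and diagnostics for each candidate factor count.

    Returns a table for analyst decision (no automatic choice); the
    ``q_drop`` column annotates the decrease in Q_robust entering each k.
    """
    rows = []
    for k in k_range:
        sol = fit_pmf(
            panel, u, k=k, restarts=restarts, seed=seed, robust=robust, **fit_kwargs
        )
        diag = diagnose_fit(sol)
        rows.append(
            {
                "k": k,
                "q_true": sol.q_true,
                "q_robust": sol.q_robust,
                "q_ratio": diag.q_ratio,
                "r2_overall": float(sol.r2["overall"]),
                "residual_fraction_in_3": diag.residual_fraction_in_3,
                "converged": sol.converged,
            }
        )
    out = pd.DataFrame(rows).set_index("k")
    out["q_drop"] = -out["q_robust"].diff()
    return out
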