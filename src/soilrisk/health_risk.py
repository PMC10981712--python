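"""Probabilistic (Monte Carlo) human-health risk for soil heavy metals.

USEPA-style average daily doses for three pathways:

    ADD_ingest = C · R_ingest · EF · ED / (BW · AT) · 1e-6
    ADD_dermal = C · SA · AF · ABF · EF · ED / (BW · AT) · 1e-6
    ADD_inhal  = C · R_inhal · EF · ED / (PEF · BW · AT)

with C the soil concentration (mg·kg⁻¹), EF in d·y⁻¹ and ED in years, so
EF·ED is total exposure days and divides directly by the averaging time AT
(days) — the receptor AT values (2190 d child, 9125 d adult) pair with the
ED ranges, so no extra 365 factor appears.  Non-carcinogenic hazard
quotients are HQ = Σ_pathway ADD/RfD (HI sums elements); carcinogenic risks
are CR = Σ_pathway ADD·SF (TCR sums elements); pathways without a published
RfD or SF are skipped.

Each Monte Carlo iteration draws one survey sample row (empirical
concentration distribution, preserving inter-element correlation) or a
fitted per-element lognormal, plus an independent draw of every exposure
parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DistributionSpec, SamplePanel, ValidationError

log = logging.getLogger(__name__)

PATHWAYS: tuple[str, ...] = ("ingestion", "dermal", "inhalation")
RECEPTORS: tuple[str, ...] = ("child", "adult")

EXPOSURE_PARAMETERS: tuple[str, ...] = (
    "R_ingest", "EF", "ED", "R_inhal", "PEF", "BW", "AT", "SA", "AF", "ABF",
)

#: Default exposure-parameter distributions per receptor.  Units: R_ingest
#: mg·d⁻¹, EF d·y⁻¹, ED y, R_inhal m³·d⁻¹, PEF m³·kg⁻¹, BW kg, AT d, SA cm²,
#: AF mg·cm⁻², ABF dimensionless.  Lognormals are (geometric mean, GSD); the
#: adult skin-adherence factor is (mean, sd) truncated-normal because its
#: published spread (0.54) cannot be a GSD.
_DEFAULT_EXPOSURE: dict[str, dict[str, DistributionSpec]] = {
    "child": {
        "R_ingest": DistributionSpec("triangular", (66.0, 103.0, 161.0)),
        "EF": DistributionSpec("point", (350.0,)),
        "ED": DistributionSpec("uniform", (0.0, 10.0)),
        "R_inhal": DistributionSpec("point", (7.6,)),
        "PEF": DistributionSpec("point", (1.36e9,)),
        "BW": DistributionSpec("lognormal", (16.68, 1.48)),
        "AT": DistributionSpec("point", (2190.0,)),
        "SA": DistributionSpec("lognormal", (7422.0, 1.25)),
        "AF": DistributionSpec("lognormal", (0.65, 1.2)),
        "ABF": DistributionSpec("point", (0.001,)),
    },
    "adult": {
        "R_ingest": DistributionSpec("triangular", (4.0, 30.0, 52.0)),
        "EF": DistributionSpec("point", (350.0,)),
        "ED": DistributionSpec("uniform", (0.0, 50.0)),
        "R_inhal": DistributionSpec("point", (20.0,)),
        "PEF": DistributionSpec("point", (1.36e9,)),
        "BW": DistributionSpec("lognormal", (57.03, 1.18)),
        "AT": DistributionSpec("point", (9125.0,)),
        "SA": DistributionSpec("lognormal", (18182.0, 1.1)),
        "AF": DistributionSpec("truncnormal", (0.49, 0.54)),
        "ABF": DistributionSpec("point", (0.001,)),
    },
}

#: Reference doses RfD (mg·(kg·d)⁻¹) and slope factors SF ((kg·d)·mg⁻¹) per
#: element and pathway; NaN marks values not available in the compiled
#: toxicology tables (those pathways are skipped).
_RFD = {
    #          ingestion  inhalation  dermal
    "As": (3.00e-4, 1.23e-4, 1.23e-4),
    "Cd": (1.00e-3, 1.00e-5, 1.00e-5),
    "Cu": (4.00e-2, 4.02e-2, 1.20e-2),
    "Cr": (3.00e-3, 2.86e-5, 6.00e-5),
    "Hg": (3.00e-4, 8.57e-5, 2.10e-5),
    "Ni": (2.00e-2, 2.06e-2, 5.40e-3),
    "Pb": (3.50e-3, 3.52e-3, 5.25e-4),
    "Zn": (3.00e-1, 3.00e-1, 6.00e-2),
}
_SF = {
    "As": (1.5, 1.51, 3.66),
    "Cd": (6.1, 6.30, np.nan),
    "Cu": (np.nan, np.nan, np.nan),
    "Cr": (8.50e-3, 4.20, np.nan),
    "Hg": (np.nan, np.nan, np.nan),
    "Ni": (np.nan, 8.4e-1, np.nan),
    "Pb": (8.50e-3, np.nan, np.nan),
    "Zn": (np.nan, np.nan, np.nan),
}


@dataclass(frozen=True)
class ExposureModel:
    """Receptor-specific distributions for every exposure parameter."""

    receptor: str
    parameters: dict[str, DistributionSpec]

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValidationError(f"unknown receptor {self.receptor!r}")
        missing = [p for p in EXPOSURE_PARAMETERS if p not in self.parameters]
        if missing:
            raise ValidationError(f"exposure model missing parameters {missing}")

    @classmethod
    def default(cls, receptor: str) -> "ExposureModel":
        if receptor not in _DEFAULT_EXPOSURE:
            raise ValidationError(f"unknown receptor {receptor!r}")
        return cls(receptor=receptor, parameters=dict(_DEFAULT_EXPOSURE[receptor]))


@dataclass(frozen=True)
class ToxicityReference:
    """Per-element, per-pathway RfD and SF lookup (NaN = not available)."""

    rfd: pd.DataFrame
    sf: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("rfd", self.rfd), ("sf", self.sf)):
            bad = (df <= 0) & df.notna()
            if bad.any().any():
                raise ValidationError(f"nonpositive value in {name} table")

    @classmethod
    def default(cls) -> "ToxicityReference":
        cols = ["ingestion", "inhalation", "dermal"]
        rfd = pd.DataFrame(_RFD, index=cols).T
        sf = pd.DataFrame(_SF, index=cols).T
        return cls(rfd=rfd[list(PATHWAYS)], sf=sf[list(PATHWAYS)])


@dataclass
class RiskDistributionSummary:
    """Monte Carlo output: summary statistics of ADD/HQ/CR per element and
    of the aggregates HI and TCR."""

    receptor: str
    iterations: int
    seed: int
    add: pd.DataFrame        # index (element, pathway), cols mean/p5/median/p95
    hq: pd.DataFrame         # index element
    cr: pd.DataFrame         # index element
    hi: pd.Series            # mean/p5/median/p95
    tcr: pd.Series
    classification: dict[str, str] = field(default_factory=dict)


def sample_parameter(
    spec: DistributionSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from a distribution spec, reproducibly.

    Uniform draws are open at the lower bound (a drawn hard zero is
    resampled) so degenerate zero-duration exposures cannot occur.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = spec.params
    if spec.family == "point":
        return np.full(n, p[0])
    if spec.family == "triangular":
        if p[0] == p[2]:
            return np.full(n, p[0])
        return rng.triangular(p[0], p[1], p[2], size=n)
    if spec.family == "uniform":
        if p[0] == p[1]:
            return np.full(n, p[0])
        draws = rng.uniform(p[0], p[1], size=n)
        while True:
            zero = draws == p[0]
            if not zero.any():
                return draws
            draws[zero] = rng.uniform(p[0], p[1], size=int(zero.sum()))
    if spec.family == "lognormal":
        gm, gsd = p
        return gm * np.exp(rng.standard_normal(n) * np.log(gsd))
    if spec.family == "truncnormal":
        mean, sd = p
        a = (0.0 - mean) / sd
        dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
        return dist.ppf(rng.uniform(size=n))
    raise ValidationError(f"unknown distribution family {spec.family!r}")


def sample_exposure(
    model: ExposureModel, n: int, seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """Joint independent draws of every exposure parameter."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return {
        name: sample_parameter(model.parameters[name], n, rng)
        for name in EXPOSURE_PARAMETERS
    }


def compute_add(C, draws: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Average daily dose per pathway, mg·(kg·d)⁻¹.

    ``C`` broadcasts against the draw arrays: scalar, (n,) or (n, elements)
    with draw vectors of length n.
    """
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        raise ValidationError("negative concentration")
    d = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
    for name in ("BW", "AT", "PEF"):
        if (d[name] <= 0).any():
            raise ValidationError(f"nonpositive {name} draw")

    def col(x):
        # align per-iteration vectors against a (n, elements) C
        x = np.asarray(x, dtype=float)
        if C.ndim == 2 and x.ndim == 1:
            return x[:, None]
        return x

    days = col(d["EF"] * d["ED"])         # total exposure days
    denom = col(d["BW"] * d["AT"])
    ingest = C * col(d["R_ingest"]) * days / denom * 1e-6
    dermal = C * col(d["SA"] * d["AF"] * d["ABF"]) * days / denom * 1e-6
    inhal = C * col(d["R_inhal"]) * days / (col(d["PEF"]) * denom)
    return {"ingestion": ingest, "dermal": dermal, "inhalation": inhal}


def compute_hq_hi(
    add: dict[str, dict[str, np.ndarray]], tox: ToxicityReference
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Hazard quotient per element (summed over pathways with an RfD) and
    the hazard index HI summed over elements.

    ``add`` maps element → pathway → dose array.  Elements lacking an RfD
    for every pathway are excluded with a warning.
    """
    hq: dict[str, np.ndarray] = {}
    hi = None
    for el, per_path in add.items():
        total = None
        any_rfd = False
        for path, dose in per_path.items():
            rfd = tox.rfd.loc[el, path] if el in tox.rfd.index else np.nan
            if np.isnan(rfd):
                log.debug("no RfD for %s/%s; pathway skipped", el, path)
                continue
            any_rfd = True
            term = np.asarray(dose) / rfd
            total = term if total is None else total + term
        if not any_rfd:
            warnings.warn(f"element {el} has no RfD for any pathway; excluded")
            continue
        hq[el] = total
        hi = total.copy() if hi is None else hi + total
    if hi is None:
        hi = np.zeros(1)
    return hq, hi


def compute_cr_tcr(
    add: dict[str, dict[str, np.ndarray]], tox: ToxicityReference
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Carcinogenic risk per element (pathways with a slope factor) and the
    total TCR; elements with no SF contribute zero."""
    cr: dict[str, np.ndarray] = {}
    tcr = None
    for el, per_path in add.items():
        total = None
        for path, dose in per_path.items():
            sf = tox.sf.loc[el, path] if el in tox.sf.index else np.nan
            if np.isnan(sf):
                continue
            term = np.asarray(dose) * sf
            total = term if total is None else total + term
        if total is None:
            continue
        cr[el] = total
        tcr = total.copy() if tcr is None else tcr + total
    if tcr is None:
        tcr = np.zeros(1)
    return cr, tcr


def classify_cr(value: float) -> str:
    """Carcinogenic-risk band: ≤1e-6 negligible, ≤1e-4 tolerable, else
    intolerable."""
    if value <= 1e-6:
        return "negligible"
    if value <= 1e-4:
        return "tolerable"
    return "intolerable"


def classify_hq(value: float) -> str:
    return "negligible" if value <= 1.0 else "risk"


def _summary(x: np.ndarray, percentiles=(5.0, 50.0, 95.0)) -> dict[str, float]:
    lo, med, hi = np.percentile(x, percentiles)
    return {"mean": float(np.mean(x)), "p5": float(lo), "median": float(med), "p95": float(hi)}


def run_monte_carlo(
    panel: SamplePanel,
    model: ExposureModel,
    tox: ToxicityReference | None = None,
    iterations: int = 10_000,
    seed: int = 0,
    concentration_mode: str = "empirical",
) -> RiskDistributionSummary:
    """Propagate concentration and exposure-parameter uncertainty.

    Each iteration draws one survey sample row (``empirical`` mode, the
    default) or an independent per-element lognormal fitted to the panel
    (``lognormal`` mode), plus fresh exposure parameters; HQ/HI and CR/TCR
    are summarised by mean and 5th/50th/95th percentiles.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if iterations < 1000:
        warnings.warn("fewer than 1000 iterations: percentile estimates are noisy")
    tox = tox or ToxicityReference.default()
    rng = np.random.default_rng(seed)

    conc = panel.values()  # (samples, elements)
    n_el = conc.shape[1]
    if concentration_mode == "empirical":
        rows = rng.integers(0, conc.shape[0], size=iterations)
        C = conc[rows, :]
    elif concentration_mode == "lognormal":
        if (conc <= 0).any():
            raise ValidationError("lognormal mode needs positive concentrations")
        mu = np.log(conc).mean(axis=0)
        sig = np.log(conc).std(axis=0, ddof=1)
        C = np.exp(mu + sig * rng.standard_normal((iterations, n_el)))
    else:
        raise ValidationError(f"unknown concentration mode {concentration_mode!r}")

    draws = sample_exposure(model, iterations, rng)
    add_all = compute_add(C, draws)  # pathway -> (iterations, elements)

    elements = list(panel.elements)
    add_by_el = {
        el: {path: add_all[path][:, j] for path in PATHWAYS}
        for j, el in enumerate(elements)
    }
    hq, hi = compute_hq_hi(add_by_el, tox)
    cr, tcr = compute_cr_tcr(add_by_el, tox)

    add_rows = {
        (el, path): _summary(add_by_el[el][path])
        for el in elements
        for path in PATHWAYS
    }
    add_df = pd.DataFrame(add_rows).T
    add_df.index.names = ["element", "pathway"]
    hq_df = pd.DataFrame({el: _summary(v) for el, v in hq.items()}).T
    cr_df = pd.DataFrame({el: _summary(v) for el, v in cr.items()}).T
    hi_s = pd.Series(_summary(hi))
    tcr_s = pd.Series(_summary(tcr))

    classification = {f"CR:{el}": classify_cr(cr_df.loc[el, "mean"]) for el in cr_df.index}
    classification.update(
        {f"HQ:{el}": classify_hq(hq_df.loc[el, "mean"]) for el in hq_df.index}
    )
    classification["TCR"] = classify_cr(tcr_s["mean"])
    classification["HI"] = classify_hq(hi_s["mean"])

    log.info(
        "%s receptor, %d iterations: mean HI %.3g, mean TCR %.3g",
        model.receptor, iterations, hi_s["mean"], tcr_s["mean"],
    )
    return RiskDistributionSummary(
        receptor=model.receptor,
        iterations=iterations,
        seed=seed,
        add=add_df,
        hq=hq_df,
        cr=cr_df,
        hi=hi_s,
        tcr=tcr_s,
        classification=classification,
    )
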