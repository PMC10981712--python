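"""Core containers and I/O for soil heavy-metal survey data.

A survey is a panel of per-sample concentrations (mg·kg⁻¹ dry soil) for a
fixed, ordered set of elements.  Cells reported below the method detection
limit are carried as *censored* with their detection limit attached; every
downstream stage (indices, health risk, PMF) requires censored cells to be
substituted first via :func:`substitute_nondetects`.

Two exchange formats are accepted:

* wide CSV — one row per sample, one column per element; a censored cell is
  written as ``<DL`` (e.g. ``<0.5``), or flagged via a paired boolean column
  ``<element>_censored`` plus ``<element>_dl``;
* long CSV — columns ``sample_id, element, value`` (optionally ``zone``),
  normalised to wide on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Default element panel, in survey-table column order.
DEFAULT_ELEMENTS: tuple[str, ...] = ("As", "Hg", "Cd", "Pb", "Cr", "Cu", "Zn", "Ni")

#: Recognised sampling-zone labels.
ZONES: tuple[str, ...] = (
    "mining",
    "beneficiation",
    "residue",
    "residential",
    "bare",
    "other",
)

#: Fraction of the detection limit substituted for non-detects.
NONDETECT_FRACTION = 5.0 / 6.0

#: Packaged per-element geochemical background values, mg·kg⁻¹
#: (non-agricultural land reference for the study region).
DEFAULT_BACKGROUND: dict[str, float] = {
    "As": 7.94,
    "Hg": 11.48,
    "Cd": 0.10,
    "Pb": 14.67,
    "Cr": 40.54,
    "Cu": 15.23,
    "Zn": 48.00,
    "Ni": 18.53,
}

#: Hakanson toxicity response coefficients T_r (dimensionless).
DEFAULT_TOXICITY: dict[str, float] = {
    "Hg": 40.0,
    "Cd": 30.0,
    "As": 10.0,
    "Pb": 5.0,
    "Cu": 5.0,
    "Ni": 5.0,
    "Cr": 2.0,
    "Zn": 1.0,
}


class ValidationError(ValueError):
    """A sample table or configuration failed validation."""


@dataclass
class SamplePanel:
    """Per-sample, per-element concentration matrix with censoring metadata.

    Attributes
    ----------
    concentration : DataFrame, samples × elements
        Measured concentrations in mg·kg⁻¹.  Censored cells are ``NaN``
        until :func:`substitute_nondetects` fills them.
    censored : DataFrame of bool, samples × elements
        True where the measurement fell below the detection limit.
    detection_limit : DataFrame, samples × elements
        Detection limit (mg·kg⁻¹) for censored cells; ``NaN`` elsewhere.
    zone : Series or None
        Optional per-sample zone label (see :data:`ZONES`).
    """

    concentration: pd.DataFrame
    censored: pd.DataFrame
    detection_limit: pd.DataFrame
    zone: pd.Series | None = None

    def __post_init__(self) -> None:
        cols = list(self.concentration.columns)
        self.censored = self.censored.reindex(
            index=self.concentration.index, columns=cols
        ).fillna(False).astype(bool)
        self.detection_limit = self.detection_limit.reindex(
            index=self.concentration.index, columns=cols
        ).astype(float)
        self.validate()

    # -- basic views -------------------------------------------------------
    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.concentration.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.concentration.index

    @property
    def n_samples(self) -> int:
        return len(self.concentration)

    def validate(self) -> None:
        conc = self.concentration
        if conc.shape[0] == 0:
            raise ValidationError("panel contains no samples")
        if conc.shape[1] == 0:
            raise ValidationError("panel contains no elements")
        neg = conc < 0
        if neg.any().any():
            row, el = _first_true(neg)
            raise ValidationError(
                f"negative concentration for element {el!r} in sample {row!r}"
            )
        cens = self.censored
        dl = self.detection_limit
        bad_dl = cens & ~(dl > 0)
        if bad_dl.any().any():
            row, el = _first_true(bad_dl)
            raise ValidationError(
                f"censored cell without positive detection limit: "
                f"element {el!r}, sample {row!r}"
            )
        # Uncensored cells must carry a value: a NaN there is a data gap.
        gap = ~cens & conc.isna()
        if gap.any().any():
            row, el = _first_true(gap)
            raise ValidationError(
                f"missing concentration (not flagged censored) for element "
                f"{el!r} in sample {row!r}"
            )

    def values(self) -> np.ndarray:
        """Concentration matrix as a float array; raises if censored cells
        have not been substituted yet."""
        arr = self.concentration.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError(
                "panel contains unsubstituted censored cells; call "
                "substitute_nondetects first"
            )
        return arr

    def copy(self) -> "SamplePanel":
        return SamplePanel(
            concentration=self.concentration.copy(),
            censored=self.censored.copy(),
            detection_limit=self.detection_limit.copy(),
            zone=None if self.zone is None else self.zone.copy(),
        )


@dataclass(frozen=True)
class ReferenceSet:
    """Per-element background values and toxicity coefficients.

    ``background`` is C0 in mg·kg⁻¹; ``toxicity_coefficient`` is the
    dimensionless Hakanson T_r; ``igeo_k`` is the background-variation
    correction applied inside the geo-accumulation index (default 1.5).
    """

    background: pd.Series
    toxicity_coefficient: pd.Series
    igeo_k: float = 1.5

    def __post_init__(self) -> None:
        if (self.background <= 0).any():
            bad = self.background[self.background <= 0].index.tolist()
            raise ValidationError(f"nonpositive background for {bad}")
        if (self.toxicity_coefficient <= 0).any():
            bad = self.toxicity_coefficient[
                self.toxicity_coefficient <= 0
            ].index.tolist()
            raise ValidationError(f"nonpositive toxicity coefficient for {bad}")
        if not self.igeo_k > 0:
            raise ValidationError("igeo_k must be positive")

    def require_elements(self, elements) -> None:
        missing = [e for e in elements if e not in self.background.index]
        if missing:
            raise ValidationError(f"background missing for elements {missing}")
        missing = [e for e in elements if e not in self.toxicity_coefficient.index]
        if missing:
            raise ValidationError(
                f"toxicity coefficient missing for elements {missing}"
            )


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of a univariate sampling distribution.

    Families and parameters:

    * ``point`` — (value,): degenerate constant
    * ``triangular`` — (min, mode, max)
    * ``uniform`` — (low, high); draws use the open-at-low convention so a
      hard zero never occurs
    * ``lognormal`` — (geometric mean, geometric SD), GSD > 1
    * ``truncnormal`` — (mean, sd), arithmetic moments, truncated at 0
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = self.family
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        if fam == "point":
            if len(p) != 1 or not np.isfinite(p[0]):
                raise ValidationError("point spec needs one finite value")
        elif fam == "triangular":
            if len(p) != 3 or not (p[0] <= p[1] <= p[2]):
                raise ValidationError(
                    "triangular spec needs (min, mode, max) with min <= mode <= max"
                )
        elif fam == "uniform":
            if len(p) != 2 or not (p[0] <= p[1]):
                raise ValidationError("uniform spec needs (low, high) with low <= high")
        elif fam == "lognormal":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 1:
                raise ValidationError(
                    "lognormal spec needs (geometric mean > 0, geometric SD > 1)"
                )
        elif fam == "truncnormal":
            if len(p) != 2 or p[1] <= 0:
                raise ValidationError("truncnormal spec needs (mean, sd > 0)")
        else:
            raise ValidationError(f"unknown distribution family {fam!r}")

    @property
    def mean(self) -> float:
        """Analytic mean of the distribution (truncnormal: pre-truncation)."""
        p = self.params
        if self.family == "point":
            return p[0]
        if self.family == "triangular":
            return sum(p) / 3.0
        if self.family == "uniform":
            return (p[0] + p[1]) / 2.0
        if self.family == "lognormal":
            return p[0] * np.exp(0.5 * np.log(p[1]) ** 2)
        return p[0]


def _first_true(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    row, el = stacked[stacked].index[0]
    return str(row), str(el)


# ---------------------------------------------------------------------------
# Sample-table I/O


def _parse_cell(cell) -> tuple[float, bool, float]:
    """Return (value, censored, detection_limit) for one concentration cell."""
    if isinstance(cell, str):
        s = cell.strip()
        if s.startswith("<"):
            dl = float(s[1:])
            return np.nan, True, dl
        cell = float(s)
    v = float(cell)
    return v, False, np.nan


def read_sample_table(
    path: str | Path,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> SamplePanel:
    """Read a wide or long sample CSV into a validated :class:`SamplePanel`.

    Wide tables need a ``sample_id`` column plus one column per panel
    element; long tables need ``sample_id, element, value``.  Censored cells
    use the ``<DL`` sentinel or ``<element>_censored``/``<element>_dl``
    column pairs.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty sample table: {path}") from None
    if raw.empty:
        raise ValidationError(f"sample table has no rows: {path}")
    raw.columns = [c.strip() for c in raw.columns]

    if {"element", "value"}.issubset(raw.columns):
        raw = _long_to_wide(raw)

    if "sample_id" not in raw.columns:
        raise ValidationError("sample table must have a 'sample_id' column")
    missing = [e for e in elements if e not in raw.columns]
    if missing:
        raise ValidationError(f"sample table missing element columns {missing}")

    ids = raw["sample_id"].astype(str)
    n = len(raw)
    conc = pd.DataFrame(index=ids, columns=list(elements), dtype=float)
    cens = pd.DataFrame(False, index=ids, columns=list(elements))
    dl = pd.DataFrame(np.nan, index=ids, columns=list(elements))

    for el in elements:
        flag_col = f"{el}_censored"
        dl_col = f"{el}_dl"
        for i in range(n):
            cell = raw[el].iloc[i]
            try:
                v, c, d = _parse_cell(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"unparseable concentration {cell!r} for element {el!r} "
                    f"in sample {ids.iloc[i]!r}"
                ) from None
            if flag_col in raw.columns:
                flagged = str(raw[flag_col].iloc[i]).strip().lower() in (
                    "1", "true", "yes",
                )
                if flagged:
                    c = True
                    v = np.nan
                    if dl_col in raw.columns:
                        d = float(raw[dl_col].iloc[i])
            conc.iloc[i, conc.columns.get_loc(el)] = v
            cens.iloc[i, cens.columns.get_loc(el)] = c
            dl.iloc[i, dl.columns.get_loc(el)] = d

    zone = None
    if "zone" in raw.columns:
        zone = raw["zone"].astype(str).str.strip().str.lower()
        zone.index = ids
        unknown = sorted(set(zone) - set(ZONES))
        if unknown:
            raise ValidationError(f"unknown zone labels {unknown}")
    return SamplePanel(concentration=conc, censored=cens, detection_limit=dl, zone=zone)


def _long_to_wide(raw: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "element", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"long table missing columns {sorted(missing)}")
    wide = raw.pivot(index="sample_id", columns="element", values="value")
    wide = wide.reset_index()
    wide.columns.name = None
    if "zone" in raw.columns:
        zones = raw.groupby("sample_id")["zone"].first()
        wide["zone"] = wide["sample_id"].map(zones)
    return wide


def write_sample_table(panel: SamplePanel, path: str | Path) -> None:
    """Write a panel as a wide CSV using the ``<DL`` censoring sentinel.

    Substituted panels retain their censoring flags, so a write/read round
    trip restores the original censored state (values go back to ``<DL``).
    """
    out = pd.DataFrame(index=panel.sample_ids)
    out.index.name = "sample_id"
    for el in panel.elements:
        col = []
        for sid in panel.sample_ids:
            if panel.censored.loc[sid, el]:
                col.append(f"<{float(panel.detection_limit.loc[sid, el])!r}")
            else:
                col.append(repr(float(panel.concentration.loc[sid, el])))
        out[el] = col
    if panel.zone is not None:
        out["zone"] = panel.zone.values
    out.to_csv(path)


def substitute_nondetects(panel: SamplePanel) -> SamplePanel:
    """Replace censored cells with 5/6 of their detection limit.

    Censoring flags are retained (PMF uncertainty construction needs them);
    uncensored cells are untouched.  Idempotent.
    """
    out = panel.copy()
    cens = out.censored.to_numpy()
    if cens.any():
        conc = out.concentration.to_numpy(dtype=float)
        dl = out.detection_limit.to_numpy(dtype=float)
        conc[cens] = NONDETECT_FRACTION * dl[cens]
        out.concentration = pd.DataFrame(
            conc, index=out.sample_ids, columns=list(out.elements)
        )
    return out


# ---------------------------------------------------------------------------
# Reference-set configuration


def default_reference_set(
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> ReferenceSet:
    """Packaged regional background values and Hakanson toxicity weights."""
    bg = pd.Series({e: DEFAULT_BACKGROUND[e] for e in elements}, dtype=float)
    tr = pd.Series({e: DEFAULT_TOXICITY[e] for e in elements}, dtype=float)
    return ReferenceSet(background=bg, toxicity_coefficient=tr)


def load_reference_set(
    path: str | Path | None = None,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> ReferenceSet:
    """Load a reference set from a YAML config, or the packaged default.

    The config carries ``background`` and ``toxicity_coefficient`` maps
    (element → value) and optionally ``igeo_k``.  Missing elements raise a
    :class:`ValidationError` naming them.
    """
    if path is None or path == "default":
        return default_reference_set(elements)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"reference config {path} is not a mapping")
    try:
        bg_map = dict(cfg["background"])
    except KeyError:
        raise ValidationError("reference config missing 'background'") from None
    tr_map = dict(cfg.get("toxicity_coefficient", DEFAULT_TOXICITY))
    missing = [e for e in elements if e not in bg_map]
    if missing:
        raise ValidationError(f"background missing for elements {missing}")
    missing = [e for e in elements if e not in tr_map]
    if missing:
        raise ValidationError(f"toxicity coefficient missing for elements {missing}")
    bg = pd.Series({e: float(bg_map[e]) for e in elements})
    tr = pd.Series({e: float(tr_map[e]) for e in elements})
    k = float(cfg.get("igeo_k", 1.5))
    return ReferenceSet(background=bg, toxicity_coefficient=tr, igeo_k=k)


def panel_from_arrays(
    concentration: np.ndarray,
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
    sample_ids=None,
    censored: np.ndarray | None = None,
    detection_limit: np.ndarray | None = None,
    zone=None,
) -> SamplePanel:
    """Convenience constructor from plain arrays (used by the generator and
    by tests)."""
    concentration = np.asarray(concentration, dtype=float)
    n, m = concentration.shape
    if m != len(elements):
        raise ValidationError("column count does not match element panel")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    idx = pd.Index(sample_ids, name="sample_id")
    cols = list(elements)
    cens = pd.DataFrame(
        np.zeros((n, m), bool) if censored is None else np.asarray(censored, bool),
        index=idx,
        columns=cols,
    )
    dl = pd.DataFrame(
        np.full((n, m), np.nan)
        if detection_limit is None
        else np.asarray(detection_limit, float),
        index=idx,
        columns=cols,
    )
    conc = pd.DataFrame(concentration, index=idx, columns=cols)
    z = None if zone is None else pd.Series(list(zone), index=idx)
    return SamplePanel(concentration=conc, censored=cens, detection_limit=dl, zone=z)
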