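"""Panel bookkeeping: canonical measures, derived ratios, z-score normalization.

The panel covers folate-dependent one-carbon metabolism (FOCM, the methylation
arm) and transsulfuration (TS, the glutathione/redox arm).  Eleven raw plasma
concentrations are measured; four derived quantities (SAM/SAH, tGSH/GSSG,
fGSH/GSSG, and the percent oxidized glutathione fraction) are recomputed from
the raw values rather than trusted from input files, so every table in memory
is algebraically self-consistent.

Normalization follows the train/apply discipline used throughout the package:
means and standard deviations are estimated on training samples only and then
frozen, so validation or trial data are scaled by the training parameters and
never by their own moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Raw concentration measures, in canonical order.  Methylation arm first.
RAW_MEASURES: tuple[str, ...] = (
    "methionine",
    "SAM",
    "SAH",
    "homocysteine",
    "adenosine",
    "cysteine",
    "Glu-Cys",
    "Cys-Gly",
    "tGSH",
    "fGSH",
    "GSSG",
)

#: Measures derived from the raw concentrations.
DERIVED_MEASURES: tuple[str, ...] = (
    "SAM/SAH",
    "tGSH/GSSG",
    "fGSH/GSSG",
    "percent_oxidized",
)

#: The 15 canonical panel measures, in canonical order.
MEASURES: tuple[str, ...] = (
    "methionine",
    "SAM",
    "SAH",
    "SAM/SAH",
    "homocysteine",
    "adenosine",
    "cysteine",
    "Glu-Cys",
    "Cys-Gly",
    "tGSH",
    "fGSH",
    "GSSG",
    "tGSH/GSSG",
    "fGSH/GSSG",
    "percent_oxidized",
)

COHORT_LABELS = ("ASD", "TD")

#: Relative tolerance for validating supplied ratio columns against
#: recomputation from the raw concentrations.
RATIO_VALIDATION_RTOL = 1e-6


class PanelError(ValueError):
    """Raised for inconsistent or incomplete metabolite panels."""


def percent_oxidized(tgsh: float | np.ndarray, gssg: float | np.ndarray):
    """Fraction of glutathione in oxidized form: 2*GSSG / (tGSH + 2*GSSG)."""
    tgsh = np.asarray(tgsh, dtype=float)
    gssg = np.asarray(gssg, dtype=float)
    denom = tgsh + 2.0 * gssg
    if np.any(denom <= 0):
        raise PanelError("percent_oxidized undefined: tGSH + 2*GSSG must be > 0")
    return 2.0 * gssg / denom


def derive_ratios(panel: dict[str, float] | pd.Series) -> dict[str, float]:
    """Fill the four derived measures of a panel from its raw concentrations.

    Accepts a mapping with at least the 11 raw measures and returns a dict
    over all 15 canonical measures.  Raw fields pass through unchanged; any
    supplied derived fields are ignored and recomputed.  Idempotent.

    Raises
    ------
    PanelError
        If a raw concentration is negative, missing, or a ratio denominator
        is zero.
    """
    p = dict(panel) if not isinstance(panel, dict) else dict(panel)
    missing = [m for m in RAW_MEASURES if m not in p or pd.isna(p[m])]
    if missing:
        raise PanelError(f"missing raw measures: {missing}")
    for m in RAW_MEASURES:
        if p[m] < 0:
            raise PanelError(f"negative concentration for {m!r}: {p[m]}")
    for num, den, name in (("SAM", "SAH", "SAM/SAH"),
                           ("tGSH", "GSSG", "tGSH/GSSG"),
                           ("fGSH", "GSSG", "fGSH/GSSG")):
        if p[den] == 0:
            raise PanelError(f"zero denominator {den!r} for ratio {name!r}")
        p[name] = p[num] / p[den]
    p["percent_oxidized"] = float(percent_oxidized(p["tGSH"], p["GSSG"]))
    return {m: float(p[m]) for m in MEASURES}


def average_timepoints(panel_a: dict[str, float], panel_b: dict[str, float]) -> dict[str, float]:
    """Average two panels measure-wise, re-deriving ratios from averaged raws.

    Used for trials that assayed the panel at two follow-up visits: raw
    concentrations are averaged arithmetically and the four derived measures
    are recomputed from those averages, which preserves the panel's algebraic
    invariants (averaging the ratio columns themselves would not).
    """
    for m in RAW_MEASURES:
        if m not in panel_a or m not in panel_b:
            raise PanelError(f"measure {m!r} missing from one of the panels")
    avg = {m: 0.5 * (float(panel_a[m]) + float(panel_b[m])) for m in RAW_MEASURES}
    return derive_ratios(avg)


def validate_panel_table(df: pd.DataFrame, rtol: float = RATIO_VALIDATION_RTOL) -> pd.DataFrame:
    """Validate a table of panels: completeness, signs, ratio consistency.

    Rows with any missing measure are dropped (the analysis requires the
    complete 15-measure panel); supplied derived columns are checked against
    recomputation and the recomputed values are kept.  Returns a new frame.
    """
    df = df.copy()
    present = [m for m in MEASURES if m in df.columns]
    missing_raw = [m for m in RAW_MEASURES if m not in df.columns]
    if missing_raw:
        raise PanelError(f"table lacks raw measure columns: {missing_raw}")
    complete = df[list(RAW_MEASURES)].notna().all(axis=1)
    for m in [c for c in DERIVED_MEASURES if c in df.columns]:
        complete &= df[m].notna()
    df = df.loc[complete].copy()
    if (df[list(RAW_MEASURES)] < 0).any().any():
        bad = [m for m in RAW_MEASURES if (df[m] < 0).any()]
        raise PanelError(f"negative concentrations in columns: {bad}")
    derived = {
        "SAM/SAH": df["SAM"] / df["SAH"],
        "tGSH/GSSG": df["tGSH"] / df["GSSG"],
        "fGSH/GSSG": df["fGSH"] / df["GSSG"],
        "percent_oxidized": percent_oxidized(df["tGSH"].to_numpy(), df["GSSG"].to_numpy()),
    }
    for name, recomputed in derived.items():
        recomputed = np.asarray(recomputed, dtype=float)
        if name in df.columns:
            supplied = df[name].to_numpy(dtype=float)
            rel = np.abs(supplied - recomputed) / np.maximum(np.abs(recomputed), 1e-300)
            if np.any(rel > rtol):
                i = int(np.argmax(rel))
                raise PanelError(
                    f"supplied {name!r} inconsistent with raw concentrations "
                    f"(row {df.index[i]}: {supplied[i]!r} vs {recomputed[i]!r})"
                )
        df[name] = recomputed
    return df


@dataclass(frozen=True)
class NormalizationParams:
    """Frozen per-measure location/scale estimated on training samples."""

    measures: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if np.any(self.std <= 0):
            bad = [m for m, s in zip(self.measures, self.std) if s <= 0]
            raise PanelError(f"non-positive standard deviation for: {bad}")

    def to_dict(self) -> dict:
        return {
            "measures": list(self.measures),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(tuple(d["measures"]), np.asarray(d["mean"]), np.asarray(d["std"]))


def zscore_fit(training: pd.DataFrame, measures: list[str] | None = None) -> NormalizationParams:
    """Estimate z-score parameters (sample sd, n-1 denominator) on training data.

    Raises on constant columns: an sd of zero cannot normalize.
    """
    cols = list(measures) if measures is not None else [c for c in MEASURES if c in training.columns]
    if not cols:
        raise PanelError("no measure columns to fit")
    X = training[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise PanelError("need at least 2 training samples")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [c for c, s in zip(cols, std) if s == 0]
        raise PanelError(f"constant training column(s): {bad}")
    return NormalizationParams(tuple(cols), mean, std)


def zscore_apply(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Scale a table by frozen training parameters (never the table's own moments)."""
    unknown = [c for c in params.measures if c not in table.columns]
    if unknown:
        raise PanelError(f"table lacks measures required by params: {unknown}")
    out = table.copy()
    cols = list(params.measures)
    out[cols] = (table[cols].to_numpy(dtype=float) - params.mean) / params.std
    return out
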