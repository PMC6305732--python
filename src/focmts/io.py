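"""CSV input/output for case-control cohort tables and trial tables.

Case-control files: one row per participant with columns
``participant_id, cohort`` (ASD|TD) followed by the 15 canonical measures.
Trial files: ``participant_id, arm`` plus ``pre_``/``post_``-prefixed measure
columns and ``pre_vabs``/``post_vabs`` Vineland Composite scores.
percent_oxidized is stored as a fraction in [0, 1].
"""

from __future__ import annotations

import logging

import pandas as pd

from .preprocessing import MEASURES, COHORT_LABELS, PanelError, validate_panel_table

log = logging.getLogger(__name__)

PRE = "pre_"
POST = "post_"
VABS_COLS = ("pre_vabs", "post_vabs")


def load_cohort_csv(path) -> pd.DataFrame:
    """Load and validate a case-control cohort CSV.

    Incomplete rows are excluded with a logged count, mirroring the
    complete-panel inclusion criterion.
    """
    df = pd.read_csv(path)
    for col in ("participant_id", "cohort"):
        if col not in df.columns:
            raise PanelError(f"cohort file missing column {col!r}")
    bad = set(df["cohort"].unique()) - set(COHORT_LABELS)
    if bad:
        raise PanelError(f"unknown cohort labels: {sorted(bad)}")
    n_before = len(df)
    df = validate_panel_table(df)
    if len(df) < n_before:
        log.info("excluded %d incomplete rows of %d", n_before - len(df), n_before)
    return df.reset_index(drop=True)


def load_trial_csv(path) -> pd.DataFrame:
    """Load and validate a trial CSV with paired pre/post panels and VABS scores."""
    df = pd.read_csv(path)
    for col in ("participant_id",) + VABS_COLS:
        if col not in df.columns:
            raise PanelError(f"trial file missing column {col!r}")
    n_before = len(df)
    keep = df[list(VABS_COLS)].notna().all(axis=1)
    for prefix in (PRE, POST):
        cols = [prefix + m for m in MEASURES if prefix + m in df.columns]
        sub = df[cols].rename(columns=lambda c: c[len(prefix):])
        validated = validate_panel_table(sub)
        keep &= df.index.isin(validated.index)
        df.loc[validated.index, cols] = validated[[c[len(prefix):] for c in cols]].to_numpy()
    df = df.loc[keep].reset_index(drop=True)
    if len(df) < n_before:
        log.info("excluded %d incomplete trial rows of %d", n_before - len(df), n_before)
    return df


def trial_panels(trial: pd.DataFrame, which: str) -> pd.DataFrame:
    """Extract the pre- or post-treatment panel block with unprefixed columns."""
    prefix = {"pre": PRE, "post": POST}[which]
    cols = [prefix + m for m in MEASURES]
    missing = [c for c in cols if c not in trial.columns]
    if missing:
        raise PanelError(f"trial table missing columns: {missing}")
    return trial[cols].rename(columns=lambda c: c[len(prefix):])


def delta_table(trials: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool trial arms into a post-minus-pre change table.

    Returns one row per participant across all supplied arms, with the 15
    Δ-measure columns (named by the measure) and a ``delta_vabs`` response
    column.
    """
    frames = []
    for t in trials:
        pre = trial_panels(t, "pre").to_numpy(dtype=float)
        post = trial_panels(t, "post").to_numpy(dtype=float)
        d = pd.DataFrame(post - pre, columns=list(MEASURES))
        d["delta_vabs"] = (t["post_vabs"] - t["pre_vabs"]).to_numpy(dtype=float)
        if "arm" in t.columns:
            d["arm"] = t["arm"].to_numpy()
        frames.append(d)
    out = pd.concat(frames, ignore_index=True)
    if out.isna().any().any():
        raise PanelError("delta table contains non-finite entries")
    return out
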