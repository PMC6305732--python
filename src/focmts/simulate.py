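"""Seeded synthetic case-control and trial cohorts.

The clinical data behind this analysis are not publicly deposited, so the
package ships a generator that emulates their statistical structure: a
case-control study (92 ASD / 82 TD by default), four treatment arms
(33 / 8 / 14 / 19 participants), correlated log-normal metabolite
concentrations with all derived ratios recomputed (never sampled), a
treatment-induced shift of each arm's log-concentrations toward the TD mean,
and a behavior-change response linked to the metabolite changes with tunable
noise.

The ASD cohort's distribution separates more strongly on the redox markers
(GSSG, percent oxidized glutathione, tGSH) than on the methylation
metabolites, mirroring the regime the analysis is designed to detect, so
variable-importance code has realistic structure to find.  All numeric
defaults (log-scale means, spreads, correlations) are fabricated:
plausible-magnitude plasma values, not estimates from any dataset.

One integer seed drives every draw through a splittable generator, so the
case-control table and each arm are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import RAW_MEASURES, derive_ratios, validate_panel_table

ARMS = ("MeCbl+LDFA", "BH4", "HDFA", "placebo")

#: TD-cohort log-scale mean concentrations (natural log of plausible plasma
#: values, arbitrary assay units).
_TD_LOG_MEAN = {
    "methionine": np.log(25.0),
    "SAM": np.log(100.0),
    "SAH": np.log(20.0),
    "homocysteine": np.log(6.0),
    "adenosine": np.log(0.25),
    "cysteine": np.log(210.0),
    "Glu-Cys": np.log(2.2),
    "Cys-Gly": np.log(40.0),
    "tGSH": np.log(4.0),
    "fGSH": np.log(1.8),
    "GSSG": np.log(0.15),
}

#: ASD-minus-TD shift of the log means.  Redox markers (GSSG up, tGSH/fGSH
#: down) separate more than the methylation arm.
_ASD_LOG_SHIFT = {
    "methionine": -0.16,
    "SAM": -0.09,
    "SAH": 0.11,
    "homocysteine": 0.05,
    "adenosine": 0.09,
    "cysteine": -0.13,
    "Glu-Cys": -0.09,
    "Cys-Gly": -0.07,
    "tGSH": -0.27,
    "fGSH": -0.22,
    "GSSG": 0.52,
}

#: Log-scale standard deviations (identical for both cohorts).
_LOG_SD = {
    "methionine": 0.22,
    "SAM": 0.25,
    "SAH": 0.28,
    "homocysteine": 0.25,
    "adenosine": 0.30,
    "cysteine": 0.18,
    "Glu-Cys": 0.25,
    "Cys-Gly": 0.22,
    "tGSH": 0.28,
    "fGSH": 0.30,
    "GSSG": 0.40,
}

_METHYLATION = ("methionine", "SAM", "SAH", "homocysteine", "adenosine")

#: Fraction of the ASD-to-TD log-mean gap recovered by each arm.
_ARM_SHIFT = {"MeCbl+LDFA": 0.85, "BH4": 0.80, "HDFA": 0.30, "placebo": 0.10}

#: Behavior link: ΔVABS is a weighted sum of relative metabolite changes.
#: Weights act on Δmeasure / TD-typical-value, so they are dimensionless.
_LINK_COEFS = {
    "methionine": 12.0,
    "Glu-Cys": 8.0,
    "Cys-Gly": 8.0,
    "tGSH": 10.0,
    "tGSH/GSSG": 6.0,
    "fGSH/GSSG": 6.0,
}

#: TD-typical values used to scale the link terms (raw and derived measures).
_LINK_SCALES = {
    "methionine": 25.0, "SAM": 100.0, "SAH": 20.0, "SAM/SAH": 5.0,
    "homocysteine": 6.0, "adenosine": 0.25, "cysteine": 210.0,
    "Glu-Cys": 2.2, "Cys-Gly": 40.0, "tGSH": 4.0, "fGSH": 1.8,
    "GSSG": 0.15, "tGSH/GSSG": 27.0, "fGSH/GSSG": 12.0,
    "percent_oxidized": 0.07,
}


def _correlation_matrix() -> np.ndarray:
    """Block-structured correlations: methylation block 0.30, redox/TS block
    0.35, cross-block 0.10 (compound-symmetric blocks are PSD)."""
    m = len(RAW_MEASURES)
    corr = np.full((m, m), 0.10)
    for block, r in ((set(_METHYLATION), 0.30),
                     (set(RAW_MEASURES) - set(_METHYLATION), 0.35)):
        idx = [i for i, name in enumerate(RAW_MEASURES) if name in block]
        for i in idx:
            for j in idx:
                corr[i, j] = r
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with study-structure defaults."""

    n_asd: int = 92
    n_td: int = 82
    arm_sizes: dict = field(default_factory=lambda: {
        "MeCbl+LDFA": 33, "BH4": 8, "HDFA": 14, "placebo": 19})
    td_log_mean: dict = field(default_factory=lambda: dict(_TD_LOG_MEAN))
    asd_log_shift: dict = field(default_factory=lambda: dict(_ASD_LOG_SHIFT))
    log_sd: dict = field(default_factory=lambda: dict(_LOG_SD))
    correlation: np.ndarray = field(default_factory=_correlation_matrix)
    arm_shift: dict = field(default_factory=lambda: dict(_ARM_SHIFT))
    #: sd of per-participant log-scale treatment noise, as a multiple of each
    #: measure's log sd
    post_noise_frac: float = 0.35
    link_coefs: dict = field(default_factory=lambda: dict(_LINK_COEFS))
    link_nonlinear: bool = False
    #: explicit response noise sd (VABS units); if None, derived from link_r2
    response_noise_sd: float | None = None
    #: target fraction of response variance explained by the link
    link_r2: float = 0.5
    vabs_baseline_mean: float = 65.0
    vabs_baseline_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        self.correlation = np.asarray(self.correlation, dtype=float)
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(self.correlation)) < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        if any(n < 1 for n in (self.n_asd, self.n_td, *self.arm_sizes.values())):
            raise ValueError("cohort and arm sizes must be >= 1")
        if self.response_noise_sd is not None and self.response_noise_sd < 0:
            raise ValueError("response noise sd must be >= 0")

    def with_overrides(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _covariance(config: GeneratorConfig) -> np.ndarray:
    sd = np.array([config.log_sd[m] for m in RAW_MEASURES])
    return config.correlation * np.outer(sd, sd)


def _draw_raw(rng: np.random.Generator, log_mean: np.ndarray,
              cov: np.ndarray, n: int) -> np.ndarray:
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    z = rng.standard_normal((n, len(cov)))
    return np.exp(log_mean + z @ chol.T)


def _panels_frame(raw: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(raw, columns=list(RAW_MEASURES))
    return validate_panel_table(df)


def generate_case_control(config: GeneratorConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Synthetic case-control cohort table (participant_id, cohort, 15 measures)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cov = _covariance(config)
    mu_td = np.array([config.td_log_mean[m] for m in RAW_MEASURES])
    mu_asd = mu_td + np.array([config.asd_log_shift[m] for m in RAW_MEASURES])
    asd = _panels_frame(_draw_raw(rng, mu_asd, cov, config.n_asd))
    td = _panels_frame(_draw_raw(rng, mu_td, cov, config.n_td))
    asd.insert(0, "cohort", "ASD")
    td.insert(0, "cohort", "TD")
    out = pd.concat([asd, td], ignore_index=True)
    out.insert(0, "participant_id", [f"S{i:04d}" for i in range(len(out))])
    return out


def _link_signal(config: GeneratorConfig, deltas: pd.DataFrame) -> np.ndarray:
    terms = []
    for measure, coef in config.link_coefs.items():
        x = deltas[measure].to_numpy(dtype=float) / _LINK_SCALES[measure]
        if config.link_nonlinear:
            x = np.tanh(x)
        terms.append(coef * x)
    return np.sum(terms, axis=0)


def generate_trial(config: GeneratorConfig, arm: str,
                   seed: int | None = None) -> pd.DataFrame:
    """Synthetic trial arm with paired pre/post panels and VABS scores.

    Pre-treatment panels come from the ASD distribution; treatment moves each
    participant's log-concentrations a configured fraction of the way toward
    the TD mean, plus per-participant noise.  The VABS Composite change is a
    (optionally nonlinear) weighted sum of relative metabolite changes plus
    Gaussian noise, so regression code has a recoverable planted signal.
    """
    if arm not in config.arm_sizes:
        raise ValueError(f"unknown arm {arm!r}; configured: {sorted(config.arm_sizes)}")
    seed = config.seed if seed is None else seed
    arm_index = list(config.arm_sizes).index(arm)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2 + arm_index)[-1])
    n = config.arm_sizes[arm]
    cov = _covariance(config)
    mu_td = np.array([config.td_log_mean[m] for m in RAW_MEASURES])
    shift_vec = -np.array([config.asd_log_shift[m] for m in RAW_MEASURES])
    mu_asd = mu_td - shift_vec

    pre_raw = _draw_raw(rng, mu_asd, cov, n)
    sd = np.array([config.log_sd[m] for m in RAW_MEASURES])
    noise = rng.standard_normal((n, len(sd))) * (config.post_noise_frac * sd)
    post_raw = np.exp(np.log(pre_raw) + config.arm_shift.get(arm, 0.0) * shift_vec + noise)

    pre = _panels_frame(pre_raw)
    post = _panels_frame(post_raw)
    deltas = post - pre
    signal = _link_signal(config, deltas)
    if config.response_noise_sd is not None:
        noise_sd = config.response_noise_sd
    else:
        sig_sd = float(np.std(signal, ddof=1)) if n > 1 else 1.0
        rho2 = config.link_r2
        noise_sd = sig_sd * np.sqrt((1.0 - rho2) / rho2) if rho2 > 0 else 1.0
    dvabs = signal + rng.standard_normal(n) * noise_sd

    out = pd.DataFrame({"participant_id": [f"{arm[:4]}{i:03d}" for i in range(n)],
                        "arm": arm})
    for col in pre.columns:
        out[f"pre_{col}"] = pre[col].to_numpy()
    for col in post.columns:
        out[f"post_{col}"] = post[col].to_numpy()
    pre_vabs = config.vabs_baseline_mean + rng.standard_normal(n) * config.vabs_baseline_sd
    out["pre_vabs"] = np.round(pre_vabs, 1)
    out["post_vabs"] = np.round(pre_vabs + dvabs, 1)
    return out


def generate_study(config: GeneratorConfig) -> dict:
    """Full synthetic study: case-control table plus one table per arm."""
    return {
        "case_control": generate_case_control(config),
        "trials": {arm: generate_trial(config, arm) for arm in config.arm_sizes},
    }
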