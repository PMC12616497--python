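"""Synthetic cohort generator.

Emulates the statistical structure the severity analysis assumes: two
correlated exogenous latents (communication and comorbidities) driving a
global-severity latent, nine bounded clinical-outcome indicators reflecting
those latents, external correlates (EEG power ratios, quality of life,
behavior) linear in global severity, instrument-block missingness, and
retest replicates with fresh measurement noise about four weeks later.

The generator works on an unbounded latent-linear scale and then maps each
indicator affinely into its instrument's scale range (centre of the range,
three generating SDs to the nearest bound) before clipping; the clipping
fraction is tracked and is below 1% under the default parameters.  All
closed-form implied moments ignore clipping, which is why moment-recovery
checks use the default (lightly clipped) regime.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (
    EXTERNAL_VARS,
    HIGHER_IS_BETTER,
    INSTRUMENTS,
    OBSERVED_VARS,
    SCALE_RANGES,
    validate_cohort,
)
from .model import ANCHORS, MEASUREMENT, SemModel, default_cdd_model

log = logging.getLogger(__name__)

# Default per-instrument missingness, matching the study cohort's reported
# rates (caregiver 4%, communication checklist 20%, clinician 28%, quality
# of life 30%, sleep 39%); EEG was available for 45 of 206 subjects.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "caregiver": 0.04,
    "csbs": 0.20,
    "clinician": 0.28,
    "qol": 0.30,
    "sleep": 0.39,
    "eeg": 1.0 - 45 / 206,
}

# Generating loadings (anchor of each latent at 1) and residual SDs, chosen
# so indicator-severity correlations are strong for motor/communication and
# weakest for the sleep domains.
DEFAULT_LOADINGS: dict[str, float] = {
    "motor": 1.0,
    "vision": 0.85,
    "feeding": 0.70,
    "comm_clinician": 1.0,
    "csbs": 0.90,
    "insomnia": 1.0,
    "sleepiness": 0.90,
    "seizures": 0.70,
    "alertness": 0.80,
}

DEFAULT_RESIDUAL_SDS: dict[str, float] = {
    "motor": 0.40,
    "vision": 0.70,
    "feeding": 0.90,
    "comm_clinician": 0.60,
    "csbs": 0.50,
    "insomnia": 1.00,
    "sleepiness": 1.10,
    "seizures": 0.90,
    "alertness": 0.60,
}

# External correlates: target correlation with latent global severity on
# the raw reported scale, plus (centre, sd, clip range) of the raw scale.
DEFAULT_EXTERNAL_R: dict[str, float] = {
    "eeg_alpha_delta": 0.61,
    "eeg_theta_delta": 0.50,
    "qol_total": 0.68,
    "behavior": -0.21,
}

EXTERNAL_SCALE: dict[str, tuple[float, float, tuple[float, float] | None]] = {
    "eeg_alpha_delta": (0.5, 0.2, None),
    "eeg_theta_delta": (1.0, 0.3, None),
    "qol_total": (60.8, 15.9, (0.0, 100.0)),
    "behavior": (50.0, 20.0, (0.0, 100.0)),
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    ``bounded=False`` skips the affine scale mapping and emits indicators on
    the latent-linear scale (severity-oriented, unclipped); this is the
    regime used for parameter-recovery experiments, where generating
    loadings are directly comparable to fitted ones.
    """

    n_subjects: int = 206
    seed: int = 0
    # structural part: global = b_com * communication + b_cmb * comorbidities + zeta
    b_communication: float = 0.65
    b_comorbidities: float = 0.45
    latent_cov: float = 0.45          # cov(communication, comorbidities)
    latent_vars: tuple[float, float] = (1.0, 1.0)
    loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    residual_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SDS))
    bounded: bool = True
    scale_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {v: SCALE_RANGES[v] for v in OBSERVED_VARS})
    orientation: dict[str, bool] = field(default_factory=lambda: dict(HIGHER_IS_BETTER))
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    retest_fraction: float = 18 / 206
    #: occasion-level measurement noise SD (latent-linear units).  Each
    #: indicator's residual splits into a stable specific part plus
    #: occasion noise of this SD on every visit, so cross-sectional moments
    #: are unchanged while test-retest reliability is
    #: 1 - retest_noise_sd^2 / Var(indicator).  0 makes retest rows equal
    #: baseline exactly (ICC = 1); None redraws the full residual at
    #: retest (no stable specific variance).  The default emulates the
    #: high component reliability seen in repeated COA administration.
    retest_noise_sd: float | None = 0.15
    external_r: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXTERNAL_R))
    age_under7_frac: float = 0.515
    female_frac: float = 0.82
    keep_latents: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        scalars = [self.b_communication, self.b_comorbidities, self.latent_cov,
                   *self.latent_vars, *self.loadings.values(),
                   *self.residual_sds.values(), self.retest_fraction,
                   self.age_under7_frac, self.female_frac,
                   *self.external_r.values(), *self.missing_rates.values()]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("non-finite value in generator config")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for inst, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {inst!r} not in [0, 1]: {rate}")
        for var, sd in self.residual_sds.items():
            if sd <= 0:
                raise ValueError(f"residual SD for {var!r} must be > 0: {sd}")
        for var, (lo, hi) in self.scale_ranges.items():
            if not lo < hi:
                raise ValueError(f"scale range for {var!r} has min >= max")
        if not 0.0 <= self.retest_fraction <= 1.0:
            raise ValueError("retest_fraction must be in [0, 1]")
        if self.retest_noise_sd is not None:
            if self.retest_noise_sd < 0:
                raise ValueError("retest_noise_sd must be >= 0")
            too_big = [v for v, sd in self.residual_sds.items()
                       if self.retest_noise_sd > sd]
            if too_big:
                raise ValueError(
                    f"retest_noise_sd exceeds the residual SD of {too_big}; "
                    "the stable specific variance would be negative")
        if abs(self.external_r.get("dummy", 0)) > 1 or any(
                abs(r) > 1 for r in self.external_r.values()):
            raise ValueError("external correlation targets must lie in [-1, 1]")
        if self.zeta_variance() <= 0:
            raise ValueError(
                "structural coefficients imply latent global variance >= 1; "
                "no admissible disturbance variance")

    # -- closed-form moments ------------------------------------------
    def zeta_variance(self) -> float:
        """Disturbance variance making latent global severity unit-variance."""
        v1, v2 = self.latent_vars
        b1, b2 = self.b_communication, self.b_comorbidities
        return 1.0 - (b1 * b1 * v1 + b2 * b2 * v2 + 2 * b1 * b2 * self.latent_cov)

    def latent_cov_matrix(self) -> np.ndarray:
        """3x3 covariance of (communication, comorbidities, global)."""
        v1, v2 = self.latent_vars
        b1, b2 = self.b_communication, self.b_comorbidities
        c12 = self.latent_cov
        cg1 = b1 * v1 + b2 * c12
        cg2 = b2 * v2 + b1 * c12
        return np.array([
            [v1, c12, cg1],
            [c12, v2, cg2],
            [cg1, cg2, 1.0],
        ])

    def _latent_index(self, var: str) -> int:
        return {"communication": 0, "comorbidities": 1, "global": 2}[MEASUREMENT[var]]

    def implied_indicator_cov(self) -> np.ndarray:
        """9x9 covariance of the indicators on the latent-linear scale."""
        V = self.latent_cov_matrix()
        lam = np.array([self.loadings[v] for v in OBSERVED_VARS])
        idx = np.array([self._latent_index(v) for v in OBSERVED_VARS])
        cov = lam[:, None] * lam[None, :] * V[np.ix_(idx, idx)]
        cov[np.diag_indices(9)] += np.array(
            [self.residual_sds[v] ** 2 for v in OBSERVED_VARS])
        return cov

    def implied_indicator_corr(self) -> np.ndarray:
        cov = self.implied_indicator_cov()
        sd = np.sqrt(np.diag(cov))
        return cov / np.outer(sd, sd)

    def _severity_scale(self, var: str) -> tuple[float, float]:
        """(offset, slope) mapping latent-linear z to the severity-oriented
        bounded scale: centre of the range, three generating SDs to the
        nearest bound."""
        lo, hi = self.scale_ranges[var]
        sd = np.sqrt(self.implied_indicator_cov()[
            OBSERVED_VARS.index(var), OBSERVED_VARS.index(var)])
        return ( (lo + hi) / 2.0, (hi - lo) / (2.0 * 3.0 * sd) )

    def indicator_global_cov(self) -> np.ndarray:
        """Cov of each indicator (latent-linear scale) with latent global."""
        V = self.latent_cov_matrix()
        return np.array([
            self.loadings[v] * V[self._latent_index(v), 2] for v in OBSERVED_VARS
        ])

    def implied_composite_external_corr(self, weights: dict[str, float],
                                        correlate: str) -> float:
        """Implied correlation of a weighted severity composite (on the
        harmonized scale) with an external correlate, ignoring clipping."""
        r = self.external_r[correlate]
        w = np.array([weights[v] for v in OBSERVED_VARS])
        if self.bounded:
            # harmonized value is a positive affine image of the severity
            # scale, which is itself affine in z; slopes cancel in the corr
            # except for per-variable positive factors
            factors = np.array([
                self._severity_scale(v)[1] * 100.0
                / (self.scale_ranges[v][1] - self.scale_ranges[v][0])
                for v in OBSERVED_VARS])
        else:
            factors = np.ones(9)
        wz = w * factors
        cov = self.implied_indicator_cov()
        var_comp = wz @ cov @ wz
        cov_with_g = wz @ self.indicator_global_cov()
        return r * cov_with_g / np.sqrt(var_comp)  # Var(global) = 1

    def to_dict(self) -> dict:
        return asdict(self)


def retest_noise_for_icc(config: GeneratorConfig, var: str, target_icc: float) -> float:
    """Occasion-noise SD giving a theoretical single-measure ICC for ``var``.

    The test-retest ICC of an indicator under the generator's
    stable-plus-occasion residual split is 1 - sigma_occ^2 / Var(indicator);
    invert for sigma_occ and assign the result to ``retest_noise_sd``.
    """
    if not 0 < target_icc <= 1:
        raise ValueError("target ICC must be in (0, 1]")
    i = OBSERVED_VARS.index(var)
    total = config.implied_indicator_cov()[i, i]
    return float(np.sqrt(total * (1.0 - target_icc)))


def theoretical_icc(config: GeneratorConfig, var: str) -> float:
    """Closed-form test-retest ICC of an indicator under the generator."""
    if config.retest_noise_sd is None:
        i = OBSERVED_VARS.index(var)
        total = config.implied_indicator_cov()[i, i]
        signal = total - config.residual_sds[var] ** 2
        return float(signal / total)
    i = OBSERVED_VARS.index(var)
    total = config.implied_indicator_cov()[i, i]
    return float(1.0 - config.retest_noise_sd ** 2 / total)


class _GeneratorState:
    """Per-subject latents and stable true scores carried in ``df.attrs``
    so retest replicates can re-measure the same subjects.  Equality is by
    identity (pandas compares attrs when concatenating frames)."""

    def __init__(self, latents: np.ndarray, true_scores: dict[str, np.ndarray]):
        self.latents = latents
        self.true_scores = true_scores

    def __eq__(self, other) -> bool:
        return self is other

    def __hash__(self) -> int:
        return id(self)


def _occasion_sds(config: GeneratorConfig) -> dict[str, float]:
    if config.retest_noise_sd is None:
        return dict(config.residual_sds)
    return {v: float(config.retest_noise_sd) for v in OBSERVED_VARS}


def _map_scores(config: GeneratorConfig, z: dict[str, np.ndarray]) -> pd.DataFrame:
    """Affine-map latent-linear indicator values into their raw scales."""
    out = {}
    clipped = 0
    n = len(next(iter(z.values())))
    for var in OBSERVED_VARS:
        if config.bounded:
            lo, hi = config.scale_ranges[var]
            centre, slope = config._severity_scale(var)
            s = centre + slope * z[var]
            clipped += int(np.sum((s < lo) | (s > hi)))
            s = np.clip(s, lo, hi)
            if config.orientation.get(var, False):
                s = lo + hi - s
            out[var] = s
        else:
            out[var] = z[var]
    frame = pd.DataFrame(out)
    frame.attrs["clipped_fraction"] = clipped / (9 * n)
    return frame


def _true_scores(config: GeneratorConfig, latents: np.ndarray,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Stable part of each indicator: loading x latent + stable specific."""
    n = latents.shape[0]
    occ = _occasion_sds(config)
    out = {}
    for var in OBSERVED_VARS:
        stable_var = config.residual_sds[var] ** 2 - occ[var] ** 2
        u = rng.normal(0.0, np.sqrt(max(stable_var, 0.0)), size=n)
        out[var] = (config.loadings[var] * latents[:, config._latent_index(var)]
                    + u)
    return out


def _occasion_draw(config: GeneratorConfig, true_z: dict[str, np.ndarray],
                   rng: np.random.Generator) -> pd.DataFrame:
    occ = _occasion_sds(config)
    n = len(next(iter(true_z.values())))
    z = {var: true_z[var] + rng.normal(0.0, occ[var], size=n)
         for var in OBSERVED_VARS}
    return _map_scores(config, z)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a baseline cohort under the configured latent model.

    Deterministic for a fixed (config, seed).  The returned frame carries
    the per-subject latents in ``df.attrs['latents']`` so retest replicates
    can re-measure the same subjects; ``keep_latents=True`` additionally
    exposes them as ``latent_*`` columns.
    """
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 17])
    n = config.n_subjects

    v1, v2 = config.latent_vars
    phi = np.array([[v1, config.latent_cov], [config.latent_cov, v2]])
    exo = rng.multivariate_normal([0.0, 0.0], phi, size=n, method="cholesky")
    zeta = rng.normal(0.0, np.sqrt(config.zeta_variance()), size=n)
    g = config.b_communication * exo[:, 0] + config.b_comorbidities * exo[:, 1] + zeta
    latents = np.column_stack([exo, g])

    true_z = _true_scores(config, latents, rng)
    scores = _occasion_draw(config, true_z, rng)
    clip_frac = scores.attrs["clipped_fraction"]
    if clip_frac > 0.01:
        log.warning("scale clipping affected %.2f%% of indicator cells", 100 * clip_frac)

    df = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "visit": "baseline",
        "age_group": np.where(rng.random(n) < config.age_under7_frac, "under7", "over7"),
        "sex": np.where(rng.random(n) < config.female_frac, "F", "M"),
    })
    df = pd.concat([df, scores], axis=1)

    for var in EXTERNAL_VARS:
        r = config.external_r.get(var)
        if r is None:
            continue
        u = r * g + np.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(size=n)
        centre, sd, clip = EXTERNAL_SCALE[var]
        val = centre + sd * u
        if clip is not None:
            val = np.clip(val, *clip)
        df[var] = val

    # instrument-block MCAR missingness: all columns of a questionnaire
    # missing together, independently across instruments and subjects
    for inst, rate in config.missing_rates.items():
        cols = [c for c in INSTRUMENTS.get(inst, ()) if c in df.columns]
        if not cols or rate == 0.0:
            continue
        mask = rng.random(n) < rate
        df.loc[mask, cols] = np.nan

    if config.keep_latents:
        df["latent_communication"] = latents[:, 0]
        df["latent_comorbidities"] = latents[:, 1]
        df["latent_global"] = latents[:, 2]

    df.attrs["generator_state"] = _GeneratorState(latents, true_z)
    df.attrs["clipped_fraction"] = clip_frac
    validate_cohort(df, ranges=SCALE_RANGES if config.bounded else {})
    return df


def generate_retest_pairs(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Append retest rows for a random ``retest_fraction`` of subjects.

    Retest rows keep each subject's latent values, stable specific scores
    and missingness pattern, and redraw only the occasion-level measurement
    noise (``retest_noise_sd``; 0 reproduces baseline exactly, so the
    downstream ICC is 1).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    state = cohort.attrs.get("generator_state")
    if state is None:
        raise ValueError(
            "cohort lacks generator state; pass the frame returned by "
            "generate_cohort")
    true_z = state.true_scores
    rng = np.random.default_rng([config.seed % (2**31), 23])
    base = cohort[cohort["visit"] == "baseline"].reset_index(drop=True)
    n = len(base)
    n_retest = int(round(n * config.retest_fraction))
    # the reliability subgroup is drawn among complete-case subjects when
    # possible, emulating complete test-retest assessment sets
    complete = np.flatnonzero(~base[list(OBSERVED_VARS)].isna().any(axis=1))
    pool = complete if complete.size >= n_retest else np.arange(n)
    idx = np.sort(rng.choice(pool, size=n_retest, replace=False))

    scores = _occasion_draw(config, {v: true_z[v][idx] for v in OBSERVED_VARS}, rng)
    retest = base.iloc[idx].copy().reset_index(drop=True)
    for var in OBSERVED_VARS:
        miss = retest[var].isna().to_numpy()
        retest[var] = scores[var].to_numpy()
        retest.loc[miss, var] = np.nan    # copy baseline missingness
    retest["visit"] = "retest"

    base_attrs = dict(cohort.attrs)
    cohort = cohort.copy()
    cohort.attrs = {}
    retest.attrs = {}
    out = pd.concat([cohort, retest], ignore_index=True)
    out.attrs = base_attrs
    return out
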