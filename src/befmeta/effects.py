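"""Effect-size construction: raw study summaries -> Fisher-z effects with variances.

Two study designs feed the synthesis:

* control-treatment studies (two groups) go through the standardized mean
  difference chain: Hedges' d -> correlation r -> Fisher z;
* gradient studies (>= 4 driver levels) yield a Pearson correlation between
  outcome means and driver concentrations, then Fisher z.

Sampling variance of z is 1/(n_eff - 3) with n_eff the total group sample size
(control-treatment) or the number of gradient levels. The alternative
log-response-ratio effect size used for sensitivity analyses is also provided,
as are the helper conversions (mass loss -> decay rate k, SD approximation from
the mean-SD relationship) that the raw records sometimes require.

Sign convention: a positive z always means "the response increases with the
driver level". Decomposition reported as proportion of mass *remaining* runs
opposite to decomposition rate, so those effects are sign-flipped (and flagged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intensity import CompoundLevel

__all__ = [
    "GroupStats",
    "GradientLevel",
    "ObservationRecord",
    "EffectSize",
    "EffectTableResult",
    "DegenerateInputError",
    "hedges_d",
    "d_to_r",
    "gradient_r",
    "fisher_z",
    "var_z",
    "mass_loss_to_k",
    "approximate_sd",
    "log_response_ratio",
    "build_effect_table",
    "effects_to_frame",
]

logger = logging.getLogger(__name__)

R_CLIP = 0.999  # |r| at or beyond this is clipped before atanh (logged, never raised)
SD_FLOOR = 1e-6  # floor for approximated standard deviations

DRIVERS = ("stressor", "nutrient")
DESIGNS = ("control_treatment", "gradient")
RESPONSES = ("diversity", "abundance", "decomposition")
DECOMPOSITION_METRICS = ("k_rate", "mass_loss", "mass_remaining", "not_applicable")


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically degenerate
    (zero pooled SD, constant gradient, ...); batch routines convert these into
    logged exclusions."""


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics of one group (control or treatment)."""

    mean: float
    sd: float | None
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group sample size must be >= 2, got {self.n}")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"group SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class GradientLevel:
    """One level of a gradient study: driver concentration and outcome mean."""

    concentration: float
    mean: float
    sd: float | None = None
    n: int | None = None


@dataclass
class ObservationRecord:
    """One extracted study observation with raw summary statistics.

    ``control``/``treatment`` are populated for control-treatment designs,
    ``levels`` for gradient designs (>= 4 levels). ``link_key`` ties
    biodiversity/abundance observations to the decomposition measurement made
    on the same experimental unit (e.g. the same litterbag). ``time`` is the
    measurement time (days) for decomposition records; when a record is
    reported at several time points (same ``obs_id``), only the last one is
    retained to capture the long-term response.
    """

    obs_id: str
    case_study_id: str
    publication_id: str
    driver: str
    design: str
    response: str
    link_key: str
    study_type: str = "experimental"
    taxon_group: str = "not_applicable"
    diversity_metric: str = "not_applicable"
    control: GroupStats | None = None
    treatment: GroupStats | None = None
    levels: list[GradientLevel] | None = None
    decomposition_metric: str = "not_applicable"
    time: float | None = None
    compound_levels: list[CompoundLevel] = field(default_factory=list)
    sd_approximated: bool = False

    def __post_init__(self) -> None:
        if self.driver not in DRIVERS:
            raise ValueError(f"driver must be one of {DRIVERS}, got {self.driver!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}, got {self.response!r}")
        if self.decomposition_metric not in DECOMPOSITION_METRICS:
            raise ValueError(
                f"decomposition_metric must be one of {DECOMPOSITION_METRICS}"
            )
        if self.design == "control_treatment":
            if self.control is None or self.treatment is None:
                raise ValueError(
                    f"{self.obs_id}: control-treatment records need exactly "
                    "two groups (control and treatment)"
                )
        else:
            if self.levels is None or len(self.levels) < 4:
                raise ValueError(
                    f"{self.obs_id}: gradient records need four or more levels"
                )


@dataclass
class EffectSize:
    """A Fisher-z (or lnRR) effect with its sampling variance and provenance."""

    obs_id: str
    case_study_id: str
    publication_id: str
    driver: str
    response: str
    link_key: str
    z: float
    var_z: float
    n_eff: int
    method: str  # hedges_chain | gradient_pearson | lnRR
    study_type: str = "experimental"
    taxon_group: str = "not_applicable"
    diversity_metric: str = "not_applicable"
    sd_approximated: bool = False
    direction_flipped: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.z):
            raise ValueError(f"{self.obs_id}: non-finite effect size")
        if not self.var_z > 0:
            raise ValueError(f"{self.obs_id}: sampling variance must be > 0")
        if self.method != "lnRR" and self.n_eff < 4:
            raise ValueError(f"{self.obs_id}: n_eff must be >= 4, got {self.n_eff}")


@dataclass
class EffectTableResult:
    """Output of :func:`build_effect_table`: effects plus an exclusion log."""

    effects: list[EffectSize]
    exclusions: list[dict]

    def frame(self) -> pd.DataFrame:
        return effects_to_frame(self.effects)


# ---------------------------------------------------------------------------
# elementary conversions


def hedges_d(
    mean_t: float,
    sd_t: float,
    n_t: int,
    mean_c: float,
    sd_c: float,
    n_c: int,
) -> tuple[float, float]:
    """Small-sample-corrected standardized mean difference and its variance.

    d = J * (mean_t - mean_c) / s_pooled, with J = 1 - 3/(4(n_t+n_c-2)-1);
    var(d) = (n_t+n_c)/(n_t*n_c) + d^2/(2(n_t+n_c)).
    """
    if n_t < 2 or n_c < 2:
        raise ValueError("both groups need n >= 2")
    if sd_t < 0 or sd_c < 0:
        raise ValueError("SDs must be >= 0")
    df = n_t + n_c - 2
    s_pooled = math.sqrt(((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / df)
    if s_pooled <= 0:
        raise DegenerateInputError("pooled SD is zero; d is undefined")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = j * (mean_t - mean_c) / s_pooled
    var_d = (n_t + n_c) / (n_t * n_c) + d**2 / (2.0 * (n_t + n_c))
    return d, var_d


def d_to_r(d: float, n_t: int, n_c: int) -> float:
    """Convert a standardized mean difference to a correlation coefficient.

    r = d / sqrt(d^2 + a) with a = (n_t+n_c)^2 / (n_t*n_c); |r| < 1 always.
    """
    if n_t < 2 or n_c < 2:
        raise ValueError("both groups need n >= 2")
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    a = (n_t + n_c) ** 2 / (n_t * n_c)
    return d / math.sqrt(d**2 + a)


def gradient_r(levels: list[float], means: list[float]) -> float:
    """Pearson correlation between outcome means and driver concentrations."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(means, dtype=float)
    if x.size != y.size:
        raise ValueError("levels and means must have equal length")
    if x.size < 4:
        raise ValueError("gradient studies need four or more paired points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant driver levels; correlation undefined")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant outcome means; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r); odd in r.

    |r| >= R_CLIP is clipped to +-R_CLIP with a logged warning rather than
    raising: four collinear gradient points legitimately produce |r| = 1.
    """
    if abs(r) >= R_CLIP:
        logger.warning("correlation %.6g clipped to +-%.3f before atanh", r, R_CLIP)
        r = math.copysign(R_CLIP, r)
    return math.atanh(r)


def var_z(n_eff: int) -> float:
    """Sampling variance of a Fisher-z correlation: 1/(n_eff - 3)."""
    if n_eff < 4:
        raise ValueError(f"n_eff must be >= 4, got {n_eff}")
    return 1.0 / (n_eff - 3)


def mass_loss_to_k(fraction_remaining: float, time: float) -> float:
    """Exponential-decay rate from the proportion of litter mass remaining."""
    if not 0 < fraction_remaining <= 1:
        raise ValueError(
            f"fraction remaining must be in (0, 1], got {fraction_remaining}"
        )
    if time <= 0:
        raise ValueError(f"time must be > 0, got {time}")
    return -math.log(fraction_remaining) / time


def approximate_sd(
    target_means: list[float], known_pairs: list[tuple[float, float]]
) -> list[float]:
    """Predict missing SDs from the linear mean-SD relationship.

    Fits sd = a + b*mean by ordinary least squares over the known (mean, sd)
    pairs of the same analysis dataset and predicts the missing SDs, floored
    at a small positive constant. Requires >= 3 known pairs with variance in
    the means; callers should exclude the record otherwise.
    """
    if len(known_pairs) < 3:
        raise ValueError(
            "SD approximation needs at least 3 known (mean, sd) pairs; "
            "exclude the record"
        )
    m = np.array([p[0] for p in known_pairs], dtype=float)
    s = np.array([p[1] for p in known_pairs], dtype=float)
    if np.ptp(m) == 0:
        raise ValueError("known means are constant; mean-SD slope is undefined")
    b, a = np.polyfit(m, s, 1)
    pred = a + b * np.asarray(target_means, dtype=float)
    return [float(max(p, SD_FLOOR)) for p in pred]


def log_response_ratio(
    mean_t: float,
    sd_t: float,
    n_t: int,
    mean_c: float,
    sd_c: float,
    n_c: int,
) -> tuple[float, float]:
    """Log response ratio ln(mean_t/mean_c) and its delta-method variance."""
    if mean_t <= 0 or mean_c <= 0:
        raise DegenerateInputError("lnRR requires strictly positive means")
    lnrr = math.log(mean_t / mean_c)
    var = sd_t**2 / (n_t * mean_t**2) + sd_c**2 / (n_c * mean_c**2)
    if var <= 0:
        var = SD_FLOOR**2  # zero-SD groups: keep the record with a token variance
    return lnrr, var


# ---------------------------------------------------------------------------
# batch construction


def _keep_last_time_point(records: list[ObservationRecord]) -> list[ObservationRecord]:
    """When the same observation is reported at several times, keep the last."""
    best: dict[str, ObservationRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.obs_id not in best:
            best[rec.obs_id] = rec
            order.append(rec.obs_id)
        else:
            prev = best[rec.obs_id]
            t_new = rec.time if rec.time is not None else -math.inf
            t_old = prev.time if prev.time is not None else -math.inf
            if t_new > t_old:
                best[rec.obs_id] = rec
    return [best[k] for k in order]


def _decomposition_outcomes(rec: ObservationRecord, means, sds):
    """Convert decomposition outcomes where needed.

    Mass loss reported with a measurement time is converted to decay rates k
    via the exponential decay equation (SDs by the delta method). Proportion
    of mass remaining is left on its own scale; its effect is sign-flipped
    downstream. Returns (means, sds, flip_sign).
    """
    metric = rec.decomposition_metric
    if metric == "mass_loss" and rec.time is not None:
        new_means, new_sds = [], []
        for m, s in zip(means, sds):
            remaining = min(max(1.0 - m, 1e-6), 1.0)
            new_means.append(mass_loss_to_k(remaining, rec.time))
            if s is None:
                new_sds.append(None)
            else:
                # |dk/dm_loss| = 1 / ((1 - m_loss) * t)
                new_sds.append(s / (remaining * rec.time))
        return new_means, new_sds, False
    if metric == "mass_remaining":
        return means, sds, True
    return means, sds, False


def _record_effect(
    rec: ObservationRecord, effect_metric: str, sd_fits: dict
) -> EffectSize:
    flip = False
    sd_approx = rec.sd_approximated

    if rec.design == "control_treatment":
        c, t = rec.control, rec.treatment
        means = [c.mean, t.mean]
        sds = [c.sd, t.sd]
        if rec.response == "decomposition":
            means, sds, flip = _decomposition_outcomes(rec, means, sds)
        if any(s is None for s in sds):
            key = (rec.driver, rec.response)
            known = sd_fits.get(key, [])
            preds = approximate_sd(means, known)
            sds = [p if s is None else s for s, p in zip(sds, preds)]
            sd_approx = True
        n_t, n_c = t.n, c.n
        if effect_metric == "lnRR":
            lnrr, v = log_response_ratio(means[1], sds[1], n_t, means[0], sds[0], n_c)
            if flip:
                lnrr = -lnrr
            return _mk_effect(rec, lnrr, v, n_t + n_c, "lnRR", sd_approx, flip)
        d, _ = hedges_d(means[1], sds[1], n_t, means[0], sds[0], n_c)
        r = d_to_r(d, n_t, n_c)
        n_eff = n_t + n_c
    else:
        if effect_metric == "lnRR":
            raise DegenerateInputError(
                "log response ratios are undefined for gradient designs"
            )
        concs = [lv.concentration for lv in rec.levels]
        means = [lv.mean for lv in rec.levels]
        if rec.response == "decomposition":
            means, _, flip = _decomposition_outcomes(
                rec, means, [lv.sd for lv in rec.levels]
            )
        r = gradient_r(concs, means)
        n_eff = len(rec.levels)

    z = fisher_z(r)
    if flip:
        z = -z
    return _mk_effect(rec, z, var_z(n_eff), n_eff,
                      "hedges_chain" if rec.design == "control_treatment"
                      else "gradient_pearson",
                      sd_approx, flip)


def _mk_effect(rec, z, v, n_eff, method, sd_approx, flip) -> EffectSize:
    return EffectSize(
        obs_id=rec.obs_id,
        case_study_id=rec.case_study_id,
        publication_id=rec.publication_id,
        driver=rec.driver,
        response=rec.response,
        link_key=rec.link_key,
        z=z,
        var_z=v,
        n_eff=n_eff,
        method=method,
        study_type=rec.study_type,
        taxon_group=rec.taxon_group,
        diversity_metric=rec.diversity_metric,
        sd_approximated=sd_approx,
        direction_flipped=flip,
    )


def build_effect_table(
    records: list[ObservationRecord], effect_metric: str = "fisher_z"
) -> EffectTableResult:
    """Route every observation record through the appropriate effect-size chain.

    Control-treatment records: Hedges' d -> r -> Fisher z (n_eff = n_t + n_c);
    gradient records: Pearson r over levels -> Fisher z (n_eff = number of
    levels). Missing SDs are approximated from the mean-SD relationship fitted
    within the record's driver x response dataset. Records that cannot be
    processed are excluded with a logged reason; the batch never aborts.
    """
    if effect_metric not in ("fisher_z", "lnRR"):
        raise ValueError("effect_metric must be 'fisher_z' or 'lnRR'")
    records = _keep_last_time_point(records)

    # Known (mean, sd) pairs per driver x response, for SD approximation.
    sd_fits: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for rec in records:
        if rec.design != "control_treatment":
            continue
        for g in (rec.control, rec.treatment):
            if g.sd is not None:
                sd_fits.setdefault((rec.driver, rec.response), []).append(
                    (g.mean, g.sd)
                )

    effects: list[EffectSize] = []
    exclusions: list[dict] = []
    for rec in records:
        try:
            effects.append(_record_effect(rec, effect_metric, sd_fits))
        except (DegenerateInputError, ValueError) as exc:
            logger.info("excluding observation %s: %s", rec.obs_id, exc)
            exclusions.append({"obs_id": rec.obs_id, "reason": str(exc)})
    return EffectTableResult(effects=effects, exclusions=exclusions)


def effects_to_frame(effects: list[EffectSize]) -> pd.DataFrame:
    """Tidy effect-size table (one row per effect)."""
    cols = [
        "obs_id", "case_study_id", "publication_id", "driver", "response",
        "link_key", "z", "var_z", "n_eff", "method", "study_type",
        "taxon_group", "diversity_metric", "sd_approximated", "direction_flipped",
    ]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} for e in effects], columns=cols
    )
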