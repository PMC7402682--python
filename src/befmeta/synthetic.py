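"""Synthetic observation and effect-size tables with known ground truth.

The generator emulates the statistical skeleton of a cross-study synthesis of
environmental-change impacts on decomposer communities and litter
decomposition: case studies nest observations; each decomposition measurement
(a "link", e.g. one litterbag) is matched to one or more biodiversity or
abundance observations; each case study addresses one driver (chemical
stressor or nutrient enrichment) at a standardized intensity; moderators
(study type, taxonomic group, diversity metric) are sampled labels.

Generative model (per case study s with driver g):

    u_B[s], u_LD[s] ~ N(0, tau_study^2)            independent study intercepts
    per link l: I ~ U(intensity_range)             standardized intensity
        core_l  = beta_g * I + u_B[s] + N(0, sigma_obs^2)
        eta_l   ~ N(0, 1/(n_l - 3))                realized sampling deviation
        biodiversity obs j (duplicates of the link):
            zeta_j  = mu_{g,response_j} + core_l                (true effect)
            z_j     = zeta_j + eta_l + N(0, dup_jitter_sd^2)    (observed)
        decomposition:
            zeta_LD = path_direct * I + path_b * (core_l + eta_l)
                      + u_LD[s] + N(0, sigma_obs^2)
            z_LD    = zeta_LD + N(0, 1/(n_LD - 3))

A litterbag's biodiversity response is thus realized once; duplicate rows are
re-measurements of that realized value with small reporting jitter, and the
decomposition response is driven by the realized (observed-scale) value. This
makes the analysis model of :mod:`befmeta.meta` / :mod:`befmeta.sem` correctly
specified, so ground-truth recovery by the pipeline is well-defined (see
docs/methods.md for what this does and does not emulate about real data).

Moderator labels carry no effects by default: they exist to exercise the
moderator machinery and the d-separation claims under a known null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .effects import (
    GradientLevel,
    GroupStats,
    ObservationRecord,
    d_to_r,
    fisher_z,
    gradient_r,
    hedges_d,
)
from .intensity import CompoundLevel

__all__ = [
    "TruthConfig",
    "SyntheticDataset",
    "generate_effect_table",
    "generate_raw_studies",
    "apply_publication_bias",
]

# quality criteria used by the raw-study generator (synthetic stand-ins on the
# scale of real regulatory benchmarks; units noted per compound)
_COMPOUNDS = {
    "stressor": [("Cu", 1.0, "mg/kg"), ("Zn", 10.0, "mg/kg"), ("atrazine", 0.6, "ug/L")],
    "nutrient": [("N", 2.0, "mg/L"), ("P", 0.1, "mg/L")],
}

_OUTCOME_SCALES = {
    # response/metric -> (baseline mean, between-unit SD)
    "diversity": (10.0, 3.0),
    "abundance": (120.0, 40.0),
    "k_rate": (0.020, 0.006),
    "mass_loss": (0.50, 0.10),
    "mass_remaining": (0.50, 0.10),
}


def _check_probs(name: str, probs: dict) -> None:
    vals = list(probs.values())
    if any(p < 0 or p > 1 for p in vals) or abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must lie in [0,1] and sum to 1")


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth parameters of the generator.

    Defaults mirror the scale of the synthesized literature: ~69 case studies
    with ~660 biodiversity/abundance observations, two drivers, duplicated
    decomposition measurements, intensities spanning roughly two orders of
    magnitude below to three above the quality criteria, and small-sample
    studies (n between 4 and 30). Grand means and paths are on the Fisher-z
    scale.
    """

    n_studies: int = 69
    obs_per_study_range: tuple[int, int] = (4, 15)
    driver_mix: float = 0.5  # probability a study addresses a chemical stressor
    mu_diversity: dict = field(
        default_factory=lambda: {"stressor": -0.35, "nutrient": -0.10}
    )
    mu_abundance: dict = field(
        default_factory=lambda: {"stressor": -0.30, "nutrient": 0.10}
    )
    beta_intensity: dict = field(
        default_factory=lambda: {"stressor": -0.05, "nutrient": -0.15}
    )
    path_b: float = 0.42  # realized biodiversity effect -> decomposition effect
    path_direct: float = -0.05  # intensity -> decomposition, not via biodiversity
    tau_study: float = 0.2
    sigma_obs: float = 0.2
    n_obs_range: tuple[int, int] = (4, 30)
    dup_range: tuple[int, int] = (1, 4)
    dup_jitter_sd: float = 0.03
    response_mix: float = 0.3  # probability an observation reports diversity
    design_mix: float = 0.5  # probability a study is control-treatment (raw mode)
    moderator_probs: dict = field(
        default_factory=lambda: {
            "study_type": {"experimental": 0.5, "observational": 0.5},
            "taxon_group": {"animal": 0.7, "microbe": 0.3},
            "diversity_metric": {"richness": 0.7, "diversity_index": 0.3},
        }
    )
    intensity_range: tuple[float, float] = (-2.0, 3.0)
    missing_sd_rate: float = 0.1
    pub_bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        for name in ("tau_study", "sigma_obs", "dup_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("obs_per_study_range", "n_obs_range", "dup_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")
        if self.dup_range[0] < 1:
            raise ValueError("dup_range minimum must be >= 1")
        if self.n_obs_range[0] < 4:
            raise ValueError("n_obs_range minimum must be >= 4 (var_z needs n > 3)")
        if self.obs_per_study_range[0] < 1:
            raise ValueError("obs_per_study_range minimum must be >= 1")
        for name in ("driver_mix", "response_mix", "design_mix", "missing_sd_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pub_bias_strength < 0:
            raise ValueError("pub_bias_strength must be >= 0")
        for key in ("study_type", "taxon_group", "diversity_metric"):
            _check_probs(key, self.moderator_probs[key])
        if self.intensity_range[0] >= self.intensity_range[1]:
            raise ValueError("intensity_range must satisfy min < max")
        for driver in ("stressor", "nutrient"):
            for d in (self.mu_diversity, self.mu_abundance, self.beta_intensity):
                if driver not in d:
                    raise ValueError(f"missing driver {driver!r} in a truth mapping")


@dataclass
class SyntheticDataset:
    """A generated dataset: effect table and/or raw observation records.

    ``effects`` (a tidy frame matching the pipeline's effect schema plus
    ``intensity`` and ``true_z`` columns) is populated by
    :func:`generate_effect_table`; ``observations`` (raw summary-statistics
    records) by :func:`generate_raw_studies`. ``true_latent_effects`` maps
    obs_id to the true effect on the z scale.
    """

    truth: TruthConfig
    effects: pd.DataFrame | None = None
    observations: list[ObservationRecord] = field(default_factory=list)
    true_latent_effects: dict = field(default_factory=dict)


def _pick(rng: np.random.Generator, probs: dict) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=[probs[k] for k in keys])]


def _study_skeleton(cfg: TruthConfig, rng: np.random.Generator, s: int):
    sid = f"S{s + 1:03d}"
    pub = f"P{1 + s - s // 7:03d}"  # some publications contribute two case studies
    driver = "stressor" if rng.random() < cfg.driver_mix else "nutrient"
    study_type = _pick(rng, cfg.moderator_probs["study_type"])
    u_b = rng.normal(0.0, cfg.tau_study)
    u_ld = rng.normal(0.0, cfg.tau_study)
    n_target = int(rng.integers(cfg.obs_per_study_range[0], cfg.obs_per_study_range[1] + 1))
    return sid, pub, driver, study_type, u_b, u_ld, n_target


def _link_sizes(cfg: TruthConfig, rng: np.random.Generator, n_target: int) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < n_target:
        d = int(rng.integers(cfg.dup_range[0], cfg.dup_range[1] + 1))
        d = min(d, n_target - total)
        sizes.append(max(d, 1))
        total += sizes[-1]
    return sizes


def generate_effect_table(config: TruthConfig) -> SyntheticDataset:
    """Generate an effect-size table directly on the Fisher-z scale.

    Deterministic under a fixed ``config.seed``. Applies the configured
    publication-bias selection when ``config.pub_bias_strength > 0``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    true_z: dict[str, float] = {}
    for s in range(config.n_studies):
        sid, pub, driver, study_type, u_b, u_ld, n_target = _study_skeleton(
            config, rng, s
        )
        for li, dup in enumerate(_link_sizes(config, rng, n_target), start=1):
            link = f"{sid}_L{li}"
            inten = float(rng.uniform(*config.intensity_range))
            n_meas = int(rng.integers(config.n_obs_range[0], config.n_obs_range[1] + 1))
            v_b = 1.0 / (n_meas - 3)
            core = (
                config.beta_intensity[driver] * inten
                + u_b
                + rng.normal(0.0, config.sigma_obs)
            )
            eta = rng.normal(0.0, math.sqrt(v_b))

            n_ld = int(rng.integers(config.n_obs_range[0], config.n_obs_range[1] + 1))
            v_ld = 1.0 / (n_ld - 3)
            zeta_ld = (
                config.path_direct * inten
                + config.path_b * (core + eta)
                + u_ld
                + rng.normal(0.0, config.sigma_obs)
            )
            oid = f"{link}_LD"
            rows.append(
                {
                    "obs_id": oid,
                    "case_study_id": sid,
                    "publication_id": pub,
                    "driver": driver,
                    "response": "decomposition",
                    "link_key": link,
                    "z": zeta_ld + rng.normal(0.0, math.sqrt(v_ld)),
                    "var_z": v_ld,
                    "n_eff": n_ld,
                    "method": "simulated",
                    "study_type": study_type,
                    "taxon_group": "not_applicable",
                    "diversity_metric": "not_applicable",
                    "sd_approximated": False,
                    "direction_flipped": False,
                    "intensity": inten,
                    "true_z": zeta_ld,
                }
            )
            true_z[oid] = zeta_ld

            for j in range(dup):
                diversity = rng.random() < config.response_mix
                response = "diversity" if diversity else "abundance"
                mu = (config.mu_diversity if diversity else config.mu_abundance)[driver]
                zeta = mu + core
                oid = f"{link}_B{j + 1}"
                rows.append(
                    {
                        "obs_id": oid,
                        "case_study_id": sid,
                        "publication_id": pub,
                        "driver": driver,
                        "response": response,
                        "link_key": link,
                        "z": zeta + eta + rng.normal(0.0, config.dup_jitter_sd),
                        "var_z": v_b,
                        "n_eff": n_meas,
                        "method": "simulated",
                        "study_type": study_type,
                        "taxon_group": _pick(rng, config.moderator_probs["taxon_group"]),
                        "diversity_metric": (
                            _pick(rng, config.moderator_probs["diversity_metric"])
                            if diversity
                            else "not_applicable"
                        ),
                        "sd_approximated": False,
                        "direction_flipped": False,
                        "intensity": inten,
                        "true_z": zeta,
                    }
                )
                true_z[oid] = zeta
    dataset = SyntheticDataset(
        truth=config, effects=pd.DataFrame(rows), true_latent_effects=true_z
    )
    if config.pub_bias_strength > 0:
        dataset = apply_publication_bias(
            dataset, config.pub_bias_strength, seed=config.seed + 1
        )
    return dataset


# ---------------------------------------------------------------------------
# raw-study generator


def _sample_group(rng, mean: float, sd: float, n: int) -> GroupStats:
    m = float(rng.normal(mean, sd / math.sqrt(n)))
    s = float(sd * math.sqrt(rng.chisquare(n - 1) / (n - 1)))
    return GroupStats(mean=m, sd=max(s, 1e-9), n=n)


def _compounds_for(cfg, rng, driver: str, inten: float) -> list[CompoundLevel]:
    pool = _COMPOUNDS[driver]
    idx = int(rng.integers(len(pool)))
    name, crit, units = pool[idx]
    levels = [
        CompoundLevel(
            compound=name,
            conc_treatment=crit * 10.0**inten,
            conc_criteria=crit,
            criteria_source="ECHA" if driver == "stressor" else "WFD",
            units=units,
        )
    ]
    if rng.random() < 0.3 and len(pool) > 1:  # a secondary, weaker compound
        jdx = (idx + 1) % len(pool)
        name2, crit2, units2 = pool[jdx]
        levels.append(
            CompoundLevel(
                compound=name2,
                conc_treatment=crit2 * 10.0 ** (inten - abs(rng.exponential(0.8)) - 0.05),
                conc_criteria=crit2,
                criteria_source="USEPA" if driver == "stressor" else "WFD",
                units=units2,
            )
        )
    return levels


def _ct_record(cfg, rng, base, response, metric, target_z, n, time=None):
    """A control-treatment record whose population effect equals target_z."""
    r = math.tanh(target_z)
    delta = 2.0 * r / math.sqrt(max(1.0 - r * r, 1e-9))
    scale_key = metric if response == "decomposition" else response
    mean0, sd0 = _OUTCOME_SCALES[scale_key]
    sign = -1.0 if metric == "mass_remaining" else 1.0
    mean_t = mean0 + sign * delta * sd0
    control = _sample_group(rng, mean0, sd0, n)
    treatment = _sample_group(rng, mean_t, sd0, n)
    if response == "decomposition" and metric in ("mass_loss", "mass_remaining"):
        control = GroupStats(min(max(control.mean, 0.02), 0.98), control.sd, control.n)
        treatment = GroupStats(
            min(max(treatment.mean, 0.02), 0.98), treatment.sd, treatment.n
        )
    rec = dict(control=control, treatment=treatment, design="control_treatment")
    if rng.random() < cfg.missing_sd_rate:
        rec["control"] = GroupStats(control.mean, None, control.n)
        rec["treatment"] = GroupStats(treatment.mean, None, treatment.n)
        rec["flag_missing_sd"] = True
    return rec


def _gradient_record(cfg, rng, response, metric, target_z, inten, crit_level):
    """A gradient record whose population correlation equals tanh(target_z)."""
    r = math.tanh(target_z)
    L = int(rng.integers(4, 9))
    conc_max = crit_level * 10.0**inten
    # levels log-spaced over 1.5 orders of magnitude up to the maximum
    concs = [conc_max * 10.0 ** (-1.5 * (L - 1 - i) / (L - 1)) for i in range(L)]
    x = np.log10(concs)
    xs = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    scale_key = metric if response == "decomposition" else response
    mean0, sd0 = _OUTCOME_SCALES[scale_key]
    sign = -1.0 if metric == "mass_remaining" else 1.0
    noise = rng.normal(0.0, 1.0, L)
    ystd = sign * r * xs + math.sqrt(max(1.0 - r * r, 0.0)) * noise
    means = mean0 + sd0 * ystd
    if response == "decomposition" and metric in ("mass_loss", "mass_remaining"):
        means = np.clip(means, 0.02, 0.98)
    levels = [
        GradientLevel(
            concentration=float(c),
            mean=float(m),
            sd=float(sd0 * math.sqrt(rng.chisquare(3) / 3)),
            n=int(rng.integers(3, 7)),
        )
        for c, m in zip(concs, means)
    ]
    return dict(levels=levels, design="gradient")


def _realized_z(parts: dict, fallback: float) -> float:
    """Observed-scale Fisher z implied by a generated record's summaries.

    Uses the same conversion chain the pipeline applies, so structural
    equations built on this value are consistent with the fitted model.
    Falls back to the latent target when the chain is unavailable (masked
    SDs, degenerate draws)."""
    try:
        if parts["design"] == "control_treatment":
            c, t = parts["control"], parts["treatment"]
            if c.sd is None or t.sd is None:
                return fallback
            d, _ = hedges_d(t.mean, t.sd, t.n, c.mean, c.sd, c.n)
            return fisher_z(d_to_r(d, t.n, c.n))
        levels = parts["levels"]
        return fisher_z(
            gradient_r([lv.concentration for lv in levels],
                       [lv.mean for lv in levels])
        )
    except (ValueError, ZeroDivisionError):
        return fallback


def generate_raw_studies(config: TruthConfig) -> SyntheticDataset:
    """Generate raw observation records (group summaries / gradient levels).

    Control-treatment records imply a target Hedges' d and gradient records a
    target Pearson correlation, both derived from the same latent effect model
    as :func:`generate_effect_table`; a ``missing_sd_rate`` fraction of
    control-treatment records omits SDs to exercise the SD approximation.
    Decomposition records use a mix of decay-rate, mass-loss and
    mass-remaining metrics, and a fraction of mass records is reported at two
    time points to exercise the keep-the-last-time-point rule.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ObservationRecord] = []
    true_z: dict[str, float] = {}
    for s in range(config.n_studies):
        sid, pub, driver, study_type, u_b, u_ld, n_target = _study_skeleton(
            config, rng, s
        )
        design_ct = rng.random() < config.design_mix
        for li, dup in enumerate(_link_sizes(config, rng, n_target), start=1):
            link = f"{sid}_L{li}"
            inten = float(rng.uniform(*config.intensity_range))
            compounds = _compounds_for(config, rng, driver, inten)
            crit_main = compounds[0].conc_criteria
            n_meas = int(rng.integers(config.n_obs_range[0], config.n_obs_range[1] + 1))
            core = (
                config.beta_intensity[driver] * inten
                + u_b
                + rng.normal(0.0, config.sigma_obs)
            )
            metric = ["k_rate", "mass_loss", "mass_remaining"][
                rng.choice(3, p=[0.6, 0.2, 0.2])
            ]
            common = dict(
                case_study_id=sid,
                publication_id=pub,
                driver=driver,
                link_key=link,
                study_type=study_type,
                compound_levels=compounds,
            )

            def emit(oid, response, metric_, target, time=None, taxon="not_applicable",
                     div_metric="not_applicable", weaker=1.0):
                if design_ct:
                    parts = _ct_record(
                        config, rng, None, response, metric_, target * weaker, n_meas
                    )
                else:
                    parts = _gradient_record(
                        config, rng, response, metric_, target * weaker, inten, crit_main
                    )
                parts.pop("flag_missing_sd", False)
                realized = _realized_z(parts, target * weaker)
                records.append(
                    ObservationRecord(
                        obs_id=oid,
                        response=response,
                        taxon_group=taxon,
                        diversity_metric=div_metric,
                        decomposition_metric=(
                            metric_ if response == "decomposition" else "not_applicable"
                        ),
                        time=time,
                        **parts,
                        **common,
                    )
                )
                return realized

            realized_b, mu_shifts = [], []
            for j in range(dup):
                diversity = rng.random() < config.response_mix
                response = "diversity" if diversity else "abundance"
                mu = (config.mu_diversity if diversity else config.mu_abundance)[driver]
                zeta = mu + core
                oid = f"{link}_B{j + 1}"
                true_z[oid] = zeta
                mu_shifts.append(mu)
                realized_b.append(
                    emit(
                        oid,
                        response,
                        "not_applicable",
                        zeta,
                        taxon=_pick(rng, config.moderator_probs["taxon_group"]),
                        div_metric=(
                            _pick(rng, config.moderator_probs["diversity_metric"])
                            if diversity
                            else "not_applicable"
                        ),
                    )
                )

            # decomposition responds to the realized biodiversity signal of
            # the link (mean of the duplicates' observed-scale effects, net
            # of the response-specific grand means), keeping the fitted
            # regression consistent for path_b on data built from summaries
            b_signal = float(np.mean(realized_b)) - float(np.mean(mu_shifts))
            zeta_ld = (
                config.path_direct * inten
                + config.path_b * b_signal
                + u_ld
                + rng.normal(0.0, config.sigma_obs)
            )
            oid = f"{link}_LD"
            true_z[oid] = zeta_ld
            if metric != "k_rate" and rng.random() < 0.15:
                # an earlier, weaker time point for the same observation
                emit(oid, "decomposition", metric, zeta_ld, time=30.0, weaker=0.5)
            emit(
                oid,
                "decomposition",
                metric,
                zeta_ld,
                time=60.0 if metric != "k_rate" else None,
            )
    return SyntheticDataset(
        truth=config, observations=records, true_latent_effects=true_z
    )


# ---------------------------------------------------------------------------
# publication-bias selection


def apply_publication_bias(
    dataset: SyntheticDataset, strength: float, seed: int
) -> SyntheticDataset:
    """Thin a dataset by significance-dependent selection.

    Each effect row is retained with probability expit(strength * (t - 1))
    where t = z/SE is the one-sided test statistic: clearly "significant"
    positive effects are almost always kept, null and negative ones are
    suppressed as ``strength`` grows. ``strength = 0`` is the identity.
    Decomposition rows left without any matched biodiversity row are dropped
    to preserve the linkage invariant.
    """
    if strength < 0:
        raise ValueError("selection strength must be >= 0")
    if dataset.effects is None:
        raise ValueError(
            "apply_publication_bias requires a dataset with realized effect sizes "
            "(run generate_effect_table, or build effects from the raw records first)"
        )
    if strength == 0:
        return replace(dataset)
    rng = np.random.default_rng(seed)
    eff = dataset.effects
    t = eff["z"].to_numpy() / np.sqrt(eff["var_z"].to_numpy())
    keep = rng.random(len(eff)) < expit(strength * (t - 1.0))
    kept = eff[keep]
    bio_links = set(kept.loc[kept["response"] != "decomposition", "link_key"])
    orphan = (kept["response"] == "decomposition") & ~kept["link_key"].isin(bio_links)
    kept = kept[~orphan].reset_index(drop=True)
    ids = set(kept["obs_id"])
    return SyntheticDataset(
        truth=dataset.truth,
        effects=kept,
        observations=[r for r in dataset.observations if r.obs_id in ids],
        true_latent_effects={
            k: v for k, v in dataset.true_latent_effects.items() if k in ids
        },
    )
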