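"""Orchestration of the full synthesis: effects -> intensity -> meta -> SEM.

`run_all` executes the analysis chain on an observation table (read from CSV
or generated synthetically): effect-size construction, intensity
standardization, first-level meta-analyses of the overall driver effects with
publication-bias diagnostics, the four mediation SEMs (stressor/nutrient x
diversity/abundance), second-level moderator and intensity meta-regressions,
and the sensitivity reruns (dropping approximated SDs, dropping extreme
effects, log-response-ratio effect sizes). All tables are written as CSV plus
one structured run-metadata file; every excluded record appears in the
exclusion log with its reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as befio
from .effects import build_effect_table
from .intensity import max_intensity
from .meta import MetaSpec, egger_test, fit_meta, grand_means, wald_qm
from .sem import mediation_analysis, pair_effects
from .synthetic import TruthConfig, generate_effect_table, generate_raw_studies

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "split_datasets",
    "flag_extremes",
    "attach_intensity",
    "run_all",
]

logger = logging.getLogger(__name__)

MIN_SEM_LINKS = 8
MIN_SEM_STUDIES = 3


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    When ``input_path`` is None a synthetic dataset is generated from
    ``truth`` (``simulate_mode`` "effects" draws Fisher-z effects directly;
    "raw" draws group summaries and exercises the effect-size chain).
    ``log_base`` is the base of the intensity standardization; ``iterations``
    the number of SEM resampling iterations.
    """

    input_path: str | None = None
    effect_metric: str = "fisher_z"
    log_base: float = 10.0
    iterations: int = 1000
    seed: int = 0
    drop_approx_sd: bool = False
    drop_extremes: bool = False
    lnRR_rerun: bool = False
    sem_in_sensitivity: bool = False
    fig4_weighting: str = "simple"  # or "inverse_variance"
    simulate_mode: str = "effects"
    truth: TruthConfig | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.effect_metric not in ("fisher_z", "lnRR"):
            raise ValueError("effect_metric must be 'fisher_z' or 'lnRR'")
        if self.simulate_mode not in ("effects", "raw"):
            raise ValueError("simulate_mode must be 'effects' or 'raw'")
        if self.fig4_weighting not in ("simple", "inverse_variance"):
            raise ValueError("fig4_weighting must be 'simple' or 'inverse_variance'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "truth" in data and data["truth"] is not None:
            data["truth"] = TruthConfig(**data["truth"])
        return cls(**data)


@dataclass
class AnalysisReport:
    """All tables produced by one run, plus run metadata."""

    effects: pd.DataFrame
    grand_means: pd.DataFrame
    egger: pd.DataFrame
    sem_paths: pd.DataFrame
    sem_fit: pd.DataFrame
    mediation: pd.DataFrame
    moderators: pd.DataFrame
    fig4_regressions: pd.DataFrame
    sensitivity: dict = field(default_factory=dict)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)


def flag_extremes(values) -> np.ndarray:
    """Boxplot-whisker outlier flags.

    True where a value lies below Q1 - 1.5 IQR or above Q3 + 1.5 IQR, with
    quartiles by linear interpolation. Fewer than 4 values: nothing is
    flagged (a warning is logged)."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        logger.warning("flag_extremes needs >= 4 values; flagging none")
        return np.zeros(x.size, dtype=bool)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def attach_intensity(frame: pd.DataFrame, records=None, log_base: float = 10.0
                     ) -> pd.DataFrame:
    """Join the standardized driver intensity onto an effect table.

    With raw ``records``, the intensity is the maximum standardized intensity
    across each record's compounds; synthetic effect tables already carry an
    ``intensity`` column and are returned as-is.
    """
    if "intensity" in frame.columns:
        return frame
    if records is None:
        raise ValueError("no intensity column and no raw records to derive it from")
    values = {}
    for rec in records:
        if rec.compound_levels:
            values[rec.obs_id] = max_intensity(rec.compound_levels, base=log_base)[0]
    out = frame.copy()
    out["intensity"] = out["obs_id"].map(values)
    return out


def split_datasets(frame: pd.DataFrame) -> dict:
    """Partition the effect table into the four SEM analysis datasets.

    Keys are (driver, response_family) with family in {diversity, abundance};
    each value holds the biodiversity effects of that family plus the paired
    effects joining them to their decomposition measurements. Decomposition
    effects without any partner are logged and retained for the grand-mean
    analyses only.
    """
    out = {}
    for driver in ("stressor", "nutrient"):
        sub = frame[frame["driver"] == driver]
        for family in ("diversity", "abundance"):
            bio = sub[sub["response"] == family]
            pairs = pair_effects(sub, response_family=family) if not bio.empty else []
            out[(driver, family)] = {"effects": bio, "pairs": pairs}
    dec = frame[frame["response"] == "decomposition"]
    partnered = set(frame.loc[frame["response"] != "decomposition", "link_key"])
    orphans = dec[~dec["link_key"].isin(partnered)]
    if not orphans.empty:
        logger.info(
            "%d decomposition effects have no biodiversity partner; "
            "kept for grand means only", len(orphans)
        )
    return out


def _first_level(frame: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grand mean effects per response with driver as moderator, plus Egger tests."""
    gm_rows, egger_rows = [], []
    for response in ("diversity", "abundance", "decomposition"):
        sub = frame[frame["response"] == response]
        if len(sub) < 4 or sub["case_study_id"].nunique() < 2:
            continue
        mods = ("driver",) if sub["driver"].nunique() > 1 else ()
        fit = fit_meta(
            sub,
            MetaSpec(outcome="z", variance_column="var_z", moderators=mods,
                     random=("study",)),
        )
        if mods:
            gm = grand_means(fit, "driver")
        else:
            ci = 1.959963984540054 * fit.se["intercept"]
            est = fit.coefficients["intercept"]
            from scipy import stats as _st
            p = 2 * _st.norm.sf(abs(est) / fit.se["intercept"])
            gm = pd.DataFrame(
                [{"group": sub["driver"].iloc[0], "estimate": est,
                  "se": fit.se["intercept"], "ci_low": est - ci,
                  "ci_high": est + ci, "p": p,
                  "signif": "*" if p < 0.05 else ""}]
            )
        gm.insert(0, "response", response)
        gm["tau2_study"] = fit.sigma2.get("study", np.nan)
        gm["QM"] = fit.QM
        gm["QM_p"] = fit.QM_p
        gm["k_studies"] = sub["case_study_id"].nunique()
        gm["k_obs"] = len(sub)
        gm_rows.append(gm)
        for driver, dsub in sub.groupby("driver"):
            try:
                er = egger_test(dsub)
                egger_rows.append(
                    {"response": response, "driver": driver,
                     "intercept": er.intercept, "se": er.se, "t": er.t,
                     "p": er.p, "k": er.k}
                )
            except ValueError as exc:
                egger_rows.append(
                    {"response": response, "driver": driver,
                     "intercept": np.nan, "se": np.nan, "t": np.nan,
                     "p": np.nan, "k": len(dsub), "note": str(exc)}
                )
    gm_frame = (pd.concat(gm_rows, ignore_index=True)
                if gm_rows else pd.DataFrame())
    return gm_frame, pd.DataFrame(egger_rows)


def _second_level(datasets: dict, frame: pd.DataFrame, cfg: PipelineConfig):
    """Moderator and intensity meta-regressions on the univariate datasets."""
    mod_rows, fig4_rows = [], []
    for (driver, family), ds in datasets.items():
        bio = ds["effects"]
        if len(bio) < 6 or bio["case_study_id"].nunique() < 2:
            continue
        candidates = [("intensity", "intensity")]
        for term in ("taxon_group", "study_type", "diversity_metric"):
            if term == "diversity_metric" and family != "diversity":
                continue
            if bio[term].nunique() > 1:
                candidates.append((term, term))
        for label, term in candidates:
            if term == "intensity" and bio["intensity"].isna().any():
                continue
            try:
                fit = fit_meta(
                    bio,
                    MetaSpec(outcome="z", variance_column="var_z",
                             moderators=(term,),
                             random=("study", "observation")),
                )
                qm, df, p = wald_qm(fit, term)
            except (ValueError, RuntimeError) as exc:
                logger.info("moderator %s skipped for %s-%s: %s",
                            term, driver, family, exc)
                continue
            row = {
                "driver": driver, "family": family, "moderator": label,
                "QM": qm, "df": df, "p": p,
                "k_studies": bio["case_study_id"].nunique(), "k_obs": len(bio),
                "intensity_log_base": cfg.log_base,
            }
            for name in fit.term_map[term]:
                row[f"coef[{name}]"] = fit.coefficients[name]
                row[f"se[{name}]"] = fit.se[name]
            mod_rows.append(row)

        # decomposition-vs-biodiversity meta-regression (one point per unique
        # decomposition measurement; duplicated biodiversity effects averaged)
        pairs = ds["pairs"]
        if len(pairs) >= 6:
            rows = []
            for p_ in pairs:
                zb = np.array([b["z"] for b in p_.biodiversity])
                if cfg.fig4_weighting == "inverse_variance":
                    w = 1.0 / np.array([b["var_z"] for b in p_.biodiversity])
                    mean_zb = float(np.sum(w * zb) / np.sum(w))
                else:
                    mean_zb = float(zb.mean())
                rows.append(
                    {"z": p_.decomposition["z"], "var_z": p_.decomposition["var_z"],
                     "mean_zb": mean_zb, "case_study_id": p_.case_study_id}
                )
            tab = pd.DataFrame(rows)
            if tab["case_study_id"].nunique() >= 2:
                try:
                    fit = fit_meta(
                        tab,
                        MetaSpec(outcome="z", variance_column="var_z",
                                 moderators=("mean_zb",), random=("study",)),
                    )
                    qm, df, p = wald_qm(fit, "mean_zb")
                    fig4_rows.append(
                        {"driver": driver, "family": family,
                         "slope": fit.coefficients["mean_zb"],
                         "se": fit.se["mean_zb"],
                         "intercept": fit.coefficients["intercept"],
                         "QM": qm, "p": p,
                         "k_studies": tab["case_study_id"].nunique(),
                         "k_obs": len(tab),
                         "weighting": cfg.fig4_weighting}
                    )
                except (ValueError, RuntimeError) as exc:
                    logger.info("between-effect regression skipped for %s-%s: %s",
                                driver, family, exc)

    # decomposition response vs intensity, per driver
    for driver in ("stressor", "nutrient"):
        dec = frame[(frame["driver"] == driver)
                    & (frame["response"] == "decomposition")]
        dec = dec.drop_duplicates(subset="link_key")
        if len(dec) < 6 or dec["intensity"].isna().any():
            continue
        try:
            fit = fit_meta(
                dec,
                MetaSpec(outcome="z", variance_column="var_z",
                         moderators=("intensity",), random=("study",)),
            )
            qm, df, p = wald_qm(fit, "intensity")
            mod_rows.append(
                {"driver": driver, "family": "decomposition",
                 "moderator": "intensity", "QM": qm, "df": df, "p": p,
                 "k_studies": dec["case_study_id"].nunique(), "k_obs": len(dec),
                 "intensity_log_base": cfg.log_base,
                 "coef[intensity]": fit.coefficients["intensity"],
                 "se[intensity]": fit.se["intensity"]}
            )
        except (ValueError, RuntimeError) as exc:
            logger.info("decomposition intensity regression skipped for %s: %s",
                        driver, exc)
    return pd.DataFrame(mod_rows), pd.DataFrame(fig4_rows)


def _sems(datasets: dict, cfg: PipelineConfig):
    path_rows, fit_rows, med_rows = [], [], []
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {key: int(s.generate_state(1)[0] % (2**31))
             for key, s in zip(sorted(datasets), ss.spawn(len(datasets)))}
    for key in sorted(datasets):
        driver, family = key
        pairs = datasets[key]["pairs"]
        n_studies = len({p.case_study_id for p in pairs})
        if len(pairs) < MIN_SEM_LINKS or n_studies < MIN_SEM_STUDIES:
            logger.info("SEM skipped for %s-%s: %d links / %d studies",
                        driver, family, len(pairs), n_studies)
            continue
        full, reduced, report = mediation_analysis(
            pairs, dataset_kind=family, iterations=cfg.iterations,
            seed=seeds[key],
        )
        for _, row in full.paths.iterrows():
            path_rows.append({"driver": driver, "family": family, **row.to_dict()})
        fit_rows.append(
            {"driver": driver, "family": family, "fisher_C": full.fisher_C,
             "C_df": full.C_df, "C_p": full.C_p, "AIC": full.AIC,
             "n_links": len(pairs), "n_studies": n_studies,
             "iterations": full.n_iterations, "failed": full.n_failed,
             "seed": full.seed}
        )
        med_rows.append(
            {"driver": driver, "family": family,
             "supported": report.supported, "reduced_C_p": report.reduced_C_p,
             "delta_AIC_reduced_minus_full": report.delta_AIC,
             "AIC_full": report.AIC_full, "AIC_reduced": report.AIC_reduced,
             "criterion_conflict": report.criterion_conflict,
             "indirect_effect": report.indirect_effect,
             "direct_effect": report.direct_effect}
        )
    return (pd.DataFrame(path_rows), pd.DataFrame(fit_rows), pd.DataFrame(med_rows))


def _drop_extreme_effects(frame: pd.DataFrame) -> pd.DataFrame:
    keep = np.ones(len(frame), dtype=bool)
    for (_d, _r), idx in frame.groupby(["driver", "response"]).groups.items():
        loc = frame.index.get_indexer(idx)
        keep[loc] = ~flag_extremes(frame.loc[idx, "z"].to_numpy())
    return frame[keep]


def run_all(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis chain and (optionally) write all outputs."""
    records = None
    exclusions: list[dict] = []
    truth = config.truth

    if config.input_path is not None:
        records = befio.read_observations_csv(config.input_path)
    elif config.simulate_mode == "raw":
        truth = truth or TruthConfig(seed=config.seed)
        records = generate_raw_studies(truth).observations

    if records is not None:
        table = build_effect_table(records, effect_metric=config.effect_metric)
        exclusions.extend(table.exclusions)
        frame = table.frame()
        frame = attach_intensity(frame, records, log_base=config.log_base)
    else:
        truth = truth or TruthConfig(seed=config.seed)
        frame = generate_effect_table(truth).effects

    if config.drop_extremes:
        before = set(frame["obs_id"])
        frame = _drop_extreme_effects(frame)
        for oid in sorted(before - set(frame["obs_id"])):
            exclusions.append({"obs_id": oid, "reason": "extreme effect size"})
    if config.drop_approx_sd and "sd_approximated" in frame.columns:
        dropped = frame[frame["sd_approximated"].astype(bool)]
        for oid in dropped["obs_id"]:
            exclusions.append({"obs_id": oid, "reason": "approximated SD"})
        frame = frame[~frame["sd_approximated"].astype(bool)]

    grand, egger = _first_level(frame, config.seed)
    datasets = split_datasets(frame)
    moderators, fig4 = _second_level(datasets, frame, config)
    sem_paths, sem_fit, mediation = _sems(datasets, config)

    sensitivity: dict[str, pd.DataFrame] = {}
    if config.lnRR_rerun:
        if records is None:
            logger.warning("lnRR rerun requires raw records; skipped")
        else:
            lnrr = build_effect_table(records, effect_metric="lnRR")
            exclusions.extend(
                {**e, "reason": f"lnRR: {e['reason']}"} for e in lnrr.exclusions
            )
            lframe = attach_intensity(lnrr.frame(), records,
                                      log_base=config.log_base)
            g2, e2 = _first_level(lframe, config.seed)
            sensitivity["lnRR_grand_means"] = g2
            sensitivity["lnRR_egger"] = e2

    cfg_dict = dataclasses.asdict(config)
    if cfg_dict.get("truth") is not None:
        cfg_dict["truth"] = {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in cfg_dict["truth"].items()}
    cfg_hash = hashlib.md5(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    metadata = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "intensity_log_base": config.log_base,
        "effect_metric": config.effect_metric,
        "n_effects": int(len(frame)),
        "n_studies": int(frame["case_study_id"].nunique()),
        "n_exclusions": len(exclusions),
    }
    report = AnalysisReport(
        effects=frame.reset_index(drop=True),
        grand_means=grand,
        egger=egger,
        sem_paths=sem_paths,
        sem_fit=sem_fit,
        mediation=mediation,
        moderators=moderators,
        fig4_regressions=fig4,
        sensitivity=sensitivity,
        exclusions=pd.DataFrame(exclusions, columns=["obs_id", "reason"]),
        metadata=metadata,
    )
    if config.output_dir is not None:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "effects.csv": report.effects,
        "grand_means.csv": report.grand_means,
        "egger.csv": report.egger,
        "sem_paths.csv": report.sem_paths,
        "sem_fit.csv": report.sem_fit,
        "mediation.csv": report.mediation,
        "moderators.csv": report.moderators,
        "fig4_regressions.csv": report.fig4_regressions,
        "exclusions.csv": report.exclusions,
    }
    for name, frame in report.sensitivity.items():
        tables[f"sensitivity_{name}.csv"] = frame
    for name, frame in tables.items():
        frame.to_csv(outdir / name, index=False)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(report.metadata, fh, indent=2, default=str, sort_keys=True)
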