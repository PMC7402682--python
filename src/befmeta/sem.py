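"""Piecewise structural equation modelling over paired effect sizes.

The SEM links the standardized driver intensity, the effect of the driver on
decomposer biodiversity/abundance (zB) and its effect on litter decomposition
(zLD) through two weighted mixed sub-models with nested random intercepts
(case study / observation) and known sampling variances:

    zLD ~ zB + intensity + study_type
    zB  ~ intensity + study_type + taxon_group (+ diversity_metric)

Because one decomposition measurement is often matched to several biodiversity
observations (different taxa in the same litterbag), the SEM is fitted on
stratified resamples: at each iteration one biodiversity effect per
decomposition measurement is drawn uniformly, the sub-models are refitted, and
coefficients, SEs, Fisher's C and AICs are averaged across iterations.

Global fit is judged by directed-separation tests: each edge missing from the
model graph implies a conditional-independence claim, tested by the Wald
p-value of the omitted predictor added to the child's sub-model; Fisher's
C = -2 sum(ln p) is chi-square with 2k df under the model. The mediation test
compares the full graph with the graph lacking the zB -> zLD edge: the
biodiversity path is supported when the reduced model fits poorly
(p(C) < 0.05) and is not better by more than 2 AIC units.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .meta import MetaFit, MetaSpec, _Likelihood, _optimize_components, fit_meta

__all__ = [
    "PairedEffect",
    "SEMResult",
    "MediationReport",
    "pair_effects",
    "full_dag",
    "reduced_dag",
    "basis_set",
    "fishers_c",
    "stratified_resample",
    "fit_submodels",
    "run_resampled_sem",
    "mediation_analysis",
    "mediation_test",
    "standardize_path",
    "indirect_effect",
]

logger = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.10


@dataclass
class PairedEffect:
    """A decomposition effect matched to its candidate biodiversity effects."""

    link_key: str
    decomposition: dict  # obs_id, z, var_z
    biodiversity: list  # dicts: obs_id, z, var_z, taxon_group, diversity_metric
    intensity: float
    case_study_id: str
    driver: str
    study_type: str

    def __post_init__(self) -> None:
        if not self.biodiversity:
            raise ValueError(f"{self.link_key}: needs >= 1 biodiversity effect")


def pair_effects(frame: pd.DataFrame, response_family: str | None = None) -> list[PairedEffect]:
    """Build paired effects from a tidy effect table with an ``intensity`` column.

    ``response_family`` restricts the biodiversity candidates to "diversity" or
    "abundance"; decomposition measurements without any candidate of that
    family are dropped (they remain available to the grand-mean analyses).
    """
    pairs: list[PairedEffect] = []
    for link, grp in frame.groupby("link_key", sort=True):
        dec = grp[grp["response"] == "decomposition"]
        bio = grp[grp["response"] != "decomposition"]
        if response_family is not None:
            bio = bio[bio["response"] == response_family]
        if dec.empty or bio.empty:
            continue
        d = dec.iloc[0]
        pairs.append(
            PairedEffect(
                link_key=link,
                decomposition={"obs_id": d["obs_id"], "z": float(d["z"]),
                               "var_z": float(d["var_z"])},
                biodiversity=[
                    {
                        "obs_id": b["obs_id"],
                        "z": float(b["z"]),
                        "var_z": float(b["var_z"]),
                        "taxon_group": str(b["taxon_group"]),
                        "diversity_metric": str(b["diversity_metric"]),
                    }
                    for _, b in bio.iterrows()
                ],
                intensity=float(d["intensity"]),
                case_study_id=str(d["case_study_id"]),
                driver=str(d["driver"]),
                study_type=str(d["study_type"]),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# graphs and d-separation


def full_dag(dataset_kind: str = "abundance") -> nx.DiGraph:
    """The hypothesized mediation graph.

    intensity, study_type, taxon_group (and diversity_metric for diversity
    datasets) are exogenous; zB and zLD are the endogenous effect sizes.
    """
    g = nx.DiGraph()
    exo = ["intensity", "study_type", "taxon_group"]
    if dataset_kind == "diversity":
        exo.append("diversity_metric")
    for node in exo:
        g.add_node(node, exogenous=True)
    for node in ("zB", "zLD"):
        g.add_node(node, exogenous=False)
    for x in exo:
        g.add_edge(x, "zB")
    g.add_edge("zB", "zLD")
    g.add_edge("intensity", "zLD")
    g.add_edge("study_type", "zLD")
    return g


def reduced_dag(dataset_kind: str = "abundance") -> nx.DiGraph:
    """The mediation graph without the biodiversity -> decomposition path."""
    g = full_dag(dataset_kind)
    g.remove_edge("zB", "zLD")
    return g


def basis_set(dag: nx.DiGraph) -> list[tuple[str, str, tuple[str, ...]]]:
    """Conditional-independence claims implied by the missing edges of ``dag``.

    For every non-adjacent pair of nodes that is not exogenous-exogenous, the
    claim is (x independent of y | parents of y), where y is the topologically
    later node of the pair (always endogenous here); the claim is tested by
    adding x to y's sub-model. Returns claims sorted deterministically.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("the model graph must be acyclic")
    order = {n: i for i, n in enumerate(nx.lexicographical_topological_sort(dag))}
    exo = {n for n, e in dag.nodes(data="exogenous") if e}
    claims = []
    nodes = sorted(dag.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if dag.has_edge(a, b) or dag.has_edge(b, a):
                continue
            if a in exo and b in exo:
                continue
            x, y = (a, b) if order[a] < order[b] else (b, a)
            if y in exo:  # claims are tested in an endogenous child's model
                x, y = y, x
            cond = tuple(sorted(set(dag.predecessors(y)) - {x}))
            claims.append((x, y, cond))
    return sorted(claims)


def fishers_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 sum(ln p) over d-separation p-values; chi2 with 2k df."""
    p = list(p_values)
    if not p:
        return 0.0, 0, 1.0
    df = 2 * len(p)
    for pi in p:
        if pi > 1.0 or pi < 0.0 or not math.isfinite(pi):
            raise ValueError(f"p-values must lie in (0, 1], got {pi}")
    if any(pi == 0.0 for pi in p):
        logger.warning("a d-separation p-value of 0: Fisher's C is infinite")
        return math.inf, df, 0.0
    c = -2.0 * sum(math.log(pi) for pi in p)
    return c, df, float(stats.chi2.sf(c, df))


# ---------------------------------------------------------------------------
# resampling

def _pairs_hash(pairs: list[PairedEffect]) -> str:
    h = hashlib.md5()
    for p in pairs:
        h.update(p.link_key.encode())
        h.update(repr((round(p.decomposition["z"], 12), p.intensity)).encode())
        for b in p.biodiversity:
            h.update(repr((b["obs_id"], round(b["z"], 12))).encode())
    return h.hexdigest()


def _resample_frame(pairs, choice) -> pd.DataFrame:
    rows = []
    for p, j in zip(pairs, choice):
        b = p.biodiversity[j]
        rows.append(
            {
                "link_key": p.link_key,
                "case_study_id": p.case_study_id,
                "driver": p.driver,
                "z_ld": p.decomposition["z"],
                "var_ld": p.decomposition["var_z"],
                "z_b": b["z"],
                "var_b": b["var_z"],
                "obs_id_b": b["obs_id"],
                "intensity": p.intensity,
                "study_type": p.study_type,
                "taxon_group": b["taxon_group"],
                "diversity_metric": b["diversity_metric"],
            }
        )
    return pd.DataFrame(rows)


def stratified_resample(pairs: list[PairedEffect], seed: int) -> pd.DataFrame:
    """One stratified resample: one biodiversity effect per decomposition
    measurement, drawn uniformly within each link. Deterministic under seed;
    the identity when no link has duplicates."""
    if not pairs:
        raise ValueError("no paired effects to resample")
    rng = np.random.default_rng(seed)
    counts = np.array([len(p.biodiversity) for p in pairs])
    choice = (rng.random(len(pairs)) * counts).astype(int)
    return _resample_frame(pairs, choice)


def fit_submodels(data: pd.DataFrame, dataset_kind: str = "abundance",
                  include_zb_path: bool = True) -> dict[str, MetaFit]:
    """Fit the two SEM sub-models on a resampled (one-row-per-link) table.

    Both are weighted multilevel meta-models with nested case-study /
    observation random intercepts and the known sampling variances of the
    respective outcome. The diversity-metric term enters the zB model only for
    diversity datasets.
    """
    zb_mods = ["intensity", "study_type", "taxon_group"]
    if dataset_kind == "diversity":
        zb_mods.append("diversity_metric")
    zld_mods = (["z_b"] if include_zb_path else []) + ["intensity", "study_type"]
    fits = {
        "zB": fit_meta(
            data,
            MetaSpec(outcome="z_b", variance_column="var_b",
                     moderators=tuple(zb_mods),
                     random=("study", "observation")),
        ),
        "zLD": fit_meta(
            data,
            MetaSpec(outcome="z_ld", variance_column="var_ld",
                     moderators=tuple(zld_mods),
                     random=("study", "observation")),
        ),
    }
    return fits


# ---------------------------------------------------------------------------
# results


@dataclass
class SEMResult:
    """Resampling-averaged piecewise SEM result for one model graph.

    ``paths`` has one row per edge into an endogenous node: the mean
    unstandardized coefficient, mean SE, and mean standardized coefficient
    (numeric predictors only; between-model comparisons should use the
    unstandardized column). Fisher's C, its p-value (computed from the mean C
    with df fixed by the graph) and the summed sub-model ML AIC are averaged
    across iterations. ``indirect_effect`` is the product of the standardized
    intensity -> zB and zB -> zLD paths; ``direct_effect`` the standardized
    intensity -> zLD path.
    """

    paths: pd.DataFrame
    fisher_C: float
    C_df: int
    C_p: float
    AIC: float
    indirect_effect: float
    direct_effect: float
    n_iterations: int
    n_failed: int
    seed: int
    data_hash: str
    dataset_kind: str
    residuals: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class MediationReport:
    """Outcome of the mediation test (reduced-model fit vs. AIC comparison).

    ``delta_AIC`` is AIC(reduced) - AIC(full): positive values mean the model
    without the biodiversity path fits worse. The path is supported when the
    reduced model is rejected (C_p < 0.05) and is not better by 2 or more AIC
    units; ``criterion_conflict`` flags the case where the fit test rejects
    the reduced model yet the AIC prefers it.
    """

    supported: bool
    reduced_C_p: float
    delta_AIC: float
    AIC_full: float
    AIC_reduced: float
    criterion_conflict: bool
    indirect_effect: float
    direct_effect: float


def mediation_test(full: SEMResult, reduced: SEMResult) -> MediationReport:
    """Apply the mediation rule to an already-fitted full/reduced pair."""
    if full.data_hash != reduced.data_hash:
        raise ValueError("full and reduced SEMs were fitted on different data")
    delta = reduced.AIC - full.AIC
    poor_fit = reduced.C_p < 0.05
    not_better = delta > -2.0
    return MediationReport(
        supported=bool(poor_fit and not_better),
        reduced_C_p=reduced.C_p,
        delta_AIC=delta,
        AIC_full=full.AIC,
        AIC_reduced=reduced.AIC,
        criterion_conflict=bool(poor_fit and not not_better),
        indirect_effect=full.indirect_effect,
        direct_effect=full.direct_effect,
    )


def standardize_path(coef: float, sd_predictor: float, sd_outcome: float) -> float:
    """Standardized path coefficient: coef * sd(predictor) / sd(outcome)."""
    if sd_predictor <= 0 or sd_outcome <= 0:
        raise ValueError("standardization requires strictly positive SDs")
    return coef * sd_predictor / sd_outcome


def indirect_effect(path_intensity_to_b: float, path_b_to_ld: float) -> float:
    """Indirect (mediated) effect: product of the standardized paths."""
    return path_intensity_to_b * path_b_to_ld


# ---------------------------------------------------------------------------
# fast resampling engine


class _Engine:
    """Vectorized data store for repeated SEM fits on resamples.

    Categorical encodings (treatment contrasts, first level alphabetical) are
    fixed from the complete candidate pool so designs are comparable across
    iterations.
    """

    def __init__(self, pairs: list[PairedEffect], dataset_kind: str):
        if not pairs:
            raise ValueError("no paired effects supplied")
        self.pairs = pairs
        self.kind = dataset_kind
        self.L = len(pairs)
        studies = sorted({p.case_study_id for p in pairs})
        smap = {s: i for i, s in enumerate(studies)}
        self.n_s = len(studies)
        self.sidx = np.array([smap[p.case_study_id] for p in pairs])
        self.intensity = np.array([p.intensity for p in pairs])
        self.z_ld = np.array([p.decomposition["z"] for p in pairs])
        self.v_ld = np.array([p.decomposition["var_z"] for p in pairs])

        st_levels = sorted({p.study_type for p in pairs})
        self.st_cols = {
            f"study_type[{lv}]": np.array(
                [1.0 if p.study_type == lv else 0.0 for p in pairs]
            )
            for lv in st_levels[1:]
        }

        self.counts = np.array([len(p.biodiversity) for p in pairs])
        self.offsets = np.concatenate(([0], np.cumsum(self.counts)))
        self.flat_zb = np.array([b["z"] for p in pairs for b in p.biodiversity])
        self.flat_vb = np.array([b["var_z"] for p in pairs for b in p.biodiversity])
        taxa = [b["taxon_group"] for p in pairs for b in p.biodiversity]
        self.taxon_levels = sorted(set(taxa))
        self.flat_taxon = np.array([self.taxon_levels.index(t) for t in taxa])
        metrics = [b["diversity_metric"] for p in pairs for b in p.biodiversity]
        self.metric_levels = sorted(set(metrics))
        self.flat_metric = np.array([self.metric_levels.index(m) for m in metrics])
        self.hash = _pairs_hash(pairs)

    def draw(self, rng: np.random.Generator):
        j = (rng.random(self.L) * self.counts).astype(int)
        pos = self.offsets[:-1] + j
        cols = {
            "z_b": self.flat_zb[pos],
            "var_b": self.flat_vb[pos],
        }
        for i, lv in enumerate(self.taxon_levels[1:], start=1):
            cols[f"taxon_group[{lv}]"] = (self.flat_taxon[pos] == i).astype(float)
        if self.kind == "diversity":
            for i, lv in enumerate(self.metric_levels[1:], start=1):
                cols[f"diversity_metric[{lv}]"] = (
                    self.flat_metric[pos] == i
                ).astype(float)
        return cols

    def term_columns(self, term: str, draw_cols: dict) -> dict[str, np.ndarray]:
        if term == "intensity":
            return {"intensity": self.intensity}
        if term == "zB":
            return {"zB": draw_cols["z_b"]}
        if term == "study_type":
            return dict(self.st_cols)
        if term == "taxon_group":
            return {k: v for k, v in draw_cols.items() if k.startswith("taxon_group[")}
        if term == "diversity_metric":
            return {
                k: v for k, v in draw_cols.items()
                if k.startswith("diversity_metric[")
            }
        raise KeyError(term)


def _fit_arrays(y, X, v, sidx, n_s, reml: bool, start):
    """Variance-component + GLS fit on raw arrays; returns a small dict."""
    lik = _Likelihood(y, X, v, sidx, n_s)
    (tau2, sig2), conv = _optimize_components(
        lik, ["study", "observation"], {}, reml, start
    )
    nll, beta, XtViX = lik.nll(tau2, sig2, reml)
    if beta is None:
        raise RuntimeError("degenerate likelihood at the optimum")
    vcov = np.linalg.inv(XtViX)
    return {
        "beta": beta, "vcov": vcov, "se": np.sqrt(np.diag(vcov)),
        "tau2": tau2, "sig2": sig2, "nll": nll, "lik": lik, "converged": conv,
    }


def _ml_aic(fit: dict, k_fixed: int) -> float:
    (tau2, sig2), _ = _optimize_components(
        fit["lik"], ["study", "observation"], {}, False,
        [max(fit["tau2"], 1e-6), max(fit["sig2"], 1e-6)],
    )
    nll_ml = fit["lik"].nll(tau2, sig2, False)[0]
    return 2.0 * nll_ml + 2.0 * (k_fixed + 2)


def _term_p(fit: dict, idx: list[int]) -> float:
    b = fit["beta"][idx]
    V = fit["vcov"][np.ix_(idx, idx)]
    q = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(q, len(idx)))


class _GraphModels:
    """Design-matrix layout of one model graph's endogenous sub-models."""

    def __init__(self, engine: _Engine, dag: nx.DiGraph):
        self.engine = engine
        self.dag = dag
        self.claims = basis_set(dag)
        exo = {n for n, e in dag.nodes(data="exogenous") if e}
        self.endogenous = [n for n in ("zB", "zLD") if n in dag and n not in exo]
        self.parents = {
            y: sorted(dag.predecessors(y), key=self._term_order)
            for y in self.endogenous
        }

    @staticmethod
    def _term_order(term: str) -> tuple:
        prefer = {"zB": 0, "intensity": 1, "study_type": 2, "taxon_group": 3,
                  "diversity_metric": 4}
        return (prefer.get(term, 9), term)

    def design(self, y: str, draw_cols: dict, extra: str | None = None):
        names = ["intercept"]
        cols = [np.ones(self.engine.L)]
        terms = list(self.parents[y]) + ([extra] if extra else [])
        col_map: dict[str, list[int]] = {}
        for term in terms:
            tc = self.engine.term_columns(term, draw_cols)
            col_map[term] = []
            for name, arr in tc.items():
                col_map[term].append(len(names))
                names.append(name)
                cols.append(arr)
        return np.column_stack(cols), names, col_map

    def outcome(self, y: str, draw_cols: dict):
        if y == "zLD":
            return self.engine.z_ld, self.engine.v_ld
        return draw_cols["z_b"], draw_cols["var_b"]


def _iterate_sem(engine: _Engine, graphs: dict[str, _GraphModels],
                 iterations: int, seed: int):
    """Shared resampling loop; fits every graph's sub-models per iteration.

    Sub-model fits are cached per iteration by (outcome node, predictor terms)
    so work shared between graphs (the zB model; a claim model that equals
    another graph's full model) is done once.
    """
    children = np.random.SeedSequence(seed).spawn(iterations)
    acc = {
        g: {"C": [], "AIC": [], "coefs": [], "ses": [], "stds": [],
            "resid": {n: [] for n in gm.endogenous}}
        for g, gm in graphs.items()
    }
    warm: dict[tuple, list] = {}
    failures = 0
    for it in range(iterations):
        rng = np.random.default_rng(children[it])
        draw = engine.draw(rng)
        sds = {
            "intensity": float(np.std(engine.intensity)),
            "zB": float(np.std(draw["z_b"])),
            "zLD": float(np.std(engine.z_ld)),
        }
        cache: dict[tuple, dict] = {}

        def fitted(gm: _GraphModels, y: str, extra: str | None, reml=True):
            key = (y, tuple(gm.parents[y]), extra)
            if key not in cache:
                X, names, col_map = gm.design(y, draw, extra)
                yv, vv = gm.outcome(y, draw)
                start = warm.get(key, [0.02, 0.02])
                fit = _fit_arrays(yv, X, vv, engine.sidx, engine.n_s, reml, start)
                fit["names"], fit["col_map"] = names, col_map
                warm[key] = [max(fit["tau2"], 1e-6), max(fit["sig2"], 1e-6)]
                cache[key] = fit
            return cache[key]

        try:
            for gname, gm in graphs.items():
                coefs, ses, stds = {}, {}, {}
                aic = 0.0
                for y in gm.endogenous:
                    fit = fitted(gm, y, None)
                    if "aic_ml" not in fit:
                        fit["aic_ml"] = _ml_aic(fit, len(fit["names"]))
                    aic += fit["aic_ml"]
                    for term in gm.parents[y]:
                        for ci in fit["col_map"][term]:
                            name = f"{fit['names'][ci]}->{y}" if term not in (
                                "intensity", "zB") else f"{term}->{y}"
                            coefs[name] = fit["beta"][ci]
                            ses[name] = fit["se"][ci]
                            if term in ("intensity", "zB"):
                                stds[name] = (
                                    fit["beta"][ci] * sds[term] / sds[y]
                                )
                    acc[gname]["resid"][y].append(
                        gm.outcome(y, draw)[0] - fit["lik"].X @ fit["beta"]
                    )
                pvals = []
                for x, y, _cond in gm.claims:
                    cfit = fitted(gm, y, x)
                    pvals.append(_term_p(cfit, cfit["col_map"][x]))
                c, _df, _p = fishers_c(pvals)
                acc[gname]["C"].append(c)
                acc[gname]["AIC"].append(aic)
                acc[gname]["coefs"].append(coefs)
                acc[gname]["ses"].append(ses)
                acc[gname]["stds"].append(stds)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.info("SEM iteration %d failed: %s", it, exc)
            if failures > MAX_FAILURE_FRACTION * iterations:
                raise RuntimeError(
                    f"more than {MAX_FAILURE_FRACTION:.0%} of SEM iterations "
                    f"failed ({failures}/{it + 1}); last error: {exc}"
                )
    return acc, failures


def _summarize(engine, gm: _GraphModels, acc_g: dict, iterations, failures,
               seed, dataset_kind) -> SEMResult:
    coef_keys = sorted(acc_g["coefs"][0]) if acc_g["coefs"] else []
    rows = []
    std_mean = {}
    for key in coef_keys:
        cs = np.array([c[key] for c in acc_g["coefs"]])
        ss = np.array([s[key] for s in acc_g["ses"]])
        st = np.array([s.get(key, np.nan) for s in acc_g["stds"]])
        std_mean[key] = float(np.nanmean(st)) if np.isfinite(st).any() else np.nan
        rows.append(
            {
                "edge": key,
                "coef": float(cs.mean()),
                "se": float(ss.mean()),
                "std_coef": std_mean[key],
            }
        )
    paths = pd.DataFrame(rows, columns=["edge", "coef", "se", "std_coef"])
    c_mean = float(np.mean(acc_g["C"])) if acc_g["C"] else 0.0
    df = 2 * len(gm.claims)
    c_p = float(stats.chi2.sf(c_mean, df)) if df > 0 else 1.0
    a_to_b = std_mean.get("intensity->zB", 0.0)
    b_to_ld = std_mean.get("zB->zLD", 0.0)
    direct = std_mean.get("intensity->zLD", 0.0)
    resid = {
        y: np.mean(np.stack(r), axis=0)
        for y, r in acc_g["resid"].items() if r
    }
    resid_frame = pd.DataFrame(
        {"link_key": [p.link_key for p in engine.pairs], **{
            f"resid_{y}": v for y, v in resid.items()
        }}
    )
    return SEMResult(
        paths=paths,
        fisher_C=c_mean,
        C_df=df,
        C_p=c_p,
        AIC=float(np.mean(acc_g["AIC"])) if acc_g["AIC"] else np.nan,
        indirect_effect=indirect_effect(
            0.0 if np.isnan(a_to_b) else a_to_b,
            0.0 if np.isnan(b_to_ld) else b_to_ld,
        ),
        direct_effect=0.0 if np.isnan(direct) else direct,
        n_iterations=iterations - failures,
        n_failed=failures,
        seed=seed,
        data_hash=engine.hash,
        dataset_kind=dataset_kind,
        residuals=resid_frame,
    )


def run_resampled_sem(
    pairs: list[PairedEffect],
    dag: nx.DiGraph | None = None,
    dataset_kind: str = "abundance",
    iterations: int = 1000,
    seed: int = 0,
) -> SEMResult:
    """Fit a piecewise SEM averaged over stratified resamples.

    Per iteration: resample one biodiversity effect per decomposition
    measurement, fit the sub-models, test the d-separation claims and record
    coefficients, SEs, Fisher's C and the summed sub-model ML AIC; report the
    arithmetic means, with the p of Fisher's C computed from the mean C at the
    graph's fixed df. Iterations whose fits fail are skipped (an error is
    raised if more than 10% fail).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if dag is None:
        dag = full_dag(dataset_kind)
    engine = _Engine(pairs, dataset_kind)
    gm = _GraphModels(engine, dag)
    acc, failures = _iterate_sem(engine, {"g": gm}, iterations, seed)
    return _summarize(engine, gm, acc["g"], iterations, failures, seed, dataset_kind)


def mediation_analysis(
    pairs: list[PairedEffect],
    dataset_kind: str = "abundance",
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[SEMResult, SEMResult, MediationReport]:
    """Full and reduced SEMs on shared resamples, plus the mediation verdict.

    Equivalent to two :func:`run_resampled_sem` calls with the same seed, but
    the per-iteration work shared between the graphs (the zB sub-model; the
    reduced model's zB claim, which equals the full zLD model) is done once.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    engine = _Engine(pairs, dataset_kind)
    graphs = {
        "full": _GraphModels(engine, full_dag(dataset_kind)),
        "reduced": _GraphModels(engine, reduced_dag(dataset_kind)),
    }
    acc, failures = _iterate_sem(engine, graphs, iterations, seed)
    full = _summarize(engine, graphs["full"], acc["full"], iterations, failures,
                      seed, dataset_kind)
    reduced = _summarize(engine, graphs["reduced"], acc["reduced"], iterations,
                         failures, seed, dataset_kind)
    return full, reduced, mediation_test(full, reduced)
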