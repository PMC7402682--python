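"""Reading and writing the flat observation-table schema and truth sidecars.

The pipeline consumes a long-format CSV with one row per observation; gradient
levels and compound lists are packed into semicolon-separated fields so the
table stays flat:

    obs_id, case_study_id, publication_id, driver, design, response, link_key,
    study_type, taxon_group, diversity_metric, decomposition_metric, time,
    mean_c, sd_c, n_c, mean_t, sd_t, n_t,                  (control-treatment)
    level_concentrations, level_means, level_sds, level_ns, (gradient; ';'-joined)
    compounds                     (compound:conc_treatment:conc_criteria:source[:units];...)

Schema violations raise ``SchemaError`` with a column-level message before any
analysis runs.
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd
import yaml

from .effects import (
    DESIGNS,
    DRIVERS,
    RESPONSES,
    GradientLevel,
    GroupStats,
    ObservationRecord,
)
from .intensity import CompoundLevel

__all__ = [
    "SchemaError",
    "observations_to_frame",
    "frame_to_observations",
    "read_observations_csv",
    "write_observations_csv",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

REQUIRED_COLUMNS = [
    "obs_id", "case_study_id", "publication_id", "driver", "design",
    "response", "link_key",
]


class SchemaError(ValueError):
    """The observation table violates the documented schema."""


def _pack(values, fmt="{:.17g}") -> str:
    return ";".join("" if v is None else fmt.format(v) for v in values)


def _unpack(cell) -> list[float | None]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    out = []
    for tok in str(cell).split(";"):
        out.append(None if tok == "" else float(tok))
    return out


def _pack_compounds(levels: list[CompoundLevel]) -> str:
    parts = []
    for lv in levels:
        fields = [lv.compound, f"{lv.conc_treatment:.17g}", f"{lv.conc_criteria:.17g}",
                  lv.criteria_source]
        if lv.units:
            fields.append(lv.units)
        parts.append(":".join(fields))
    return ";".join(parts)


def _unpack_compounds(cell) -> list[CompoundLevel]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    out = []
    for tok in str(cell).split(";"):
        fields = tok.split(":")
        if len(fields) < 4:
            raise SchemaError(
                f"column 'compounds': entry {tok!r} needs at least "
                "compound:conc_treatment:conc_criteria:source"
            )
        out.append(
            CompoundLevel(
                compound=fields[0],
                conc_treatment=float(fields[1]),
                conc_criteria=float(fields[2]),
                criteria_source=fields[3],
                units=fields[4] if len(fields) > 4 else None,
            )
        )
    return out


def observations_to_frame(records: list[ObservationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "obs_id": r.obs_id,
            "case_study_id": r.case_study_id,
            "publication_id": r.publication_id,
            "driver": r.driver,
            "design": r.design,
            "response": r.response,
            "link_key": r.link_key,
            "study_type": r.study_type,
            "taxon_group": r.taxon_group,
            "diversity_metric": r.diversity_metric,
            "decomposition_metric": r.decomposition_metric,
            "time": r.time,
            "compounds": _pack_compounds(r.compound_levels),
        }
        if r.design == "control_treatment":
            row.update(
                mean_c=r.control.mean, sd_c=r.control.sd, n_c=r.control.n,
                mean_t=r.treatment.mean, sd_t=r.treatment.sd, n_t=r.treatment.n,
            )
        else:
            row.update(
                level_concentrations=_pack([lv.concentration for lv in r.levels]),
                level_means=_pack([lv.mean for lv in r.levels]),
                level_sds=_pack([lv.sd for lv in r.levels]),
                level_ns=_pack([lv.n for lv in r.levels], fmt="{:d}"),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_observations(frame: pd.DataFrame) -> list[ObservationRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"observation table is missing required columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        def bad(col, msg):
            return SchemaError(f"row {i} (obs_id={row.get('obs_id')!r}), "
                               f"column {col!r}: {msg}")

        if row["driver"] not in DRIVERS:
            raise bad("driver", f"must be one of {DRIVERS}, got {row['driver']!r}")
        if row["design"] not in DESIGNS:
            raise bad("design", f"must be one of {DESIGNS}, got {row['design']!r}")
        if row["response"] not in RESPONSES:
            raise bad("response", f"must be one of {RESPONSES}, got {row['response']!r}")

        def opt(col, default):
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return default
            return val

        common = dict(
            obs_id=str(row["obs_id"]),
            case_study_id=str(row["case_study_id"]),
            publication_id=str(row["publication_id"]),
            driver=row["driver"],
            design=row["design"],
            response=row["response"],
            link_key=str(row["link_key"]),
            study_type=str(opt("study_type", "experimental")),
            taxon_group=str(opt("taxon_group", "not_applicable")),
            diversity_metric=str(opt("diversity_metric", "not_applicable")),
            decomposition_metric=str(opt("decomposition_metric", "not_applicable")),
            time=(float(opt("time", math.nan))
                  if not math.isnan(float(opt("time", math.nan))) else None),
            compound_levels=_unpack_compounds(row.get("compounds")),
        )
        try:
            if row["design"] == "control_treatment":
                for col in ("mean_c", "n_c", "mean_t", "n_t"):
                    if math.isnan(float(opt(col, math.nan))):
                        raise bad(col, "required for control-treatment records")
                sd_c, sd_t = opt("sd_c", None), opt("sd_t", None)
                rec = ObservationRecord(
                    control=GroupStats(float(row["mean_c"]),
                                       None if sd_c is None else float(sd_c),
                                       int(row["n_c"])),
                    treatment=GroupStats(float(row["mean_t"]),
                                         None if sd_t is None else float(sd_t),
                                         int(row["n_t"])),
                    **common,
                )
            else:
                concs = _unpack(row.get("level_concentrations"))
                means = _unpack(row.get("level_means"))
                if len(concs) != len(means) or len(concs) < 4:
                    raise bad(
                        "level_concentrations/level_means",
                        "gradient records need >= 4 matching concentration/mean pairs",
                    )
                sds = _unpack(row.get("level_sds")) or [None] * len(concs)
                ns = _unpack(row.get("level_ns")) or [None] * len(concs)
                rec = ObservationRecord(
                    levels=[
                        GradientLevel(c, m, s, None if n is None else int(n))
                        for c, m, s, n in zip(concs, means, sds, ns)
                    ],
                    **common,
                )
        except ValueError as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"row {i} (obs_id={row.get('obs_id')!r}): {exc}") from exc
        records.append(rec)
    return records


def write_observations_csv(records: list[ObservationRecord], path) -> None:
    observations_to_frame(records).to_csv(path, index=False)


def read_observations_csv(path) -> list[ObservationRecord]:
    return frame_to_observations(pd.read_csv(path))


def write_truth_sidecar(truth, path) -> None:
    """Write the generator's ground-truth parameters next to a dataset."""
    data = dataclasses.asdict(truth)
    for key, val in data.items():
        if isinstance(val, tuple):
            data[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_truth_sidecar(path):
    from .synthetic import TruthConfig

    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("obs_per_study_range", "n_obs_range", "dup_range", "intensity_range"):
        if key in data:
            data[key] = tuple(data[key])
    return TruthConfig(**data)
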