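"""Cohort ingestion, averaging protocol and the full study analysis.

A cohort is a long-format table of per-subject measurements: each
transthoracic echo (TTE) row carries one distance triplet for one
observer, one cardiac cycle and one phase; each cardiac MR (CMR) row
carries one observer's end-diastolic/end-systolic volume pair.  The
averaging protocol mirrors clinical practice: distances are averaged
over up to three cardiac cycles per observer, each observer's EF is
computed from the averaged distances (TTE, via the ellipsoid model) or
the volume pair (CMR), and the per-modality EF is the mean of the two
observers.

:func:`analyze_study` then runs the complete method-agreement suite on
the derived per-subject table: Pearson correlations with strength bands
for EF_TTE vs EF_CMR and TAPSE vs EF_CMR, Steiger's test comparing
those two dependent correlations, replicate-corrected Bland-Altman
(observers as replicates), the normality-routed paired test, the same
battery on the patient-only subgroup, and inter-observer (intra-
modality) agreement per modality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import agreement as ag
from .ellipsoid import DistanceTriplet, VolumePair
from .exceptions import (
    DataError,
    DegenerateSampleError,
    DomainError,
    FormatError,
    RVEllipseError,
    SampleSizeError,
)

__all__ = [
    "LONG_COLUMNS",
    "CohortTable",
    "SubjectRecord",
    "AnalysisConfig",
    "AgreementReport",
    "average_cycles",
    "derive_table",
    "derive_subject",
    "analyze_study",
    "interobserver_analysis",
    "pooled_mean",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_rvef_wide_csv",
]

#: Long-format input schema. TTE rows fill the three distances (and
#: optionally TAPSE); CMR rows fill the volume pair.
LONG_COLUMNS = [
    "subject_id",
    "group",
    "modality",
    "observer",
    "cycle",
    "phase",
    "rvit3_cm",
    "rvlax_cm",
    "lvd_cm",
    "tapse_mm",
    "edv_ml",
    "esv_ml",
]

_GROUPS = ("patient", "healthy")
_DISTANCE_COLS = ["rvit3_cm", "rvlax_cm", "lvd_cm"]
MAX_CYCLES = 3


@dataclass
class CohortTable:
    """A cohort as a validated long-format DataFrame plus metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing columns: {missing}")
        bad_groups = set(df["group"].dropna().unique()) - set(_GROUPS)
        if bad_groups:
            raise FormatError(f"unknown group labels: {sorted(bad_groups)}")
        bad_mod = set(df["modality"].dropna().unique()) - {"tte", "cmr"}
        if bad_mod:
            raise FormatError(f"unknown modalities: {sorted(bad_mod)}")
        counts = (
            df[df["modality"] == "tte"]
            .groupby(["subject_id", "observer", "phase"], sort=False)["cycle"]
            .nunique()
        )
        if (counts > MAX_CYCLES).any():
            raise FormatError(f"more than {MAX_CYCLES} cycles for some measurement")
        self.df = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, subject_ids: Sequence) -> "CohortTable":
        mask = self.df["subject_id"].isin(list(subject_ids))
        return CohortTable(self.df[mask].copy(), dict(self.metadata))


@dataclass
class SubjectRecord:
    """Convenience container for building one subject programmatically.

    ``tte_measurements`` maps observer label -> list of per-cycle
    ``(diastolic, systolic)`` :class:`DistanceTriplet` pairs;
    ``cmr_volumes`` maps observer label -> :class:`VolumePair`.
    """

    subject_id: str
    group: str
    tte_measurements: dict[str, list[tuple[DistanceTriplet, DistanceTriplet]]]
    cmr_volumes: dict[str, VolumePair]
    tapse_mm: float | None = None
    modality_gap_days: int | None = None

    def to_rows(self) -> list[dict]:
        if self.group not in _GROUPS:
            raise DataError(f"group must be one of {_GROUPS}, got {self.group!r}")
        rows = []
        for obs, cycles in self.tte_measurements.items():
            if not (1 <= len(cycles) <= MAX_CYCLES):
                raise DataError(
                    f"subject {self.subject_id} observer {obs}: need 1-{MAX_CYCLES} "
                    f"cycles, got {len(cycles)}"
                )
            for ci, (dia, sys_) in enumerate(cycles, start=1):
                for phase, trip in (("end_diastole", dia), ("end_systole", sys_)):
                    rows.append(
                        {
                            "subject_id": self.subject_id,
                            "group": self.group,
                            "modality": "tte",
                            "observer": obs,
                            "cycle": ci,
                            "phase": phase,
                            "rvit3_cm": trip.rvit3,
                            "rvlax_cm": trip.rvlax,
                            "lvd_cm": trip.lvd,
                            "tapse_mm": self.tapse_mm,
                            "edv_ml": np.nan,
                            "esv_ml": np.nan,
                        }
                    )
        for obs, vp in self.cmr_volumes.items():
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "group": self.group,
                    "modality": "cmr",
                    "observer": obs,
                    "cycle": 1,
                    "phase": "",
                    "rvit3_cm": np.nan,
                    "rvlax_cm": np.nan,
                    "lvd_cm": np.nan,
                    "tapse_mm": np.nan,
                    "edv_ml": vp.edv,
                    "esv_ml": vp.esv,
                }
            )
        return rows

    @staticmethod
    def build_cohort(records: Sequence["SubjectRecord"], **metadata) -> CohortTable:
        rows: list[dict] = []
        seen = set()
        for rec in records:
            if rec.subject_id in seen:
                raise DataError(f"duplicate subject_id {rec.subject_id!r}")
            seen.add(rec.subject_id)
            rows.extend(rec.to_rows())
        return CohortTable(pd.DataFrame(rows, columns=LONG_COLUMNS), metadata)


def average_cycles(values: Sequence[float]) -> float:
    """Arithmetic mean of 1-3 per-cycle measurements."""
    vals = [float(v) for v in values]
    if not vals:
        raise DataError("no cycle values to average")
    if len(vals) > MAX_CYCLES:
        raise DataError(f"at most {MAX_CYCLES} cycles allowed, got {len(vals)}")
    if not all(math.isfinite(v) for v in vals):
        raise DataError("cycle values must be finite")
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# Derivation: long table -> per-subject derived row
# ---------------------------------------------------------------------------

def _tte_ef_per_observer(tte: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, observer) ellipsoid EF from cycle-averaged distances."""
    if tte.empty:
        return pd.DataFrame(columns=["subject_id", "observer", "ef", "inverted"])
    mean_d = (
        tte.groupby(["subject_id", "observer", "phase"], sort=False)[_DISTANCE_COLS]
        .mean()
    )
    vol = (np.pi / 6.0) * mean_d.prod(axis=1)
    vol = vol.unstack("phase")
    for col in ("end_diastole", "end_systole"):
        if col not in vol.columns:
            vol[col] = np.nan
    ef = 100.0 * (1.0 - vol["end_systole"] / vol["end_diastole"])
    out = ef.rename("ef").reset_index()
    out["inverted"] = out["ef"] < 0
    return out.dropna(subset=["ef"])


def _cmr_ef_per_observer(cmr: pd.DataFrame) -> pd.DataFrame:
    if cmr.empty:
        return pd.DataFrame(columns=["subject_id", "observer", "ef", "inverted"])
    vols = cmr.groupby(["subject_id", "observer"], sort=False)[["edv_ml", "esv_ml"]].mean()
    ef = 100.0 * (1.0 - vols["esv_ml"] / vols["edv_ml"])
    out = ef.rename("ef").reset_index()
    out["inverted"] = out["ef"] < 0
    return out.dropna(subset=["ef"])


def derive_table(cohort: CohortTable) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject derived table and the exclusion/warning log.

    Returns a DataFrame indexed by subject with columns:
    ``group``, ``rvef_tte`` / ``rvef_cmr`` (observer means), per-observer
    columns ``rvef_tte:<obs>`` / ``rvef_cmr:<obs>``, ``tapse_mm``, and
    boolean ``inverted_any``.  Subjects lacking all data for a modality
    get NaN there and an exclusion entry with a reason code; a single
    observer yields that observer's value with a warning entry.
    """
    df = cohort.df
    log: list[dict] = []
    subjects = pd.unique(df["subject_id"])
    groups = df.groupby("subject_id", sort=False)["group"].first()

    per_mod: dict[str, pd.DataFrame] = {}
    for mod, extractor in (("tte", _tte_ef_per_observer), ("cmr", _cmr_ef_per_observer)):
        eff = extractor(df[df["modality"] == mod])
        wide = (
            eff.pivot(index="subject_id", columns="observer", values="ef")
            if not eff.empty
            else pd.DataFrame(index=pd.Index([], name="subject_id"))
        )
        wide.columns = [f"rvef_{mod}:{c}" for c in wide.columns]
        per_mod[mod] = wide
        inv = (
            eff.groupby("subject_id")["inverted"].any()
            if not eff.empty
            else pd.Series(dtype=bool)
        )
        per_mod[mod + "_inv"] = inv

    out = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
    out["group"] = groups
    for mod in ("tte", "cmr"):
        wide = per_mod[mod].reindex(out.index)
        obs_cols = list(wide.columns)
        out[obs_cols] = wide
        out[f"rvef_{mod}"] = wide.mean(axis=1)
        n_obs = wide.notna().sum(axis=1)
        for sid in out.index[n_obs == 0]:
            log.append(
                {"subject_id": sid, "modality": mod, "code": "no_data",
                 "message": f"no usable {mod} measurements; excluded from {mod} statistics"}
            )
        if len(obs_cols) >= 2:
            for sid in out.index[n_obs == 1]:
                log.append(
                    {"subject_id": sid, "modality": mod, "code": "single_observer",
                     "message": f"only one {mod} observer; modality mean is that observer"}
                )
    tapse = (
        df[df["modality"] == "tte"].groupby("subject_id", sort=False)["tapse_mm"].mean()
    )
    out["tapse_mm"] = tapse.reindex(out.index)
    inv = pd.Series(False, index=out.index)
    for key in ("tte_inv", "cmr_inv"):
        inv |= per_mod[key].reindex(out.index).eq(True)
    out["inverted_any"] = inv
    return out, log


def derive_subject(record: SubjectRecord) -> pd.Series:
    """Derived row (EF per observer and per modality, TAPSE) for one subject."""
    cohort = SubjectRecord.build_cohort([record])
    table, _ = derive_table(cohort)
    return table.iloc[0]


# ---------------------------------------------------------------------------
# Study analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of the study analysis.

    direction
        Sign convention of every reported difference.  The default
        ``"tte_minus_cmr"`` makes a positive bias mean that the
        ellipsoid model overestimates EF relative to the CMR reference.
    alpha_normality
        Shapiro-Wilk level routing the paired test.
    ef_decimals, r_decimals
        Display rounding (EF/TAPSE as integers, correlations and z to
        one decimal); machine output stays unrounded.
    """

    direction: str = "tte_minus_cmr"
    alpha_normality: float = 0.05
    ef_decimals: int = 0
    r_decimals: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("tte_minus_cmr", "cmr_minus_tte"):
            raise DomainError(f"unknown direction {self.direction!r}")


def _asdict(obj):
    if obj is None:
        return None
    if hasattr(obj, "__dataclass_fields__"):
        d = {}
        for k in obj.__dataclass_fields__:
            v = getattr(obj, k)
            d[k] = v.value if hasattr(v, "value") and not isinstance(v, float) else v
        return d
    return obj


@dataclass
class AgreementReport:
    """Full method-agreement report for one cohort (or subgroup).

    Every statistic is recomputable from ``derived`` alone; fields that
    could not be computed are ``None`` with the reason recorded in
    ``degenerate``.
    """

    n_subjects: int
    direction: str
    summary: dict
    pearson_tte_cmr: ag.PearsonResult | None
    pearson_tapse_cmr: ag.PearsonResult | None
    pearson_tte_tapse: ag.PearsonResult | None
    steiger: ag.SteigerResult | None
    bland_altman: ag.BlandAltmanResult | None
    paired_test: ag.RoutedTestResult | None
    interobserver: dict
    subgroup_patients: "AgreementReport | None"
    exclusions: list
    degenerate: dict
    derived: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "direction": self.direction,
            "summary": self.summary,
            "pearson_tte_cmr": _asdict(self.pearson_tte_cmr),
            "pearson_tapse_cmr": _asdict(self.pearson_tapse_cmr),
            "pearson_tte_tapse": _asdict(self.pearson_tte_tapse),
            "steiger": _asdict(self.steiger),
            "bland_altman": _asdict(self.bland_altman),
            "paired_test": _asdict(self.paired_test),
            "interobserver": {
                k: {kk: _asdict(vv) for kk, vv in v.items()} if isinstance(v, dict) else v
                for k, v in self.interobserver.items()
            },
            "exclusions": self.exclusions,
            "degenerate": self.degenerate,
        }
        if self.subgroup_patients is not None:
            d["subgroup_patients"] = self.subgroup_patients.to_dict()
        else:
            d["subgroup_patients"] = self.degenerate.get("subgroup_patients")
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_json_default, **kwargs)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _summary_block(derived: pd.DataFrame) -> dict:
    """Mean +/- SD of the derived quantities, per group and overall."""
    out = {}
    frames = {"overall": derived}
    for g in _GROUPS:
        frames[g] = derived[derived["group"] == g]
    for label, frame in frames.items():
        block = {"n": int(len(frame))}
        for col in ("rvef_tte", "rvef_cmr", "tapse_mm"):
            vals = frame[col].dropna()
            if len(vals):
                block[col] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            else:
                block[col] = None
        out[label] = block
    return out


def _observer_columns(derived: pd.DataFrame, modality: str) -> list[str]:
    prefix = f"rvef_{modality}:"
    return sorted(c for c in derived.columns if c.startswith(prefix))


def interobserver_analysis(
    derived: pd.DataFrame, modality: str, config: AnalysisConfig | None = None
) -> dict | None:
    """Inter-observer (intra-modality) agreement block for one modality.

    Mean +/- SD of the observer differences, Pearson r with band, and
    the routed paired test, over subjects with both observers present.
    Returns ``None`` (unavailable) when fewer than two observers exist
    or fewer than four subjects have both.
    """
    config = config or AnalysisConfig()
    cols = _observer_columns(derived, modality)
    if len(cols) < 2:
        return None
    a, b = cols[0], cols[1]
    both = derived[[a, b]].dropna()
    if len(both) < 4:
        return None
    diffs = both[a].to_numpy() - both[b].to_numpy()
    block = {
        "observer_a": a.split(":", 1)[1],
        "observer_b": b.split(":", 1)[1],
        "n": int(len(both)),
        "mean_diff": float(np.mean(diffs)),
        "sd_diff": float(np.std(diffs, ddof=1)),
        "pearson": None,
        "paired_test": None,
    }
    try:
        block["pearson"] = ag.pearson_result(both[a], both[b])
    except RVEllipseError:
        pass
    try:
        block["paired_test"] = ag.routed_paired_test(
            ag.PairedSample(both[b].to_numpy(), both[a].to_numpy(), b, a),
            alpha_normality=config.alpha_normality,
        )
    except RVEllipseError:
        pass
    return block


def _agreement_core(
    derived: pd.DataFrame, cohort_df: pd.DataFrame, config: AnalysisConfig
) -> dict:
    """The inter-method statistics on one derived table."""
    res: dict = {
        "pearson_tte_cmr": None,
        "pearson_tapse_cmr": None,
        "pearson_tte_tapse": None,
        "steiger": None,
        "bland_altman": None,
        "paired_test": None,
        "degenerate": {},
    }
    paired = derived[["rvef_tte", "rvef_cmr"]].dropna()
    if config.direction == "tte_minus_cmr":
        a_col, b_col, a_lab, b_lab = "rvef_cmr", "rvef_tte", "RVEF_CMR", "RVEF_TTE"
    else:
        a_col, b_col, a_lab, b_lab = "rvef_tte", "rvef_cmr", "RVEF_TTE", "RVEF_CMR"

    try:
        res["pearson_tte_cmr"] = ag.pearson_result(paired["rvef_tte"], paired["rvef_cmr"])
    except RVEllipseError as e:
        res["degenerate"]["pearson_tte_cmr"] = str(e)

    triple = derived[["rvef_tte", "rvef_cmr", "tapse_mm"]].dropna()
    if len(triple) >= 4:
        try:
            res["pearson_tapse_cmr"] = ag.pearson_result(
                triple["tapse_mm"], triple["rvef_cmr"]
            )
            res["pearson_tte_tapse"] = ag.pearson_result(
                triple["rvef_tte"], triple["tapse_mm"]
            )
            res["steiger"] = ag.steiger_z(
                r12=ag.pearson_result(triple["rvef_tte"], triple["rvef_cmr"]).r,
                r13=res["pearson_tapse_cmr"].r,
                r23=res["pearson_tte_tapse"].r,
                n=len(triple),
            )
        except RVEllipseError as e:
            res["degenerate"]["steiger"] = str(e)
    else:
        res["degenerate"]["steiger"] = "fewer than 4 subjects with TTE, CMR and TAPSE"

    # Bland-Altman with the two observers per modality as replicates.
    obs_a = _observer_columns(derived, a_col.split("_")[1])
    obs_b = _observer_columns(derived, b_col.split("_")[1])
    sub = derived.loc[paired.index]
    if len(sub) >= 3:
        a_reps = [row.dropna().to_numpy() for _, row in sub[obs_a].iterrows()]
        b_reps = [row.dropna().to_numpy() for _, row in sub[obs_b].iterrows()]
        try:
            res["bland_altman"] = ag.bland_altman_replicate_corrected(
                a_reps, b_reps, label_a=a_lab, label_b=b_lab
            )
        except RVEllipseError as e:
            res["degenerate"]["bland_altman"] = str(e)
    else:
        res["degenerate"]["bland_altman"] = "fewer than 3 subjects with both modalities"

    if len(paired) >= 3:
        try:
            res["paired_test"] = ag.routed_paired_test(
                ag.PairedSample(
                    paired[a_col].to_numpy(), paired[b_col].to_numpy(), a_lab, b_lab
                ),
                alpha_normality=config.alpha_normality,
            )
        except DegenerateSampleError as e:
            res["degenerate"]["paired_test"] = str(e)
    else:
        res["degenerate"]["paired_test"] = "fewer than 3 subjects with both modalities"
    return res


def _build_report(
    cohort: CohortTable,
    config: AnalysisConfig,
    with_subgroup: bool,
    keep_derived: bool,
) -> AgreementReport:
    derived, log = derive_table(cohort)
    core = _agreement_core(derived, cohort.df, config)
    inter = {
        mod: interobserver_analysis(derived, mod, config) for mod in ("tte", "cmr")
    }
    degenerate = core.pop("degenerate")

    subgroup = None
    if with_subgroup:
        patients = derived.index[derived["group"] == "patient"]
        if len(patients) >= 4:
            subgroup = _build_report(
                cohort.subset(patients), config, with_subgroup=False,
                keep_derived=False,
            )
        else:
            degenerate["subgroup_patients"] = "unavailable: fewer than 4 patients"

    return AgreementReport(
        n_subjects=cohort.n_subjects,
        direction=config.direction,
        summary=_summary_block(derived),
        pearson_tte_cmr=core["pearson_tte_cmr"],
        pearson_tapse_cmr=core["pearson_tapse_cmr"],
        pearson_tte_tapse=core["pearson_tte_tapse"],
        steiger=core["steiger"],
        bland_altman=core["bland_altman"],
        paired_test=core["paired_test"],
        interobserver=inter,
        subgroup_patients=subgroup,
        exclusions=log,
        degenerate=degenerate,
        derived=derived if keep_derived else None,
    )


def analyze_study(
    cohort: CohortTable, config: AnalysisConfig | None = None
) -> AgreementReport:
    """Run the full method-agreement analysis on a cohort.

    Produces the complete report on all subjects and, when at least four
    patients are present, on the patient-only subgroup.  Statistics that
    cannot be computed (degenerate or too-small samples) are flagged in
    ``report.degenerate`` rather than raising.
    """
    config = config or AnalysisConfig()
    if cohort.n_subjects < 4:
        raise SampleSizeError(
            f"study analysis needs at least 4 subjects, got {cohort.n_subjects}"
        )
    return _build_report(cohort, config, with_subgroup=True, keep_derived=True)


def pooled_mean(group_means: Sequence[float], group_ns: Sequence[int]) -> float:
    """Subject-count-weighted pooled mean of group means.

    The overall mean of a table decomposes exactly into the weighted
    mean of its group means; this helper makes the decomposition (and
    the consistency of published group/overall columns) checkable.
    """
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    if means.shape != ns.shape or means.ndim != 1 or means.size == 0:
        raise DataError("group_means and group_ns must be equal-length non-empty")
    if (ns <= 0).any():
        raise DataError("group sizes must be positive")
    return float(np.sum(means * ns) / np.sum(ns))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort_csv(path: str | Path, **metadata) -> CohortTable:
    """Read a long-format cohort CSV (schema :data:`LONG_COLUMNS`)."""
    # round_trip parsing keeps written float64 values bit-for-bit
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return CohortTable(df[LONG_COLUMNS].copy(), metadata)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    # %.17g keeps float64 values bit-for-bit across a CSV round-trip
    cohort.df.to_csv(path, index=False, float_format="%.17g")


def read_rvef_wide_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide per-subject EF table, bypassing derivation.

    Expected columns: ``subject_id``, per-observer EF columns named
    ``rvef_tte_obs*`` and ``rvef_cmr_obs*``; optional ``group`` and
    ``tapse_mm``.  Returns a derived-table-shaped DataFrame directly
    usable by the statistics (observer columns renamed to the
    ``rvef_<mod>:<obs>`` convention, modality means added).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing subject_id column")
    out = pd.DataFrame(index=pd.Index(df["subject_id"], name="subject_id"))
    out["group"] = (
        df.set_index("subject_id")["group"] if "group" in df.columns else pd.NA
    )
    for mod in ("tte", "cmr"):
        obs_cols = sorted(c for c in df.columns if c.startswith(f"rvef_{mod}_"))
        if not obs_cols:
            raise FormatError(f"{path}: no rvef_{mod}_* observer columns")
        for c in obs_cols:
            out[f"rvef_{mod}:{c.removeprefix(f'rvef_{mod}_')}"] = (
                df.set_index("subject_id")[c]
            )
        out[f"rvef_{mod}"] = df.set_index("subject_id")[obs_cols].mean(axis=1)
    out["tapse_mm"] = (
        df.set_index("subject_id")["tapse_mm"] if "tapse_mm" in df.columns else np.nan
    )
    out["inverted_any"] = (out[["rvef_tte", "rvef_cmr"]] < 0).any(axis=1)
    return out


def analyze_derived(
    derived: pd.DataFrame, config: AnalysisConfig | None = None
) -> AgreementReport:
    """Run the agreement suite directly on a derived-level table.

    For inputs already at per-subject EF level (e.g. a published
    per-subject EF table) where cycle/observer derivation is not
    applicable.  The patient subgroup is analyzed when group labels are
    present.
    """
    config = config or AnalysisConfig()
    core = _agreement_core(derived, pd.DataFrame(), config)
    inter = {
        mod: interobserver_analysis(derived, mod, config) for mod in ("tte", "cmr")
    }
    degenerate = core.pop("degenerate")
    subgroup = None
    if derived["group"].notna().any():
        patients = derived[derived["group"] == "patient"]
        if len(patients) >= 4:
            sub_core = _agreement_core(patients, pd.DataFrame(), config)
            sub_deg = sub_core.pop("degenerate")
            subgroup = AgreementReport(
                n_subjects=len(patients),
                direction=config.direction,
                summary=_summary_block(patients),
                interobserver={},
                subgroup_patients=None,
                exclusions=[],
                degenerate=sub_deg,
                derived=None,
                **sub_core,
            )
        else:
            degenerate["subgroup_patients"] = "unavailable: fewer than 4 patients"
    return AgreementReport(
        n_subjects=len(derived),
        direction=config.direction,
        summary=_summary_block(derived),
        interobserver=inter,
        subgroup_patients=subgroup,
        exclusions=[],
        degenerate=degenerate,
        derived=derived,
        **core,
    )
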