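"""Retrospective cohort procedures over classifier output and structured EHR.

Patients identified by the classifier as having received a wearable AF
prediagnosis are compared against those who did not, in three stages:

1. **all** — everyone with a wearable note, characterized at the index note
   (the oldest prediagnosis-positive note, or the oldest wearable note when
   no note is positive).
2. **no_prior_af** — after a washout: patients with an ambulatory or
   inpatient AF-coded occurrence (code 313217 or a descendant) strictly
   before the index date are excluded.
3. **diagnosed** — patients with a clinician-assigned AF diagnosis within 60
   days (inclusive) of the index note, characterized at the index diagnosis;
   index prescriptions and procedures count only within 60 days of that
   diagnosis.

Continuous characteristics are compared with the one-tailed Welch t test,
categorical ones with the chi-square test; CHA2DS2-VASc is scored with the
standard point weights. Percentages and the relative risk reproduce the
printed-table convention (half-up rounding to two decimals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .corpus import ClinicalNote, age_in_years
from .synthetic_ehr import AF_ROOT_CODE, AF_SUBTYPE_BY_CODE, COMORBIDITY_CODES

__all__ = [
    "PatientRecord",
    "IndexAssignment",
    "ChadsVascScore",
    "CohortComparisonTable",
    "records_from_tables",
    "assign_index",
    "descendants",
    "exclude_prior_af",
    "af_diagnosis_within",
    "chads_vasc",
    "welch_t_one_tailed",
    "chi_square",
    "relative_risk",
    "percent_of",
    "build_comparison_table",
    "ANTICOAGULANT_NAMES",
    "RHYTHM_NAMES",
]

RACE_LEVELS = ("Asian", "Black", "Hispanic", "White", "Others", "Undisclosed")

ANTICOAGULANT_NAMES = ("warfarin", "apixaban", "dabigatran", "rivaroxaban",
                       "edoxaban", "betrixaban")
RHYTHM_NAMES = ("propafenone", "disopyramide", "quinidine", "mexiletine",
                "flecainide", "metoprolol", "carvedilol", "labetalol", "nadolol",
                "propranolol", "carteolol", "penbutolol", "pindolol", "atenolol",
                "betaxolol", "bisoprolol", "esmolol", "nebivolol", "timolol",
                "sotalol", "dofetilide", "verapamil", "diltiazem", "nicardipine",
                "amlodipine", "felodipine", "nifedipine", "isradipine",
                "nisoldipine", "digoxin")

#: CHA2DS2-VASc point weights (standard instrument)
CHADS_POINTS = {
    "congestive_heart_failure": 1,
    "hypertension": 1,
    "age_ge_75": 2,
    "diabetes": 1,
    "stroke": 2,
    "vascular_disease": 1,
    "age_65_74": 1,
    "female_sex": 1,
}

#: condition-concept codes scoring each comorbidity component (config-driven;
#: defaults match the synthetic tables)
DEFAULT_COMPONENT_CODES: Mapping[str, frozenset[int]] = {
    name: frozenset({code}) for name, code in COMORBIDITY_CODES.items()
}


@dataclass(frozen=True)
class PatientRecord:
    """Demographics plus dated condition/drug/procedure occurrences."""

    patient_id: str
    birth_date: date
    sex: str                      # male | female | missing
    race_ethnicity: str           # one of RACE_LEVELS
    conditions: tuple[tuple[int, date, str], ...] = ()   # (code, date, setting)
    drugs: tuple[tuple[str, date], ...] = ()
    procedures: tuple[tuple[str, date], ...] = ()

    def __post_init__(self) -> None:
        if self.race_ethnicity not in RACE_LEVELS:
            raise ValueError(f"race_ethnicity {self.race_ethnicity!r} not in {RACE_LEVELS}")
        if self.sex not in ("male", "female", "missing"):
            raise ValueError(f"sex {self.sex!r} invalid")


@dataclass(frozen=True)
class IndexAssignment:
    patient_id: str
    group: str          # "prediagnosis" | "no_prediagnosis"
    index_note_id: str
    index_date: date


@dataclass(frozen=True)
class ChadsVascScore:
    components: Mapping[str, int]  # component -> points awarded
    total: int
    missing_sex: bool = False

    def __post_init__(self) -> None:
        if self.total != sum(self.components.values()):
            raise ValueError("total must equal the sum of component points")
        if not 0 <= self.total <= 9:
            raise ValueError("CHA2DS2-VASc total outside [0, 9]")


@dataclass
class CohortComparisonTable:
    """Two-group characteristics table with test statistics."""

    stage: str
    rows: pd.DataFrame  # characteristic, value_prediagnosis, value_no_prediagnosis, test, p_value
    n_prediagnosis: int
    n_no_prediagnosis: int


def _parse(d) -> date:
    return d if isinstance(d, date) else date.fromisoformat(str(d))


def records_from_tables(tables: Mapping[str, pd.DataFrame]) -> dict[str, PatientRecord]:
    """Assemble per-patient records from the structured CSV tables."""
    conds: dict[str, list] = {}
    for r in tables["conditions"].itertuples(index=False):
        conds.setdefault(r.patient_id, []).append(
            (int(r.concept_code), _parse(r.date), str(r.setting)))
    drugs: dict[str, list] = {}
    for r in tables["drugs"].itertuples(index=False):
        drugs.setdefault(r.patient_id, []).append((str(r.drug_name), _parse(r.date)))
    procs: dict[str, list] = {}
    for r in tables["procedures"].itertuples(index=False):
        procs.setdefault(r.patient_id, []).append((str(r.procedure), _parse(r.date)))
    records = {}
    for r in tables["patients"].itertuples(index=False):
        pid = str(r.patient_id)
        records[pid] = PatientRecord(
            pid, _parse(r.birth_date), str(r.sex), str(r.race_ethnicity),
            tuple(conds.get(pid, ())), tuple(drugs.get(pid, ())),
            tuple(procs.get(pid, ())))
    return records


def assign_index(
    notes_by_patient: Mapping[str, Sequence[ClinicalNote]],
    hard_labels: Mapping[str, int],
) -> list[IndexAssignment]:
    """Pick each patient's index note.

    Patients with at least one classifier-positive note join the
    prediagnosis group with the oldest positive note as index; everyone else
    gets the oldest wearable note. Date ties break to the lexicographically
    smallest note id.
    """
    out = []
    for pid in sorted(notes_by_patient):
        notes = notes_by_patient[pid]
        if not notes:
            raise ValueError(f"patient {pid} has no notes")
        positives = [n for n in notes if hard_labels.get(n.note_id, 0) == 1]
        pool = positives if positives else list(notes)
        idx = min(pool, key=lambda n: (n.note_date, n.note_id))
        out.append(IndexAssignment(pid, "prediagnosis" if positives else "no_prediagnosis",
                                   idx.note_id, idx.note_date))
    return out


def descendants(concept: int, hierarchy: Iterable[tuple[int, int]]) -> set[int]:
    """The concept plus its transitive descendants in a parent->child edge list.

    Raises on a cycle reachable from ``concept``; a concept absent from the
    hierarchy returns ``{concept}`` with a warning.
    """
    children: dict[int, list[int]] = {}
    nodes = set()
    for parent, child in hierarchy:
        children.setdefault(int(parent), []).append(int(child))
        nodes.update((int(parent), int(child)))
    if concept not in nodes:
        warnings.warn(f"concept {concept} absent from hierarchy; closure is itself")
        return {concept}
    closure = {concept}
    stack = [concept]
    # iterative DFS with path-based cycle detection on the reachable subgraph
    color: dict[int, int] = {}

    def visit(node: int) -> None:
        color[node] = 1
        for ch in children.get(node, ()):
            if color.get(ch) == 1:
                raise ValueError(f"cycle detected in hierarchy at concept {ch}")
            if color.get(ch) != 2:
                visit(ch)
            closure.add(ch)
        color[node] = 2

    visit(concept)
    return closure


def exclude_prior_af(
    assignments: Sequence[IndexAssignment],
    records: Mapping[str, PatientRecord],
    af_codes: set[int],
) -> list[IndexAssignment]:
    """Washout: drop patients with an ambulatory/inpatient AF-coded occurrence
    strictly before their index date."""
    kept = []
    for a in assignments:
        rec = records[a.patient_id]
        prior = any(code in af_codes and setting in ("ambulatory", "inpatient")
                    and d < a.index_date
                    for code, d, setting in rec.conditions)
        if not prior:
            kept.append(a)
    return kept


def af_diagnosis_within(
    assignments: Sequence[IndexAssignment],
    records: Mapping[str, PatientRecord],
    af_codes: set[int],
    window_days: int = 60,
) -> tuple[pd.DataFrame, float]:
    """Earliest AF-coded occurrence in [index, index + window], per patient.

    Returns a DataFrame (patient_id, group, diagnosed, diagnosis_date) and
    the mean index-to-diagnosis lag in days over diagnosed prediagnosis-group
    patients (NaN when none). Window boundaries are inclusive.
    """
    rows = []
    lags = []
    for a in assignments:
        rec = records[a.patient_id]
        in_window = [d for code, d, setting in rec.conditions
                     if code in af_codes
                     and a.index_date <= d <= a.index_date + timedelta(days=window_days)]
        dx = min(in_window) if in_window else None
        rows.append({"patient_id": a.patient_id, "group": a.group,
                     "diagnosed": dx is not None, "diagnosis_date": dx})
        if dx is not None and a.group == "prediagnosis":
            lags.append((dx - a.index_date).days)
    mean_lag = float(np.mean(lags)) if lags else float("nan")
    return pd.DataFrame(rows), mean_lag


def chads_vasc(
    record: PatientRecord,
    as_of: date,
    component_codes: Mapping[str, frozenset[int]] = DEFAULT_COMPONENT_CODES,
) -> ChadsVascScore:
    """CHA2DS2-VASc at ``as_of`` from condition occurrences on/before that date.

    Age bands are mutually exclusive (>=75 scores 2, 65-74 scores 1); female
    sex scores 1. Missing sex scores 0 for the sex component and sets
    ``missing_sex``.
    """
    active = {code for code, d, _ in record.conditions if d <= as_of}
    comp: dict[str, int] = {}
    for name in ("congestive_heart_failure", "hypertension", "diabetes",
                 "stroke", "vascular_disease"):
        hit = bool(active & component_codes[name])
        comp[name] = CHADS_POINTS[name] if hit else 0
    age = age_in_years(record.birth_date, as_of)
    comp["age_ge_75"] = CHADS_POINTS["age_ge_75"] if age >= 75 else 0
    comp["age_65_74"] = CHADS_POINTS["age_65_74"] if 65 <= age <= 74 else 0
    comp["female_sex"] = CHADS_POINTS["female_sex"] if record.sex == "female" else 0
    return ChadsVascScore(comp, sum(comp.values()), missing_sex=record.sex == "missing")


# --- statistics ---------------------------------------------------------------

def welch_t_one_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: str = "a_greater",
) -> tuple[float, float]:
    """Welch unequal-variance t statistic with a one-tailed P value.

    Degrees of freedom follow Welch-Satterthwaite. ``direction`` fixes the
    alternative: "a_greater" tests mean(a) > mean(b), "b_greater" the
    reverse.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate variance in both groups")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if direction == "a_greater":
        p = float(_sps.t.sf(t, df))
    elif direction == "b_greater":
        p = float(_sps.t.cdf(t, df))
    else:
        raise ValueError("direction must be 'a_greater' or 'b_greater'")
    return float(t), p


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table, df = (r-1)(c-1)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected <= 0).any():
        r, c = np.argwhere(expected <= 0)[0]
        raise ValueError(f"expected count is zero at cell ({r}, {c})")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(_sps.chi2.sf(stat, df))


def percent_of(count: int, denom: int, decimals: int = 2) -> float:
    """Percentage with exact half-up rounding from integer counts
    (the printed-table convention: 305/1037 -> 29.41)."""
    if denom <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(100 * count) / Decimal(denom)
    return float(q.quantize(Decimal(10) ** -decimals, rounding=ROUND_HALF_UP))


def round_half_up(value_num: int, value_den: int, decimals: int = 2) -> float:
    """Exact half-up rounding of an integer ratio."""
    q = Decimal(value_num) / Decimal(value_den)
    return float(q.quantize(Decimal(10) ** -decimals, rounding=ROUND_HALF_UP))


def relative_risk(
    a: int, n1: int, b: int, n2: int, rounding: str = "raw",
) -> float:
    """Risk ratio (a/n1) / (b/n2).

    ``rounding="printed_percent"`` reproduces the printed-table convention:
    each risk is first rendered as a percentage rounded half-up to 2
    decimals, then their ratio is rounded to 2 decimals (29.41 / 1.58 ->
    18.61). ``"raw"`` divides the unrounded risks.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if b == 0:
        raise ValueError("relative risk undefined: zero events in the reference group")
    if rounding == "raw":
        return (a / n1) / (b / n2)
    if rounding == "printed_percent":
        pa = Decimal(100 * a) / Decimal(n1)
        pb = Decimal(100 * b) / Decimal(n2)
        two = Decimal("0.01")
        ratio = pa.quantize(two, rounding=ROUND_HALF_UP) / pb.quantize(two, rounding=ROUND_HALF_UP)
        return float(ratio.quantize(two, rounding=ROUND_HALF_UP))
    raise ValueError("rounding must be 'raw' or 'printed_percent'")


# --- table builders -----------------------------------------------------------

@dataclass
class CohortConfig:
    """Knobs of the cohort stage: washout codes, windows, test directions."""

    af_codes: set[int] = field(default_factory=lambda: set(AF_SUBTYPE_BY_CODE))
    window_days: int = 60
    component_codes: Mapping[str, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_CODES))
    subtype_by_code: Mapping[int, str] = field(
        default_factory=lambda: dict(AF_SUBTYPE_BY_CODE))
    # one-tailed directions per continuous variable (prediagnosis group is "a")
    directions: Mapping[str, str] = field(
        default_factory=lambda: {"age": "a_greater", "chads_vasc": "a_greater"})


def _safe_chi_square(table) -> float:
    try:
        return chi_square(table)[1]
    except ValueError:
        return float("nan")


def _group_split(assignments: Sequence[IndexAssignment]):
    a = [x for x in assignments if x.group == "prediagnosis"]
    b = [x for x in assignments if x.group == "no_prediagnosis"]
    return a, b


def build_comparison_table(
    assignments: Sequence[IndexAssignment],
    records: Mapping[str, PatientRecord],
    stage: str = "all",
    config: CohortConfig | None = None,
) -> CohortComparisonTable:
    """Emit the two-group characteristics table for one cohort stage.

    Stages: "all" (index note), "no_prior_af" (after washout), "diagnosed"
    (AF diagnosis within the window; characterized at the diagnosis date,
    with medication/procedure counts restricted to 60 days from it, and
    all-zero medication rows omitted). Patients with missing sex are excluded
    from every stage's table.
    """
    cfg = config or CohortConfig()
    if stage not in ("all", "no_prior_af", "diagnosed"):
        raise ValueError(f"unknown stage {stage!r}")

    work = [a for a in assignments if records[a.patient_id].sex != "missing"]
    as_of: dict[str, date] = {a.patient_id: a.index_date for a in work}
    if stage in ("no_prior_af", "diagnosed"):
        work = exclude_prior_af(work, records, cfg.af_codes)
    dx_code: dict[str, int] = {}
    if stage == "diagnosed":
        flags, _ = af_diagnosis_within(work, records, cfg.af_codes, cfg.window_days)
        dx_date = {r.patient_id: r.diagnosis_date
                   for r in flags.itertuples(index=False) if r.diagnosed}
        work = [a for a in work if a.patient_id in dx_date]
        as_of = dx_date
        for a in work:
            rec = records[a.patient_id]
            coded = [(code, d) for code, d, _ in rec.conditions
                     if code in cfg.af_codes and d == dx_date[a.patient_id]]
            if coded:
                dx_code[a.patient_id] = coded[0][0]

    grp_a, grp_b = _group_split(work)
    if not grp_a or not grp_b:
        raise ValueError(f"stage {stage!r}: a comparison group is empty "
                         f"({len(grp_a)} prediagnosis vs {len(grp_b)} without)")
    na, nb = len(grp_a), len(grp_b)
    rows: list[dict] = []

    def fmt_count(k: int, n: int) -> str:
        return f"{k} ({percent_of(k, n)}%)"

    # age
    ages_a = [age_in_years(records[a.patient_id].birth_date, as_of[a.patient_id]) for a in grp_a]
    ages_b = [age_in_years(records[a.patient_id].birth_date, as_of[a.patient_id]) for a in grp_b]
    _, p = welch_t_one_tailed(ages_a, ages_b, cfg.directions.get("age", "a_greater"))
    rows.append({"characteristic": "age_years_mean_sd",
                 "prediagnosis": f"{np.mean(ages_a):.2f} ({np.std(ages_a, ddof=1):.2f})",
                 "no_prediagnosis": f"{np.mean(ages_b):.2f} ({np.std(ages_b, ddof=1):.2f})",
                 "test": "welch_t_one_tailed", "p_value": p})

    # race/ethnicity block: one chi-square over the 6x2 table
    def race_counts(group):
        c = {lvl: 0 for lvl in RACE_LEVELS}
        for a in group:
            c[records[a.patient_id].race_ethnicity] += 1
        return c
    ra, rb = race_counts(grp_a), race_counts(grp_b)
    levels = [lvl for lvl in RACE_LEVELS if ra[lvl] + rb[lvl] > 0]
    p_race = _safe_chi_square([[ra[lvl], rb[lvl]] for lvl in levels])
    for i, lvl in enumerate(levels):
        rows.append({"characteristic": f"race_{lvl}",
                     "prediagnosis": fmt_count(ra[lvl], na),
                     "no_prediagnosis": fmt_count(rb[lvl], nb),
                     "test": "chi_square" if i == 0 else "",
                     "p_value": p_race if i == 0 else float("nan")})

    # sex block
    ma = sum(records[a.patient_id].sex == "male" for a in grp_a)
    mb = sum(records[a.patient_id].sex == "male" for a in grp_b)
    p_sex = _safe_chi_square([[ma, mb], [na - ma, nb - mb]])
    rows.append({"characteristic": "sex_male", "prediagnosis": fmt_count(ma, na),
                 "no_prediagnosis": fmt_count(mb, nb), "test": "chi_square",
                 "p_value": p_sex})
    rows.append({"characteristic": "sex_female", "prediagnosis": fmt_count(na - ma, na),
                 "no_prediagnosis": fmt_count(nb - mb, nb), "test": "",
                 "p_value": float("nan")})

    # comorbidities: 2x2 chi-square each
    for name in ("congestive_heart_failure", "hypertension", "diabetes", "vascular_disease"):
        codes = cfg.component_codes[name]
        ka = sum(any(c in codes and d <= as_of[a.patient_id]
                     for c, d, _ in records[a.patient_id].conditions) for a in grp_a)
        kb = sum(any(c in codes and d <= as_of[a.patient_id]
                     for c, d, _ in records[a.patient_id].conditions) for a in grp_b)
        p_c = _safe_chi_square([[ka, kb], [na - ka, nb - kb]])
        rows.append({"characteristic": f"comorbidity_{name}",
                     "prediagnosis": fmt_count(ka, na),
                     "no_prediagnosis": fmt_count(kb, nb),
                     "test": "chi_square", "p_value": p_c})

    # CHA2DS2-VASc
    sa = [chads_vasc(records[a.patient_id], as_of[a.patient_id], cfg.component_codes).total
          for a in grp_a]
    sb = [chads_vasc(records[a.patient_id], as_of[a.patient_id], cfg.component_codes).total
          for a in grp_b]
    _, p_s = welch_t_one_tailed(sa, sb, cfg.directions.get("chads_vasc", "a_greater"))
    rows.append({"characteristic": "chads_vasc_mean_sd",
                 "prediagnosis": f"{np.mean(sa):.2f} ({np.std(sa, ddof=1):.2f})",
                 "no_prediagnosis": f"{np.mean(sb):.2f} ({np.std(sb, ddof=1):.2f})",
                 "test": "welch_t_one_tailed", "p_value": p_s})

    if stage == "diagnosed":
        # AF subtype block from the diagnosis concept code
        subtypes = ("generic", "chronic", "paroxysmal", "persistent")
        sub_a = {s: 0 for s in subtypes}
        sub_b = {s: 0 for s in subtypes}
        for a in grp_a:
            sub_a[cfg.subtype_by_code.get(dx_code.get(a.patient_id, AF_ROOT_CODE), "generic")] += 1
        for a in grp_b:
            sub_b[cfg.subtype_by_code.get(dx_code.get(a.patient_id, AF_ROOT_CODE), "generic")] += 1
        present = [s for s in subtypes if sub_a[s] + sub_b[s] > 0]
        p_sub = _safe_chi_square([[sub_a[s], sub_b[s]] for s in present]) \
            if len(present) >= 2 else float("nan")
        for i, s in enumerate(present):
            rows.append({"characteristic": f"subtype_{s}",
                         "prediagnosis": fmt_count(sub_a[s], na),
                         "no_prediagnosis": fmt_count(sub_b[s], nb),
                         "test": "chi_square" if i == 0 else "",
                         "p_value": p_sub if i == 0 else float("nan")})

        def drug_row(prefix: str, drug: str) -> None:
            def count(group):
                k = 0
                for a in group:
                    rec = records[a.patient_id]
                    d0 = as_of[a.patient_id]
                    hits = [d for name, d in rec.drugs if name == drug
                            and d0 <= d <= d0 + timedelta(days=60)]
                    k += bool(hits)
                return k
            ka, kb = count(grp_a), count(grp_b)
            if ka + kb == 0:
                return  # medications never prescribed are omitted
            p_d = _safe_chi_square([[ka, kb], [na - ka, nb - kb]])
            rows.append({"characteristic": f"{prefix}_{drug}",
                         "prediagnosis": fmt_count(ka, na),
                         "no_prediagnosis": fmt_count(kb, nb),
                         "test": "chi_square", "p_value": p_d})

        for drug in ANTICOAGULANT_NAMES:
            drug_row("anticoagulant", drug)
        for drug in RHYTHM_NAMES:
            drug_row("rhythm", drug)

        def cardio(group):
            k = 0
            for a in group:
                d0 = as_of[a.patient_id]
                k += any(p == "cardioversion" and d0 <= d <= d0 + timedelta(days=60)
                         for p, d in records[a.patient_id].procedures)
            return k
        ca, cb = cardio(grp_a), cardio(grp_b)
        p_cv = _safe_chi_square([[ca, cb], [na - ca, nb - cb]])
        rows.append({"characteristic": "procedure_cardioversion",
                     "prediagnosis": fmt_count(ca, na),
                     "no_prediagnosis": fmt_count(cb, nb),
                     "test": "chi_square", "p_value": p_cv})

    return CohortComparisonTable(stage, pd.DataFrame(rows), na, nb)
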