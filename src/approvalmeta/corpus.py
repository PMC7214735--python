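"""Corpus schema for approval dossiers and lossless CSV/JSON round-tripping.

A corpus is a list of marketing-authorisation records (one per drug × route ×
indication), each holding the randomised trials presented in the dossier, their
arms, and the investigational-vs-comparator arm contrasts together with a
*reporting tier* describing how completely each contrast was reported
(full arm statistics, arm contrast only, p-value and group sizes only, or
insufficient).

Two on-disk forms are supported:

* ``csv_bundle`` — four linked tables (``approvals.csv``, ``trials.csv``,
  ``arms.csv``, ``comparisons.csv``) joined by id columns, plus a
  ``manifest.json`` carrying the schema version.  This mirrors a data
  extraction sheet.
* ``json`` — one nested document ``{"schema_version": ..., "approvals": [...]}``.

Missing values are encoded as empty CSV cells / JSON nulls, never as sentinel
numbers: a dossier that does not report a non-inferiority boundary is not a
dossier reporting a boundary of zero.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Iterable, List, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = "1.0"

__all__ = [
    "SCHEMA_VERSION",
    "Route",
    "SubgroupBasis",
    "BiasAssessment",
    "ComparisonReporting",
    "IssueFlag",
    "DesignPhase",
    "Hypothesis",
    "PrimaryOutcomeKind",
    "SuicidalExcluded",
    "NIVerdict",
    "ArmRole",
    "OutcomeType",
    "ComparatorClass",
    "ReportingTier",
    "Direction",
    "BetterIs",
    "ArmRecord",
    "ArmComparison",
    "TrialRecord",
    "ApprovalRecord",
    "CorpusValidationError",
    "validate_corpus",
    "read_corpus",
    "write_corpus",
]


class Route(str, enum.Enum):
    oral = "oral"
    intramuscular = "intramuscular"
    sublingual = "sublingual"
    inhalation = "inhalation"
    other = "other"


class SubgroupBasis(str, enum.Enum):
    none = "none"
    pre_specified = "pre_specified"
    post_hoc = "post_hoc"


class BiasAssessment(str, enum.Enum):
    none_reported = "none_reported"
    reported_no_bias = "reported_no_bias"
    reported_bias_found = "reported_bias_found"


class ComparisonReporting(str, enum.Enum):
    """How a safety/tolerance comparison was reported in the dossier."""

    quantitative = "quantitative"
    qualitative = "qualitative"
    absent = "absent"


class IssueFlag(str, enum.Enum):
    yes = "yes"
    possible = "possible"
    no = "no"


class DesignPhase(str, enum.Enum):
    initiation = "initiation"
    continuation = "continuation"


class Hypothesis(str, enum.Enum):
    superiority = "superiority"
    non_inferiority = "non_inferiority"


class PrimaryOutcomeKind(str, enum.Enum):
    symptom_scale = "symptom_scale"
    clinical_global_impression = "clinical_global_impression"
    global_functioning = "global_functioning"
    quality_of_life = "quality_of_life"
    relapse = "relapse"
    response = "response"
    remission = "remission"
    other = "other"


class SuicidalExcluded(str, enum.Enum):
    yes = "yes"
    not_stated = "not_stated"


class NIVerdict(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    not_applicable = "not_applicable"


class ArmRole(str, enum.Enum):
    investigational = "investigational"
    active_comparator = "active_comparator"
    placebo = "placebo"


class OutcomeType(str, enum.Enum):
    continuous = "continuous"
    binary = "binary"


class ComparatorClass(str, enum.Enum):
    active = "active"
    placebo = "placebo"


class ReportingTier(str, enum.Enum):
    arm_stats = "arm_stats"
    contrast_only = "contrast_only"
    p_and_n_only = "p_and_n_only"
    insufficient = "insufficient"


class Direction(str, enum.Enum):
    favours_investigational = "favours_investigational"
    favours_comparator = "favours_comparator"
    null = "null"


class BetterIs(str, enum.Enum):
    lower = "lower"
    higher = "higher"


class _Record(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArmRecord(_Record):
    arm_id: str
    role: ArmRole
    drug: Optional[str] = None
    daily_dose: Optional[float] = Field(default=None, gt=0)
    n_randomised: int = Field(gt=0)
    n_withdrawn: Optional[int] = Field(default=None, ge=0)
    n_discontinued_ae: Optional[int] = Field(default=None, ge=0)
    outcome_type: OutcomeType = OutcomeType.continuous
    mean_change: Optional[float] = None
    sd_change: Optional[float] = Field(default=None, gt=0)
    events: Optional[int] = Field(default=None, ge=0)

    def has_outcome_stats(self) -> bool:
        if self.outcome_type is OutcomeType.continuous:
            return self.mean_change is not None and self.sd_change is not None
        return self.events is not None


class ArmComparison(_Record):
    trial_id: str
    investigational_arm_id: str
    comparator_arm_id: str
    comparator_class: ComparatorClass
    reporting_tier: ReportingTier
    contrast_value: Optional[float] = None
    contrast_se: Optional[float] = Field(default=None, gt=0)
    reported_p: Optional[float] = Field(default=None, gt=0, le=1)
    direction: Optional[Direction] = None
    better_is: BetterIs = BetterIs.lower


class TrialRecord(_Record):
    trial_id: str
    design_phase: DesignPhase
    hypothesis: Hypothesis
    duration_weeks: Optional[float] = Field(default=None, gt=0)
    non_inferiority_boundary: Optional[float] = None
    primary_outcome_kind: PrimaryOutcomeKind = PrimaryOutcomeKind.symptom_scale
    suicidal_excluded: SuicidalExcluded = SuicidalExcluded.not_stated
    reported_ni_verdict: NIVerdict = NIVerdict.not_applicable
    pooled_analysis: bool = False
    arms: List[ArmRecord] = Field(default_factory=list)
    comparisons: List[ArmComparison] = Field(default_factory=list)

    def arm(self, arm_id: str) -> ArmRecord:
        for a in self.arms:
            if a.arm_id == arm_id:
                return a
        raise KeyError(arm_id)

    def investigational_arms(self) -> List[ArmRecord]:
        return [a for a in self.arms if a.role is ArmRole.investigational]

    def comparator_arms(self, klass: ComparatorClass) -> List[ArmRecord]:
        role = (
            ArmRole.active_comparator
            if klass is ComparatorClass.active
            else ArmRole.placebo
        )
        return [a for a in self.arms if a.role is role]


class ApprovalRecord(_Record):
    approval_id: str
    drug: str
    route: Route
    indication: str
    year: int
    manufacturer: Optional[str] = None
    comparative_evidence_required: bool = True
    continuation_evidence_required: bool = True
    subgroup_basis: SubgroupBasis = SubgroupBasis.none
    bias_assessment: BiasAssessment = BiasAssessment.none_reported
    safety_comparison_active: ComparisonReporting = ComparisonReporting.absent
    safety_comparison_placebo: ComparisonReporting = ComparisonReporting.absent
    safety_issue: IssueFlag = IssueFlag.no
    tolerance_comparison_active: ComparisonReporting = ComparisonReporting.absent
    tolerance_comparison_placebo: ComparisonReporting = ComparisonReporting.absent
    tolerance_issue: IssueFlag = IssueFlag.no
    divergent_opinion: bool = False
    n_exposed_presubmission: Optional[int] = Field(default=None, ge=0)
    approved_dose_min: Optional[float] = Field(default=None, gt=0)
    approved_dose_max: Optional[float] = Field(default=None, gt=0)
    trials: List[TrialRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _dose_bounds(self) -> "ApprovalRecord":
        if (
            self.approved_dose_min is not None
            and self.approved_dose_max is not None
            and self.approved_dose_min > self.approved_dose_max
        ):
            raise ValueError(
                f"approval {self.approval_id}: approved_dose_min "
                f"{self.approved_dose_min} > approved_dose_max {self.approved_dose_max}"
            )
        return self


class CorpusValidationError(ValueError):
    """Raised when a corpus violates cross-record invariants.

    ``errors`` holds one human-readable message per violation, each naming the
    offending record.
    """

    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("corpus validation failed:\n" + "\n".join(self.errors))


def validate_corpus(corpus: Iterable[ApprovalRecord]) -> None:
    """Check cross-record invariants; raise :class:`CorpusValidationError` listing
    every violation found (not just the first)."""
    errors: List[str] = []
    seen_approvals: set = set()
    for app in corpus:
        if app.approval_id in seen_approvals:
            errors.append(f"duplicate approval_id {app.approval_id!r}")
        seen_approvals.add(app.approval_id)
        seen_trials: set = set()
        for trial in app.trials:
            tid = trial.trial_id
            if tid in seen_trials:
                errors.append(f"approval {app.approval_id}: duplicate trial_id {tid!r}")
            seen_trials.add(tid)
            if len(trial.arms) < 2:
                errors.append(f"trial {tid}: fewer than 2 arms")
            arm_ids = set()
            for arm in trial.arms:
                if arm.arm_id in arm_ids:
                    errors.append(f"trial {tid}: duplicate arm_id {arm.arm_id!r}")
                arm_ids.add(arm.arm_id)
                if arm.events is not None and arm.events > arm.n_randomised:
                    errors.append(
                        f"arm {arm.arm_id} (trial {tid}): events {arm.events} "
                        f"> n_randomised {arm.n_randomised}"
                    )
                if arm.outcome_type is OutcomeType.binary and (
                    arm.mean_change is not None or arm.sd_change is not None
                ):
                    errors.append(
                        f"arm {arm.arm_id} (trial {tid}): binary outcome with "
                        "continuous summary statistics"
                    )
                if arm.outcome_type is OutcomeType.continuous and arm.events is not None:
                    errors.append(
                        f"arm {arm.arm_id} (trial {tid}): continuous outcome "
                        "with event count"
                    )
            if (
                trial.non_inferiority_boundary is not None
                and trial.hypothesis is not Hypothesis.non_inferiority
            ):
                errors.append(
                    f"trial {tid}: non-inferiority boundary on a "
                    f"{trial.hypothesis.value} trial"
                )
            for comp in trial.comparisons:
                if comp.trial_id != tid:
                    errors.append(
                        f"comparison in trial {tid} carries trial_id "
                        f"{comp.trial_id!r}"
                    )
                for ref, label in (
                    (comp.investigational_arm_id, "investigational"),
                    (comp.comparator_arm_id, "comparator"),
                ):
                    if ref not in arm_ids:
                        errors.append(
                            f"trial {tid}: comparison references unknown "
                            f"{label} arm {ref!r}"
                        )
                        continue
                if comp.investigational_arm_id in arm_ids:
                    inv = trial.arm(comp.investigational_arm_id)
                    if inv.role is not ArmRole.investigational:
                        errors.append(
                            f"trial {tid}: comparison investigational arm "
                            f"{inv.arm_id!r} has role {inv.role.value}"
                        )
                if comp.comparator_arm_id in arm_ids:
                    cmp_arm = trial.arm(comp.comparator_arm_id)
                    expected = (
                        ArmRole.active_comparator
                        if comp.comparator_class is ComparatorClass.active
                        else ArmRole.placebo
                    )
                    if cmp_arm.role is not expected:
                        errors.append(
                            f"trial {tid}: comparator arm {cmp_arm.arm_id!r} has "
                            f"role {cmp_arm.role.value}, expected {expected.value}"
                        )
                if comp.reporting_tier is ReportingTier.arm_stats:
                    for ref in (comp.investigational_arm_id, comp.comparator_arm_id):
                        if ref in arm_ids and not trial.arm(ref).has_outcome_stats():
                            errors.append(
                                f"trial {tid}: arm_stats comparison but arm "
                                f"{ref!r} lacks outcome statistics"
                            )
                if (
                    comp.reporting_tier is ReportingTier.p_and_n_only
                    and comp.reported_p is None
                ):
                    errors.append(
                        f"trial {tid}: p_and_n_only comparison without reported_p"
                    )
    if errors:
        raise CorpusValidationError(errors)


# ---------------------------------------------------------------------------
# serialisation

_APPROVAL_COLS = [
    "approval_id", "drug", "route", "indication", "year", "manufacturer",
    "comparative_evidence_required", "continuation_evidence_required",
    "subgroup_basis", "bias_assessment", "safety_comparison_active",
    "safety_comparison_placebo", "safety_issue", "tolerance_comparison_active",
    "tolerance_comparison_placebo", "tolerance_issue", "divergent_opinion",
    "n_exposed_presubmission", "approved_dose_min", "approved_dose_max",
]
_TRIAL_COLS = [
    "approval_id", "trial_id", "design_phase", "hypothesis", "duration_weeks",
    "non_inferiority_boundary", "primary_outcome_kind", "suicidal_excluded",
    "reported_ni_verdict", "pooled_analysis",
]
_ARM_COLS = [
    "trial_id", "arm_id", "role", "drug", "daily_dose", "n_randomised",
    "n_withdrawn", "n_discontinued_ae", "outcome_type", "mean_change",
    "sd_change", "events",
]
_COMPARISON_COLS = [
    "trial_id", "investigational_arm_id", "comparator_arm_id",
    "comparator_class", "reporting_tier", "contrast_value", "contrast_se",
    "reported_p", "direction", "better_is",
]

_BOOL_FIELDS = {
    "comparative_evidence_required",
    "continuation_evidence_required",
    "divergent_opinion",
    "pooled_analysis",
}
_INT_FIELDS = {
    "year", "n_exposed_presubmission", "n_randomised", "n_withdrawn",
    "n_discontinued_ae", "events",
}
_FLOAT_FIELDS = {
    "approved_dose_min", "approved_dose_max", "duration_weeks",
    "non_inferiority_boundary", "daily_dose", "mean_change", "sd_change",
    "contrast_value", "contrast_se", "reported_p",
}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isnan(value):  # pragma: no cover - guarded upstream
            return ""
        return repr(value)
    return str(value)


def _parse(value: str, field: str):
    if value == "":
        return None
    if field in _BOOL_FIELDS:
        if value not in ("true", "false"):
            raise ValueError(f"invalid boolean {value!r} in column {field}")
        return value == "true"
    if field in _INT_FIELDS:
        return int(value)
    if field in _FLOAT_FIELDS:
        return float(value)
    return value


def _rows_to_frame(rows: List[dict], cols: List[str]) -> pd.DataFrame:
    return pd.DataFrame([[_cell(r[c]) for c in cols] for r in rows], columns=cols)


def _corpus_tables(corpus: List[ApprovalRecord]):
    approvals, trials, arms, comparisons = [], [], [], []
    for app in corpus:
        approvals.append({c: getattr(app, c) for c in _APPROVAL_COLS})
        for trial in app.trials:
            row = {c: getattr(trial, c) for c in _TRIAL_COLS if c != "approval_id"}
            row["approval_id"] = app.approval_id
            trials.append(row)
            for arm in trial.arms:
                arow = {c: getattr(arm, c) for c in _ARM_COLS if c != "trial_id"}
                arow["trial_id"] = trial.trial_id
                arms.append(arow)
            for comp in trial.comparisons:
                comparisons.append({c: getattr(comp, c) for c in _COMPARISON_COLS})
    return approvals, trials, arms, comparisons


def write_corpus(corpus: List[ApprovalRecord], path, format: str = "csv_bundle") -> None:
    """Serialise a validated corpus.

    ``csv_bundle`` writes four CSV tables plus ``manifest.json`` into the
    directory ``path``; ``json`` writes a single nested document to the file
    ``path``.  Output is byte-stable for a fixed corpus: field order follows
    the schema, record order follows the corpus.
    """
    validate_corpus(corpus)
    path = Path(path)
    if format == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "approvals": [app.model_dump(mode="json") for app in corpus],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return
    if format != "csv_bundle":
        raise ValueError(f"unknown corpus format {format!r}")
    path.mkdir(parents=True, exist_ok=True)
    approvals, trials, arms, comparisons = _corpus_tables(corpus)
    for name, rows, cols in (
        ("approvals", approvals, _APPROVAL_COLS),
        ("trials", trials, _TRIAL_COLS),
        ("arms", arms, _ARM_COLS),
        ("comparisons", comparisons, _COMPARISON_COLS),
    ):
        frame = _rows_to_frame(rows, cols)
        frame.to_csv(path / f"{name}.csv", index=False, lineterminator="\n")
    (path / "manifest.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION}) + "\n", encoding="utf-8"
    )


def _read_table(path: Path, cols: List[str]) -> List[dict]:
    if not path.exists():
        raise FileNotFoundError(f"missing corpus table {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise CorpusValidationError(
            [f"{path.name}: missing required column(s) {', '.join(missing)}"]
        )
    out = []
    for rec in frame.to_dict(orient="records"):
        out.append({c: _parse(rec[c], c) for c in cols})
    return out


def _build_nested(approvals, trials, arms, comparisons) -> List[ApprovalRecord]:
    errors: List[str] = []
    trial_index: dict = {}
    corpus: List[ApprovalRecord] = []
    app_by_id: dict = {}
    for row in approvals:
        try:
            app = ApprovalRecord(**row)
        except Exception as exc:  # pydantic ValidationError
            errors.append(f"approval {row.get('approval_id')!r}: {exc}")
            continue
        corpus.append(app)
        app_by_id[app.approval_id] = app
    for row in trials:
        app_id = row.pop("approval_id")
        if app_id not in app_by_id:
            errors.append(f"trial {row.get('trial_id')!r}: dangling approval_id {app_id!r}")
            continue
        try:
            trial = TrialRecord(**row)
        except Exception as exc:
            errors.append(f"trial {row.get('trial_id')!r}: {exc}")
            continue
        app_by_id[app_id].trials.append(trial)
        trial_index[trial.trial_id] = trial
    for row in arms:
        trial_id = row.pop("trial_id")
        if trial_id not in trial_index:
            errors.append(f"arm {row.get('arm_id')!r}: dangling trial_id {trial_id!r}")
            continue
        try:
            arm = ArmRecord(**row)
        except Exception as exc:
            errors.append(f"arm {row.get('arm_id')!r}: {exc}")
            continue
        trial_index[trial_id].arms.append(arm)
    for row in comparisons:
        trial_id = row["trial_id"]
        if trial_id not in trial_index:
            errors.append(f"comparison: dangling trial_id {trial_id!r}")
            continue
        try:
            comp = ArmComparison(**row)
        except Exception as exc:
            errors.append(f"comparison in trial {trial_id!r}: {exc}")
            continue
        trial_index[trial_id].comparisons.append(comp)
    if errors:
        raise CorpusValidationError(errors)
    return corpus


def read_corpus(path, format: str = "csv_bundle") -> List[ApprovalRecord]:
    """Read and fully validate a corpus written by :func:`write_corpus`."""
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        version = doc.get("schema_version")
        if version != SCHEMA_VERSION:
            raise CorpusValidationError(
                [f"unknown schema version {version!r} (expected {SCHEMA_VERSION!r})"]
            )
        corpus = [ApprovalRecord(**app) for app in doc["approvals"]]
        validate_corpus(corpus)
        return corpus
    if format != "csv_bundle":
        raise ValueError(f"unknown corpus format {format!r}")
    manifest = path / "manifest.json"
    if manifest.exists():
        version = json.loads(manifest.read_text(encoding="utf-8")).get("schema_version")
    else:
        version = None
    if version != SCHEMA_VERSION:
        raise CorpusValidationError(
            [f"unknown schema version {version!r} (expected {SCHEMA_VERSION!r})"]
        )
    approvals = _read_table(path / "approvals.csv", _APPROVAL_COLS)
    trials = _read_table(path / "trials.csv", _TRIAL_COLS)
    arms = _read_table(path / "arms.csv", _ARM_COLS)
    comparisons = _read_table(path / "comparisons.csv", _COMPARISON_COLS)
    corpus = _build_nested(approvals, trials, arms, comparisons)
    validate_corpus(corpus)
    return corpus
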