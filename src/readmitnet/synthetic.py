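"""Seeded synthetic EMR cohort generator.

Emulates the statistical structure a 30-day readmission study assumes:
admissions chained into index -> readmission sequences with a target
marginal 30-day readmission rate (default 23.3%), excludable
planned / transfer / against-medical-advice stays, structured clinical
events (diagnoses, procedures, medications, abnormal labs), sectioned
note token streams, and covariates carrying both linear and nonlinear
(XOR / product interaction) signal for the outcome.

No claim of clinical realism is made: codes are opaque identifiers,
dates live on an integer-day axis, and note "text" is a Zipf token
stream whose frequencies shift with the outcome so bag-of-words
features carry signal.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortConfig",
    "AdmissionRecord",
    "NoteSection",
    "CohortConfigError",
    "generate_cohort",
    "generate_outcomes",
    "sample_risk_dataset",
    "write_cohort",
    "read_cohort",
]

DISPOSITIONS = ("routine", "transfer", "against_medical_advice")

#: note sections per note type; the "rare" section exercises the >=50% presence filter
NOTE_SECTIONS = {
    "physician_note": (("social_history", 0.9), ("assessment", 0.7), ("sparse_section", 0.3)),
    "discharge_summary": (
        ("hospital_course", 0.95),
        ("reason_for_hospitalization", 0.8),
        ("allergies", 0.7),
        ("significant_findings", 0.55),
        ("rare_addendum", 0.25),
    ),
}


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid; names the field."""


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    Covariates are ``n_binary_codes`` Bernoulli(``binary_code_prob``)
    indicators followed by ``n_continuous_vars`` Uniform(0, 1) values.
    The per-admission 30-day readmission risk is
    ``logistic(intercept + linear + interactions + noise)`` where the
    intercept is calibrated so the marginal risk equals
    ``target_readmit_rate`` (unless given explicitly).
    """

    n_patients: int = 500
    mean_admissions_per_patient: float = 2.4
    target_readmit_rate: float = 0.233
    n_binary_codes: int = 20
    n_continuous_vars: int = 4
    n_note_tokens: int = 200
    frac_planned: float = 0.05
    frac_transfer: float = 0.02
    frac_ama: float = 0.01
    linear_weights: tuple = ()
    nonlinear_pairs: tuple = ()  # (i, j, weight); XOR if both binary, else product
    noise_sd: float = 0.0
    binary_code_prob: float = 0.3
    intercept: float | None = None  # None -> calibrated to target_readmit_rate
    max_admissions_per_patient: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in ("target_readmit_rate", "frac_planned", "frac_transfer",
                     "frac_ama", "binary_code_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("n_patients", "n_binary_codes", "n_note_tokens",
                     "max_admissions_per_patient"):
            if getattr(self, name) <= 0:
                raise CohortConfigError(f"{name} must be a positive count")
        if self.n_continuous_vars < 0:
            raise CohortConfigError("n_continuous_vars must be nonnegative")
        if self.mean_admissions_per_patient < 1.0:
            raise CohortConfigError("mean_admissions_per_patient must be >= 1")
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be nonnegative")
        if self.frac_planned + self.frac_transfer + self.frac_ama > 1.0:
            raise CohortConfigError("frac_planned + frac_transfer + frac_ama exceeds 1")
        p = self.n_binary_codes + self.n_continuous_vars
        if len(self.linear_weights) > p:
            raise CohortConfigError("linear_weights longer than the covariate vector")

    @property
    def n_covariates(self) -> int:
        return self.n_binary_codes + self.n_continuous_vars


@dataclass
class NoteSection:
    """One section of one clinical note (tokens only, no free text)."""

    note_type: str
    section: str
    date: int
    tokens: list


@dataclass
class AdmissionRecord:
    """One hospital stay on an integer-day axis.

    ``true_risk`` is the generator's ground-truth 30-day readmission
    probability, retained for recovery tests only; the feature pipeline
    never reads it (nor ``covariates``).
    """

    patient_id: str
    admit_date: int
    discharge_date: int
    disposition: str = "routine"
    planned: bool = False
    principal_code: str = ""
    diagnosis_codes: list = field(default_factory=list)   # (code, day)
    procedure_codes: list = field(default_factory=list)   # (code, day)
    medication_events: list = field(default_factory=list)  # (code, day)
    lab_events: list = field(default_factory=list)         # (code, day, abnormal)
    note_sections: list = field(default_factory=list)      # list[NoteSection]
    demographics: dict = field(default_factory=dict)
    admission_measures: dict = field(default_factory=dict)
    covariates: np.ndarray | None = None
    true_risk: float = 0.0

    def __post_init__(self):
        if self.admit_date > self.discharge_date:
            raise ValueError("admit_date must be <= discharge_date")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _risk_score(x: np.ndarray, config: CohortConfig) -> float:
    """Linear + interaction score (without intercept/noise) for one covariate row."""
    s = 0.0
    w = np.asarray(config.linear_weights, dtype=float)
    if w.size:
        s += float(w @ x[: w.size])
    nb = config.n_binary_codes
    for i, j, wij in config.nonlinear_pairs:
        if not (0 <= i < x.size and 0 <= j < x.size):
            raise CohortConfigError(
                f"nonlinear_pairs index ({i}, {j}) outside covariate range [0, {x.size})"
            )
        if i < nb and j < nb:  # XOR on two binary indicators
            s += wij * float(x[i] != x[j])
        else:
            s += wij * float(x[i] * x[j])
    return s


def _draw_covariates(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    xb = (rng.random(config.n_binary_codes) < config.binary_code_prob).astype(float)
    xc = rng.random(config.n_continuous_vars)
    return np.concatenate([xb, xc])


def _calibrate_intercept(config: CohortConfig) -> float:
    """Bisect the intercept so that E[sigmoid(b0 + score + noise)] hits the target rate."""
    if config.target_readmit_rate <= 0.0:
        return -np.inf
    if config.target_readmit_rate >= 1.0:
        return np.inf
    rng = np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), 7919]))
    n = 4000
    scores = np.empty(n)
    for i in range(n):
        scores[i] = _risk_score(_draw_covariates(rng, config), config)
    if config.noise_sd > 0:
        scores = scores + rng.normal(0.0, config.noise_sd, size=n)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + scores).mean() < config.target_readmit_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _admission_risk(x: np.ndarray, intercept: float,
                    rng: np.random.Generator, config: CohortConfig) -> float:
    eta = intercept + _risk_score(x, config)
    if config.noise_sd > 0:
        eta += rng.normal(0.0, config.noise_sd)
    return float(_sigmoid(eta))


# -- clinical event materialisation -------------------------------------------
# Binary covariates are split round-robin over diagnoses / medications /
# procedures / labs so the feature pipeline can reconstruct the signal from
# events alone; continuous covariates surface as admission-level measures.

def _event_group(j: int) -> str:
    return ("diagnosis", "medication", "procedure", "lab")[j % 4]


def _materialise_events(rec: AdmissionRecord, rng: np.random.Generator,
                        config: CohortConfig) -> None:
    x = rec.covariates
    admit, disch = rec.admit_date, rec.discharge_date
    for j in range(config.n_binary_codes):
        if x[j] != 1.0:
            continue
        code = f"C{j:03d}"
        group = _event_group(j)
        if group == "diagnosis":
            # within [admit - 2y, discharge] and inside the 2y-pre-discharge window
            day = disch - int(rng.integers(0, 700))
            rec.diagnosis_codes.append((code, day))
        elif group == "medication":
            for _ in range(1 + int(rng.poisson(1.0))):
                rec.medication_events.append((code, int(rng.integers(admit, disch + 1))))
        elif group == "procedure":
            rec.procedure_codes.append((code, int(rng.integers(admit, disch + 1))))
        else:  # lab: abnormal results near admission and/or discharge
            span = disch - admit
            rec.lab_events.append((code, admit + int(rng.integers(0, min(8, span + 1))), True))
            if rng.random() < 0.5:
                rec.lab_events.append((code, disch - int(rng.integers(0, min(8, span + 1))), True))
    # normal lab chatter independent of the outcome
    for _ in range(int(rng.poisson(2.0))):
        code = f"C{int(rng.integers(0, config.n_binary_codes)):03d}"
        rec.lab_events.append((code, int(rng.integers(admit, disch + 1)), False))
    for k in range(config.n_continuous_vars):
        rec.admission_measures[f"util_{k}"] = float(x[config.n_binary_codes + k])


def _zipf_probs(v: int) -> np.ndarray:
    p = 1.0 / np.arange(1, v + 1) ** 1.3
    return p / p.sum()


def _materialise_notes(rec: AdmissionRecord, rng: np.random.Generator,
                       config: CohortConfig, base_probs: np.ndarray) -> None:
    v = config.n_note_tokens
    n_signal = max(1, v // 10)
    signal = np.zeros(v)
    signal[:n_signal] = 1.0 / n_signal
    # token distribution shifts toward the low-index "signal" words with risk
    mix = 0.5 * rec.true_risk
    probs = (1.0 - mix) * base_probs + mix * signal
    for note_type, sections in NOTE_SECTIONS.items():
        date = int(rng.integers(rec.admit_date, rec.discharge_date + 1))
        for section, presence in sections:
            if rng.random() >= presence:
                continue
            n_tok = 5 + int(rng.poisson(20.0))
            toks = rng.choice(v, size=n_tok, p=probs)
            rec.note_sections.append(
                NoteSection(note_type, section, date, [f"w{t:04d}" for t in toks])
            )


def _draw_exclusion(rng: np.random.Generator, config: CohortConfig):
    """Return (planned, disposition) with the configured marginal fractions."""
    u = rng.random()
    if u < config.frac_planned:
        return True, "routine"
    if u < config.frac_planned + config.frac_transfer:
        return False, "transfer"
    if u < config.frac_planned + config.frac_transfer + config.frac_ama:
        return False, "against_medical_advice"
    return False, "routine"


def _new_admission(pid: str, admit: int, rng: np.random.Generator,
                   config: CohortConfig, demographics: dict,
                   is_readmission_target: bool) -> AdmissionRecord:
    los = 1 + int(rng.integers(0, 14))
    if is_readmission_target:
        planned, dispo = False, "routine"  # a readmission must be countable
    else:
        planned, dispo = _draw_exclusion(rng, config)
    return AdmissionRecord(
        patient_id=pid,
        admit_date=admit,
        discharge_date=admit + los,
        disposition=dispo,
        planned=planned,
        principal_code=f"P{int(rng.integers(0, 10)):02d}",
        demographics=demographics,
        covariates=_draw_covariates(rng, config),
    )


def generate_cohort(config: CohortConfig) -> list[AdmissionRecord]:
    """Generate a full cohort: patients, admission chains, events, outcomes.

    Deterministic per ``(config, config.seed)``. Outcome linkage (risk
    computation, 30-day gap realisation) is delegated to
    :func:`generate_outcomes`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), 1]))
    records: list[AdmissionRecord] = []
    # index stays beyond the first arise from a continuation process; the
    # readmission process in generate_outcomes inserts roughly a
    # 1/(1 - rate) multiplier, so discount the index-stay budget accordingly
    extra_mean = max(0.0, config.mean_admissions_per_patient
                     * (1.0 - config.target_readmit_rate) - 1.0)
    for pid_i in range(config.n_patients):
        pid = f"pt{pid_i:06d}"
        demographics = {
            "age": float(np.round(40 + 50 * rng.random(), 1)),
            "gender": "male" if rng.random() < 0.53 else "female",
            "marital_status": ("married", "single", "widowed")[int(rng.integers(0, 3))],
        }
        n_index = 1 + int(rng.poisson(extra_mean))
        t = int(rng.integers(0, 2000))
        for _ in range(n_index):
            rec = _new_admission(pid, t, rng, config, demographics,
                                 is_readmission_target=False)
            records.append(rec)
            t = rec.discharge_date + 31 + int(rng.integers(0, 335))
    return generate_outcomes(records, config)


def generate_outcomes(records: list[AdmissionRecord],
                      config: CohortConfig) -> list[AdmissionRecord]:
    """Realise per-admission risk and 30-day readmission gaps.

    Each countable stay draws a Bernoulli(risk) readmission indicator; on
    success a readmission stay (itself countable, itself at risk) is
    inserted <=30 days after discharge and the rest of the patient's
    timeline is shifted to keep stays disjoint. Excluded stays never draw
    a readmission, so the realised flagged fraction among countable
    admissions converges to the marginal risk, i.e. the target rate.
    """
    config.validate()
    intercept = config.intercept if config.intercept is not None \
        else _calibrate_intercept(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), 2]))
    base_probs = _zipf_probs(config.n_note_tokens)

    by_patient: dict[str, list[AdmissionRecord]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    out: list[AdmissionRecord] = []
    for pid, stays in by_patient.items():
        stays = sorted(stays, key=lambda r: (r.admit_date, r.discharge_date))
        queue = list(stays)
        timeline: list[AdmissionRecord] = []
        t = queue[0].admit_date
        while queue:
            rec = queue.pop(0)
            if timeline:  # shift to preserve the planned gap from the prior stay
                los = rec.discharge_date - rec.admit_date
                rec.admit_date = max(rec.admit_date, t)
                rec.discharge_date = rec.admit_date + los
            excluded = rec.planned or rec.disposition != "routine"
            rec.true_risk = _admission_risk(rec.covariates, intercept, rng, config)
            _materialise_events(rec, rng, config)
            _materialise_notes(rec, rng, config, base_probs)
            timeline.append(rec)
            readmit = (not excluded
                       and len(timeline) + len(queue) < config.max_admissions_per_patient
                       and rng.random() < rec.true_risk)
            if readmit:
                gap = min(int(rng.geometric(0.15)), 30)
                target = _new_admission(pid, rec.discharge_date + gap, rng, config,
                                        rec.demographics, is_readmission_target=True)
                queue.insert(0, target)
                t = target.admit_date
            else:
                t = rec.discharge_date + 31 + int(rng.integers(0, 335))
        out.extend(timeline)
    return out


def sample_risk_dataset(config: CohortConfig, n: int, seed: int | None = None):
    """Draw ``n`` i.i.d. (covariates, outcome) pairs from the admission-level
    risk model — the covariate/outcome law of the cohort without the
    admission scaffolding. Returns ``(X, y, p_true)``.

    Used for model benchmarking where only the classification problem
    matters (e.g. nonlinear-vs-linear separation experiments).
    """
    config.validate()
    sd = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([sd % (2**31), 3]))
    intercept = config.intercept if config.intercept is not None \
        else _calibrate_intercept(config)
    X = np.empty((n, config.n_covariates))
    for i in range(n):
        X[i] = _draw_covariates(rng, config)
    p = np.array([_admission_risk(X[i], intercept, rng, config) for i in range(n)])
    y = (rng.random(n) < p).astype(int)
    return X, y, p


# -- plain-text persistence ----------------------------------------------------

def write_cohort(records: list[AdmissionRecord], out_dir: str,
                 config: CohortConfig | None = None) -> None:
    """Write one CSV per data type plus a JSON config sidecar and notes JSONL."""
    os.makedirs(out_dir, exist_ok=True)

    def _w(name, header, rows):
        with open(os.path.join(out_dir, name), "w", newline="") as f:
            wr = csv.writer(f)
            wr.writerow(header)
            wr.writerows(rows)

    seen = set()
    demo_rows = []
    for r in records:
        if r.patient_id not in seen:
            seen.add(r.patient_id)
            d = r.demographics
            demo_rows.append([r.patient_id, d.get("age", ""), d.get("gender", ""),
                              d.get("marital_status", "")])
    _w("demographics.csv", ["patient_id", "age", "gender", "marital_status"], demo_rows)
    _w("admissions.csv",
       ["patient_id", "admit_date", "discharge_date", "disposition", "planned",
        "principal_code", "true_risk", "measures_json"],
       [[r.patient_id, r.admit_date, r.discharge_date, r.disposition,
         int(r.planned), r.principal_code, repr(r.true_risk),
         json.dumps(r.admission_measures)] for r in records])
    _w("diagnoses.csv", ["patient_id", "admit_date", "code", "event_date"],
       [[r.patient_id, r.admit_date, c, d] for r in records for c, d in r.diagnosis_codes])
    _w("procedures.csv", ["patient_id", "admit_date", "code", "event_date"],
       [[r.patient_id, r.admit_date, c, d] for r in records for c, d in r.procedure_codes])
    _w("medications.csv", ["patient_id", "admit_date", "code", "event_date"],
       [[r.patient_id, r.admit_date, c, d] for r in records for c, d in r.medication_events])
    _w("labs.csv", ["patient_id", "admit_date", "code", "event_date", "abnormal"],
       [[r.patient_id, r.admit_date, c, d, int(a)]
        for r in records for c, d, a in r.lab_events])
    with open(os.path.join(out_dir, "notes.jsonl"), "w") as f:
        for r in records:
            for ns in r.note_sections:
                f.write(json.dumps({
                    "patient_id": r.patient_id, "admit_date": r.admit_date,
                    "note_type": ns.note_type, "section": ns.section,
                    "date": ns.date, "tokens": ns.tokens}) + "\n")
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["linear_weights"] = list(cfg["linear_weights"])
        cfg["nonlinear_pairs"] = [list(p) for p in cfg["nonlinear_pairs"]]
        if cfg["intercept"] is not None and not math.isfinite(cfg["intercept"]):
            cfg["intercept"] = repr(cfg["intercept"])
        with open(os.path.join(out_dir, "config.json"), "w") as f:
            json.dump(cfg, f, indent=1)


def read_cohort(in_dir: str) -> list[AdmissionRecord]:
    """Read a cohort previously written by :func:`write_cohort`."""
    def _rows(name):
        path = os.path.join(in_dir, name)
        if not os.path.exists(path):
            return []
        with open(path, newline="") as f:
            return list(csv.DictReader(f))

    demo = {r["patient_id"]: {"age": float(r["age"]), "gender": r["gender"],
                              "marital_status": r["marital_status"]}
            for r in _rows("demographics.csv")}
    recs: dict[tuple, AdmissionRecord] = {}
    for r in _rows("admissions.csv"):
        key = (r["patient_id"], int(r["admit_date"]))
        recs[key] = AdmissionRecord(
            patient_id=r["patient_id"],
            admit_date=int(r["admit_date"]),
            discharge_date=int(r["discharge_date"]),
            disposition=r["disposition"],
            planned=bool(int(r["planned"])),
            principal_code=r["principal_code"],
            demographics=demo.get(r["patient_id"], {}),
            admission_measures=json.loads(r["measures_json"]),
            true_risk=float(r["true_risk"]),
        )
    for name, attr in (("diagnoses.csv", "diagnosis_codes"),
                       ("procedures.csv", "procedure_codes"),
                       ("medications.csv", "medication_events")):
        for r in _rows(name):
            rec = recs[(r["patient_id"], int(r["admit_date"]))]
            getattr(rec, attr).append((r["code"], int(r["event_date"])))
    for r in _rows("labs.csv"):
        rec = recs[(r["patient_id"], int(r["admit_date"]))]
        rec.lab_events.append((r["code"], int(r["event_date"]), bool(int(r["abnormal"]))))
    notes_path = os.path.join(in_dir, "notes.jsonl")
    if os.path.exists(notes_path):
        with open(notes_path) as f:
            for line in f:
                d = json.loads(line)
                rec = recs[(d["patient_id"], int(d["admit_date"]))]
                rec.note_sections.append(
                    NoteSection(d["note_type"], d["section"], d["date"], d["tokens"]))
    return sorted(recs.values(), key=lambda r: (r.patient_id, r.admit_date))
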