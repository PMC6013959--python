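"""Feature-vector generation and total-KL-divergence variable filtering.

Admission-level EMR records become a numeric feature matrix through:

* windowed value expressions per data type — diagnoses as binary
  occurrence over the two years before discharge; labs as abnormal-result
  counts in the first week after admission and the last week before
  discharge (two variables per test); medications and procedures as
  occurrence counts during the stay; admission-level continuous measures;
  patient-level demographics;
* clinical-note bag-of-words over sections present in at least half of
  the notes of their note type, with corpus-rare words removed;
* 1-of-K expansion of categoricals, zero imputation of missing values,
  and per-variable min–max scaling to [0, 1];
* variable filtering by total (symmetrized) Kullback–Leibler divergence
  between the readmitted and non-readmitted class-conditional
  distributions, keeping variables with divergence >= mean + sd/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import LabeledAdmission

__all__ = [
    "FeatureSpec", "FeatureMatrix", "KLReport", "Window", "Expression",
    "extract_windowed_features", "select_note_sections", "build_bow",
    "MinMaxZeroEncoder", "encode_and_scale",
    "TotalKLDivergenceSelector", "total_kl_divergence",
]

logger = logging.getLogger(__name__)

DAYS_2Y = 730
DAYS_WEEK = 7


class Window(str, Enum):
    patient_level = "patient_level"
    admit_to_discharge = "admit_to_discharge"
    two_years_pre_discharge = "two_years_pre_discharge"
    admit_plus_7d = "admit_plus_7d"
    discharge_minus_7d = "discharge_minus_7d"
    penultimate_to_admit = "penultimate_to_admit"


class Expression(str, Enum):
    binary_occurrence = "binary_occurrence"
    occurrence_count = "occurrence_count"
    abnormal_count = "abnormal_count"
    continuous = "continuous"


#: admissible (data_type, window, expression) rows
_SPEC_ROWS = {
    ("demographics", Window.patient_level, Expression.continuous),
    ("demographics", Window.patient_level, Expression.binary_occurrence),
    ("admissions", Window.admit_to_discharge, Expression.continuous),
    ("diagnoses", Window.two_years_pre_discharge, Expression.binary_occurrence),
    ("labs", Window.admit_plus_7d, Expression.abnormal_count),
    ("labs", Window.discharge_minus_7d, Expression.abnormal_count),
    ("medications", Window.admit_to_discharge, Expression.occurrence_count),
    ("procedures", Window.admit_to_discharge, Expression.occurrence_count),
    ("notes", Window.admit_to_discharge, Expression.binary_occurrence),
    ("notes", Window.admit_to_discharge, Expression.occurrence_count),
    ("notes", Window.penultimate_to_admit, Expression.binary_occurrence),
}

_KNOWN_DATA_TYPES = {r[0] for r in _SPEC_ROWS}


@dataclass(frozen=True)
class FeatureSpec:
    variable_name: str
    data_type: str
    window: Window
    expression: Expression

    def __post_init__(self):
        if self.data_type not in _KNOWN_DATA_TYPES:
            raise ValueError(f"unknown data type: {self.data_type!r}")
        if (self.data_type, self.window, self.expression) not in _SPEC_ROWS:
            raise ValueError(
                f"({self.data_type}, {self.window.value}, {self.expression.value}) "
                "is not an admissible data-type/window/expression combination")


@dataclass
class FeatureMatrix:
    """Dense n x p matrix in [0, 1] with column metadata and outcome labels."""

    values: np.ndarray
    columns: list
    labels: np.ndarray
    row_keys: list

    @property
    def shape(self):
        return self.values.shape


def resolve_window(window: Window, rec, prev_discharge: int | None = None):
    """Inclusive integer-day interval for a window, or ``None`` (patient level)."""
    a, d = rec.admit_date, rec.discharge_date
    if window is Window.patient_level:
        return None
    if window is Window.admit_to_discharge:
        return (a, d)
    if window is Window.two_years_pre_discharge:
        return (d - DAYS_2Y, d)
    if window is Window.admit_plus_7d:
        return (a, a + DAYS_WEEK)
    if window is Window.discharge_minus_7d:
        return (d - DAYS_WEEK, d)
    if window is Window.penultimate_to_admit:
        # (previous admission's discharge, current admission date]
        lo = (prev_discharge + 1) if prev_discharge is not None else a - DAYS_2Y
        return (lo, a)
    raise ValueError(window)


def _in_window(day: int, win) -> bool:
    return win is None or (win[0] <= day <= win[1])


def _apply_lookup(code: str, table: dict | None, missed: list) -> str:
    if table is None:
        return code
    if code in table:
        return table[code]
    missed.append(code)
    return code


def select_note_sections(labeled: list[LabeledAdmission],
                         min_presence: float = 0.5) -> dict[str, set]:
    """Sections present in >= ``min_presence`` of notes, per note type.

    A "note" is one (admission, note type) document; a section is present
    in it if any tokens were recorded under that header.
    """
    totals: dict[str, int] = {}
    counts: dict[str, dict[str, int]] = {}
    for lab in labeled:
        by_type: dict[str, set] = {}
        for ns in lab.record.note_sections:
            by_type.setdefault(ns.note_type, set()).add(ns.section)
        for ntype, secs in by_type.items():
            totals[ntype] = totals.get(ntype, 0) + 1
            d = counts.setdefault(ntype, {})
            for s in secs:
                d[s] = d.get(s, 0) + 1
    return {ntype: {s for s, c in d.items() if c / totals[ntype] >= min_presence}
            for ntype, d in counts.items()}


def build_bow(documents: list[list[str]], normalizer=None,
              min_total_count: int = 6, prefix: str = "w") -> pd.DataFrame:
    """Bag-of-words variables: per retained word a count column
    (``{prefix}_cnt_{word}``) and a binary-presence column
    (``{prefix}_bin_{word}``).

    ``normalizer`` is any deterministic token -> token-or-None hook
    (default: lowercasing). Words whose corpus-wide total count is below
    ``min_total_count`` (i.e. appearing <= min_total_count - 1 times) are
    removed.
    """
    if normalizer is None:
        normalizer = str.lower
    norm_docs = []
    totals: dict[str, int] = {}
    for doc in documents:
        nd = []
        for tok in doc:
            t = normalizer(tok)
            if t:
                nd.append(t)
                totals[t] = totals.get(t, 0) + 1
        norm_docs.append(nd)
    vocab = sorted(w for w, c in totals.items() if c >= min_total_count)
    idx = {w: j for j, w in enumerate(vocab)}
    counts = np.zeros((len(documents), len(vocab)))
    for i, nd in enumerate(norm_docs):
        for t in nd:
            j = idx.get(t)
            if j is not None:
                counts[i, j] += 1
    cols = {}
    for j, w in enumerate(vocab):
        cols[f"{prefix}_cnt_{w}"] = counts[:, j]
        cols[f"{prefix}_bin_{w}"] = (counts[:, j] > 0).astype(float)
    return pd.DataFrame(cols)


def extract_windowed_features(labeled: list[LabeledAdmission],
                              lookups: dict[str, dict] | None = None,
                              min_section_presence: float = 0.5,
                              bow_min_total_count: int = 6) -> pd.DataFrame:
    """Raw (unscaled, un-encoded) feature table over countable admissions.

    ``lookups`` optionally maps data types (``"medications"``,
    ``"diagnoses"``, ...) to two-column source->target code tables (e.g.
    drug code -> ATC level 5); unmapped codes pass through under their raw
    identity and the mapping coverage fraction is logged.
    """
    lookups = lookups or {}
    for dt in lookups:
        if dt not in _KNOWN_DATA_TYPES:
            raise ValueError(f"lookup table for unknown data type: {dt!r}")
    rows = [l for l in labeled if l.is_countable]

    prev_discharge: dict[int, int | None] = {}
    last_seen: dict[str, int] = {}
    for l in sorted(labeled, key=lambda l: (l.record.patient_id, l.record.admit_date)):
        pid = l.record.patient_id
        prev_discharge[id(l)] = last_seen.get(pid)
        last_seen[pid] = l.record.discharge_date

    missed: dict[str, list] = {dt: [] for dt in _KNOWN_DATA_TYPES}
    mapped_total: dict[str, int] = {dt: 0 for dt in _KNOWN_DATA_TYPES}

    def _lk(dt, code):
        mapped_total[dt] += 1
        return _apply_lookup(code, lookups.get(dt), missed[dt])

    base_rows = []
    for l in rows:
        r = l.record
        row: dict[str, float | str] = {}
        for k, v in r.demographics.items():
            row[f"demo_{k}"] = v
        row["adm_length_of_stay"] = float(r.discharge_date - r.admit_date)
        row["adm_cumulative_prior_30day_readmissions"] = \
            float(l.cumulative_prior_30day_readmissions)
        for k, v in r.admission_measures.items():
            row[f"adm_{k}"] = float(v)
        win = resolve_window(Window.two_years_pre_discharge, r)
        for code, day in r.diagnosis_codes:
            if _in_window(day, win):
                row[f"dx_{_lk('diagnoses', code)}"] = 1.0
        win = resolve_window(Window.admit_to_discharge, r)
        for code, day in r.medication_events:
            if _in_window(day, win):
                key = f"rx_{_lk('medications', code)}"
                row[key] = row.get(key, 0.0) + 1.0
        for code, day in r.procedure_codes:
            if _in_window(day, win):
                key = f"px_{_lk('procedures', code)}"
                row[key] = row.get(key, 0.0) + 1.0
        win_a = resolve_window(Window.admit_plus_7d, r)
        win_d = resolve_window(Window.discharge_minus_7d, r)
        for code, day, abnormal in r.lab_events:
            if not abnormal:
                continue
            c = _lk("labs", code)
            if _in_window(day, win_a):
                key = f"lab_{c}_admit7"
                row[key] = row.get(key, 0.0) + 1.0
            if _in_window(day, win_d):
                key = f"lab_{c}_dis7"
                row[key] = row.get(key, 0.0) + 1.0
        base_rows.append(row)
    table = pd.DataFrame(base_rows).reset_index(drop=True)
    # absent event variables are structural zeros, not missing measurements
    event_cols = [c for c in table.columns
                  if c.split("_")[0] in ("dx", "rx", "px", "lab")]
    if event_cols:
        table[event_cols] = table[event_cols].fillna(0.0)

    # notes: BOW per retained section; binary-presence variables except the
    # allergies section, which keeps counts; social history uses the
    # penultimate-discharge-to-admission window
    retained = select_note_sections(rows, min_presence=min_section_presence)
    note_frames = []
    for ntype, sections in sorted(retained.items()):
        for section in sorted(sections):
            window = (Window.penultimate_to_admit if section == "social_history"
                      else Window.admit_to_discharge)
            docs = []
            for l in rows:
                win = resolve_window(window, l.record, prev_discharge[id(l)])
                toks: list[str] = []
                for ns in l.record.note_sections:
                    if (ns.note_type == ntype and ns.section == section
                            and _in_window(ns.date, win)):
                        toks.extend(ns.tokens)
                docs.append(toks)
            bow = build_bow(docs, min_total_count=bow_min_total_count,
                            prefix=f"note_{section}")
            wanted = "_cnt_" if section == "allergies" else "_bin_"
            bow = bow[[c for c in bow.columns if wanted in c]]
            note_frames.append(bow.reset_index(drop=True))
    if note_frames:
        table = pd.concat([table] + note_frames, axis=1)

    for dt, tab in lookups.items():
        if tab and mapped_total[dt]:
            cov = 1.0 - len(missed[dt]) / mapped_total[dt]
            logger.info("%s code mapping coverage: %.1f%% (%d unmapped events)",
                        dt, 100 * cov, len(missed[dt]))
    return table


class MinMaxZeroEncoder(TransformerMixin, BaseEstimator):
    """1-of-K expansion of categoricals, zero imputation, min–max scaling.

    Fit learns the category sets and per-column minima/maxima on the
    training data only; transform zero-fills missing entries, one-hot
    expands, affinely maps each column so train-min -> 0 and train-max -> 1,
    and clips to [0, 1]. Constant columns map to all zeros. Already-scaled
    data passes through unchanged (the transform is idempotent).
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.cat_columns_ = [c for c in X.columns
                             if X[c].dtype == object or str(X[c].dtype) == "category"]
        self.categories_ = {c: sorted(X[c].dropna().astype(str).unique())
                            for c in self.cat_columns_}
        num = self._expand(X)
        self.feature_names_out_ = list(num.columns)
        vals = num.to_numpy(dtype=float)
        vals = np.nan_to_num(vals, nan=0.0)
        self.min_ = vals.min(axis=0) if len(vals) else np.zeros(vals.shape[1])
        self.max_ = vals.max(axis=0) if len(vals) else np.ones(vals.shape[1])
        return self

    def _expand(self, X: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in X.columns:
            if c in getattr(self, "cat_columns_", []) or X[c].dtype == object:
                cats = self.categories_.get(c, sorted(X[c].dropna().astype(str).unique()))
                s = X[c].astype(str)
                for cat in cats:
                    out[f"{c}={cat}"] = (s == cat).astype(float).to_numpy()
            else:
                out[c] = X[c].to_numpy(dtype=float)
        return pd.DataFrame(out, index=X.index)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "min_")
        X = pd.DataFrame(X)
        num = self._expand(X)
        num = num.reindex(columns=self.feature_names_out_, fill_value=0.0)
        vals = np.nan_to_num(num.to_numpy(dtype=float), nan=0.0)
        span = self.max_ - self.min_
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (vals - self.min_) / np.where(span > 0, span, 1.0)
        scaled[:, span <= 0] = 0.0  # constant columns
        return np.clip(scaled, 0.0, 1.0)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


def encode_and_scale(raw: pd.DataFrame, labels=None,
                     row_keys=None) -> FeatureMatrix:
    """Fit-and-apply :class:`MinMaxZeroEncoder`, returning a FeatureMatrix."""
    enc = MinMaxZeroEncoder().fit(raw)
    values = enc.transform(raw)
    labels = np.zeros(len(raw), dtype=int) if labels is None \
        else np.asarray(labels, dtype=int)
    row_keys = list(range(len(raw))) if row_keys is None else list(row_keys)
    return FeatureMatrix(values=values, columns=list(enc.feature_names_out_),
                         labels=labels, row_keys=row_keys)


@dataclass
class KLReport:
    divergence: np.ndarray
    threshold: float
    keep_mask: np.ndarray
    smoothing_epsilon: float


def _class_distributions(col: np.ndarray, y: np.ndarray, eps: float, n_bins: int):
    """Class-conditional cell probabilities: Bernoulli cells for 0/1 columns,
    equal-width histogram over the pooled range otherwise."""
    uniq = np.unique(col)
    if np.isin(uniq, (0.0, 1.0)).all():
        edges = np.array([-0.5, 0.5, 1.5])
    else:
        lo, hi = col.min(), col.max()
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
    p_cnt = np.histogram(col[y == 1], bins=edges)[0].astype(float) + eps
    q_cnt = np.histogram(col[y == 0], bins=edges)[0].astype(float) + eps
    return p_cnt / p_cnt.sum(), q_cnt / q_cnt.sum()


def total_kl_divergence(X, y, eps: float = 1e-9, n_bins: int = 10) -> KLReport:
    """Per-variable total (symmetrized) KL divergence between the
    readmitted (P) and non-readmitted (Q) class-conditional distributions,
    ``D = KL(P||Q) + KL(Q||P)``, with the retention rule
    ``D >= mean(D) + sd(D)/2``.

    Distributions are additively smoothed with ``eps`` pseudo-mass per
    cell so empty cells never produce infinite divergence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    D = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        p, q = _class_distributions(X[:, j], y, eps, n_bins)
        D[j] = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
    tau = float(D.mean() + 0.5 * D.std())
    return KLReport(divergence=D, threshold=tau, keep_mask=D >= tau,
                    smoothing_epsilon=eps)


class TotalKLDivergenceSelector(TransformerMixin, BaseEstimator):
    """Feature selector keeping variables whose total KL divergence between
    outcome classes is at least ``mean + sd/2`` of all variables'
    divergences (see :func:`total_kl_divergence`).
    """

    def __init__(self, eps: float = 1e-9, n_bins: int = 10):
        self.eps = eps
        self.n_bins = n_bins

    def fit(self, X, y):
        report = total_kl_divergence(X, y, eps=self.eps, n_bins=self.n_bins)
        self.divergence_ = report.divergence
        self.threshold_ = report.threshold
        self.support_ = report.keep_mask
        if not self.support_.any():
            warnings.warn("KL filter would drop every variable; keeping all")
            self.support_ = np.ones_like(report.keep_mask)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_
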