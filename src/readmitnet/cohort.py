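"""Index-admission / 30-day-readmission labeling and cohort summaries.

Every hospitalization is an index admission with potential for a
readmission: an index is flagged when the next *countable* admission of
the same patient begins within 30 days of its discharge (same-day
counts; the gap is ``next.admit_date - index.discharge_date`` in whole
days). Planned admissions, within-hospital transfers, and stays ending
against medical advice are excluded: they are neither evaluated as
indexes nor eligible to serve as readmissions, and they are invisible
to the gap computation. A readmission may itself be an index for a
subsequent readmission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .synthetic import AdmissionRecord

__all__ = ["LabeledAdmission", "DataError", "label_readmissions",
           "cohort_summary", "rate_from_counts"]

logger = logging.getLogger(__name__)

READMIT_WINDOW_DAYS = 30


class DataError(ValueError):
    """Raised for unsorted or overlapping stays; lists the offending patients."""


@dataclass
class LabeledAdmission:
    record: AdmissionRecord
    is_countable: bool
    days_to_next_countable_admission: int | None = None
    has_30day_readmission: bool = False
    cumulative_prior_30day_readmissions: int = 0

    @property
    def label(self) -> int:
        return int(self.has_30day_readmission)


def _is_countable(rec: AdmissionRecord) -> bool:
    return not rec.planned and rec.disposition == "routine"


def label_readmissions(records: list[AdmissionRecord]) -> list[LabeledAdmission]:
    """Label each admission with the 30-day readmission outcome.

    ``records`` may arrive in any order; within a patient they are sorted
    by admit date (ties broken by discharge date, then input order).
    Overlapping stays for one patient raise :class:`DataError`.
    """
    by_patient: dict[str, list[tuple[int, AdmissionRecord]]] = {}
    for i, rec in enumerate(records):
        by_patient.setdefault(rec.patient_id, []).append((i, rec))

    bad_patients = []
    labeled: list[tuple[int, LabeledAdmission]] = []
    for pid, items in by_patient.items():
        order = sorted(items, key=lambda t: (t[1].admit_date, t[1].discharge_date, t[0]))
        recs = [r for _, r in order]
        for a, b in zip(recs, recs[1:]):
            if a.admit_date == b.admit_date:
                logger.info("patient %s: two admissions start day %d; tie broken "
                            "by discharge date then record order", pid, a.admit_date)
            if b.admit_date < a.discharge_date:
                bad_patients.append(pid)
                break
        if pid in bad_patients:
            continue
        countable = [_is_countable(r) for r in recs]
        cum = 0
        for k, rec in enumerate(recs):
            lab = LabeledAdmission(record=rec, is_countable=countable[k],
                                   cumulative_prior_30day_readmissions=cum)
            if countable[k]:
                nxt = next((recs[m] for m in range(k + 1, len(recs)) if countable[m]), None)
                if nxt is not None:
                    gap = nxt.admit_date - rec.discharge_date
                    lab.days_to_next_countable_admission = gap
                    lab.has_30day_readmission = 0 <= gap <= READMIT_WINDOW_DAYS
                if lab.has_30day_readmission:
                    cum += 1
            labeled.append((order[k][0], lab))
    if bad_patients:
        raise DataError(f"overlapping stays for patients: {sorted(set(bad_patients))}")
    labeled.sort(key=lambda t: t[0])  # restore input order
    return [lab for _, lab in labeled]


def rate_from_counts(flagged: int, total: int) -> float:
    """Percentage ``100 * flagged / total`` reported to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * flagged / total, 1)


def cohort_summary(labeled: list[LabeledAdmission],
                   code_subset: set | None = None) -> dict:
    """Cohort-level counts and rates, with an optional principal-code cross-tab.

    With ``code_subset`` (e.g. the heart-failure codes), index->readmission
    pairs are cross-tabulated: how many flagged indexes and how many of
    their readmissions carry a subset code, the overlap where both do, and
    the share of code-specific readmissions whose index was also
    code-specific.
    """
    if not labeled:
        raise ValueError("empty labeled admission list")
    countable = [l for l in labeled if l.is_countable]
    flagged = [l for l in countable if l.has_30day_readmission]
    n_countable = len(countable)
    summary = {
        "n_admissions": len(labeled),
        "n_countable": n_countable,
        "n_flagged": len(flagged),
        "readmission_rate_pct": rate_from_counts(len(flagged), n_countable)
        if n_countable else 0.0,
    }
    if code_subset is not None:
        # pair each flagged index with its realized readmission
        by_patient: dict[str, list[LabeledAdmission]] = {}
        for l in labeled:
            by_patient.setdefault(l.record.patient_id, []).append(l)
        n_index_rel = n_readmit_rel = n_both = 0
        for pid, ls in by_patient.items():
            ls = sorted(ls, key=lambda l: (l.record.admit_date, l.record.discharge_date))
            cnt = [l for l in ls if l.is_countable]
            for k, l in enumerate(cnt):
                if not l.has_30day_readmission:
                    continue
                readmit = cnt[k + 1]
                idx_rel = l.record.principal_code in code_subset
                re_rel = readmit.record.principal_code in code_subset
                n_index_rel += idx_rel
                n_readmit_rel += re_rel
                n_both += idx_rel and re_rel
        summary["crosstab"] = {
            "n_index_code_related": n_index_rel,
            "n_readmission_code_related": n_readmit_rel,
            "n_both_code_related": n_both,
            "pct_index_related_of_flagged": rate_from_counts(n_index_rel, len(flagged))
            if flagged else 0.0,
            "pct_overlap_of_flagged": rate_from_counts(n_both, len(flagged))
            if flagged else 0.0,
            "pct_related_readmissions_with_related_index":
                rate_from_counts(n_both, n_readmit_rel) if n_readmit_rel else 0.0,
        }
    return summary
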