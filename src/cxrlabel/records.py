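"""HIS report parsing, PA-view filtering and study–report matching.

The hospital information system (HIS) exports one XML document per batch of
assessment-and-treatment *sessions*.  A session carries the patient id and
the check-in/check-out window and contains the radiology reports written
during that stay.  Imaging studies live on the PACS side and are described
here by a manifest row: study id, patient id, acquisition timestamp and the
probability (from an upstream frontal-view classifier) that the image is a
posterior-anterior chest radiograph.

Matching a study to its report uses three predicates:

1. same patient id,
2. ``|report_time − study_time| ≤ window`` (24 h by default, the hospital's
   reporting protocol),
3. ``check_in_time ≤ study_time ≤ check_out_time``.

A study with exactly one candidate report is paired.  When several
candidates exist and their normalized descriptions are identical the study
is paired to the earliest-reported candidate (the reports are
interchangeable); when the descriptions differ the study is routed to a
manual review queue.  One report may serve several studies, but each study
receives at most one report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .textnorm import normalize

__all__ = [
    "RadiologyReport",
    "ImagingStudy",
    "MatchResult",
    "parse_his_sessions",
    "filter_pa_views",
    "match_records",
    "qc_sample",
    "read_study_manifest",
    "write_match_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RadiologyReport:
    """One radiology report with its session context."""

    session_id: str
    patient_id: str
    check_in_time: datetime
    check_out_time: datetime
    service_id: str
    report_time: datetime
    description: str

    def __post_init__(self) -> None:
        if self.check_in_time > self.check_out_time:
            raise ValueError(
                f"session {self.session_id}: check_in_time after check_out_time"
            )


@dataclass(frozen=True)
class ImagingStudy:
    """One imaging study's metadata row."""

    study_id: str
    patient_id: str
    study_time: datetime
    pa_probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pa_probability <= 1.0):
            raise ValueError(
                f"study {self.study_id}: pa_probability {self.pa_probability} "
                "outside [0, 1]"
            )


@dataclass
class MatchResult:
    """Partition of the study set produced by :func:`match_records`."""

    pairs: list[tuple[str, RadiologyReport]] = field(default_factory=list)
    unmatched_studies: list[ImagingStudy] = field(default_factory=list)
    unmatched_reports: list[RadiologyReport] = field(default_factory=list)
    manual_queue: list[tuple[str, list[RadiologyReport]]] = field(
        default_factory=list
    )


_MANDATORY_SESSION = ("SESSION_ID", "PATIENT_ID", "CHECK_IN_TIME", "CHECK_OUT_TIME")
_MANDATORY_REPORT = ("SERVICE_ID", "REPORT_TIME")


def _parse_ts(value: str, where: str) -> datetime:
    try:
        return datetime.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"{where}: bad timestamp {value!r}") from exc


def parse_his_sessions(
    xml_document: str | bytes,
    service_ids: Iterable[str] | None = None,
) -> list[RadiologyReport]:
    """Parse a HIS session export into :class:`RadiologyReport` records.

    Parameters
    ----------
    xml_document:
        The export text: a ``<SESSIONS>`` root of ``<SESSION>`` elements,
        each holding ``<REPORT>`` children with a ``<DESCRIPTION>`` text
        node.  Timestamps are ISO-8601 on a single hospital clock.
    service_ids:
        The set of chest-radiography service codes to keep.  Reports whose
        ``SERVICE_ID`` is not in this set are dropped (the HIS mixes chest
        films with ultrasound, CT, …).  ``None`` keeps every report.

    Reports missing a mandatory field are skipped with a warning; malformed
    XML raises immediately.
    """
    keep = None if service_ids is None else {str(s) for s in service_ids}
    if isinstance(xml_document, str):
        xml_document = xml_document.encode("utf-8")
    try:
        root = etree.fromstring(xml_document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed HIS XML: {exc}") from exc
    if root.tag != "SESSIONS":
        raise ValueError(f"expected <SESSIONS> root, found <{root.tag}>")

    reports: list[RadiologyReport] = []
    for session in root.iterfind("SESSION"):
        missing = [k for k in _MANDATORY_SESSION if not session.get(k)]
        if missing:
            logger.warning("session skipped: missing %s", ", ".join(missing))
            continue
        sid = session.get("SESSION_ID")
        try:
            check_in = _parse_ts(session.get("CHECK_IN_TIME"), f"session {sid}")
            check_out = _parse_ts(session.get("CHECK_OUT_TIME"), f"session {sid}")
        except ValueError as exc:
            logger.warning("session %s skipped: %s", sid, exc)
            continue
        for rep in session.iterfind("REPORT"):
            missing = [k for k in _MANDATORY_REPORT if not rep.get(k)]
            desc_el = rep.find("DESCRIPTION")
            if desc_el is None or desc_el.text is None:
                missing.append("DESCRIPTION")
            if missing:
                logger.warning(
                    "report in session %s skipped: missing %s",
                    sid,
                    ", ".join(missing),
                )
                continue
            service = rep.get("SERVICE_ID")
            if keep is not None and service not in keep:
                continue
            try:
                rtime = _parse_ts(rep.get("REPORT_TIME"), f"session {sid} report")
                reports.append(
                    RadiologyReport(
                        session_id=sid,
                        patient_id=session.get("PATIENT_ID"),
                        check_in_time=check_in,
                        check_out_time=check_out,
                        service_id=service,
                        report_time=rtime,
                        description=desc_el.text,
                    )
                )
            except ValueError as exc:
                logger.warning("report in session %s skipped: %s", sid, exc)
    return reports


def filter_pa_views(
    studies: Sequence[ImagingStudy], threshold: float = 0.5
) -> tuple[list[ImagingStudy], list[ImagingStudy]]:
    """Partition studies into PA views (probability strictly above
    ``threshold``) and ignored studies."""
    kept: list[ImagingStudy] = []
    ignored: list[ImagingStudy] = []
    for s in studies:
        if not (0.0 <= s.pa_probability <= 1.0):
            raise ValueError(
                f"study {s.study_id}: pa_probability outside [0, 1]"
            )
        (kept if s.pa_probability > threshold else ignored).append(s)
    return kept, ignored


def _is_candidate(
    study: ImagingStudy, report: RadiologyReport, window_hours: float
) -> bool:
    if study.patient_id != report.patient_id:
        return False
    delta_h = abs((report.report_time - study.study_time).total_seconds()) / 3600.0
    if delta_h > window_hours:
        return False
    return report.check_in_time <= study.study_time <= report.check_out_time


def match_records(
    studies: Sequence[ImagingStudy],
    reports: Sequence[RadiologyReport],
    window_hours: float = 24.0,
) -> MatchResult:
    """Match each imaging study to at most one radiology report.

    See the module docstring for the three predicates and the duplicate
    handling.  The result partitions the study set: every study appears in
    exactly one of ``pairs``, ``unmatched_studies`` or ``manual_queue``.
    """
    seen: set[str] = set()
    for s in studies:
        if s.study_id in seen:
            raise ValueError(f"duplicate study_id {s.study_id!r}")
        seen.add(s.study_id)

    result = MatchResult()
    used_reports: set[int] = set()
    for study in studies:
        candidates = [r for r in reports if _is_candidate(study, r, window_hours)]
        if not candidates:
            result.unmatched_studies.append(study)
            continue
        if len(candidates) == 1:
            chosen = candidates[0]
        else:
            descs = {normalize(r.description) for r in candidates}
            if len(descs) > 1:
                result.manual_queue.append((study.study_id, candidates))
                continue
            # interchangeable duplicates: deterministic earliest-report pick
            chosen = min(
                candidates, key=lambda r: (r.report_time, r.session_id)
            )
            logger.info(
                "study %s: %d identical candidate reports, paired to "
                "earliest (session %s)",
                study.study_id,
                len(candidates),
                chosen.session_id,
            )
        result.pairs.append((study.study_id, chosen))
        used_reports.add(id(chosen))
    result.unmatched_reports = [r for r in reports if id(r) not in used_reports]
    return result


def qc_sample(
    manifest: pd.DataFrame, fraction: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Draw the quality-control sample: ``⌈fraction·n⌉`` rows uniformly
    without replacement, reproducible for a fixed seed."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    n = len(manifest)
    if n == 0:
        raise ValueError("empty manifest")
    k = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return manifest.iloc[idx]


def read_study_manifest(path) -> list[ImagingStudy]:
    """Read a ``study_id,patient_id,study_time,pa_probability`` CSV."""
    df = pd.read_csv(path, dtype={"study_id": str, "patient_id": str}, comment="#")
    required = {"study_id", "patient_id", "study_time", "pa_probability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study manifest missing columns: {sorted(missing)}")
    return [
        ImagingStudy(
            study_id=row.study_id,
            patient_id=row.patient_id,
            study_time=datetime.fromisoformat(row.study_time),
            pa_probability=float(row.pa_probability),
        )
        for row in df.itertuples(index=False)
    ]


def write_match_csv(result: MatchResult, path) -> pd.DataFrame:
    """Serialise a :class:`MatchResult` as the
    ``study_id,report_session_id,report_time,status`` CSV."""
    rows = []
    for study_id, report in result.pairs:
        rows.append(
            {
                "study_id": study_id,
                "report_session_id": report.session_id,
                "report_time": report.report_time.isoformat(),
                "status": "matched",
            }
        )
    for study in result.unmatched_studies:
        rows.append(
            {
                "study_id": study.study_id,
                "report_session_id": "",
                "report_time": "",
                "status": "unmatched",
            }
        )
    for study_id, _cands in result.manual_queue:
        rows.append(
            {
                "study_id": study_id,
                "report_session_id": "",
                "report_time": "",
                "status": "manual",
            }
        )
    df = pd.DataFrame(
        rows, columns=["study_id", "report_session_id", "report_time", "status"]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
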