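"""Synthetic report corpora and matching fixtures with known ground truth.

No hospital chest X-ray report corpus with this labeling scheme is publicly
deposited, so the pipeline is exercised end-to-end on generated data.  Two
generators are provided:

* :func:`generate_corpus` emits Vietnamese-style report descriptions in the
  four-category dash-separated layout (chest wall — pleura — parenchyma —
  cardio) with per-class positivity sampled independently at configurable
  prevalences.  Negative studies reuse a normality template; positive
  classes embed a keyword drawn from the lexicon.  An optional misspelling
  process corrupts the embedded evidence (one random character substitution
  per embedded phrase) so the report can no longer be auto-labeled — such
  rows are expected to land in the manual queue, never to be silently
  mislabeled.
* :func:`generate_matching_fixture` emits an imaging-study manifest plus a
  conforming HIS XML export with known correct pairings, including
  duplicate-report cases (identical and differing descriptions) and
  reports displaced beyond the matching window.

Default prevalences are the deployment-scale marginals (chest wall 2.37%,
pleura 2.22%, parenchyma 21.72%, cardio 7.83%).  Both generators are pure
functions of their configuration and seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from lxml import etree

from .labeler import CLASSES, LABEL_COLUMNS, Lexicon, load_lexicon
from .records import ImagingStudy
from .textnorm import normalize

__all__ = [
    "SynthConfig",
    "generate_corpus",
    "generate_matching_fixture",
    "seed_lexicon_path",
    "load_seed_lexicon",
    "DEFAULT_PREVALENCE",
    "DEFAULT_SERVICE_ID",
]

#: Deployment-scale marginal prevalences of the four region classes.
DEFAULT_PREVALENCE: dict[str, float] = {
    "chest_wall": 0.0237,
    "pleura": 0.0222,
    "parenchyma": 0.2172,
    "cardio": 0.0783,
}

#: Service code used for chest radiography in generated HIS exports.
DEFAULT_SERVICE_ID = "CXR-PA"

# per-category benign filler sentences; none contains a lexicon keyword or
# a full normality template
_FILLERS: dict[str, str] = {
    "chest_wall": "khung xương lồng ngực cân đối",
    "pleura": "góc sườn hoành hai bên rõ",
    "parenchyma": "nhu mô phổi hai bên đồng đều",
    "cardio": "bóng tim kích thước bình thường",
}


def seed_lexicon_path() -> str:
    """Path of the packaged seed lexicon file."""
    from importlib.resources import files

    return str(files("cxrlabel") / "data" / "seed_lexicon.yaml")


def load_seed_lexicon() -> Lexicon:
    """Load the packaged seed lexicon (example keywords per class plus the
    synthetic normality templates)."""
    return load_lexicon(seed_lexicon_path())


@dataclass
class SynthConfig:
    """Corpus-generation conditions.

    ``class_prevalence`` are marginal positivity rates sampled
    independently per class; ``other_abnormal_rate`` is the rate of
    findings outside the four regions; ``misspell_rate`` is the fraction of
    keyword-bearing reports whose embedded evidence is corrupted (these are
    expected to require manual annotation); ``n_normal_templates`` is the
    size of the no-findings template pool.
    """

    n_reports: int = 10_000
    class_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    other_abnormal_rate: float = 0.005
    misspell_rate: float = 0.01
    n_normal_templates: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for cls, p in self.class_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {cls!r} outside [0, 1]")
        for name in ("other_abnormal_rate", "misspell_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_normal_templates < 1:
            raise ValueError("n_normal_templates must be >= 1")


def _corrupt(phrase: str, rng: np.random.Generator, forbidden: list[str]) -> str:
    """Substitute one character so that the phrase no longer contains any
    lexicon entry."""
    letters = [i for i, ch in enumerate(phrase) if ch.isalpha()]
    for _ in range(20):
        i = int(rng.choice(letters))
        repl = string.ascii_lowercase[int(rng.integers(26))]
        if repl == phrase[i]:
            continue
        cand = phrase[:i] + repl + phrase[i + 1:]
        if not any(kw in normalize(cand) for kw in forbidden):
            return cand
    raise RuntimeError(f"could not corrupt phrase {phrase!r}")  # pragma: no cover


def generate_corpus(
    config: SynthConfig, lexicon: Lexicon | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Generate report descriptions with their ground-truth label table.

    Returns ``(descriptions, truth)`` where ``truth`` has columns
    ``study_id``, the five labels and ``status``: ``auto`` for cleanly
    labelable rows, ``manual_pending`` for rows whose evidence was
    corrupted by the misspelling process (their labels record the
    generating intent).
    """
    if lexicon is None:
        lexicon = load_seed_lexicon()
    for cls in CLASSES:
        if config.class_prevalence.get(cls, 0.0) > 0 and not lexicon.expanded_keywords[cls]:
            raise ValueError(f"prevalence > 0 for class {cls!r} with empty keyword list")
    if config.other_abnormal_rate > 0 and not lexicon.expanded_keywords["other"]:
        raise ValueError("other_abnormal_rate > 0 with empty 'other' keyword list")
    if config.n_normal_templates > len(lexicon.normal_templates):
        raise ValueError(
            f"n_normal_templates={config.n_normal_templates} exceeds the "
            f"lexicon's {len(lexicon.normal_templates)} templates"
        )
    templates = lexicon.normal_templates[: config.n_normal_templates]
    all_variants = [
        kw for cls in (*CLASSES, "other") for kw in lexicon.expanded_keywords[cls]
    ]

    rng = np.random.default_rng(config.seed)
    descriptions: list[str] = []
    rows: list[dict] = []
    for i in range(config.n_reports):
        flags = {
            cls: int(rng.random() < config.class_prevalence.get(cls, 0.0))
            for cls in CLASSES
        }
        other = int(rng.random() < config.other_abnormal_rate)
        abnormal = int(any(flags.values()) or other)

        if not abnormal:
            desc = templates[int(rng.integers(len(templates)))] + "."
            status = "auto"
        else:
            segments = []
            embedded: list[str] = []
            for cls in CLASSES:
                if flags[cls]:
                    pool = lexicon.expanded_keywords[cls]
                    phrase = pool[int(rng.integers(len(pool)))]
                    embedded.append(phrase)
                    segments.append(phrase)
                else:
                    segments.append(_FILLERS[cls])
            if other:
                pool = lexicon.expanded_keywords["other"]
                phrase = pool[int(rng.integers(len(pool)))]
                embedded.append(phrase)
                segments.append(phrase)
            status = "auto"
            if rng.random() < config.misspell_rate:
                # corrupt every embedded phrase: a partially corrupted row
                # would be auto-labeled with a wrong vector, whereas the
                # intended failure mode is the manual queue
                segments = [
                    _corrupt(s, rng, all_variants) if s in embedded else s
                    for s in segments
                ]
                status = "manual_pending"
            desc = "- " + " - ".join(segments) + "."
        descriptions.append(desc)
        row = {"study_id": f"r{i:06d}", **flags, "abnormal": abnormal, "status": status}
        rows.append(row)

    truth = pd.DataFrame(rows, columns=["study_id", *LABEL_COLUMNS, "status"])
    return descriptions, truth


def _session_xml(
    parent: etree._Element,
    session_id: str,
    patient_id: str,
    check_in: datetime,
    check_out: datetime,
    reports: list[tuple[datetime, str]],
) -> None:
    sess = etree.SubElement(
        parent,
        "SESSION",
        SESSION_ID=session_id,
        PATIENT_ID=patient_id,
        CHECK_IN_TIME=check_in.isoformat(),
        CHECK_OUT_TIME=check_out.isoformat(),
    )
    for rtime, desc in reports:
        rep = etree.SubElement(
            sess, "REPORT", SERVICE_ID=DEFAULT_SERVICE_ID, REPORT_TIME=rtime.isoformat()
        )
        etree.SubElement(rep, "DESCRIPTION").text = desc


def generate_matching_fixture(
    n_patients: int,
    dup_rate: float = 0.0,
    out_of_window_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[ImagingStudy], str, pd.DataFrame]:
    """Generate studies plus a HIS XML export with known correct pairings.

    Per patient: one session, one PA study inside the session window, and
    normally one report two hours after the study.  With probability
    ``dup_rate`` a second in-window report is added (identical description
    half the time → still matchable to the earliest report; differing
    description otherwise → manual review).  With probability
    ``out_of_window_rate`` the report is displaced 30 h from the study →
    no match.  Returns ``(studies, xml_text, truth)`` where ``truth`` has
    columns ``study_id, expected_status, expected_session_id``.
    """
    for name, v in (("dup_rate", dup_rate), ("out_of_window_rate", out_of_window_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} outside [0, 1]")
    rng = np.random.default_rng(seed)
    base = datetime(2021, 3, 1, 8, 0, 0)
    root = etree.Element("SESSIONS")
    studies: list[ImagingStudy] = []
    truth_rows: list[dict] = []

    for i in range(n_patients):
        patient_id = f"p{i:05d}"
        session_id = f"s{i:05d}"
        study_id = f"d{i:05d}"
        check_in = base + timedelta(days=i)
        check_out = check_in + timedelta(hours=48)
        study_time = check_in + timedelta(hours=6)
        studies.append(
            ImagingStudy(
                study_id=study_id,
                patient_id=patient_id,
                study_time=study_time,
                pa_probability=0.9,
            )
        )
        desc = f"- mô tả số {i} - không thấy bất thường."
        u = rng.random()
        if u < out_of_window_rate:
            reports = [(study_time + timedelta(hours=30), desc)]
            expected = "unmatched"
        elif u < out_of_window_rate + dup_rate:
            if rng.random() < 0.5:
                # interchangeable duplicates → earliest wins
                reports = [
                    (study_time + timedelta(hours=2), desc),
                    (study_time + timedelta(hours=5), desc),
                ]
                expected = "matched"
            else:
                reports = [
                    (study_time + timedelta(hours=2), desc),
                    (study_time + timedelta(hours=5), desc + " có tổn thương."),
                ]
                expected = "manual"
        else:
            reports = [(study_time + timedelta(hours=2), desc)]
            expected = "matched"
        _session_xml(root, session_id, patient_id, check_in, check_out, reports)
        truth_rows.append(
            {
                "study_id": study_id,
                "expected_status": expected,
                "expected_session_id": session_id if expected == "matched" else "",
            }
        )

    xml_text = etree.tostring(
        root, encoding="unicode", pretty_print=True
    )
    truth = pd.DataFrame(truth_rows)
    return studies, xml_text, truth
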