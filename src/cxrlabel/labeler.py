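"""Semi-automated rule-based annotation of Vietnamese radiology reports.

A report description is turned into five binary labels — abnormality of the
chest wall, pleura, lung parenchyma, cardiac silhouette, and a global
``abnormal`` flag — by a four-stage pipeline:

1. **Pattern filtering** — a fixed set of *normality templates* (report
   phrasings that by themselves assert "no findings"); a description
   containing one verbatim is normal.
2. **Keyword detection** — per-class keyword lists; a description containing
   a keyword of a class is positive for that class.  An extra "other
   abnormality" list catches findings outside the four regions (e.g. free
   air under the diaphragm).
3. **Abnormality interpolating** — ``abnormal`` is the logical OR of the
   four region flags and the other-abnormality flag.
4. **Manual queue** — descriptions matching neither a template nor any
   keyword (likely misspelled or describing rare pathology) are routed to a
   human annotator.

All comparisons are substring containment over :func:`~cxrlabel.textnorm.
normalize`-canonicalized text.  A description that matches a template but
also contains an abnormality keyword takes the keyword path (abnormal
evidence wins) and raises a lexicon-conflict warning.  There is no negation
handling: normality is encoded by templates, not by negated findings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .textnorm import normalize

__all__ = [
    "CLASSES",
    "LABEL_COLUMNS",
    "Lexicon",
    "LabelVector",
    "load_lexicon",
    "expand_variants",
    "is_normal_template",
    "detect_keywords",
    "interpolate_abnormal",
    "annotate",
    "split_sections",
    "resolve_manual",
    "labels_frame",
    "read_labels_csv",
]

logger = logging.getLogger(__name__)

#: The four anatomical region classes, in canonical order.
CLASSES: tuple[str, ...] = ("chest_wall", "pleura", "parenchyma", "cardio")

#: Region classes plus the interpolated global flag.
LABEL_COLUMNS: tuple[str, ...] = CLASSES + ("abnormal",)

_ALTERNATION_RE = re.compile(r"(\S+)\s*/\s*(\S+)")
_PAREN_RE = re.compile(r"\s*\(([^()]+)\)")


def expand_variants(keyword: str) -> list[str]:
    """Expand the shorthand used in keyword lists into concrete phrases.

    Two notations are supported, at most one alternation per keyword:

    * left/right alternation: ``"dày màng phổi trái/phải"`` →
      ``["dày màng phổi trái", "dày màng phổi phải"]``;
    * parenthesized abbreviation: ``"quai động mạch chủ (đmc) vồng"`` →
      the spelled-out phrase and, when the abbreviation's letters are the
      initials of the preceding words, the abbreviated phrase
      (``"quai đmc vồng"``).

    Keywords without shorthand return themselves.
    """
    kw = normalize(keyword)
    variants = [kw]

    m = _PAREN_RE.search(kw)
    if m is not None:
        spelled = (kw[: m.start()] + kw[m.end():]).strip()
        spelled = re.sub(r"\s+", " ", spelled)
        variants = [spelled]
        abbr = m.group(1).strip()
        prefix_words = kw[: m.start()].split()
        k = len(abbr)
        if k and len(prefix_words) >= k:
            tail = prefix_words[-k:]
            if "".join(w[0] for w in tail) == abbr:
                abbreviated = " ".join(prefix_words[:-k] + [abbr]) + kw[m.end():]
                variants.append(re.sub(r"\s+", " ", abbreviated).strip())
        if len(variants) == 1:
            # abbreviation does not decode against the prefix; keep the
            # literal parenthesized form as the second variant
            variants.append(kw)

    out: list[str] = []
    for v in variants:
        matches = list(_ALTERNATION_RE.finditer(v))
        if len(matches) > 1:
            raise ValueError(
                f"keyword {keyword!r}: multiple alternation groups unsupported"
            )
        if matches:
            m = matches[0]
            out.append((v[: m.start()] + m.group(1) + v[m.end():]).strip())
            out.append((v[: m.start()] + m.group(2) + v[m.end():]).strip())
        else:
            out.append(v)
    # dedupe, order-preserving
    seen: set[str] = set()
    return [v for v in out if not (v in seen or seen.add(v))]


@dataclass
class Lexicon:
    """Normality templates plus per-class abnormality keyword lists.

    All entries are canonicalized on construction and left/right and
    abbreviation shorthand is expanded into ``expanded_keywords``.  A
    keyword may not appear in two different lists.
    """

    normal_templates: list[str]
    class_keywords: dict[str, list[str]]
    other_keywords: list[str] = field(default_factory=list)
    expanded_keywords: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.normal_templates:
            raise ValueError("lexicon has no normality templates")
        self.normal_templates = [normalize(t) for t in self.normal_templates]
        if any(not t for t in self.normal_templates):
            raise ValueError("empty normality template after normalization")
        for i, a in enumerate(self.normal_templates):
            for j, b in enumerate(self.normal_templates):
                if i != j and a in b:
                    logger.warning(
                        "template %r is a substring of template %r; the "
                        "shorter one shadows the longer", a, b,
                    )

        self.class_keywords = {
            cls: [normalize(k) for k in self.class_keywords.get(cls, [])]
            for cls in CLASSES
        }
        self.other_keywords = [normalize(k) for k in self.other_keywords]

        expanded: dict[str, list[str]] = {}
        owner: dict[str, str] = {}
        for cls in (*CLASSES, "other"):
            raw = (
                self.other_keywords if cls == "other" else self.class_keywords[cls]
            )
            if any(not k for k in raw):
                raise ValueError(f"empty keyword in class {cls!r}")
            bucket: list[str] = []
            for kw in raw:
                for variant in expand_variants(kw):
                    if variant in owner and owner[variant] != cls:
                        raise ValueError(
                            f"keyword {variant!r} appears in both "
                            f"{owner[variant]!r} and {cls!r}"
                        )
                    owner[variant] = cls
                    if variant not in bucket:
                        bucket.append(variant)
            expanded[cls] = bucket
        self.expanded_keywords = expanded


def load_lexicon(path) -> Lexicon:
    """Load a UTF-8 YAML lexicon file.

    Expected keys: ``normal_templates`` (list) and ``keywords`` with
    sub-lists ``chest_wall``, ``pleura``, ``parenchyma``, ``cardio`` and
    ``other``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: lexicon file must be a mapping")
    keywords = doc.get("keywords", {})
    return Lexicon(
        normal_templates=list(doc.get("normal_templates", [])),
        class_keywords={cls: list(keywords.get(cls, [])) for cls in CLASSES},
        other_keywords=list(keywords.get("other", [])),
    )


@dataclass
class LabelVector:
    """Five binary labels plus annotation provenance.

    ``status`` is ``auto`` for rule-derived labels, ``manual_pending`` for
    descriptions awaiting human review (labels meaningless until resolved),
    and ``manual_resolved`` after :func:`resolve_manual`.  ``evidence``
    records every ``(class, matched phrase)`` hit.
    """

    chest_wall: int = 0
    pleura: int = 0
    parenchyma: int = 0
    cardio: int = 0
    abnormal: int = 0
    status: str = "auto"
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in LABEL_COLUMNS:
            if getattr(self, col) not in (0, 1):
                raise ValueError(f"label {col} must be 0 or 1")
        if self.status not in ("auto", "manual_pending", "manual_resolved"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status != "manual_pending" and self.abnormal < max(
            self.chest_wall, self.pleura, self.parenchyma, self.cardio
        ):
            raise ValueError("abnormal must be 1 when any region label is 1")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (
            self.chest_wall,
            self.pleura,
            self.parenchyma,
            self.cardio,
            self.abnormal,
        )


def is_normal_template(description: str, lexicon: Lexicon) -> bool:
    """True iff a normality template appears verbatim (as a normalized
    substring) in the description."""
    desc = normalize(description)
    return any(t in desc for t in lexicon.normal_templates)


def detect_keywords(
    description: str, lexicon: Lexicon
) -> tuple[dict[str, int], int, list[tuple[str, str]]]:
    """Scan the whole description for per-class and other-abnormality
    keywords.

    Returns ``(flags, other_flag, evidence)`` where ``flags[c]`` is 1 iff
    any expanded keyword of class ``c`` occurs as a substring.
    """
    desc = normalize(description)
    flags = {cls: 0 for cls in CLASSES}
    other_flag = 0
    evidence: list[tuple[str, str]] = []
    for cls in (*CLASSES, "other"):
        for phrase in lexicon.expanded_keywords[cls]:
            if phrase in desc:
                evidence.append((cls, phrase))
                if cls == "other":
                    other_flag = 1
                else:
                    flags[cls] = 1
    return flags, other_flag, evidence


def interpolate_abnormal(flags: Mapping[str, int], other_flag: int) -> int:
    """Global abnormality: OR of the four region flags and the
    other-abnormality flag."""
    return int(any(flags[cls] for cls in CLASSES) or bool(other_flag))


def annotate(
    description: str,
    lexicon: Lexicon,
    template_match: str = "contains",
) -> LabelVector:
    """Run the full pipeline on one raw description.

    ``template_match`` selects how "a template exactly appears" is read:
    ``"contains"`` (default; templates may be embedded in longer text) or
    ``"equals"`` (the whole normalized description must equal a template).

    Deterministic for a fixed lexicon: a pure function of the normalized
    description.
    """
    if template_match not in ("contains", "equals"):
        raise ValueError(f"unknown template_match {template_match!r}")
    desc = normalize(description)
    if not desc:
        logger.warning("empty description routed to manual queue")
        return LabelVector(status="manual_pending")

    flags, other_flag, evidence = detect_keywords(desc, lexicon)
    if template_match == "contains":
        template_hit = any(t in desc for t in lexicon.normal_templates)
    else:
        template_hit = desc in lexicon.normal_templates

    if any(flags.values()) or other_flag:
        if template_hit:
            logger.warning(
                "lexicon conflict: description matches a normality template "
                "but contains abnormality keyword(s) %s; keyword path wins",
                [p for _, p in evidence],
            )
        return LabelVector(
            **flags,
            abnormal=interpolate_abnormal(flags, other_flag),
            status="auto",
            evidence=evidence,
        )
    if template_hit:
        return LabelVector(status="auto")
    return LabelVector(status="manual_pending")


# a dash opens a category when it is not glued to a word on its left:
# start of string, or after whitespace / sentence-terminal punctuation.
# Intra-word hyphens ("x-quang") never split.
_SECTION_RE = re.compile(r"(?:^|(?<=\s)|(?<=[.!?;:\n]))-\s*")


def split_sections(description: str) -> list[str]:
    """Split a normalized description into its dash-separated category
    segments (reports list findings per anatomical region, one dash-led
    segment each).  Used for lexicon curation, not label assignment."""
    desc = normalize(description)
    parts = [p.strip() for p in _SECTION_RE.split(desc)]
    if len(parts) > 1 and parts[0] == "":
        parts = parts[1:]
    return parts if parts else [""]


def resolve_manual(
    vector: LabelVector, assigned: Sequence[int]
) -> LabelVector:
    """Apply a human annotator's five labels to a pending vector."""
    if vector.status != "manual_pending":
        raise ValueError(
            f"cannot resolve a vector with status {vector.status!r}"
        )
    labels = tuple(int(x) for x in assigned)
    if len(labels) != 5 or any(x not in (0, 1) for x in labels):
        raise ValueError("assigned labels must be five binaries")
    if labels[4] < max(labels[:4]):
        raise ValueError("abnormal must be 1 when any region label is 1")
    return LabelVector(
        chest_wall=labels[0],
        pleura=labels[1],
        parenchyma=labels[2],
        cardio=labels[3],
        abnormal=labels[4],
        status="manual_resolved",
        evidence=list(vector.evidence),
    )


def labels_frame(
    study_ids: Iterable[str], vectors: Iterable[LabelVector]
) -> pd.DataFrame:
    """Assemble the label table
    ``study_id,chest_wall,pleura,parenchyma,cardio,abnormal,status,evidence``."""
    rows = []
    for sid, vec in zip(study_ids, vectors, strict=True):
        row = {"study_id": sid}
        row.update(dict(zip(LABEL_COLUMNS, vec.as_tuple())))
        row["status"] = vec.status
        row["evidence"] = ";".join(f"{c}:{p}" for c, p in vec.evidence)
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["study_id", *LABEL_COLUMNS, "status", "evidence"]
    )


def read_labels_csv(path) -> pd.DataFrame:
    """Read a label CSV produced by :func:`labels_frame`."""
    df = pd.read_csv(path, dtype={"study_id": str}, comment="#", keep_default_na=False)
    missing = {"study_id", *LABEL_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    for col in LABEL_COLUMNS:
        df[col] = df[col].astype(int)
    return df
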