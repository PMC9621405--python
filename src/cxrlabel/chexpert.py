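"""Mapping CheXpert's 14 observations onto the five coarse region classes.

The 14-observation scheme (No Finding, Enlarged Cardiomediastinum,
Cardiomegaly, Lung Lesion, Lung Opacity, Edema, Consolidation, Pneumonia,
Atelectasis, Pneumothorax, Pleural Effusion, Pleural Other, Fracture,
Support Devices) is collapsed by anatomical location: fractures are chest
wall; pneumothorax and pleural findings are pleura; the six lung findings
are parenchyma; the two cardiac findings are cardio.  ``abnormal`` is
positive for every observation except No Finding — including Support
Devices, which marks the film abnormal without a region.

The mapping is a join-homomorphism: each coarse label is the OR over its
positive fine observations, so mapping the OR of two fine vectors equals
the OR of their mappings.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .labeler import CLASSES, LABEL_COLUMNS, LabelVector

__all__ = ["OBSERVATIONS", "COARSE_FROM_FINE", "map_fine_to_coarse", "batch_map"]

logger = logging.getLogger(__name__)

#: The fixed ordered observation set (CheXpert train.csv header names).
OBSERVATIONS: tuple[str, ...] = (
    "No Finding",
    "Enlarged Cardiomediastinum",
    "Cardiomegaly",
    "Lung Lesion",
    "Lung Opacity",
    "Edema",
    "Consolidation",
    "Pneumonia",
    "Atelectasis",
    "Pneumothorax",
    "Pleural Effusion",
    "Pleural Other",
    "Fracture",
    "Support Devices",
)

# accepted spelling variants for the truncated header form
_ALIASES: dict[str, str] = {
    "Enlarged Cardiom": "Enlarged Cardiomediastinum",
    "Enlarged Cardiom.": "Enlarged Cardiomediastinum",
}

#: Coarse class → fine observations mapped positive for it.
COARSE_FROM_FINE: dict[str, tuple[str, ...]] = {
    "chest_wall": ("Fracture",),
    "pleura": ("Pneumothorax", "Pleural Effusion", "Pleural Other"),
    "parenchyma": (
        "Lung Lesion",
        "Lung Opacity",
        "Edema",
        "Consolidation",
        "Pneumonia",
        "Atelectasis",
    ),
    "cardio": ("Enlarged Cardiomediastinum", "Cardiomegaly"),
    "abnormal": tuple(o for o in OBSERVATIONS if o != "No Finding"),
}


def _canonical(name: str) -> str:
    name = name.strip()
    return _ALIASES.get(name, name)


def map_fine_to_coarse(fine: Mapping[str, int]) -> LabelVector:
    """Map one binary fine-label vector onto the five coarse classes.

    ``fine`` maps observation names (any subset of :data:`OBSERVATIONS`;
    absent observations count as negative) to {0, 1}.  A positive
    No Finding alongside positive observations triggers a warning and the
    positives win.
    """
    values: dict[str, int] = {}
    for name, v in fine.items():
        canon = _canonical(name)
        if canon not in OBSERVATIONS:
            raise ValueError(
                f"unknown observation {name!r}; accepted: {list(OBSERVATIONS)}"
            )
        if v not in (0, 1):
            raise ValueError(f"observation {name!r} has non-binary value {v!r}")
        values[canon] = int(v)
    if values.get("No Finding") and any(
        values.get(o) for o in OBSERVATIONS if o != "No Finding"
    ):
        logger.warning(
            "No Finding set alongside positive observations; positives win"
        )
    coarse = {
        cls: int(any(values.get(o) for o in COARSE_FROM_FINE[cls]))
        for cls in LABEL_COLUMNS
    }
    return LabelVector(**coarse, status="auto")


# CheXpert train.csv metadata columns that may accompany the observations
_ID_COLUMNS = ("study_id", "Path", "Sex", "Age", "Frontal/Lateral", "AP/PA")


def batch_map(
    table: pd.DataFrame, uncertain_policy: str = "to_negative"
) -> pd.DataFrame:
    """Row-wise :func:`map_fine_to_coarse` over a fine-label table.

    Column names must match the observation set (order-insensitive; the
    CheXpert ``train.csv`` header is accepted, and its metadata columns
    such as ``Path`` are carried through untouched as leading columns).
    Any other column name is an error.  CheXpert uncertainty labels (−1)
    are resolved by ``uncertain_policy``: ``"to_negative"`` (default) or
    ``"to_positive"``; blanks count negative.
    """
    if uncertain_policy not in ("to_negative", "to_positive"):
        raise ValueError(f"unknown uncertain_policy {uncertain_policy!r}")
    obs_cols = [c for c in table.columns if _canonical(c) in OBSERVATIONS]
    unknown = [
        c for c in table.columns if c not in obs_cols and c not in _ID_COLUMNS
    ]
    if unknown:
        raise ValueError(
            f"unknown columns {unknown}; accepted observation names: "
            f"{list(OBSERVATIONS)}"
        )
    if not obs_cols:
        raise ValueError(
            f"no observation columns found; accepted names: {list(OBSERVATIONS)}"
        )

    fine = table[obs_cols].fillna(0)
    fine = fine.replace(-1, 1 if uncertain_policy == "to_positive" else 0)
    bad = ~fine.isin((0, 1)).all(axis=None)
    if bad:
        raise ValueError("fine labels must be binary (or -1 uncertain)")

    rows = []
    for rec in fine.astype(int).to_dict("records"):
        vec = map_fine_to_coarse(rec)
        rows.append(dict(zip(LABEL_COLUMNS, vec.as_tuple())))
    out = pd.DataFrame(rows, columns=list(LABEL_COLUMNS), index=table.index)
    out["status"] = "auto"
    carried = [c for c in table.columns if c not in obs_cols]
    if carried:
        out = pd.concat([table[carried], out], axis=1)
    return out
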