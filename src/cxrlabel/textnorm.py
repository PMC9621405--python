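"""Canonicalization of Vietnamese free text.

Report descriptions arrive from hospital information systems with mixed
Unicode composition forms (Vietnamese IMEs emit both precomposed and
combining-mark spellings), inconsistent casing and ragged whitespace.
Template containment and keyword search are exact substring operations, so
every string that enters a comparison is first reduced to one canonical
form:

* Unicode NFC (composed) normalization,
* lower-casing,
* all dash-like characters unified to ``-``,
* whitespace collapsed to single ASCII spaces, outer whitespace stripped.

``normalize`` is total on strings and idempotent.  Punctuation other than
dashes is preserved: lexicon entries may legitimately contain parentheses
(abbreviations such as ``(đmc)``).
"""

from __future__ import annotations

import re
import unicodedata

__all__ = ["normalize"]

# hyphen, non-breaking hyphen, figure dash, en dash, em dash, horizontal
# bar, minus sign — all seen in hospital exports, all mean the category
# separator here
_DASHES = "‐‑‒–—―−"
_DASH_RE = re.compile("[%s]" % _DASHES)
_WS_RE = re.compile(r"\s+")


def normalize(raw: str) -> str:
    """Return the canonical form of ``raw``.

    Idempotent: ``normalize(normalize(x)) == normalize(x)``.  The sequence
    of non-whitespace, non-dash letters is unchanged apart from case and
    composition form.
    """
    if not isinstance(raw, str):
        raise TypeError(f"expected str, got {type(raw).__name__}")
    text = unicodedata.normalize("NFC", raw)
    text = text.lower()
    # lower() can denormalize some scripts; re-compose so the result is a
    # fixed point of the whole pipeline
    text = unicodedata.normalize("NFC", text)
    text = _DASH_RE.sub("-", text)
    text = _WS_RE.sub(" ", text).strip()
    return text
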