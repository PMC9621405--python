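"""Annotate a handful of Vietnamese report descriptions.

Each description is run through the four-stage labeler (template filtering,
keyword detection, abnormality interpolation, manual routing) with the
packaged seed lexicon.  The printed vector is
(chest_wall, pleura, parenchyma, cardio, abnormal); `manual_pending` means
the description matched neither a normality template nor any keyword and
would be forwarded to a radiologist.
"""

from cxrlabel import annotate, load_seed_lexicon

lexicon = load_seed_lexicon()

descriptions = [
    # a no-findings template embedded in boilerplate -> all-negative
    "kết luận: tim và phổi trong giới hạn bình thường. tái khám sau 6 tháng.",
    # two keywords from different classes -> parenchyma + cardio
    "dải mờ giữa phổi trái. hình tim trái to.",
    # abbreviation variant of the aortic-arch keyword -> cardio
    "theo dõi quai đmc vồng.",
    # free air under the diaphragm: outside the four regions -> abnormal only
    "liềm hơi dưới vòm hoành phải.",
    # misspelled fracture, no template, no keyword -> manual queue
    "gaỹ xưong đòn trái.",
]

for desc in descriptions:
    vec = annotate(desc, lexicon)
    print(f"{vec.as_tuple()}  {vec.status:<15} {desc}")
    for cls, phrase in vec.evidence:
        print(f"    evidence: {cls} <- {phrase!r}")
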