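# cxrlabel

Tools for building labeled chest X-ray (CXR) datasets from Vietnamese
free-text radiology reports — for hospitals whose imaging lives in a PACS
and whose reports live in an HIS, and for researchers who need structured
multi-label ground truth without asking radiologists to annotate every
film.

English rule-based report labelers (CheXpert, NegBio, …) do not transfer
to Vietnamese clinical text, and no Vietnamese medical lexicon exists to
drive the usual NLP systems. `cxrlabel` implements a deliberately simple,
auditable alternative: a semi-automated pipeline that links each imaging
study to its report and converts the report into five binary labels —
**chest wall**, **pleura**, **parenchyma** (lung tissue), **cardio**, and
a global **abnormal** flag.

## The pipeline

1. **PA-view filtering** — keep studies whose posterior-anterior view
   probability `p > 0.5` (the probability comes from an upstream image
   classifier and is consumed, not computed, here).
2. **XML parsing** — read HIS session exports (`SESSION_ID`, `PATIENT_ID`,
   check-in/check-out times; per report `SERVICE_ID`, `REPORT_TIME`,
   `DESCRIPTION`), keeping only chest-radiography service codes.
3. **Record matching** — study *s* matches report *r* iff
   `patient(s) = patient(r)`, `|t_report − t_study| ≤ 24 h`, and
   `t_study ∈ [check_in, check_out]`. A study with one candidate is
   paired; several candidates with identical normalized descriptions pair
   to the earliest report; differing candidates go to manual review.
4. **Annotation** — for normalized description *d* with normality-template
   set *T* and per-class keyword sets *K_c*:
   * if some keyword of *K_c* occurs in *d*, class *c* := 1;
   * `abnormal := ∨_c class_c ∨ other`, where *other* flags findings
     outside the four regions (e.g. free air under the diaphragm);
   * else if some template *t ∈ T* appears verbatim in *d*, all labels 0;
   * else *d* joins the **manual queue** for a radiologist.
5. **Evaluation & bookkeeping** — per-class TP/FP/TN/FN, precision,
   recall, F1 and macro averages against human ground truth; 95%
   percentile-bootstrap confidence intervals (3,000 row resamples,
   2.5/97.5 percentiles); stratified 7/3 train/validation split that
   preserves per-class prevalence; random 5% quality-control sampling.

A separate module maps CheXpert-style 14-observation labels onto the same
five classes (fracture → chest wall; pneumothorax/effusion/pleural other →
pleura; the six lung findings → parenchyma; cardiomegaly/enlarged
cardiomediastinum → cardio; everything but No Finding → abnormal), and a
synthetic-data module generates report corpora and matching fixtures with
known ground truth so the whole pipeline is testable without hospital
data.

## Worked example

```python
from cxrlabel import annotate, load_seed_lexicon

lexicon = load_seed_lexicon()
vec = annotate("dải mờ giữa phổi trái. hình tim trái to.", lexicon)
print(vec.as_tuple(), vec.status)   # (0, 0, 1, 1, 1) auto
print(vec.evidence)                 # [('parenchyma', 'dải mờ giữa phổi trái'),
                                    #  ('cardio', 'hình tim trái to')]
```

The description contains a mid-lung opacity keyword (parenchyma) and a
cardiomegaly keyword (cardio); `abnormal` is their OR. Running
`python examples/annotate_reports.py` prints, among others:

```
(0, 0, 0, 0, 0)  auto            kết luận: tim và phổi trong giới hạn bình thường. ...
(0, 0, 1, 1, 1)  auto            dải mờ giữa phổi trái. hình tim trái to.
(0, 0, 0, 0, 1)  auto            liềm hơi dưới vòm hoành phải.
(0, 0, 0, 0, 0)  manual_pending  gaỹ xưong đòn trái.
```

— a template-matched normal film, two keyword-labeled abnormal films
(the last positive only in the global flag: free air under the diaphragm
belongs to none of the four regions) and a misspelled description routed
to the manual queue. The other scripts in `examples/` demonstrate record
matching, the 14→5 mapping, and the evaluation/split machinery; each
prints the numbers it computes with a note on their meaning.

A thin CLI mirrors the stages (`cxrlabel parse | match | label |
map-chexpert | evaluate | split | simulate | qc-sample`); every output CSV
carries a provenance header with the package version, seed and
configuration hash.

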