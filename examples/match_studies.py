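"""Match imaging studies to radiology reports on a generated fixture.

Builds a small synthetic hospital export (studies + HIS XML with known
correct pairings, including duplicate reports and out-of-window reports),
parses the XML, runs the three-predicate matcher (patient id, 24-hour
reporting window, session interval) and compares with the ground truth.
"""

from cxrlabel import match_records, parse_his_sessions
from cxrlabel.synth import DEFAULT_SERVICE_ID, generate_matching_fixture

studies, xml, truth = generate_matching_fixture(
    n_patients=40, dup_rate=0.25, out_of_window_rate=0.15, seed=8
)
reports = parse_his_sessions(xml, service_ids={DEFAULT_SERVICE_ID})
result = match_records(studies, reports, window_hours=24)

print(f"{len(studies)} studies, {len(reports)} chest-radiography reports")
print(f"matched:        {len(result.pairs)}")
print(f"unmatched:      {len(result.unmatched_studies)}")
print(f"manual review:  {len(result.manual_queue)}")

got = {sid: "matched" for sid, _ in result.pairs}
got.update({s.study_id: "unmatched" for s in result.unmatched_studies})
got.update({sid: "manual" for sid, _ in result.manual_queue})
expected = dict(zip(truth["study_id"], truth["expected_status"]))
print("agrees with fixture ground truth:", got == expected)
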