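"""Score the study instruments and apply the screening rules.

Shows BED-Q and MDI scoring with their severity bands, the eligibility
rule (severe BED or MDI > 40 excludes), and programme-completion
categorisation.
"""

from bedmot import (
    BedqResponse,
    MdiResponse,
    check_eligibility,
    classify_bedq_severity,
    completion_category,
    score_bedq,
    score_mdi,
)

resp = BedqResponse(items_1_7=(3, 2, 1, 0, 4, 5, 0), item_8=5, item_9_distress=True)
bedq = score_bedq(resp)
print(f"BED-Q sum (items 1-7 only): {bedq}  band: {classify_bedq_severity(bedq).name}")

mdi_total, mdi_band = score_mdi(MdiResponse(items=(3, 2, 3, 2, 3, 2, 3, 2, 2, 1)))
print(f"MDI total: {mdi_total}  band: {mdi_band.name}")

for bedq_score, mdi_score in [(15, 23), (22, 0), (10, 41)]:
    verdict = check_eligibility(bedq_score, mdi_score)
    status = "eligible" if verdict.eligible else f"excluded: {'; '.join(verdict.reasons)}"
    print(f"BED-Q {bedq_score:>2}, MDI {mdi_score:>2} -> {status}")

for sessions, followup in [(5, True), (10, False), (10, True)]:
    cat = completion_category(sessions, followup)
    print(f"{sessions} sessions, follow-up={followup} -> {cat.name}")
# 10 sessions without the follow-up questionnaire counts as High, not
# Full: Full is defined as all ten sessions *plus* follow-up.
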