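"""Score an olfactory quality-of-life questionnaire sheet.

Builds one complete 19-item sheet (17 negative + 2 positive statements)
and computes the LQrv raw score.
"""

from mcsqol import Answer, Polarity, QODResponseSheet, compute_lqrv

# A moderately impaired respondent: ten NS items "partly agree", seven
# NS "disagree", both PS "partly disagree".
responses = []
for i in range(1, 18):
    ans = Answer.PARTLY_AGREE if i <= 10 else Answer.DISAGREE
    responses.append((i, Polarity.NS, ans))
for i in (18, 19):
    responses.append((i, Polarity.PS, Answer.PARTLY_DISAGREE))

score = compute_lqrv(QODResponseSheet("P01", tuple(responses)))
print(f"NS subscore : {score.ns_score}")
print(f"PS subscore : {score.ps_score}")
print(f"LQrv        : {score.lqrv}")
print("LQrv ranges 0-57; higher means stronger olfactory-related "
      "impairment of daily life (cohort mean was about 28.7).")
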