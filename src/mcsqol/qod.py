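"""Scoring of the Questionnaire of Olfactory Disorders life-quality items.

Nineteen "life quality" statements are answered on a 4-level Likert scale.
Seventeen are negative statements (NS; agreeing indicates impairment) and
two are positive statements (PS; reverse-scored).  NS items score
agree→3, partly agree→2, partly disagree→1, disagree→0; PS items score the
mirror image.  The NS and PS sums add up to the life-quality raw score
LQrv ∈ [0, 57]; higher means stronger olfactory impairment.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Polarity(str, Enum):
    NS = "NS"
    PS = "PS"


class Answer(str, Enum):
    AGREE = "agree"
    PARTLY_AGREE = "partly_agree"
    PARTLY_DISAGREE = "partly_disagree"
    DISAGREE = "disagree"


#: points for an NS item; PS items are reverse-scored
_NS_POINTS = {
    Answer.AGREE: 3,
    Answer.PARTLY_AGREE: 2,
    Answer.PARTLY_DISAGREE: 1,
    Answer.DISAGREE: 0,
}

N_NS_ITEMS = 17
N_PS_ITEMS = 2
MAX_LQRV = 3 * (N_NS_ITEMS + N_PS_ITEMS)  # 57

#: default questionnaire layout: items 1-17 negative, 18-19 positive
DEFAULT_ITEM_POLARITIES: dict[int, Polarity] = {
    **{i: Polarity.NS for i in range(1, N_NS_ITEMS + 1)},
    **{i: Polarity.PS for i in range(N_NS_ITEMS + 1, N_NS_ITEMS + N_PS_ITEMS + 1)},
}


def score_item(polarity: Polarity | str, answer: Answer | str) -> int:
    """Points for a single questionnaire item.

    NS: agree→3 … disagree→0; PS: agree→0 … disagree→3.
    """
    polarity = Polarity(polarity)
    answer = Answer(answer)
    pts = _NS_POINTS[answer]
    return pts if polarity is Polarity.NS else 3 - pts


@dataclass(frozen=True)
class QODResponseSheet:
    """One subject's complete questionnaire: 17 NS + 2 PS answered items."""

    patient_id: str
    #: (item_index, polarity, answer) triples
    responses: tuple[tuple[int, Polarity, Answer], ...]

    def validate(self) -> None:
        indices = [i for i, _, _ in self.responses]
        if len(indices) != len(set(indices)):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise ValueError(
                f"patient {self.patient_id}: items answered more than once: {dupes}")
        n_ns = sum(1 for _, pol, _ in self.responses if Polarity(pol) is Polarity.NS)
        n_ps = len(self.responses) - n_ns
        if n_ns != N_NS_ITEMS or n_ps != N_PS_ITEMS:
            expected = set(DEFAULT_ITEM_POLARITIES)
            missing = sorted(expected - set(indices))
            raise ValueError(
                f"patient {self.patient_id}: incomplete sheet "
                f"({n_ns} NS and {n_ps} PS answers; expected {N_NS_ITEMS} NS + "
                f"{N_PS_ITEMS} PS; missing items {missing})")


@dataclass(frozen=True)
class LQrvScore:
    patient_id: str
    ns_score: int
    ps_score: int

    @property
    def lqrv(self) -> int:
        return self.ns_score + self.ps_score


def compute_lqrv(sheet: QODResponseSheet) -> LQrvScore:
    """Sum the per-item points of a complete sheet into the LQrv score.

    Raises ``ValueError`` for incomplete or duplicated sheets.
    """
    sheet.validate()
    ns = ps = 0
    for _, pol, ans in sheet.responses:
        pts = score_item(pol, ans)
        if Polarity(pol) is Polarity.NS:
            ns += pts
        else:
            ps += pts
    return LQrvScore(sheet.patient_id, ns, ps)
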