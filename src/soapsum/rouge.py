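"""ROUGE-1 / ROUGE-2 / ROUGE-L implemented from first principles.

ROUGE-n counts clipped n-gram co-occurrences: each candidate n-gram may
match at most as many times as it occurs in the reference.  Recall
divides the match count by the reference n-gram count, precision by the
candidate count.  ROUGE-L uses the length of the longest common
subsequence instead of n-gram matches.  No stemming or stopword removal
is applied; pair these scores with the same lowercase tokenizer used for
the notes so that training and evaluation see identical token streams.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = ["RougeComponent", "RougeScore", "rouge_n", "rouge_l", "rouge_score", "corpus_rouge"]


@dataclass(frozen=True)
class RougeComponent:
    """Precision/recall/F1 for one ROUGE variant."""

    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # set when an input was too short/empty

    @classmethod
    def from_counts(cls, matches: float, cand_total: float, ref_total: float) -> "RougeComponent":
        degenerate = cand_total == 0 or ref_total == 0
        p = matches / cand_total if cand_total > 0 else 0.0
        r = matches / ref_total if ref_total > 0 else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return cls(precision=p, recall=r, f1=f1, degenerate=degenerate)


@dataclass(frozen=True)
class RougeScore:
    """The three standard variants for one candidate/reference pair."""

    rouge1: RougeComponent
    rouge2: RougeComponent
    rougeL: RougeComponent


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def rouge_n(candidate: Sequence[str], reference: Sequence[str], n: int) -> RougeComponent:
    """Clipped n-gram overlap between a candidate and one reference.

    A reference shorter than ``n`` has no n-grams; the component is
    reported as zero with the ``degenerate`` flag set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cand = _ngrams(candidate, n)
    ref = _ngrams(reference, n)
    matches = sum(min(count, ref[gram]) for gram, count in cand.items())
    return RougeComponent.from_counts(matches, sum(cand.values()), sum(ref.values()))


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    # one-row dynamic program
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def rouge_l(candidate: Sequence[str], reference: Sequence[str]) -> RougeComponent:
    """Longest-common-subsequence overlap: R = LCS/|ref|, P = LCS/|cand|."""
    lcs = _lcs_length(candidate, reference)
    return RougeComponent.from_counts(lcs, len(candidate), len(reference))


def rouge_score(candidate: Sequence[str], reference: Sequence[str]) -> RougeScore:
    return RougeScore(
        rouge1=rouge_n(candidate, reference, 1),
        rouge2=rouge_n(candidate, reference, 2),
        rougeL=rouge_l(candidate, reference),
    )


def corpus_rouge(pairs: Sequence[tuple[Sequence[str], Sequence[str]]]) -> RougeScore:
    """Macro (sentence-level) average over (candidate, reference) pairs."""
    if not pairs:
        raise ValueError("corpus_rouge needs at least one pair")
    scores = [rouge_score(c, r) for c, r in pairs]

    def avg(variant: str) -> RougeComponent:
        comps = [getattr(s, variant) for s in scores]
        k = len(comps)
        return RougeComponent(
            precision=sum(c.precision for c in comps) / k,
            recall=sum(c.recall for c in comps) / k,
            f1=sum(c.f1 for c in comps) / k,
            degenerate=any(c.degenerate for c in comps),
        )

    return RougeScore(rouge1=avg("rouge1"), rouge2=avg("rouge2"), rougeL=avg("rougeL"))
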