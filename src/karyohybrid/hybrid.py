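"""Meiotic-additivity model for hybrid karyotypes.

A diploid with an even count of every chromosome type produces balanced
haploid gametes by strict halving; an F1 complement is the union of one
balanced gamete from each parent. A putative hybrid is *additive* with
respect to a parent pair when its observed per-type counts equal that
predicted union exactly. Type classes are matched at full resolution
(m and sm are distinct).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

from .errors import UnbalancedParentError
from .karyotype import TYPE_ORDER, KaryotypeSummary, format_formula

CountMap = Mapping[str, int]


def _counts_of(parent: CountMap | KaryotypeSummary) -> dict[str, int]:
    if isinstance(parent, KaryotypeSummary):
        return dict(parent.counts)
    return {t: int(n) for t, n in parent.items() if n}


@dataclass(frozen=True)
class GameteComposition:
    """A balanced haploid complement: per-type counts and total n."""

    counts: dict[str, int]
    n: int

    def formula(self) -> str:
        terms = [f"{self.counts[t]}{t}" for t in TYPE_ORDER if self.counts.get(t, 0)]
        return f"n = {self.n} = " + " + ".join(terms)


@dataclass(frozen=True)
class AdditivityResult:
    """Outcome of testing an observed complement against a parent pair."""

    consistent: bool
    predicted: dict[str, int]
    observed: dict[str, int]
    residual: dict[str, int]  # observed − predicted, per type
    parents: tuple[str, str] = ("parentA", "parentB")

    def to_dict(self) -> dict:
        return {
            "consistent": self.consistent,
            "parents": list(self.parents),
            "predicted": dict(self.predicted),
            "observed": dict(self.observed),
            "residual": dict(self.residual),
        }


def balanced_gamete(parent: CountMap | KaryotypeSummary) -> GameteComposition:
    """Halve every per-type count of a euploid parent into a balanced gamete.

    Raises :class:`UnbalancedParentError` on any odd per-type count — such a
    complement cannot halve into balanced gametes (aneuploid/unreduced
    gametes are outside this model).
    """
    counts = _counts_of(parent)
    odd = [t for t, n in counts.items() if n % 2]
    if odd:
        raise UnbalancedParentError(
            f"odd per-type counts {odd}: only balanced (euploid) gametes are "
            "modeled; aneuploid or unreduced gametes are not"
        )
    gamete = {t: n // 2 for t, n in counts.items() if n}
    return GameteComposition(counts=gamete, n=sum(gamete.values()))


def predict_f1(
    parent_a: CountMap | KaryotypeSummary, parent_b: CountMap | KaryotypeSummary
) -> tuple[dict[str, int], int]:
    """Predicted F1 complement: per-type sum of one balanced gamete per parent."""
    ga = balanced_gamete(parent_a)
    gb = balanced_gamete(parent_b)
    merged: dict[str, int] = {}
    for g in (ga, gb):
        for t, n in g.counts.items():
            merged[t] = merged.get(t, 0) + n
    return merged, ga.n + gb.n


def f1_formula(
    parent_a: CountMap | KaryotypeSummary, parent_b: CountMap | KaryotypeSummary
) -> str:
    counts, two_n = predict_f1(parent_a, parent_b)
    return format_formula(counts, two_n)


def additivity_test(
    observed: CountMap,
    parent_a: CountMap | KaryotypeSummary,
    parent_b: CountMap | KaryotypeSummary,
    labels: tuple[str, str] = ("parentA", "parentB"),
) -> AdditivityResult:
    """Test whether an observed complement equals the predicted F1 of a pair."""
    predicted, _ = predict_f1(parent_a, parent_b)
    obs = _counts_of(observed)
    residual = {
        t: obs.get(t, 0) - predicted.get(t, 0)
        for t in sorted(set(obs) | set(predicted), key=TYPE_ORDER.index)
    }
    consistent = all(v == 0 for v in residual.values())
    return AdditivityResult(
        consistent=consistent,
        predicted=predicted,
        observed=obs,
        residual=residual,
        parents=labels,
    )


def screen_parent_pairs(
    observed: CountMap, panel: Sequence[KaryotypeSummary]
) -> list[tuple[str, str]]:
    """All unordered panel pairs (self-pairs included) additive with ``observed``.

    Parents whose complements cannot form balanced gametes are simply never
    consistent. Pairs are returned sorted by taxon labels.
    """
    hits = []
    for a, b in combinations_with_replacement(sorted(panel, key=lambda s: s.taxon), 2):
        try:
            res = additivity_test(observed, a, b, labels=(a.taxon, b.taxon))
        except UnbalancedParentError:
            continue
        if res.consistent:
            hits.append((a.taxon, b.taxon))
    return sorted(hits)
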