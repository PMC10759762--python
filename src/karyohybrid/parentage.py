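"""Combine plastome maternal assignment with karyotype additivity.

The chloroplast genome is maternally inherited, so the candidate parent
whose plastome variants (against a common reference) best match the
hybrid's identifies the seed (♀) parent; nuclear karyotype additivity ties
in the other parent as pollen (♂) donor. Confidence is a margin-based
boolean — the parentage call is confident only when the karyotype is
exactly additive and the top cp candidate strictly outranks the runner-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError
from .hybrid import AdditivityResult
from .cp_variation import (
    VariantSet,
    shared_snp_sites,
    variant_set_symmetric_difference,
)


@dataclass
class CandidateScore:
    taxon: str
    shared_snp: int
    symmetric_difference: int

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "shared_snp_sites": self.shared_snp,
            "variant_symmetric_difference": self.symmetric_difference,
        }


@dataclass
class MaternalRanking:
    hybrid: str
    ranked: list[CandidateScore]
    margin: int

    @property
    def top(self) -> CandidateScore:
        return self.ranked[0]

    def to_dict(self) -> dict:
        return {
            "hybrid": self.hybrid,
            "ranked": [c.to_dict() for c in self.ranked],
            "margin": self.margin,
        }


@dataclass
class CrossReport:
    """Final parentage call: maternal (♀) × paternal (♂) with evidence."""

    hybrid: str
    maternal: str
    paternal: str
    cp_evidence: MaternalRanking
    karyotype_evidence: AdditivityResult
    confident: bool
    reason: str = ""
    notes: dict = field(default_factory=dict)

    def cross_notation(self) -> str:
        return f"{self.maternal} (♀) × {self.paternal} (♂)"

    def to_dict(self) -> dict:
        return {
            "hybrid": self.hybrid,
            "maternal": self.maternal,
            "paternal": self.paternal,
            "cross": self.cross_notation(),
            "confident": self.confident,
            "reason": self.reason,
            "cp_evidence": self.cp_evidence.to_dict(),
            "karyotype_evidence": self.karyotype_evidence.to_dict(),
            "notes": dict(self.notes),
        }


def maternal_assignment(
    hybrid_variants: VariantSet,
    candidate_variants: dict[str, VariantSet],
) -> MaternalRanking:
    """Rank candidate maternal parents by plastome similarity to the hybrid.

    Primary score: shared substitution sites with the hybrid (descending).
    Tie-break: smaller symmetric difference of the full variant sets. All
    variant sets must share one reference. Margin is the gap between the
    top two primary scores.
    """
    if len(candidate_variants) < 2:
        raise InputError("maternal assignment needs at least two candidates")
    scores = []
    for taxon, vset in candidate_variants.items():
        scores.append(
            CandidateScore(
                taxon=taxon,
                shared_snp=shared_snp_sites(hybrid_variants, vset),
                symmetric_difference=variant_set_symmetric_difference(
                    hybrid_variants, vset
                ),
            )
        )
    scores.sort(key=lambda c: (-c.shared_snp, c.symmetric_difference, c.taxon))
    margin = scores[0].shared_snp - scores[1].shared_snp
    return MaternalRanking(
        hybrid=hybrid_variants.query_id, ranked=scores, margin=margin
    )


def infer_cross(
    hybrid: str,
    karyotype_result: AdditivityResult,
    maternal_ranking: MaternalRanking,
) -> CrossReport:
    """Orient a parent pair into a ♀ × ♂ cross.

    The top cp-ranked candidate is maternal; the other member of the
    additivity parent pair is paternal. ``confident`` requires karyotype
    additivity and a strictly positive cp margin.
    """
    parents = set(karyotype_result.parents)
    maternal = maternal_ranking.top.taxon
    if maternal not in parents:
        raise InputError(
            f"top cp candidate {maternal!r} is not in the additivity parent "
            f"pair {sorted(parents)}"
        )
    others = [p for p in karyotype_result.parents if p != maternal]
    paternal = others[0] if others else maternal
    reasons = []
    if not karyotype_result.consistent:
        reasons.append("karyotype not additive for this parent pair")
    if maternal_ranking.margin <= 0:
        reasons.append("no cp margin between top candidates")
    confident = not reasons
    return CrossReport(
        hybrid=hybrid,
        maternal=maternal,
        paternal=paternal,
        cp_evidence=maternal_ranking,
        karyotype_evidence=karyotype_result,
        confident=confident,
        reason="; ".join(reasons),
    )
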