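"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* diploid karyotypes measured over replicate metaphase cells with
  multiplicative log-normal noise on arm lengths (cytological measurement
  error is scale-proportional);
* circular quadripartite plastomes with exact inverted repeats, gene stubs
  straddling the region junctions, and planted SSR motifs;
* strict maternal plastome inheritance — an offspring plastome is its seed
  parent's sequence plus a few private substitutions/indels.

Everything is deterministic given a seed. Default plastome scale (~6 kb)
keeps full-pipeline runs in milliseconds; pass a larger
:class:`PlastomeSimSpec` for stress tests at the ~158 kb scale of real
plastomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cp_structure import GeneFeature, PlastomeRecord, revcomp
from .cp_variation import VariantCall, _left_align_deletion, _left_align_insertion
from .errors import InputError, UnbalancedParentError
from .karyotype import TYPE_ORDER

#: arm-ratio target ranges per type, kept inside the classification bands
#: with enough margin that log-normal noise at cv=0.05 over >=5 cells keeps
#: cell-averaged ratios inside the band (see docs/methods.md)
DEFAULT_RATIO_TARGETS: dict[str, tuple[float, float]] = {
    "M": (1.0, 1.0),
    "m": (1.05, 1.50),
    "sm": (1.85, 2.85),
    "st": (3.50, 6.00),
    "t": (8.0, 12.0),
    "T": (0.0, 0.0),  # short arm absent
}


# ---------------------------------------------------------------------------
# karyotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaryotypeSimSpec:
    """Recipe for one diploid taxon's measurement table."""

    taxon: str
    counts: dict[str, int]  # diploid per-type counts, all even
    pair_totals: tuple[float, ...]  # total length (µm) per homolog pair
    ratio_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_TARGETS)
    )
    noise_cv: float = 0.05
    n_cells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        odd = [t for t, n in self.counts.items() if n % 2]
        if odd:
            raise UnbalancedParentError(f"odd per-type counts {odd} in sim spec")
        if sum(self.counts.values()) // 2 != len(self.pair_totals):
            raise InputError("pair_totals length must equal haploid number")


def make_karyotype_spec(
    taxon: str,
    counts: dict[str, int],
    tcl: float,
    ls_ratio: float,
    noise_cv: float = 0.05,
    n_cells: int = 5,
    seed: int = 0,
) -> KaryotypeSimSpec:
    """Build a spec whose noiseless complement has the given TCL and L/S ratio."""
    n_pairs = sum(counts.values()) // 2
    mean = tcl / n_pairs
    longest = 2 * mean * ls_ratio / (1 + ls_ratio)
    shortest = longest / ls_ratio
    totals = tuple(np.linspace(longest, shortest, n_pairs))
    return KaryotypeSimSpec(
        taxon=taxon,
        counts=dict(counts),
        pair_totals=totals,
        noise_cv=noise_cv,
        n_cells=n_cells,
        seed=seed,
    )


def radiata_like(seed: int = 0, **kwargs) -> KaryotypeSimSpec:
    """2n = 22 = 10t + 12st at the study's scale (TCL ≈ 115.6 µm, L/S 1.73)."""
    return make_karyotype_spec(
        "L_radiata", {"t": 10, "st": 12}, tcl=115.61, ls_ratio=1.73, seed=seed, **kwargs
    )


def aurea_like(seed: int = 0, **kwargs) -> KaryotypeSimSpec:
    """2n = 14 = 8m + 6T at the study's scale (TCL ≈ 146.0 µm, L/S 2.45)."""
    return make_karyotype_spec(
        "L_aurea", {"m": 8, "T": 6}, tcl=145.95, ls_ratio=2.45, seed=seed, **kwargs
    )


def _pair_targets(spec: KaryotypeSimSpec) -> list[tuple[str, float, float]]:
    """Per-pair (type, short, long) arm targets, deterministic from the seed."""
    rng = np.random.default_rng(spec.seed)
    types = [t for t in TYPE_ORDER for _ in range(spec.counts.get(t, 0) // 2)]
    targets = []
    for t, total in zip(types, spec.pair_totals):
        if t == "T":
            short = 0.0
        else:
            lo, hi = spec.ratio_targets[t]
            ratio = float(rng.uniform(lo, hi))
            short = total / (1 + ratio)
        targets.append((t, short, total - short))
    return targets


def _measure(
    targets: list[tuple[str, float, float]],
    taxon: str,
    noise_cv: float,
    n_cells: int,
    rng: np.random.Generator,
    copies_per_target: int = 2,
) -> pd.DataFrame:
    rows = []
    for c in range(1, n_cells + 1):
        idx = 0
        for _t, short, long_ in targets:
            for _copy in range(copies_per_target):
                idx += 1
                s = short * float(np.exp(rng.normal(0, noise_cv))) if short > 0 else 0.0
                l = long_ * float(np.exp(rng.normal(0, noise_cv)))
                rows.append(
                    {
                        "taxon": taxon,
                        "cell": f"cell{c:02d}",
                        "chrom": idx,
                        "short_um": round(min(s, l), 4),
                        "long_um": round(max(s, l), 4),
                    }
                )
    return pd.DataFrame(rows)


def simulate_karyotype_measurements(spec: KaryotypeSimSpec) -> pd.DataFrame:
    """Measurement TSV rows for one diploid taxon (homologs share targets)."""
    rng = np.random.default_rng(spec.seed + 1)
    return _measure(
        _pair_targets(spec), spec.taxon, spec.noise_cv, spec.n_cells, rng
    )


def simulate_f1_measurements(
    parent_a: KaryotypeSimSpec,
    parent_b: KaryotypeSimSpec,
    seed: int = 0,
    taxon: str = "F1",
    n_cells: int | None = None,
    noise_cv: float | None = None,
) -> pd.DataFrame:
    """Measurements for an F1: one homolog per parental pair, re-noised.

    Homologs of a pair share arm targets, so the sampled gamete is the
    parent's balanced haploid set; the F1 complement is the union of the
    two gametes.
    """
    targets = _pair_targets(parent_a) + _pair_targets(parent_b)
    rng = np.random.default_rng(seed + 2)
    return _measure(
        targets,
        taxon,
        parent_a.noise_cv if noise_cv is None else noise_cv,
        parent_a.n_cells if n_cells is None else n_cells,
        rng,
        copies_per_target=1,
    )


# ---------------------------------------------------------------------------
# plastome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlastomeSimSpec:
    """Recipe for a quadripartite plastome (built LSC | IRb | SSC | IRa)."""

    id: str = "synthetic_plastome"
    lsc_len: int = 3000
    ssc_len: int = 800
    ir_len: int = 1000
    ssr_plants: tuple[tuple[str, int, str], ...] = (
        ("A", 10, "lsc"),
        ("T", 14, "lsc"),
        ("GGAAA", 3, "lsc"),
    )
    with_gene_stubs: bool = True
    seed: int = 0

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def _default_gene_stubs(spec: PlastomeSimSpec) -> list[GeneFeature]:
    """Junction-straddling gene stubs mimicking the canonical plastid layout.

    rps19 crosses LSC-IRb with 176 bp in the LSC and 34 bp in the IRb; ndhF
    crosses IRb-SSC with 107 bp duplicated in the IRb; ycf1 crosses SSC-IRa
    with 41 bp in the IRa; a 31 bp rps19 fragment ends 3 bp before the
    IRa-LSC junction and psbA starts 86 bp after it.
    """
    p1 = spec.lsc_len
    p2 = p1 + spec.ir_len
    p3 = p2 + spec.ssc_len
    L = spec.total_len
    return [
        GeneFeature("psbA", -1, ((87, 586),)),
        GeneFeature("matK", +1, ((1200, 1800),)),
        GeneFeature("rps19", -1, ((p1 - 175, p1 + 34),)),
        GeneFeature("ndhF", -1, ((p2 - 106, p2 + 493),)),
        GeneFeature("ycf1", +1, ((p3 - 299, p3 + 41),)),
        GeneFeature("rps19", +1, ((L - 33, L - 3),)),
    ]


def simulate_plastome(spec: PlastomeSimSpec) -> tuple[PlastomeRecord, dict]:
    """Generate a plastome with an exact planted IR and recorded ground truth.

    Returns the record (with gene-stub features when requested) and a truth
    dict holding the region lengths and the planted SSR loci. The first and
    last base of each single-copy region are fixed non-complementary so the
    planted IR is exactly maximal.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))

    def rand_region(n: int) -> list[str]:
        return list(bases[rng.integers(0, 4, n)])

    lsc = rand_region(spec.lsc_len)
    ssc = rand_region(spec.ssc_len)
    irb = rand_region(spec.ir_len)
    # guard bases: extension across a junction must fail on both strands
    lsc[0] = lsc[-1] = "A"
    ssc[0] = ssc[-1] = "A"

    regions = {"lsc": lsc, "ssc": ssc, "irb": irb}
    planted: list[tuple[int, str, int]] = []
    offsets = {"lsc": 0, "irb": spec.lsc_len, "ssc": spec.lsc_len + spec.ir_len}
    used: list[tuple[int, int]] = []
    for motif, repeats, region in spec.ssr_plants:
        reg = regions[region]
        run = motif * repeats
        if len(run) + 100 > len(reg):
            raise InputError(f"region {region} too short for planted ({motif}){repeats}")
        for _attempt in range(200):
            start = int(rng.integers(50, len(reg) - len(run) - 50))
            # keep planted loci farther apart than the compound-merge gap
            span = (start - 120, start + len(run) + 120)
            if all(span[1] < s or span[0] > e for s, e in used):
                break
        else:
            raise InputError("could not place planted SSRs without overlap")
        used.append(span)
        reg[start : start + len(run)] = list(run)
        # flanks must break the repeat so the planted run is exactly maximal
        reg[start - 1] = "C" if motif[-1] != "C" else "G"
        reg[start + len(run)] = "C" if motif[0] != "C" else "G"
        planted.append((offsets[region] + start + 1, motif, repeats))

    seq = "".join(lsc) + "".join(irb) + "".join(ssc) + revcomp("".join(irb))
    features = _default_gene_stubs(spec) if spec.with_gene_stubs else []
    record = PlastomeRecord(id=spec.id, sequence=seq, features=features)
    truth = {
        "lengths": {
            "LSC": spec.lsc_len,
            "IRb": spec.ir_len,
            "SSC": spec.ssc_len,
            "IRa": spec.ir_len,
        },
        "ssrs": sorted(planted),
    }
    return record, truth


def derive_maternal_offspring(
    parent: PlastomeRecord,
    n_subs: int = 5,
    n_indels: int = 2,
    seed: int = 0,
    min_spacing: int = 100,
    avoid: tuple[int, ...] = (),
) -> tuple[PlastomeRecord, list[VariantCall]]:
    """Copy a plastome with a few private substitutions and short (1-3 bp) indels.

    Edit positions are pairwise >= ``min_spacing`` apart, away from the
    sequence ends and from any ``avoid`` positions. Every planted indel is
    already left-aligned, so the returned edit log (parent coordinates,
    sorted) is the exact expected output of variant calling child-vs-parent.
    """
    rng = np.random.default_rng(seed)
    seq = parent.sequence
    L = len(seq)
    n_edits = n_subs + n_indels
    if n_edits == 0:
        return replace(parent, id=parent.id + "_offspring"), []
    positions: list[int] = []
    guard = list(avoid)
    for _attempt in range(5000):
        p = int(rng.integers(150, L - 150))
        if all(abs(p - q) >= min_spacing for q in positions + guard):
            positions.append(p)
        if len(positions) == n_edits:
            break
    else:
        raise InputError("could not place edits with the requested spacing")
    rng.shuffle(positions)

    edits: list[VariantCall] = []
    for i, p in enumerate(positions):  # p is 1-based
        if i < n_subs:
            old = seq[p - 1]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            edits.append(VariantCall(p, "substitution", old, new))
        elif (i - n_subs) % 2 == 0:  # insertion after base p
            for _ in range(50):
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                if _left_align_insertion(p, ins, seq) == (p, ins):
                    break
            edits.append(VariantCall(p, "insertion", "", ins))
        else:  # deletion starting at p
            for _ in range(50):
                d = int(rng.integers(1, 4))
                deleted = seq[p - 1 : p - 1 + d]
                if _left_align_deletion(p, deleted, seq) == (p, deleted):
                    break
                p += 1
                deleted = seq[p - 1 : p - 1 + d]
            edits.append(VariantCall(p, "deletion", deleted, ""))

    child = list(seq)
    for e in sorted(edits, key=lambda c: -c.ref_pos):
        if e.kind == "substitution":
            child[e.ref_pos - 1] = e.alt_allele
        elif e.kind == "insertion":
            child[e.ref_pos : e.ref_pos] = list(e.alt_allele)
        else:
            del child[e.ref_pos - 1 : e.ref_pos - 1 + len(e.ref_allele)]
    offspring = PlastomeRecord(
        id=parent.id + "_offspring", sequence="".join(child), features=[]
    )
    return offspring, sorted(edits, key=lambda c: c.ref_pos)


def simulate_trio(
    seed: int = 0,
    maternal: str = "parentA",
    plastome_spec: PlastomeSimSpec | None = None,
    parent_subs: int = 8,
    parent_indels: int = 2,
    private_subs: int = 3,
    private_indels: int = 1,
) -> dict:
    """Reference + two diverged parents + one hybrid with maternal plastome.

    The ancestor plays the role of the external reference genome; each
    parent diverges from it independently; the hybrid plastome is the
    chosen maternal parent's plus a few private edits (placed away from the
    parent's own edit sites so planted truth stays unambiguous).
    """
    if maternal not in {"parentA", "parentB"}:
        raise InputError("maternal must be 'parentA' or 'parentB'")
    spec = plastome_spec or PlastomeSimSpec(seed=seed)
    reference, truth = simulate_plastome(spec)
    reference = replace(reference, id="reference")
    sub = lambda i: (seed * 1_000_003 + i) % (2**31 - 1)  # noqa: E731
    parent_a, edits_a = derive_maternal_offspring(
        reference, parent_subs, parent_indels, seed=sub(1)
    )
    parent_b, edits_b = derive_maternal_offspring(
        reference, parent_subs, parent_indels, seed=sub(2)
    )
    parent_a = replace(parent_a, id="parentA")
    parent_b = replace(parent_b, id="parentB")
    mother = parent_a if maternal == "parentA" else parent_b
    mother_edits = edits_a if maternal == "parentA" else edits_b
    hybrid, private_edits = derive_maternal_offspring(
        mother,
        private_subs,
        private_indels,
        seed=sub(3),
        avoid=tuple(e.ref_pos for e in mother_edits),
    )
    hybrid = replace(hybrid, id="hybrid")
    return {
        "reference": reference,
        "parentA": parent_a,
        "parentB": parent_b,
        "hybrid": hybrid,
        "maternal": maternal,
        "truth": {
            "plastome": truth,
            "parentA_edits": edits_a,
            "parentB_edits": edits_b,
            "hybrid_private_edits": private_edits,
        },
    }


# ---------------------------------------------------------------------------
# trait table for phenetics
# ---------------------------------------------------------------------------

def simulate_trait_table(
    seed: int = 0,
    maternal_bias: float = 0.5,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Four-taxon trait table: two parents plus reciprocal hybrids.

    Eight variables per taxon: leaf length/width, three numerically encoded
    flower-colour stages, and the karyotype statistics A1, A2 and TCL.
    Hybrid traits are intermediate but biased toward the maternal side with
    weight w = (1 + maternal_bias) / 2, plus small Gaussian noise scaled by
    the parental gap.
    """
    if not 0 < maternal_bias <= 1:
        raise InputError("maternal_bias must be in (0, 1]")
    rng = np.random.default_rng(seed)
    variables = [
        "leaf_length_cm",
        "leaf_width_cm",
        "color_bud",
        "color_early",
        "color_mid",
        "A1",
        "A2",
        "TCL_um",
    ]
    radiata = np.array([45.8, 0.9, 1.0, 1.0, 1.0, 0.811, 0.063, 115.61])
    aurea = np.array([55.6, 3.2, 5.0, 5.0, 5.0, 0.438, 0.041, 145.95])
    w = (1 + maternal_bias) / 2.0
    gap = np.abs(aurea - radiata)

    def hybrid(mat: np.ndarray, pat: np.ndarray) -> np.ndarray:
        return w * mat + (1 - w) * pat + rng.normal(0, noise_sd, mat.size) * gap

    data = {
        "L_radiata": radiata,
        "L_aurea": aurea,
        "hybrid1": hybrid(radiata, aurea),  # ♀ radiata
        "hybrid2": hybrid(aurea, radiata),  # ♀ aurea
    }
    return pd.DataFrame(data, index=variables).T
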