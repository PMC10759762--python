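"""Karyotype statistics from chromosome arm measurements.

Implements the classical cytogenetic summary of a mitotic complement:
centromere-position classification of each chromosome from its arm ratio,
the karyotype formula (e.g. ``2n = 22 = 10t + 12st``), total haploid
chromosome length (TCL), the longest/shortest ratio (L/S), the Romero Zarco
intrachromosomal (A1) and interchromosomal (A2) asymmetry indices, and the
Stebbins two-character asymmetry type.

Conventions
-----------
* Arm ratio is long/short with arms normalized so short ≤ long; a missing
  short arm (length 0) is the telocentric extreme, class ``T``.
* Class bounds: ``M`` ratio ≤ 1.005 (median point), ``m`` ≤ 1.70,
  ``sm`` ≤ 3.00, ``st`` ≤ 7.00, ``t`` > 7.00, ``T`` short arm = 0.
  The ``sm`` band (1.71–3.00) is kept so the classifier is total even
  though none of the focal taxa use it.
* Replicate metaphase cells are aggregated by ordering each cell's
  complement by (type class, descending length) and averaging arms
  position-wise across cells before computing indices.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormulaError,
    InputError,
    InvalidMeasurementError,
    PairingError,
)

logger = logging.getLogger(__name__)

#: canonical ordering of centromere-position classes, most median first
TYPE_ORDER = ("M", "m", "sm", "st", "t", "T")
_TYPE_RANK = {t: i for i, t in enumerate(TYPE_ORDER)}

MEASUREMENT_COLUMNS = ["taxon", "cell", "chrom", "short_um", "long_um"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeMeasurement:
    """Arm lengths (µm) of one chromosome in one metaphase cell."""

    taxon: str
    cell_id: str
    chrom_index: int
    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.long_arm <= 0 and self.short_arm <= 0:
            raise InvalidMeasurementError(
                f"{self.taxon}/{self.cell_id}/chrom {self.chrom_index}: "
                "both arms are zero"
            )
        if self.short_arm > self.long_arm:
            raise InvalidMeasurementError(
                "short_arm must not exceed long_arm; normalize on read"
            )


@dataclass(frozen=True)
class ChromosomeRecord:
    """A measured chromosome with its derived per-chromosome statistics."""

    measurement: ChromosomeMeasurement
    total_length: float
    arm_ratio: float  # math.inf for T-type
    type_class: str
    relative_length: float  # percent of haploid complement length

    @property
    def short_arm(self) -> float:
        return self.measurement.short_arm

    @property
    def long_arm(self) -> float:
        return self.measurement.long_arm


@dataclass(frozen=True)
class HomologPair:
    """A homolog pair (or a singleton in lenient mode) with mean arm lengths."""

    type_class: str
    mean_short: float  # b
    mean_long: float   # B
    members: tuple[ChromosomeRecord, ...]


@dataclass
class KaryotypeSummary:
    """Complement-level karyotype summary for one taxon."""

    taxon: str
    two_n: int
    counts: dict[str, int]
    formula: str
    TCL: float
    LS_ratio: float
    A1: float
    A2: float
    stebbins: str
    n_cells: int
    records: list[ChromosomeRecord] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "two_n": self.two_n,
            "formula": self.formula,
            "counts": dict(self.counts),
            "TCL_um": round(self.TCL, 2),
            "LS": round(self.LS_ratio, 2),
            "A1": round(self.A1, 3),
            "A2": round(self.A2, 3),
            "stebbins": self.stebbins,
            "n_cells": self.n_cells,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# per-chromosome operations
# ---------------------------------------------------------------------------

def classify_chromosome(short_arm: float, long_arm: float) -> str:
    """Classify one chromosome by centromere position from its arm lengths.

    Arms are swapped if given in the wrong order. Returns one of
    ``M m sm st t T``.
    """
    if short_arm > long_arm:
        short_arm, long_arm = long_arm, short_arm
    if long_arm <= 0:
        raise InvalidMeasurementError("both arms are zero")
    if short_arm < 0:
        raise InvalidMeasurementError("negative arm length")
    if short_arm == 0:
        return "T"
    ratio = long_arm / short_arm
    if ratio <= 1.005:
        return "M"
    if ratio <= 1.70:
        return "m"
    if ratio <= 3.00:
        logger.warning(
            "arm ratio %.3f falls in the 1.71-3.00 band: classified 'sm'", ratio
        )
        return "sm"
    if ratio <= 7.00:
        return "st"
    return "t"


def arm_ratio(short_arm: float, long_arm: float) -> float:
    """Long/short arm ratio; +inf for a telocentric (short arm 0)."""
    if short_arm > long_arm:
        short_arm, long_arm = long_arm, short_arm
    if short_arm == 0:
        return math.inf
    return long_arm / short_arm


# ---------------------------------------------------------------------------
# measurement I/O
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a TSV of arm measurements (columns: taxon cell chrom short_um long_um).

    Arms are auto-swapped so short ≤ long, with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"measurement file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"measurement TSV missing columns: {missing}")
    df = df[MEASUREMENT_COLUMNS].copy()
    swapped = df["short_um"] > df["long_um"]
    if swapped.any():
        logger.warning("auto-swapping arms in %d rows (short > long)", int(swapped.sum()))
        s = df.loc[swapped, "short_um"].copy()
        df.loc[swapped, "short_um"] = df.loc[swapped, "long_um"]
        df.loc[swapped, "long_um"] = s
    if ((df["short_um"] <= 0) & (df["long_um"] <= 0)).any():
        raise InvalidMeasurementError("rows with both arms zero")
    if (df["short_um"] < 0).any():
        raise InvalidMeasurementError("negative arm lengths")
    return df


# ---------------------------------------------------------------------------
# complement-level statistics
# ---------------------------------------------------------------------------

def _cell_sort_key(short: float, long_: float) -> tuple:
    return (_TYPE_RANK[classify_chromosome(short, long_)], -(short + long_))


def average_complement(df: pd.DataFrame) -> list[tuple[float, float]]:
    """Average a taxon's cells position-wise into one consensus complement.

    Each cell's chromosomes are ordered by (type class, descending total
    length); arm lengths at each rank are then averaged across cells.
    Returns a list of (mean_short, mean_long), one per chromosome.
    """
    cells = []
    for _, cell_df in df.groupby("cell", sort=True):
        arms = sorted(
            zip(cell_df["short_um"], cell_df["long_um"]),
            key=lambda sl: _cell_sort_key(*sl),
        )
        cells.append(arms)
    sizes = {len(c) for c in cells}
    if len(sizes) != 1:
        raise InputError(f"inconsistent 2n across cells: {sorted(sizes)}")
    arr = np.asarray(cells, dtype=float)  # (n_cells, 2n, 2)
    mean = arr.mean(axis=0)
    return [(s, l) for s, l in mean]


def complement_stats(df: pd.DataFrame) -> tuple[float, float, list[float]]:
    """TCL (µm), L/S ratio and per-chromosome relative lengths (% of haploid total).

    TCL is the mean over cells of half the summed complement length; L/S is
    the mean over cells of (longest / shortest chromosome); relative lengths
    are computed on the cell-averaged complement.
    """
    tcls, ls = [], []
    for _, cell_df in df.groupby("cell", sort=True):
        totals = (cell_df["short_um"] + cell_df["long_um"]).to_numpy()
        if len(totals) == 0:
            continue
        tcls.append(totals.sum() / 2.0)
        ls.append(totals.max() / totals.min())
    if not tcls:
        raise InputError("no cells present")
    avg = average_complement(df)
    totals = np.array([s + l for s, l in avg])
    haploid = totals.sum() / 2.0
    rel = list(100.0 * totals / haploid)
    return float(np.mean(tcls)), float(np.mean(ls)), rel


def pair_homologs(
    records: Sequence[ChromosomeRecord], strict: bool = True
) -> list[HomologPair]:
    """Pair homologs within each type class by descending total length.

    In strict mode an odd within-type count raises :class:`PairingError`
    naming the offending type. In lenient mode the leftover chromosome forms
    a singleton group (its own arms serve as the group means), which is how
    structurally heterozygous hybrid complements are handled.
    """
    by_type: dict[str, list[ChromosomeRecord]] = {}
    for rec in records:
        by_type.setdefault(rec.type_class, []).append(rec)
    pairs: list[HomologPair] = []
    for t in TYPE_ORDER:
        group = sorted(by_type.get(t, []), key=lambda r: -r.total_length)
        if len(group) % 2 == 1:
            if strict:
                raise PairingError(
                    f"odd number of '{t}'-type chromosomes ({len(group)}): "
                    "cannot pair homologs strictly"
                )
            logger.warning(
                "odd '%s'-type count (%d): last chromosome kept as singleton",
                t,
                len(group),
            )
        for i in range(0, len(group) - 1, 2):
            a, b = group[i], group[i + 1]
            pairs.append(
                HomologPair(
                    type_class=t,
                    mean_short=(a.short_arm + b.short_arm) / 2.0,
                    mean_long=(a.long_arm + b.long_arm) / 2.0,
                    members=(a, b),
                )
            )
        if len(group) % 2 == 1:
            last = group[-1]
            pairs.append(
                HomologPair(
                    type_class=t,
                    mean_short=last.short_arm,
                    mean_long=last.long_arm,
                    members=(last,),
                )
            )
    return pairs


def asymmetry_indices(
    pairs: Sequence[HomologPair],
    all_lengths: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Romero Zarco asymmetry indices (A1, A2).

    A1 = 1 − mean(b_i / B_i) over homolog pairs (b/B = 0 for T-type pairs);
    A2 = s / x̄ of all chromosome total lengths (sample standard deviation).
    When ``all_lengths`` is omitted it is reconstructed from pair members.
    """
    if not pairs:
        raise InputError("at least one homolog pair required")
    ratios = []
    for p in pairs:
        if p.mean_long <= 0:
            raise InvalidMeasurementError("pair with zero long arm")
        ratios.append(p.mean_short / p.mean_long)
    a1 = 1.0 - float(np.mean(ratios))
    if all_lengths is None:
        all_lengths = [m.total_length for p in pairs for m in p.members]
    lengths = np.asarray(all_lengths, dtype=float)
    if len(lengths) < 2:
        a2 = 0.0
    else:
        a2 = float(lengths.std(ddof=1) / lengths.mean())
    return a1, a2


def stebbins_class(
    records: Sequence[ChromosomeRecord], ls_ratio: float
) -> str:
    """Stebbins two-character asymmetry type from a classified complement.

    Digit from the proportion p of chromosomes with arm ratio > 2.00
    (telocentrics count): p=0 → 1; 0<p≤0.5 → 2; 0.5<p<1 → 3; p=1 → 4.
    Letter from L/S: <2 → A; 2–4 → B; >4 → C.
    """
    if not records:
        raise InputError("empty complement")
    over = sum(1 for r in records if r.arm_ratio > 2.00)
    return _stebbins_from_p(over / len(records), ls_ratio)


def stebbins_from_counts(counts: Mapping[str, int], ls_ratio: float) -> str:
    """Stebbins type from a karyotype formula's type counts plus the L/S ratio.

    Classes st, t and T always have arm ratio > 2; M and m never do. The sm
    band straddles 2.00 and is counted as > 2 (its midpoint exceeds 2).
    """
    total = sum(counts.values())
    if total == 0:
        raise InputError("empty count map")
    over = sum(counts.get(t, 0) for t in ("sm", "st", "t", "T"))
    return _stebbins_from_p(over / total, ls_ratio)


def _stebbins_from_p(p: float, ls_ratio: float) -> str:
    if p == 0:
        digit = "1"
    elif p <= 0.50:
        digit = "2"
    elif p < 1:
        digit = "3"
    else:
        digit = "4"
    if ls_ratio < 2:
        letter = "A"
    elif ls_ratio <= 4:
        letter = "B"
    else:
        letter = "C"
    return digit + letter


# ---------------------------------------------------------------------------
# karyotype formula
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^\s*(\d+)\s*(M|m|sm|st|t|T)\s*$")


def format_formula(counts: Mapping[str, int], two_n: int) -> str:
    """Canonical karyotype formula string, e.g. ``2n = 18 = 4m + 6st + 5t + 3T``."""
    if sum(counts.values()) != two_n:
        raise FormulaError(
            f"type counts sum to {sum(counts.values())}, not 2n = {two_n}"
        )
    terms = [f"{counts[t]}{t}" for t in TYPE_ORDER if counts.get(t, 0) > 0]
    return f"2n = {two_n} = " + " + ".join(terms)


def parse_formula(text: str) -> tuple[int, dict[str, int]]:
    """Parse a karyotype formula; accepts any term order, optional '2x =' segment."""
    parts = [p.strip() for p in text.split("=")]
    if len(parts) < 2:
        raise FormulaError(f"cannot parse formula: {text!r}")
    head = parts[0].replace(" ", "").lower()
    if head not in {"2n", "n"}:
        raise FormulaError(f"formula must start with '2n =': {text!r}")
    # drop an optional ploidy segment like '2x'
    body = [p for p in parts[1:] if not re.fullmatch(r"\d+\s*x", p.replace(" ", ""))]
    if len(body) < 2:
        raise FormulaError(f"formula lacks a term list: {text!r}")
    try:
        two_n = int(body[0])
    except ValueError as exc:
        raise FormulaError(f"bad chromosome number in {text!r}") from exc
    counts: dict[str, int] = {}
    for term in body[1].split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise FormulaError(f"bad term {term!r} in {text!r}")
        n, t = int(m.group(1)), m.group(2)
        counts[t] = counts.get(t, 0) + n
    if sum(counts.values()) != two_n:
        raise FormulaError(
            f"terms sum to {sum(counts.values())} but formula states 2n = {two_n}"
        )
    return two_n, counts


# ---------------------------------------------------------------------------
# top-level summary
# ---------------------------------------------------------------------------

def summarize_karyotype(
    df: pd.DataFrame, taxon: str | None = None, strict_pairing: bool = False
) -> KaryotypeSummary:
    """Full karyotype summary for one taxon from an arm-measurement table."""
    if taxon is not None:
        df = df[df["taxon"] == taxon]
    taxa = df["taxon"].unique()
    if len(taxa) != 1:
        raise InputError(f"expected one taxon, found {list(taxa)}")
    taxon = str(taxa[0])
    n_cells = df["cell"].nunique()

    tcl, ls_ratio, rel = complement_stats(df)
    avg = average_complement(df)
    haploid = sum(s + l for s, l in avg) / 2.0
    records = []
    for i, (s, l) in enumerate(avg):
        meas = ChromosomeMeasurement(taxon, "<mean>", i + 1, min(s, l), max(s, l))
        records.append(
            ChromosomeRecord(
                measurement=meas,
                total_length=s + l,
                arm_ratio=arm_ratio(s, l),
                type_class=classify_chromosome(s, l),
                relative_length=100.0 * (s + l) / haploid,
            )
        )
    counts: dict[str, int] = {}
    for r in records:
        counts[r.type_class] = counts.get(r.type_class, 0) + 1
    two_n = len(records)
    pairs = pair_homologs(records, strict=strict_pairing)
    a1, a2 = asymmetry_indices(pairs, [r.total_length for r in records])
    return KaryotypeSummary(
        taxon=taxon,
        two_n=two_n,
        counts=counts,
        formula=format_formula(counts, two_n),
        TCL=tcl,
        LS_ratio=ls_ratio,
        A1=a1,
        A2=a2,
        stebbins=stebbins_class(records, ls_ratio),
        n_cells=n_cells,
        records=records,
    )


def summarize_all(
    df: pd.DataFrame, strict_pairing: bool = False
) -> dict[str, KaryotypeSummary]:
    """Summaries for every taxon in a measurement table, keyed by taxon."""
    return {
        str(t): summarize_karyotype(sub, strict_pairing=strict_pairing)
        for t, sub in df.groupby("taxon", sort=True)
    }


def records_table(summary: KaryotypeSummary) -> pd.DataFrame:
    """Per-chromosome table mirroring a supplementary measurement sheet."""
    rows = []
    for r in summary.records:
        rows.append(
            {
                "index": r.measurement.chrom_index,
                "type": r.type_class,
                "short_um": round(r.short_arm, 3),
                "long_um": round(r.long_arm, 3),
                "total_um": round(r.total_length, 3),
                "relative_pct": round(r.relative_length, 3),
                "arm_ratio": "inf" if math.isinf(r.arm_ratio) else round(r.arm_ratio, 3),
            }
        )
    return pd.DataFrame(rows)
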