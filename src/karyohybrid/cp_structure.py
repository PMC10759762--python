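"""Quadripartite structure of circular plastomes.

Land-plant chloroplast genomes carry two exact reverse-complementary copies
of an inverted repeat (IRb/IRa) separating a large and a small single-copy
region (LSC/SSC). This module detects the IR pair on a circular sequence by
k-mer seeding against the reverse complement with exact bidirectional
extension, rotates coordinates so the LSC starts at position 1, and reports
which annotated genes straddle (or flank) the four region junctions.

All coordinates are 1-based closed intervals (GenBank convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import InputError, NoInvertedRepeatError

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMP)[::-1]


def gc_content(sequence: str | "PlastomeRecord") -> float:
    """GC percent of a sequence; Ns excluded from the denominator."""
    seq = sequence.sequence if isinstance(sequence, PlastomeRecord) else sequence
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise InputError("sequence has no unambiguous bases")
    return round(100.0 * (seq.count("G") + seq.count("C")) / acgt, 2)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A gene annotation: name, strand (+1/-1), and 1-based closed intervals."""

    name: str
    strand: int
    intervals: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass
class PlastomeRecord:
    """A circular plastome: id, sequence, optional gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError(f"{self.id}: empty sequence")
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (1 <= s <= L and 1 <= e <= L):
                    raise InputError(
                        f"{self.id}: feature {f.name} interval ({s},{e}) "
                        f"outside [1,{L}]"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the rotated circular plastome."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def lengths(self) -> dict[str, int]:
        return {
            name: iv[1] - iv[0] + 1
            for name, iv in zip(("LSC", "IRb", "SSC", "IRa"), self)
        }

    def __iter__(self):
        return iter((self.lsc, self.irb, self.ssc, self.ira))

    def region_of(self, pos: int) -> str:
        for name, (s, e) in zip(("LSC", "IRb", "SSC", "IRa"), self):
            if s <= pos <= e:
                return name
        raise InputError(f"position {pos} outside partition")

    def to_dict(self) -> dict:
        return {
            "LSC": list(self.lsc),
            "IRb": list(self.irb),
            "SSC": list(self.ssc),
            "IRa": list(self.ira),
            "lengths": self.lengths,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_plastome(path: str | Path, format: str = "fasta") -> PlastomeRecord:
    """Read a plastome from FASTA or GenBank flat file.

    GenBank gene features are extracted with strand and multi-interval joins
    preserved; gene name comes from the ``gene`` qualifier (falling back to
    ``locus_tag``).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    fmt = format.lower()
    if fmt not in {"fasta", "genbank", "gb"}:
        raise InputError(f"unsupported format: {format}")
    try:
        rec = next(SeqIO.parse(str(path), "genbank" if fmt != "fasta" else "fasta"))
    except StopIteration:
        raise InputError(f"no records in {path}") from None
    except ValueError as exc:
        raise InputError(f"malformed {fmt} file {path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise InputError(f"{path}: empty sequence")
    features: list[GeneFeature] = []
    if fmt != "fasta":
        for feat in rec.features:
            if feat.type != "gene":
                continue
            name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
            ivs = tuple(
                (int(part.start) + 1, int(part.end)) for part in feat.location.parts
            )
            features.append(
                GeneFeature(name=name, strand=int(feat.location.strand or 1), intervals=ivs)
            )
    return PlastomeRecord(id=rec.id, sequence=seq, features=features)


def write_fasta(record: PlastomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        for i in range(0, len(record.sequence), width):
            fh.write(record.sequence[i : i + width] + "\n")


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write sequence + gene features as a GenBank flat file."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="synthetic plastome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in record.features:
        locs = [
            FeatureLocation(s - 1, e, strand=f.strand) for s, e in f.intervals
        ]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        seqrec.features.append(SeqFeature(loc, type="gene", qualifiers={"gene": [f.name]}))
    SeqIO.write([seqrec], str(path), "genbank")


# ---------------------------------------------------------------------------
# inverted-repeat detection
# ---------------------------------------------------------------------------

def _find_largest_ir(seq: str, min_ir: int, k: int) -> tuple[int, int, int]:
    """Largest pair of disjoint exact reverse-complement repeats on a circle.

    Returns (i, j, m): copy1 occupies circular positions [i, i+m), copy2
    [j, j+m), 0-based, with seq[i+t] complementary to seq[j+m-1-t].

    Seeds are k-mer matches between the sequence and its reverse complement;
    seeds of one repeat pair share the anti-diagonal (i + j + k) mod L, so
    each anti-diagonal is extended once.
    """
    L = len(seq)
    D = seq + seq

    kmer_pos: dict[str, list[int]] = {}
    for i in range(L):
        kmer_pos.setdefault(D[i : i + k], []).append(i)

    def at(p: int) -> str:
        return seq[p % L]

    pairs = "AT TA CG GC".split()

    def complementary(a: str, b: str) -> bool:
        return a + b in pairs

    seen: set[int] = set()
    best = (0, 0, 0)  # (m, i, j)
    for j in range(L):
        km = revcomp(D[j : j + k])
        if km not in kmer_pos:
            continue
        for i in kmer_pos[km]:
            diag = (i + j) % L
            if diag in seen:
                continue
            seen.add(diag)
            # extend the seed (i, j, k) outward while bases pair
            m = k
            i0, j0 = i, j
            while m < L // 2 and complementary(at(i0 - 1), at(j0 + m)):
                i0 -= 1
                m += 1
            while m < L // 2 and complementary(at(i0 + m), at(j0 - 1)):
                j0 -= 1
                m += 1
            i0 %= L
            j0 %= L
            # the two copies must be disjoint on the circle
            gap_a = (j0 - (i0 + m)) % L
            gap_b = (i0 - (j0 + m)) % L
            if gap_a + gap_b + 2 * m != L:
                continue  # overlapping copies (self-complementary stretch)
            if m > best[0]:
                best = (m, i0, j0)
    m, i0, j0 = best
    if m < min_ir:
        raise NoInvertedRepeatError(
            f"no inverted repeat of length >= {min_ir} bp found (best {m} bp): "
            "input does not look quadripartite"
        )
    return i0, j0, m


def _rotate_features(
    features: Sequence[GeneFeature], offset: int, L: int
) -> list[GeneFeature]:
    """Shift features left by ``offset`` (0-based), splitting wrapped intervals."""
    out = []
    for f in features:
        ivs: list[tuple[int, int]] = []
        for s, e in f.intervals:
            ns = (s - 1 - offset) % L + 1
            ne = ns + (e - s)
            if ne <= L:
                ivs.append((ns, ne))
            else:  # wraps the new origin
                ivs.append((ns, L))
                ivs.append((1, ne - L))
        out.append(GeneFeature(name=f.name, strand=f.strand, intervals=tuple(ivs)))
    return out


def detect_inverted_repeat(
    record: PlastomeRecord, min_ir: int = 1000, k: int = 25
) -> tuple[PlastomeRecord, QuadripartitePartition]:
    """Partition a circular plastome into LSC/IRb/SSC/IRa.

    Finds the maximal pair of disjoint exact reverse-complement repeats,
    rotates the sequence so the longer single-copy region (LSC) starts at
    position 1, and labels the IR copy immediately following the LSC as IRb.
    Returns the rotated record (features remapped) and the partition.

    Without features the strand is canonicalized by picking the
    lexicographically smaller of the two LSC-first orientations, so a
    genome and its reverse complement yield identical output.
    """
    seq = record.sequence
    L = len(seq)
    if L < 4 * min_ir:
        raise NoInvertedRepeatError(
            f"genome of {L} bp is shorter than 4 x min_ir ({min_ir} bp)"
        )
    i0, j0, m = _find_largest_ir(seq, min_ir, k)

    gap_after_i = (j0 - (i0 + m)) % L  # single-copy between copy-i end and copy-j
    gap_after_j = (i0 - (j0 + m)) % L
    if gap_after_i >= gap_after_j:
        # LSC runs from end of copy-i to start of copy-j: copy-j is IRb
        lsc_start, lsc_len = (i0 + m) % L, gap_after_i
        irb_start, ira_start = j0, i0
        ssc_len = gap_after_j
    else:
        lsc_start, lsc_len = (j0 + m) % L, gap_after_j
        irb_start, ira_start = i0, j0
        ssc_len = gap_after_i

    rotated = seq[lsc_start:] + seq[:lsc_start]
    if not record.features:
        flipped = revcomp(rotated)
        # reverse-complementing LSC|IRb|SSC|IRa gives IRb|rc(SSC)|IRa|rc(LSC);
        # rotating rc(LSC) to the front restores the LSC-first convention
        alt = flipped[-lsc_len:] + flipped[:-lsc_len] if lsc_len else flipped
        if alt < rotated:
            rotated = alt
    features = _rotate_features(record.features, lsc_start, L)

    a, s = lsc_len, ssc_len
    partition = QuadripartitePartition(
        lsc=(1, a),
        irb=(a + 1, a + m),
        ssc=(a + m + 1, a + m + s),
        ira=(a + m + s + 1, L),
    )
    out = PlastomeRecord(id=record.id, sequence=rotated, features=features)
    # sanity: the two IR copies must be exact reverse complements
    irb_seq = rotated[a : a + m]
    ira_seq = rotated[a + m + s :]
    if revcomp(irb_seq) != ira_seq:
        raise NoInvertedRepeatError("internal error: detected IR copies disagree")
    return out, partition


# ---------------------------------------------------------------------------
# junction genes
# ---------------------------------------------------------------------------

JUNCTION_NAMES = ("LSC-IRb", "IRb-SSC", "SSC-IRa", "IRa-LSC")


def _junction_positions(partition: QuadripartitePartition) -> dict[str, int]:
    """Left-flank position p of each junction (junction lies between p and p+1)."""
    return {
        "LSC-IRb": partition.lsc[1],
        "IRb-SSC": partition.irb[1],
        "SSC-IRa": partition.ssc[1],
        "IRa-LSC": partition.ira[1],  # circular: p+1 wraps to 1
    }


def junction_genes(
    partition: QuadripartitePartition,
    features: Sequence[GeneFeature],
    genome_length: int | None = None,
    window: int = 1000,
) -> dict[str, dict]:
    """Gene spans across (or distances from) each of the four region junctions.

    A gene overlapping a junction is reported with the number of its bases
    on each side; a gene ending exactly at the junction counts as
    overlapping with zero bases on the far side. Otherwise the nearest gene
    on each side within ``window`` bp is reported with its distance from
    the junction.
    """
    if genome_length is None:
        genome_length = partition.ira[1]
    L = genome_length
    junctions = _junction_positions(partition)
    report: dict[str, dict] = {}
    half = L // 2
    for jname, p in junctions.items():
        left_region, right_region = jname.split("-")
        overlapping = None
        nearest_left: tuple[str, int] | None = None
        nearest_right: tuple[str, int] | None = None
        for f in features:
            for s, e in f.intervals:
                length = e - s + 1
                # junction-centric coordinate: 0 = first base right of junction
                cs = (s - p - 1) % L
                end = cs + length - 1
                if cs >= half:  # starts on the left side
                    left_bp = min(length, L - cs)
                    right_bp = length - left_bp
                else:
                    left_bp, right_bp = 0, length
                crosses = left_bp > 0 and right_bp > 0
                abuts = (left_bp == length and cs + length == L) or cs == 0
                if crosses or abuts:
                    cand = {
                        "gene": f.name,
                        "strand": f.strand,
                        left_region: left_bp,
                        right_region: right_bp,
                    }
                    # prefer the gene with most bases across the junction
                    if overlapping is None or min(left_bp, right_bp) > min(
                        overlapping[left_region], overlapping[right_region]
                    ):
                        overlapping = cand
                elif left_bp == length:  # entirely left
                    dist = L - end - 1  # bases between gene end and junction
                    if dist <= window and (nearest_left is None or dist < nearest_left[1]):
                        nearest_left = (f.name, dist)
                else:  # entirely right
                    dist = cs
                    if dist <= window and (nearest_right is None or dist < nearest_right[1]):
                        nearest_right = (f.name, dist)
        if overlapping is not None:
            report[jname] = {"overlapping": overlapping}
        else:
            report[jname] = {
                "nearest_left": (
                    {"gene": nearest_left[0], "distance_bp": nearest_left[1]}
                    if nearest_left
                    else None
                ),
                "nearest_right": (
                    {"gene": nearest_right[0], "distance_bp": nearest_right[1]}
                    if nearest_right
                    else None
                ),
            }
    return report
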