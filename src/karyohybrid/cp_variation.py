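"""Variant calling and SSR scanning for near-identical plastomes.

Two plastomes rotated to the same LSC-start convention are compared by
anchor chaining: k-mers unique in both sequences seed a longest collinear
chain, and the short unanchored segments between chain blocks are resolved
by global alignment (match +1, mismatch −1, gap open −4, gap extend −1).
Alignment columns become substitution / insertion / deletion calls with
indels left-aligned, so shared-site counting across taxa is well defined.

The SSR scanner reports maximal perfect tandem repeats of primitive 1–6 bp
motifs above unit-size-specific repeat thresholds (MISA-style), with
adjacent loci within a configurable gap merged into compound loci.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .cp_structure import GeneFeature, PlastomeRecord
from .errors import InputError, InsufficientHomologyError, ReferenceMismatchError

logger = logging.getLogger(__name__)

#: minimum repeat count per motif unit size (1-6); admits (A)10 and (GGAAA)3
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
DEFAULT_COMPOUND_GAP = 100


# ---------------------------------------------------------------------------
# variant types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """One difference vs the reference, 1-based.

    Substitution: ref_pos is the changed base, |ref|=|alt|=1.
    Insertion: anchored left — alt bases inserted after reference base
    ref_pos (ref_allele empty).
    Deletion: ref_pos is the first deleted base (alt_allele empty).
    """

    ref_pos: int
    kind: str  # substitution | insertion | deletion
    ref_allele: str
    alt_allele: str
    gene: str | None = None

    def key(self) -> tuple:
        return (self.ref_pos, self.kind, self.ref_allele, self.alt_allele)


@dataclass
class VariantSet:
    """Ordered variant calls of one query against one reference."""

    reference_id: str
    query_id: str
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: (c.ref_pos, c.kind))

    @property
    def substitutions(self) -> list[VariantCall]:
        return [c for c in self.calls if c.kind == "substitution"]

    def counts(self) -> dict[str, int]:
        """Per-class totals using the conventional report row names."""
        return {
            "SNP": sum(c.kind == "substitution" for c in self.calls),
            "Insert": sum(c.kind == "insertion" for c in self.calls),
            "Missing": sum(c.kind == "deletion" for c in self.calls),
        }


# ---------------------------------------------------------------------------
# anchor chaining
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        seen[km] = -1 if km in seen else i
    return {km: i for km, i in seen.items() if i >= 0}


def anchor_chain(query: str, reference: str, k: int = 31) -> list[tuple[int, int]]:
    """Longest collinear chain of shared unique k-mers.

    Returns (ref_pos, query_pos) anchor starts (0-based), strictly
    increasing in both coordinates. Raises
    :class:`InsufficientHomologyError` with fewer than two anchors.
    """
    uq = _unique_kmers(query, k)
    ur = _unique_kmers(reference, k)
    matches = sorted((ur[km], uq[km]) for km in uq.keys() & ur.keys())
    if len(matches) < 2:
        raise InsufficientHomologyError(
            f"only {len(matches)} shared unique {k}-mers: sequences are not "
            "collinearly alignable"
        )
    # longest strictly increasing subsequence in the query coordinate
    tails: list[int] = []      # tail query positions
    tail_idx: list[int] = []   # index of match achieving each tail
    parent = [-1] * len(matches)
    for idx, (_, q) in enumerate(matches):
        pos = bisect.bisect_left(tails, q)
        if pos == len(tails):
            tails.append(q)
            tail_idx.append(idx)
        else:
            tails[pos] = q
            tail_idx[pos] = idx
        parent[idx] = tail_idx[pos - 1] if pos > 0 else -1
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(matches[i])
        i = parent[i]
    chain.reverse()
    if len(chain) < 2:
        raise InsufficientHomologyError("collinear chain too short")
    return chain


def _chain_blocks(chain: Sequence[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge chained anchors into maximal contiguous same-diagonal blocks.

    Each block (r, q, length) covers identical sequence; anchors that
    overlap a previous block on a different diagonal are dropped.
    """
    blocks: list[list[int]] = []
    for r, q in chain:
        if blocks:
            r0, q0, ln = blocks[-1]
            if q - r == q0 - r0 and r <= r0 + ln:
                blocks[-1][2] = max(ln, r + k - r0)
                continue
            if r < r0 + ln or q < q0 + ln:
                continue
        blocks.append([r, q, k])
    return [tuple(b) for b in blocks]


# ---------------------------------------------------------------------------
# alignment of inter-anchor segments
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = 1.0 if a == b else -1.0
    # N rows/columns stay 0: ambiguity codes neither match nor penalize
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner

_ALIGNER = _make_aligner()


def _left_align_deletion(pos: int, deleted: str, ref: str) -> tuple[int, str]:
    """Shift a deletion (1-based start ``pos``) as far left as possible."""
    while pos > 1 and ref[pos - 2] == deleted[-1]:
        deleted = ref[pos - 2] + deleted[:-1]
        pos -= 1
    return pos, deleted


def _left_align_insertion(pos: int, inserted: str, ref: str) -> tuple[int, str]:
    """Shift an insertion (after ref base ``pos``; 0 = before first base)."""
    while pos >= 1 and ref[pos - 1] == inserted[-1]:
        inserted = ref[pos - 1] + inserted[:-1]
        pos -= 1
    return pos, inserted


def _segment_variants(rseg: str, qseg: str, r_offset: int) -> list[VariantCall]:
    """Call variants in one unanchored segment; positions are full-reference."""
    if rseg == qseg:
        return []
    if not rseg:
        return [VariantCall(r_offset, "insertion", "", qseg)]
    if not qseg:
        return [VariantCall(r_offset + 1, "deletion", rseg, "")]
    aln = _ALIGNER.align(rseg, qseg)[0]
    ra, qa = str(aln[0]), str(aln[1])
    calls: list[VariantCall] = []
    rpos = 0  # consumed reference bases within segment
    ins_buf: list[str] = []
    del_buf: list[str] = []

    def flush() -> None:
        nonlocal ins_buf, del_buf
        if ins_buf:
            calls.append(VariantCall(r_offset + rpos, "insertion", "", "".join(ins_buf)))
            ins_buf = []
        if del_buf:
            start = r_offset + rpos - len(del_buf) + 1
            calls.append(VariantCall(start, "deletion", "".join(del_buf), ""))
            del_buf = []

    for rc, qc in zip(ra, qa):
        if rc == "-":
            if del_buf:
                flush()
            ins_buf.append(qc)
        elif qc == "-":
            if ins_buf:
                flush()
            rpos += 1
            del_buf.append(rc)
        else:
            flush()
            rpos += 1
            if rc != qc and rc != "N" and qc != "N":
                calls.append(VariantCall(r_offset + rpos, "substitution", rc, qc))
    flush()
    return calls


def call_variants(
    query: PlastomeRecord | str,
    reference: PlastomeRecord | str,
    k: int = 31,
) -> VariantSet:
    """Call substitutions and short indels of ``query`` against ``reference``.

    Both sequences should already share the LSC-start rotation convention
    (see :func:`karyohybrid.cp_structure.detect_inverted_repeat`). Indels
    are left-aligned; substitution positions are unique. Variants are
    annotated with the reference gene containing them, when the reference
    carries features.
    """
    qrec = query if isinstance(query, PlastomeRecord) else PlastomeRecord("query", query)
    rrec = (
        reference
        if isinstance(reference, PlastomeRecord)
        else PlastomeRecord("reference", reference)
    )
    qseq, rseq = qrec.sequence, rrec.sequence
    if qseq == rseq:
        return VariantSet(reference_id=rrec.id, query_id=qrec.id, calls=[])
    chain = anchor_chain(qseq, rseq, k=k)
    blocks = _chain_blocks(chain, k)
    raw: list[VariantCall] = []
    prev_r, prev_q = 0, 0
    for r, q, ln in blocks + [(len(rseq), len(qseq), 0)]:
        raw.extend(_segment_variants(rseq[prev_r:r], qseq[prev_q:q], prev_r))
        prev_r, prev_q = r + ln, q + ln

    calls: list[VariantCall] = []
    for c in raw:
        if c.kind == "deletion":
            pos, dels = _left_align_deletion(c.ref_pos, c.ref_allele, rseq)
            c = VariantCall(pos, "deletion", dels, "")
        elif c.kind == "insertion":
            pos, ins = _left_align_insertion(c.ref_pos, c.alt_allele, rseq)
            c = VariantCall(pos, "insertion", "", ins)
        calls.append(c)
    if rrec.features:
        calls = [
            VariantCall(c.ref_pos, c.kind, c.ref_allele, c.alt_allele,
                        gene=_gene_at(rrec.features, c.ref_pos))
            for c in calls
        ]
    return VariantSet(reference_id=rrec.id, query_id=qrec.id, calls=calls)


def _gene_at(features: Sequence[GeneFeature], pos: int) -> str | None:
    for f in features:
        for s, e in f.intervals:
            if s <= pos <= e:
                return f.name
    return None


def shared_snp_sites(a: VariantSet, b: VariantSet) -> int:
    """Substitution calls identical in (position, ref allele, alt allele)."""
    if a.reference_id != b.reference_id:
        raise ReferenceMismatchError(
            f"variant sets have different references: "
            f"{a.reference_id!r} vs {b.reference_id!r}"
        )
    ka = {(c.ref_pos, c.ref_allele, c.alt_allele) for c in a.substitutions}
    kb = {(c.ref_pos, c.ref_allele, c.alt_allele) for c in b.substitutions}
    return len(ka & kb)


def variant_set_symmetric_difference(a: VariantSet, b: VariantSet) -> int:
    """Calls present in exactly one of the two sets (all variant kinds)."""
    if a.reference_id != b.reference_id:
        raise ReferenceMismatchError("variant sets have different references")
    return len({c.key() for c in a.calls} ^ {c.key() for c in b.calls})


def write_vcf(vset: VariantSet, ref_seq: str, path: str | Path) -> None:
    """Minimal VCF v4.2 output; INFO carries TYPE and GENE."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={vset.reference_id}\n")
        fh.write(f"##contig=<ID={vset.reference_id},length={len(ref_seq)}>\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Reference gene">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in vset.calls:
            if c.kind == "substitution":
                pos, ref, alt = c.ref_pos, c.ref_allele, c.alt_allele
            elif c.kind == "insertion":
                pos = max(c.ref_pos, 1)
                anchor = ref_seq[pos - 1]
                ref = anchor
                alt = anchor + c.alt_allele if c.ref_pos >= 1 else c.alt_allele + anchor
            else:  # deletion
                pos = max(c.ref_pos - 1, 1)
                anchor = ref_seq[pos - 1]
                ref = anchor + c.ref_allele if c.ref_pos > 1 else c.ref_allele + anchor
                alt = anchor
            info = f"TYPE={c.kind}"
            if c.gene:
                info += f";GENE={c.gene}"
            fh.write(
                f"{vset.reference_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# SSR scanning (MISA-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem repeat locus: ``motif`` repeated ``repeats`` times."""

    start: int  # 1-based
    motif: str
    repeats: int
    unit_size: int
    compound: bool = False
    components: tuple["SSRLocus", ...] = ()

    @property
    def end(self) -> int:
        if self.compound:
            return max(c.end for c in self.components)
        return self.start + self.unit_size * self.repeats - 1


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssrs(
    sequence: str | PlastomeRecord,
    thresholds: Mapping[int, int] | None = None,
    compound_gap: int = DEFAULT_COMPOUND_GAP,
) -> list[SSRLocus]:
    """Scan for perfect SSRs of unit size 1-6.

    Per unit size the sequence is scanned left to right; at each position a
    primitive motif is extended to its maximal full-repeat count, reported
    when it meets the unit's threshold, and scanning resumes after the run.
    Motifs are reported as observed (not cycle-canonicalized). Loci of any
    unit size separated by at most ``compound_gap`` interruption bases are
    merged into compound loci; pass a negative ``compound_gap`` to disable
    merging.
    """
    seq = (
        sequence.sequence if isinstance(sequence, PlastomeRecord) else sequence
    ).upper()
    thresholds = dict(thresholds or DEFAULT_SSR_THRESHOLDS)
    bad = [u for u in thresholds if not 1 <= u <= 6]
    if bad:
        raise InputError(f"SSR unit sizes must be 1-6, got {bad}")
    L = len(seq)
    simple: list[SSRLocus] = []
    for u, minrep in sorted(thresholds.items()):
        if minrep < 1:
            raise InputError(f"threshold for unit size {u} must be >= 1")
        i = 0
        limit = L - u * minrep
        while i <= limit:
            motif = seq[i : i + u]
            if "N" in motif or not _is_primitive(motif):
                i += 1
                continue
            r = 1
            while seq[i + r * u : i + (r + 1) * u] == motif:
                r += 1
            if r >= minrep:
                simple.append(SSRLocus(start=i + 1, motif=motif, repeats=r, unit_size=u))
                i += r * u
            else:
                i += 1
    simple.sort(key=lambda s: (s.start, s.unit_size))
    if compound_gap < 0 or len(simple) <= 1:
        return simple
    # merge runs separated by <= compound_gap interruption bases
    merged: list[list[SSRLocus]] = [[simple[0]]]
    for locus in simple[1:]:
        if locus.start - merged[-1][-1].end - 1 <= compound_gap:
            merged[-1].append(locus)
        else:
            merged.append([locus])
    out: list[SSRLocus] = []
    for group in merged:
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(
                SSRLocus(
                    start=group[0].start,
                    motif="-".join(g.motif for g in group),
                    repeats=0,
                    unit_size=0,
                    compound=True,
                    components=tuple(group),
                )
            )
    return out


def diff_ssr_catalogs(
    a: Sequence[SSRLocus],
    b: Sequence[SSRLocus],
    pos_tolerance: int = 20,
) -> dict[str, list]:
    """Compare two SSR catalogues.

    Loci are matched by motif within a positional tolerance (starts shift
    slightly when upstream indels move coordinates). Matched loci are
    ``identical`` or ``repeat_changed``; unmatched loci at the same start
    with the same unit size are ``motif_changed`` pairs; the rest are
    private to one catalogue. Compound loci are compared by their
    components' joint description.
    """
    unmatched_b = list(b)
    identical, repeat_changed, motif_changed = [], [], []
    private_a: list[SSRLocus] = []
    for la in a:
        cands = [
            lb
            for lb in unmatched_b
            if lb.motif == la.motif and abs(lb.start - la.start) <= pos_tolerance
        ]
        if cands:
            lb = min(cands, key=lambda x: abs(x.start - la.start))
            unmatched_b.remove(lb)
            if lb.repeats == la.repeats and not la.compound:
                identical.append((la, lb))
            else:
                repeat_changed.append((la, lb))
        else:
            private_a.append(la)
    still_private_a = []
    for la in private_a:
        cands = [
            lb
            for lb in unmatched_b
            if lb.unit_size == la.unit_size
            and lb.repeats == la.repeats
            and abs(lb.start - la.start) <= pos_tolerance
        ]
        if cands:
            lb = min(cands, key=lambda x: abs(x.start - la.start))
            unmatched_b.remove(lb)
            motif_changed.append((la, lb))
        else:
            still_private_a.append(la)
    return {
        "identical": identical,
        "repeat_changed": repeat_changed,
        "motif_changed": motif_changed,
        "private_a": still_private_a,
        "private_b": unmatched_b,
    }


def ssr_table(loci: Sequence[SSRLocus], taxon: str = "") -> "object":
    """SSR catalogue as a pandas DataFrame (taxon, start, motif, repeats, ...)."""
    import pandas as pd

    rows = []
    for l in loci:
        rows.append(
            {
                "taxon": taxon,
                "start": l.start,
                "motif": l.motif,
                "repeats": l.repeats,
                "type": "compound" if l.compound else f"{l.unit_size}-mer",
                "compound": l.compound,
            }
        )
    return pd.DataFrame(rows)
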