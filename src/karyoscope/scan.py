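"""Telomere and rDNA detection in assemblies, and chromosome accounting.

A contig carrying a telomeric repeat array at both ends is taken as a
complete chromosome. In this species the ribosomal DNA array can occupy a
chromosome end, so a contig with a single terminal telomere whose opposite
end carries an rDNA array is also counted complete. The accounting reports
both the strict count (double-sided telomeres only) and the extended count
(plus single-telomere-with-terminal-rDNA contigs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .synthetic import TELOMERE_LEFT_UNIT

DEFAULT_END_WINDOW = 1_000
DEFAULT_MIN_COPIES = 5
DEFAULT_MAX_MISMATCH_FRACTION = 0.1
DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_MIN_MATCH_LENGTH = 500


@dataclass
class TelomereHit:
    """One tandem telomere-repeat array."""

    contig: str
    side: str  # left | right | interstitial
    start: int
    end: int
    unit: str
    copies: int
    strand: str  # '+' if the array matches the queried unit, '-' its revcomp

    @property
    def terminal(self) -> bool:
        return self.side in ("left", "right")


@dataclass
class RdnaLocus:
    """One (merged) rDNA similarity match."""

    contig: str
    start: int
    end: int
    reference: str
    identity: float
    terminal: bool
    strand: str


@dataclass
class ContigAnnotation:
    contig: str
    length: int
    telomeres: list[TelomereHit] = field(default_factory=list)
    rdna: list[RdnaLocus] = field(default_factory=list)

    @property
    def terminal_sides(self) -> set[str]:
        return {h.side for h in self.telomeres if h.terminal}

    @property
    def n_terminal_arrays(self) -> int:
        """More than 2 flags a suspect join (e.g. a three-telomere contig)."""
        return sum(h.terminal for h in self.telomeres)

    @property
    def telomere_class(self) -> str:
        sides = self.terminal_sides
        if len(sides) == 2:
            return "double"
        if len(sides) == 1:
            return "single"
        return "none"

    @property
    def completeness(self) -> str:
        sides = self.terminal_sides
        if len(sides) == 2:
            return "complete_two_telomeres"
        if len(sides) == 1:
            opposite = "right" if "left" in sides else "left"
            for locus in self.rdna:
                if locus.terminal and _end_of(locus, self.length) == opposite:
                    return "complete_telomere_plus_rdna"
        return "partial"


def _end_of(locus: RdnaLocus, length: int) -> str:
    mid = (locus.start + locus.end) / 2
    return "left" if mid < length / 2 else "right"


@dataclass
class ChromosomeAccounting:
    """Completeness tallies over an assembly."""

    n_contigs: int
    n_double_sided: int
    n_single_plus_rdna: int
    n_single_only: int
    n_none: int
    n_anomalous: int  # contigs with >2 terminal telomere arrays

    @property
    def chromosome_count_strict(self) -> int:
        return self.n_double_sided

    @property
    def chromosome_count_extended(self) -> int:
        return self.n_double_sided + self.n_single_plus_rdna

    def to_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "n_double_sided": self.n_double_sided,
            "n_single_plus_rdna": self.n_single_plus_rdna,
            "n_single_only": self.n_single_only,
            "n_none": self.n_none,
            "n_anomalous": self.n_anomalous,
            "chromosome_count_strict": self.chromosome_count_strict,
            "chromosome_count_extended": self.chromosome_count_extended,
        }


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _tandem_arrays(seq: str, unit: str, max_mismatch_fraction: float):
    """Maximal tandem arrays of ``unit`` seeded at exact occurrences.

    Arrays are grown outward one unit at a time; a candidate unit joins the
    array while (a) its own mismatches stay within the per-unit cap and
    (b) the total mismatching bases stay within ``max_mismatch_fraction``
    of the array length. The per-unit cap keeps arbitrary flanking sequence
    (~75% mismatching) from riding a long array's accumulated budget.
    Mismatches only, no indels: telomeric arrays are unit-phased, so
    frame-preserving growth is sufficient for terminal arrays.
    """
    k = len(unit)
    per_unit_max = max(1, int(max_mismatch_fraction * k)) if max_mismatch_fraction > 0 else 0
    seeds = []
    i = seq.find(unit)
    while i != -1:
        seeds.append(i)
        i = seq.find(unit, i + 1)
    arrays: list[tuple[int, int, int]] = []  # start, end, copies
    for s in seeds:
        if arrays and s < arrays[-1][1]:
            continue
        start, end, copies, mism = s, s + k, 1, 0
        while end + k <= len(seq):
            d = _hamming(seq[end: end + k], unit)
            if d <= per_unit_max and mism + d <= max_mismatch_fraction * (copies + 1) * k:
                mism += d
                end += k
                copies += 1
            else:
                break
        while start - k >= 0:
            d = _hamming(seq[start - k: start], unit)
            if d <= per_unit_max and mism + d <= max_mismatch_fraction * (copies + 1) * k:
                mism += d
                start -= k
                copies += 1
            else:
                break
        if arrays and start < arrays[-1][1]:
            if end - start > arrays[-1][1] - arrays[-1][0]:
                arrays[-1] = (start, end, copies)
        else:
            arrays.append((start, end, copies))
    return arrays


def scan_telomeres(
    record: SeqRecord | tuple[str, str],
    motifs: tuple[str, ...] = (TELOMERE_LEFT_UNIT,),
    min_copies: int = DEFAULT_MIN_COPIES,
    end_window: int = DEFAULT_END_WINDOW,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> list[TelomereHit]:
    """Telomere-repeat arrays in one contig.

    Each motif and its reverse complement are searched; an array is reported
    as ``left``/``right`` when it starts/ends within ``end_window`` of the
    corresponding contig end, and as ``interstitial`` otherwise (interstitial
    arrays are excluded from chromosome accounting).
    """
    if not motifs:
        raise ValueError("at least one telomere motif required")
    if isinstance(record, SeqRecord):
        name, seq = record.id, str(record.seq)
    else:
        name, seq = record
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    if any(c not in "ACGT" for c in set(seq)):
        warnings.warn(f"{name}: non-ACGT characters present; treated as mismatches",
                      stacklevel=2)
    hits: list[TelomereHit] = []
    seen: set[tuple[int, int]] = set()
    for motif in motifs:
        for unit, strand in ((motif.upper(), "+"), (revcomp(motif).upper(), "-")):
            for start, end, copies in _tandem_arrays(seq, unit, max_mismatch_fraction):
                if copies < min_copies or (start, end) in seen:
                    continue
                seen.add((start, end))
                if start < end_window:
                    side = "left"
                elif end > len(seq) - end_window:
                    side = "right"
                else:
                    side = "interstitial"
                hits.append(TelomereHit(name, side, start, end, unit, copies, strand))
    hits.sort(key=lambda h: h.start)
    return hits


def detect_rdna(
    record: SeqRecord | tuple[str, str],
    references,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_match_length: int = DEFAULT_MIN_MATCH_LENGTH,
    end_window: int = DEFAULT_END_WINDOW,
    max_matches: int = 1_000,
) -> list[RdnaLocus]:
    """rDNA similarity matches in one contig, merged over tandem copies.

    Each reference is aligned (infix, both strands, affine-free edit
    distance) against the contig repeatedly, masking each match, until no
    match reaches ``min_identity``; overlapping or abutting matches are
    merged into loci. The terminal flag marks loci within ``end_window`` of
    a contig end.
    """
    if isinstance(record, SeqRecord):
        name, seq = record.id, str(record.seq)
    else:
        name, seq = record
    seq = seq.upper()
    refs: list[tuple[str, str]] = []
    for ref in references:
        if isinstance(ref, SeqRecord):
            refs.append((ref.id, str(ref.seq).upper()))
        elif isinstance(ref, tuple):
            refs.append((ref[0], ref[1].upper()))
        else:
            raise TypeError("references must be SeqRecords or (name, sequence) tuples")
    for rname, rseq in refs:
        if not rseq:
            raise ValueError(f"reference {rname!r} is empty")

    raw: list[tuple[int, int, str, float, str]] = []
    for rname, rseq in refs:
        if len(rseq) < min_match_length:
            continue
        k = int((1 - min_identity) * len(rseq))
        for strand, query in (("+", rseq), ("-", revcomp(rseq))):
            target = seq
            for _ in range(max_matches):
                res = edlib.align(query, target, mode="HW", task="locations", k=k)
                if res["editDistance"] < 0 or not res["locations"]:
                    break
                s, e = res["locations"][0]
                e += 1  # edlib end is inclusive
                ident = 1 - res["editDistance"] / (e - s)
                if e - s >= min_match_length and ident >= min_identity:
                    raw.append((s, e, rname, ident, strand))
                target = target[:s] + "X" * (e - s) + target[e:]

    raw.sort()
    loci: list[RdnaLocus] = []
    for s, e, rname, ident, strand in raw:
        if loci and s <= loci[-1].end:
            last = loci[-1]
            last.end = max(last.end, e)
            last.identity = min(last.identity, ident)
        else:
            loci.append(RdnaLocus(name, s, e, rname, ident, False, strand))
    for locus in loci:
        locus.terminal = locus.start < end_window or locus.end > len(seq) - end_window
    return loci


def annotate_contigs(
    records,
    rdna_references=None,
    motifs: tuple[str, ...] = (TELOMERE_LEFT_UNIT,),
    min_copies: int = DEFAULT_MIN_COPIES,
    end_window: int = DEFAULT_END_WINDOW,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_match_length: int = DEFAULT_MIN_MATCH_LENGTH,
) -> list[ContigAnnotation]:
    """Scan every contig for telomeres (and rDNA if references are given)."""
    annotations = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            name, seq = rec.id, str(rec.seq)
        else:
            name, seq = rec
        tel = scan_telomeres((name, seq), motifs, min_copies, end_window,
                             max_mismatch_fraction)
        rd = []
        if rdna_references:
            rd = detect_rdna((name, seq), rdna_references, min_identity,
                             min_match_length, end_window)
        annotations.append(ContigAnnotation(name, len(seq), tel, rd))
    return annotations


def account_chromosomes(annotations: list[ContigAnnotation]) -> ChromosomeAccounting:
    """Completeness tallies and the strict/extended chromosome counts."""
    names = [a.contig for a in annotations]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig ids in annotations")
    n_double = n_rdna = n_single = n_none = n_anom = 0
    for a in annotations:
        if a.n_terminal_arrays > 2:
            n_anom += 1
        cls = a.completeness
        if cls == "complete_two_telomeres":
            n_double += 1
        elif cls == "complete_telomere_plus_rdna":
            n_rdna += 1
        elif a.telomere_class == "single":
            n_single += 1
        else:
            n_none += 1
    return ChromosomeAccounting(
        n_contigs=len(annotations),
        n_double_sided=n_double,
        n_single_plus_rdna=n_rdna,
        n_single_only=n_single,
        n_none=n_none,
        n_anomalous=n_anom,
    )


def scan_fasta(
    fasta: str | Path,
    rdna_fasta: str | Path | None = None,
    **kwargs,
) -> tuple[list[ContigAnnotation], ChromosomeAccounting]:
    """Convenience wrapper: annotate a FASTA assembly and account chromosomes."""
    records = list(SeqIO.parse(str(fasta), "fasta"))
    refs = list(SeqIO.parse(str(rdna_fasta), "fasta")) if rdna_fasta else None
    ann = annotate_contigs(records, rdna_references=refs, **kwargs)
    return ann, account_chromosomes(ann)


def hits_to_bed(annotations: list[ContigAnnotation]) -> str:
    """BED6 text for all telomere and rDNA features."""
    lines = []
    for a in annotations:
        for h in a.telomeres:
            lines.append(f"{a.contig}\t{h.start}\t{h.end}\ttelomere_{h.side}\t{h.copies}\t{h.strand}")
        for r in a.rdna:
            flag = "terminal" if r.terminal else "interior"
            lines.append(f"{a.contig}\t{r.start}\t{r.end}\trdna_{flag}\t{int(round(r.identity * 1000))}\t{r.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
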