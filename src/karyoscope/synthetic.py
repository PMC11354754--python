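"""Seeded synthetic assemblies, coverage profiles and offspring cohorts.

Everything downstream — telomere/rDNA scanning, depth summarisation, fold
classification, cohort screening — is tested against genomes and coverage
tracks built here with known truth: planted terminal telomere arrays,
tandem rDNA arrays, and per-chromosome copy numbers realised as binned
coverage with negative-binomial noise and sporadic outlier bins.

The emulated organism is a multi-chromosome basidiomycete whose strains may
be homokaryotic (one nucleus type) or heterokaryotic (a weighted mixture of
nucleus genotypes); whole-chromosome duplications then appear as depth folds
of 1.5x, 2x, 3x or 4x relative to the genome baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import random_dna, revcomp, rng_for
from .depth import DEFAULT_BIN_SIZE, DepthBins, make_bins

#: telomeric repeat units; the right-end unit is the reverse complement of
#: the left-end unit, so a single repeat family marks both chromosome ends.
TELOMERE_LEFT_UNIT = "CCCCTAA"
TELOMERE_RIGHT_UNIT = "TTAGGGG"

_RDNA_UNIT_SEED = 777
_RDNA_UNIT_LENGTH = 3_000


def synthetic_rdna_unit(length: int = _RDNA_UNIT_LENGTH) -> str:
    """Fixed synthetic rRNA-like repeat unit (GC-rich, deterministic).

    A stand-in reference for ribosomal DNA arrays so that fixtures need no
    external rRNA download; real rRNA FASTA records are equally accepted by
    the scanner. Synthetic: the sequence has no biological meaning beyond
    being a reproducible, GC-rich query/target pair.
    """
    rng = np.random.default_rng(_RDNA_UNIT_SEED)
    return random_dna(rng, length, gc=0.55)


@dataclass
class TelomerePlan:
    """Telomere copies to plant at each end of one contig (None = no array)."""

    left: int | None = None
    right: int | None = None

    def __post_init__(self) -> None:
        for side, copies in (("left", self.left), ("right", self.right)):
            if copies is not None and copies < 1:
                raise ValueError(f"{side} telomere copy count must be >= 1, got {copies}")


@dataclass
class RdnaPlan:
    """Tandem rDNA array planted in one contig."""

    contig: int
    offset: int
    copies: int
    unit_length: int | None = None  # None = full bundled unit

    def unit(self) -> str:
        u = synthetic_rdna_unit()
        return u if self.unit_length is None else u[: self.unit_length]


@dataclass
class GenomeTruth:
    """Blueprint for a synthetic assembly."""

    lengths: list[int]
    telomeres: list[TelomerePlan] = field(default_factory=list)
    rdna: list[RdnaPlan] = field(default_factory=list)
    gc: list[float] | float = 0.5
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if any(ln <= 0 for ln in self.lengths):
            raise ValueError("contig lengths must be positive")
        if not self.telomeres:
            self.telomeres = [TelomerePlan() for _ in self.lengths]
        if len(self.telomeres) != len(self.lengths):
            raise ValueError("one TelomerePlan per contig required")
        if self.names is None:
            self.names = [f"chr{i + 1:02d}" for i in range(len(self.lengths))]

    @property
    def n_contigs(self) -> int:
        return len(self.lengths)

    def gc_of(self, i: int) -> float:
        return self.gc[i] if isinstance(self.gc, list) else self.gc


def generate_assembly(
    truth: GenomeTruth, seed: int
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Build the assembly described by ``truth``.

    Returns the contig records and a truth table listing every planted
    feature with 0-based half-open coordinates (columns: contig, feature,
    side, start, end, unit, copies).
    """
    rng = rng_for(seed, 1)
    records: list[SeqRecord] = []
    rows: list[dict] = []
    rdna_by_contig: dict[int, list[RdnaPlan]] = {}
    for plan in truth.rdna:
        rdna_by_contig.setdefault(plan.contig, []).append(plan)

    for i, length in enumerate(truth.lengths):
        name = truth.names[i]
        tel = truth.telomeres[i]
        left = TELOMERE_LEFT_UNIT * tel.left if tel.left else ""
        right = TELOMERE_RIGHT_UNIT * tel.right if tel.right else ""
        if len(left) + len(right) > length:
            raise ValueError(f"{name}: telomere plan exceeds contig length {length}")
        seq = list(random_dna(rng, length, truth.gc_of(i)))
        seq[: len(left)] = left
        if right:
            seq[-len(right):] = right
        if left:
            rows.append(dict(contig=name, feature="telomere", side="left",
                             start=0, end=len(left),
                             unit=TELOMERE_LEFT_UNIT, copies=tel.left))
        if right:
            rows.append(dict(contig=name, feature="telomere", side="right",
                             start=length - len(right), end=length,
                             unit=TELOMERE_RIGHT_UNIT, copies=tel.right))
        for plan in rdna_by_contig.get(i, []):
            unit = plan.unit()
            span = len(unit) * plan.copies
            if plan.offset < len(left) or plan.offset + span > length - len(right):
                raise ValueError(
                    f"{name}: rDNA plan (offset {plan.offset}, span {span}) "
                    f"does not fit between telomeres in contig of length {length}"
                )
            seq[plan.offset: plan.offset + span] = unit * plan.copies
            rows.append(dict(contig=name, feature="rdna", side="interior",
                             start=plan.offset, end=plan.offset + span,
                             unit=f"rdna_unit_{len(unit)}bp", copies=plan.copies))
        records.append(SeqRecord(Seq("".join(seq)), id=name, description=""))

    table = pd.DataFrame(rows, columns=["contig", "feature", "side", "start",
                                        "end", "unit", "copies"])
    return records, table


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


@dataclass
class StrainConfig:
    """A strain's nuclear state plus sequencing-noise settings.

    ``mixture`` is a weighted set of nucleus genotypes, each a per-chromosome
    copy vector of positive integers. A homokaryon is a single-component
    mixture; a dikaryon carrying one duplicated chromosome in one nucleus is
    a two-component mixture at weights 0.5/0.5, giving that chromosome a
    1.5x depth fold.
    """

    strain_id: str
    mixture: list[tuple[tuple[int, ...], float]]
    base_depth: float = 50.0
    dispersion: float = 0.1
    outlier_fraction: float = 0.02
    outlier_range: tuple[float, float] = (0.2, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mixture:
            raise ValueError("mixture must be non-empty")
        weights = [w for _, w in self.mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(weights)}")
        k = len(self.mixture[0][0])
        for vec, _ in self.mixture:
            if len(vec) != k:
                raise ValueError("all copy vectors must have the same length")
            if any(c < 1 for c in vec):
                raise ValueError("copy numbers must be positive integers")
        if self.base_depth <= 0:
            raise ValueError("base depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier fraction must be in [0, 1]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.mixture[0][0])

    def weighted_copies(self) -> np.ndarray:
        """Effective copy number per chromosome, averaged over nuclei."""
        out = np.zeros(self.n_chromosomes)
        for vec, w in self.mixture:
            out += w * np.asarray(vec, dtype=float)
        return out

    def truth_folds(self) -> np.ndarray:
        """Copy number relative to the genome baseline (median chromosome)."""
        wc = self.weighted_copies()
        return wc / np.median(wc)

    @classmethod
    def homokaryon(cls, strain_id: str, copies: tuple[int, ...], **kw) -> "StrainConfig":
        return cls(strain_id, [(tuple(copies), 1.0)], **kw)

    @classmethod
    def dikaryon(
        cls, strain_id: str, nucleus_a: tuple[int, ...], nucleus_b: tuple[int, ...], **kw
    ) -> "StrainConfig":
        return cls(strain_id, [(tuple(nucleus_a), 0.5), (tuple(nucleus_b), 0.5)], **kw)


def simulate_depth(
    lengths: list[int] | GenomeTruth,
    strain: StrainConfig,
    bin_size: int = DEFAULT_BIN_SIZE,
    names: list[str] | None = None,
) -> tuple[DepthBins, np.ndarray]:
    """Binned coverage for a strain, plus the true per-chromosome folds.

    Each bin's depth is drawn from a negative binomial with mean
    ``base_depth * weighted copies`` and variance ``m + dispersion * m^2``
    (dispersion 0 collapses to the exact mean). A random ``outlier_fraction``
    of bins is then multiplied by a factor drawn uniformly from
    ``outlier_range`` to emulate repeat-driven depth spikes.
    """
    if isinstance(lengths, GenomeTruth):
        names = lengths.names
        lengths = lengths.lengths
    if any(ln <= 0 for ln in lengths):
        raise ValueError("chromosome lengths must be positive")
    if len(lengths) != strain.n_chromosomes:
        raise ValueError(
            f"copy vector length {strain.n_chromosomes} != chromosome count {len(lengths)}"
        )
    if names is None:
        names = [f"chr{i + 1:02d}" for i in range(len(lengths))]
    rng = rng_for(strain.seed, 2)
    bins = make_bins(dict(zip(names, lengths)), bin_size)
    wc = strain.weighted_copies()
    mean_by_seq = dict(zip(names, strain.base_depth * wc))
    means = bins["sequence"].map(mean_by_seq).to_numpy(dtype=float)
    if strain.dispersion == 0:
        depth = means.copy()
    else:
        n = 1.0 / strain.dispersion
        p = n / (n + means)
        depth = rng.negative_binomial(n, p).astype(float)
    if strain.outlier_fraction > 0:
        mask = rng.random(len(depth)) < strain.outlier_fraction
        lo, hi = strain.outlier_range
        depth[mask] *= rng.uniform(lo, hi, size=int(mask.sum()))
    bins["depth"] = depth
    return DepthBins(bins, bin_size, source="table"), strain.truth_folds()


def simulate_reads(
    lengths: list[int] | GenomeTruth,
    strain: StrainConfig,
    n_reads: int,
    read_length: int = 150,
    seed: int | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Uniform error-free read origins (no sequences), copy-number weighted.

    The chromosome of each read is drawn with probability proportional to
    length x weighted copies; the start is uniform over valid positions.
    The returned origin table (read, sequence, start, end) suffices to build
    a truth alignment without an external aligner.
    """
    if isinstance(lengths, GenomeTruth):
        names = lengths.names
        lengths = lengths.lengths
    if read_length >= min(lengths):
        raise ValueError("read length must be shorter than the shortest chromosome")
    if names is None:
        names = [f"chr{i + 1:02d}" for i in range(len(lengths))]
    rng = rng_for(strain.seed if seed is None else seed, 3)
    wc = strain.weighted_copies()
    rates = np.asarray(lengths, dtype=float) * wc
    probs = rates / rates.sum()
    if n_reads == 0:
        return pd.DataFrame(columns=["read", "sequence", "start", "end"])
    chrom_idx = rng.choice(len(lengths), size=n_reads, p=probs)
    starts = np.empty(n_reads, dtype=int)
    for i, ln in enumerate(lengths):
        sel = chrom_idx == i
        starts[sel] = rng.integers(0, ln - read_length + 1, size=int(sel.sum()))
    return pd.DataFrame(
        {
            "read": [f"read{j}" for j in range(n_reads)],
            "sequence": [names[i] for i in chrom_idx],
            "start": starts,
            "end": starts + read_length,
        }
    )


def write_truth_alignment(
    origins: pd.DataFrame,
    lengths: dict[str, int],
    path: str | Path,
    sort_and_index: bool = True,
) -> str:
    """Materialise a truth alignment (perfect matches) as a BAM file.

    Reads are written as fully matching records at their true origins; with
    ``sort_and_index`` the output is coordinate-sorted and indexed, ready
    for ``depth.compute_bins``.
    """
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(ln)} for name, ln in lengths.items()],
    }
    tids = {name: i for i, name in enumerate(lengths)}
    unsorted = path + ".unsorted.bam" if sort_and_index else path
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for row in origins.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read
            a.reference_id = tids[row.sequence]
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            rl = int(row.end - row.start)
            a.cigarstring = f"{rl}M"
            a.query_sequence = "A" * rl
            a.flag = 0
            out.write(a)
    if sort_and_index:
        pysam.sort("-o", path, unsorted)
        Path(unsorted).unlink()
        pysam.index(path)
    return path


@dataclass
class CohortTruth:
    """A parent strain plus its offspring with known copy-number truth."""

    parent: StrainConfig
    offspring: list[StrainConfig]
    labels: pd.DataFrame  # strain, verdict, duplicated (dict chrom index -> fold)

    @property
    def n_aneuploid(self) -> int:
        return int((self.labels["verdict"] == "aneuploid").sum())


def _truth_label(strain: StrainConfig) -> tuple[str, dict[int, float]]:
    folds = strain.truth_folds()
    dup = {i: float(f) for i, f in enumerate(folds) if not np.isclose(f, 1.0)}
    return ("aneuploid" if dup else "euploid"), dup


def build_cohort(
    parent: StrainConfig,
    offspring_mixtures: list[list[tuple[tuple[int, ...], float]]],
    lengths: list[int],
    bin_size: int = DEFAULT_BIN_SIZE,
    seed: int = 0,
    **noise_kwargs,
) -> tuple[CohortTruth, dict[str, DepthBins]]:
    """Simulate a cohort of offspring sharing the parent's noise settings.

    Each element of ``offspring_mixtures`` is a nucleus mixture (often a
    single homokaryotic copy vector wrapped as ``[(vec, 1.0)]``). Returns
    the cohort truth (per-offspring euploid/aneuploid labels, duplicated
    chromosomes and folds) and one DepthBins per offspring.
    """
    if not offspring_mixtures:
        raise ValueError("cohort must contain at least one offspring")
    noise = dict(
        base_depth=parent.base_depth,
        dispersion=parent.dispersion,
        outlier_fraction=parent.outlier_fraction,
        outlier_range=parent.outlier_range,
    )
    noise.update(noise_kwargs)
    offspring: list[StrainConfig] = []
    bins: dict[str, DepthBins] = {}
    rows = []
    for j, mixture in enumerate(offspring_mixtures):
        sid = f"{parent.strain_id}-S{j + 1:02d}"
        child = StrainConfig(sid, [(tuple(v), w) for v, w in mixture],
                             seed=int(rng_for(seed, 4, j).integers(2**31)), **noise)
        offspring.append(child)
        bins[sid], _ = simulate_depth(lengths, child, bin_size)
        verdict, dup = _truth_label(child)
        rows.append(dict(strain=sid, verdict=verdict, duplicated=dup))
    truth = CohortTruth(parent, offspring, pd.DataFrame(rows))
    return truth, bins
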