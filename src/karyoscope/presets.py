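"""Preset strain configurations and assembly plans for the emulated species.

These presets encode the karyotype states reported for a 15-chromosome
sclerotium-forming basidiomycete: a homokaryon with chromosome 15 at two
copies, heterokaryons whose second nucleus carries an extra chromosome 15
(1.5x fold), a 3x strain, protoplast-derived strains with nucleus-population
mixtures, and the two offspring cohorts screened for aneuploidy. They are
the fixture vocabulary for tests and for end-to-end pipeline demos.
"""

from __future__ import annotations

import numpy as np

from .synthetic import GenomeTruth, RdnaPlan, StrainConfig, TelomerePlan

N_CHROMOSOMES = 15

#: Mb-scale chromosome lengths spanning the observed range (longest 5.46 Mb,
#: shortest 2.15 Mb; chromosome 15 is the small accessory chromosome).
CHROMOSOME_LENGTHS = [
    int(round(x / 10_000)) * 10_000
    for x in np.linspace(5_460_000, 2_150_000, N_CHROMOSOMES)
]

CHROMOSOME_NAMES = [f"chr{i + 1:02d}" for i in range(N_CHROMOSOMES)]


def cv(**extra: int) -> tuple[int, ...]:
    """Copy vector: one copy everywhere, overridden per chromosome.

    ``cv(chr15=2)`` gives chromosome 15 two copies. Keyword names are
    ``chr1`` .. ``chr15``.
    """
    vec = [1] * N_CHROMOSOMES
    for name, copies in extra.items():
        idx = int(name.removeprefix("chr")) - 1
        if not 0 <= idx < N_CHROMOSOMES:
            raise ValueError(f"unknown chromosome {name!r}")
        vec[idx] = copies
    return tuple(vec)


_NOISE = dict(base_depth=50.0, dispersion=0.1, outlier_fraction=0.02)


def _protoplast_mixture(duplicated_fractional: str, **fixed: int):
    """Two nucleus populations at equal weight: one with, one without an
    extra copy of ``duplicated_fractional`` (gives that chromosome a 1.5x
    fold); ``fixed`` duplications are shared by both populations."""
    low = cv(**fixed)
    high = cv(**{duplicated_fractional: 2}, **fixed)
    return [(low, 0.5), (high, 0.5)]


def strain_L7(seed: int = 0, **noise) -> StrainConfig:
    """Single-spore homokaryon, chromosome 15 duplicated (2x)."""
    return StrainConfig.homokaryon("L7", cv(chr15=2), seed=seed, **{**_NOISE, **noise})


def strain_Pr2C(seed: int = 0, **noise) -> StrainConfig:
    """Protoplast strain: chromosome 14 at 1.5x (population mixture),
    chromosome 15 at 2x."""
    return StrainConfig("Pr2C", _protoplast_mixture("chr14", chr15=2),
                        seed=seed, **{**_NOISE, **noise})


def strain_PrT(seed: int = 0, **noise) -> StrainConfig:
    """Protoplast strain: chromosomes 1 and 14 at 1.5x, chromosome 15 at 2x."""
    low = cv(chr15=2)
    high = cv(chr1=2, chr14=2, chr15=2)
    return StrainConfig("PrT", [(low, 0.5), (high, 0.5)],
                        seed=seed, **{**_NOISE, **noise})


def strain_L12(seed: int = 0, **noise) -> StrainConfig:
    """Dikaryon: one euploid nucleus, one with an extra chromosome 15
    (1.5x fold)."""
    return StrainConfig.dikaryon("L12", cv(), cv(chr15=2),
                                 seed=seed, **{**_NOISE, **noise})


def strain_L2(seed: int = 0, **noise) -> StrainConfig:
    cfg = strain_L12(seed, **noise)
    cfg.strain_id = "L2"
    return cfg


def strain_L14(seed: int = 0, **noise) -> StrainConfig:
    """Dikaryon with chromosome 15 at three copies in both nuclei (3x fold)."""
    return StrainConfig.dikaryon("L14", cv(chr15=3), cv(chr15=3),
                                 seed=seed, **{**_NOISE, **noise})


def strain_S10(seed: int = 0, **noise) -> StrainConfig:
    """L14 offspring: chromosome 14 at 1.5x (mixture) plus chromosome 15 at 2x."""
    return StrainConfig("S10", _protoplast_mixture("chr14", chr15=2),
                        seed=seed, **{**_NOISE, **noise})


def offspring_chr15_4x(seed: int = 0, **noise) -> StrainConfig:
    """The most duplicated offspring observed: chromosome 15 at four copies."""
    return StrainConfig.homokaryon("L14-4x", cv(chr15=4), seed=seed,
                                   **{**_NOISE, **noise})


def heterokaryon_screen_strains(seed: int = 0, **noise) -> list[StrainConfig]:
    """The six-strain heterokaryon screen: three aneuploid (two at 1.5x, one
    at 3x on chromosome 15), three euploid."""
    euploid_ids = ["L4", "L11", "L43"]
    strains = [strain_L2(seed, **noise), strain_L12(seed + 1, **noise),
               strain_L14(seed + 2, **noise)]
    for j, sid in enumerate(euploid_ids):
        strains.append(StrainConfig.dikaryon(sid, cv(), cv(),
                                             seed=seed + 3 + j, **{**_NOISE, **noise}))
    return strains


def l12_offspring_mixtures() -> list[list[tuple[tuple[int, ...], float]]]:
    """Eight single-spore offspring of the 1.5x dikaryon: three carry the
    chromosome-15 duplication, five are euploid."""
    dup = [[(cv(chr15=2), 1.0)]] * 3
    eup = [[(cv(), 1.0)]] * 5
    return dup + eup


def l14_offspring_mixtures() -> list[list[tuple[tuple[int, ...], float]]]:
    """Twenty single-spore offspring of the 3x strain: fifteen aneuploid,
    five euploid. Ten strains carry chromosome 15 at 2x — three of them
    (S10/S13/S15) additionally carry a 1.5x population-mixture chromosome —
    four carry chromosome 15 at 3x and one at 4x."""
    out: list[list[tuple[tuple[int, ...], float]]] = []
    out += [[(cv(chr15=2), 1.0)]] * 7
    out += [_protoplast_mixture("chr14", chr15=2)]  # S10
    out += [_protoplast_mixture("chr13", chr15=2)]  # S13
    out += [_protoplast_mixture("chr11", chr15=2)]  # S15
    out += [[(cv(chr15=3), 1.0)]] * 4
    out += [[(cv(chr15=4), 1.0)]]
    out += [[(cv(), 1.0)]] * 5
    return out


# ---------------------------------------------------------------------------
# assembly plans (contig completeness fixtures; contigs shortened to 60 kb
# because accounting depends only on contig ends)


def l7_assembly_truth(contig_length: int = 60_000, telomere_copies: int = 10,
                      rdna_copies: int = 3) -> GenomeTruth:
    """15 contigs: 14 with double-sided telomeres, 1 with a left telomere
    and a right-terminal rDNA array."""
    telomeres = [TelomerePlan(telomere_copies, telomere_copies) for _ in range(14)]
    telomeres.append(TelomerePlan(left=telomere_copies, right=None))
    rdna_span = 3_000 * rdna_copies
    rdna = [RdnaPlan(contig=14, offset=contig_length - rdna_span, copies=rdna_copies)]
    return GenomeTruth([contig_length] * 15, telomeres, rdna)


def pr2c_assembly_truth(contig_length: int = 60_000, telomere_copies: int = 10,
                        rdna_copies: int = 3) -> GenomeTruth:
    """16 contigs: 13 double-sided, 1 single telomere + terminal rDNA,
    2 single-sided telomeres only."""
    telomeres = [TelomerePlan(telomere_copies, telomere_copies) for _ in range(13)]
    telomeres.append(TelomerePlan(left=telomere_copies, right=None))  # + rDNA
    telomeres.append(TelomerePlan(left=telomere_copies, right=None))
    telomeres.append(TelomerePlan(left=None, right=telomere_copies))
    rdna_span = 3_000 * rdna_copies
    rdna = [RdnaPlan(contig=13, offset=contig_length - rdna_span, copies=rdna_copies)]
    return GenomeTruth([contig_length] * 16, telomeres, rdna)


def prt_assembly_truth(contig_length: int = 60_000,
                       telomere_copies: int = 10) -> GenomeTruth:
    """16 contigs: 11 double-sided, 5 single-sided telomeres."""
    telomeres = [TelomerePlan(telomere_copies, telomere_copies) for _ in range(11)]
    telomeres += [TelomerePlan(left=telomere_copies, right=None) for _ in range(5)]
    return GenomeTruth([contig_length] * 16, telomeres)
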