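"""Karyogamy and meiotic chromosome allocation in a dikaryotic fungus.

Model: the two nuclei of a dikaryon fuse (karyogamy, copy vectors add),
every chromosome copy is replicated into two chromatids, and the chromatids
are allocated to four spores. In the ``faithful`` mode each chromosome's
``2*K`` chromatids are split as evenly as possible over the four spores
(the remainder goes to a uniformly random subset); the ``disordered`` mode
additionally moves, with probability ``p_nd`` per chromosome, one chromatid
from a random donor spore to a random recipient — a one-step nondisjunction
abstraction. A spore lacking any chromosome is inviable (chromosome loss is
lethal), so observed offspring are draws from the viable spores only.

For a dikaryon with one trisomic chromosome (K = 3, six chromatids over
four spores = 2,2,1,1) this predicts exactly two viable offspring classes —
balanced and duplicated — at equal frequency, which is the model used to
explain a 1.5x-fold parent producing a mix of 1x and 2x offspring.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import factorial, isclose
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chisquare

from ._util import rng_for

N_SPORES = 4


@dataclass
class FusedNucleus:
    """Post-karyogamy copy vector (sum of the two parental nuclei)."""

    copies: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 2 for c in self.copies):
            raise ValueError("a fused nucleus must carry >= 2 copies per chromosome")


@dataclass
class AllocationParams:
    mode: str = "faithful"  # faithful | disordered
    p_nd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("faithful", "disordered"):
            raise ValueError(f"unknown allocation mode {self.mode!r}")
        if not 0.0 <= self.p_nd <= 1.0:
            raise ValueError("p_nd must be in [0, 1]")


@dataclass
class SporeSet:
    """Four spores from one meiosis; inviable = any chromosome at 0 copies."""

    spores: np.ndarray  # shape (4, n_chromosomes), integer chromatid counts
    viable: np.ndarray  # shape (4,), bool

    def viable_spores(self) -> list[tuple[int, ...]]:
        return [tuple(int(c) for c in row) for row in self.spores[self.viable]]


def karyogamy(nucleus_a, nucleus_b) -> FusedNucleus:
    """Nuclear fusion: element-wise sum of the two copy vectors."""
    a = tuple(int(c) for c in nucleus_a)
    b = tuple(int(c) for c in nucleus_b)
    if len(a) != len(b):
        raise ValueError(f"copy vector lengths differ: {len(a)} vs {len(b)}")
    if any(c < 1 for c in a + b):
        raise ValueError("parental copy numbers must be positive")
    return FusedNucleus(tuple(x + y for x, y in zip(a, b)))


def meiose(fused: FusedNucleus, params: AllocationParams,
           rng: np.random.Generator | None = None) -> SporeSet:
    """Allocate each chromosome's 2*K chromatids to four spores."""
    if rng is None:
        rng = rng_for(params.seed, 5)
    k = np.asarray(fused.copies, dtype=int)
    n_chrom = k.size
    total = 2 * k
    spores = np.tile(total // N_SPORES, (N_SPORES, 1))
    for c in range(n_chrom):
        r = int(total[c] % N_SPORES)
        if r:
            lucky = rng.choice(N_SPORES, size=r, replace=False)
            spores[lucky, c] += 1
    if params.mode == "disordered" and params.p_nd > 0:
        for c in range(n_chrom):
            if rng.random() < params.p_nd:
                donors = np.flatnonzero(spores[:, c] > 0)
                donor = int(rng.choice(donors))
                others = [s for s in range(N_SPORES) if s != donor]
                recipient = int(rng.choice(others))
                spores[donor, c] -= 1
                spores[recipient, c] += 1
    assert (spores.sum(axis=0) == total).all(), "chromatid conservation violated"
    viable = (spores > 0).all(axis=1)
    return SporeSet(spores, viable)


@dataclass
class MeiosisCohort:
    """Simulated viable offspring and their copy-vector class frequencies."""

    offspring: list[tuple[int, ...]]
    n_meioses: int

    @property
    def n(self) -> int:
        return len(self.offspring)

    def class_counts(self) -> dict[tuple[int, ...], int]:
        counts: dict[tuple[int, ...], int] = {}
        for vec in self.offspring:
            counts[vec] = counts.get(vec, 0) + 1
        return dict(sorted(counts.items(), key=lambda kv: -kv[1]))

    def frequencies(self) -> pd.DataFrame:
        """Class frequencies with Monte-Carlo standard errors."""
        rows = []
        for vec, cnt in self.class_counts().items():
            p = cnt / self.n
            rows.append(dict(
                copy_vector=",".join(map(str, vec)),
                count=cnt,
                frequency=p,
                se=float(np.sqrt(p * (1 - p) / self.n)),
                aneuploid=set(vec) != {1},
            ))
        return pd.DataFrame(rows)

    def aneuploid_frequency(self) -> float:
        return sum(1 for vec in self.offspring if set(vec) != {1}) / self.n

    def to_tsv(self, path: str | Path) -> None:
        self.frequencies().to_csv(path, sep="\t", index=False)


def simulate_offspring(
    nucleus_a,
    nucleus_b,
    params: AllocationParams,
    n_offspring: int,
    seed: int | None = None,
    max_retries: int = 1_000,
) -> MeiosisCohort:
    """Repeated karyogamy + meiosis; one viable spore sampled per offspring.

    Offspring are independent viable spores (single-spore isolates), not
    constrained tetrads. Meioses whose four spores are all inviable are
    redrawn; exhausting ``max_retries`` consecutive all-inviable meioses is
    an error.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = rng_for(params.seed if seed is None else seed, 5)
    fused = karyogamy(nucleus_a, nucleus_b)
    offspring: list[tuple[int, ...]] = []
    n_meioses = 0
    while len(offspring) < n_offspring:
        for attempt in range(max_retries):
            spore_set = meiose(fused, params, rng)
            n_meioses += 1
            viable = spore_set.viable_spores()
            if viable:
                break
        else:
            raise RuntimeError(
                f"no viable spores in {max_retries} consecutive meioses"
            )
        offspring.append(viable[int(rng.integers(len(viable)))])
    return MeiosisCohort(offspring, n_meioses)


@dataclass
class GoodnessOfFit:
    method: str  # exact_binomial | exact_multinomial | chi_square
    p_value: float
    statistic: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {"method": self.method, "p_value": self.p_value,
                "statistic": self.statistic, "note": self.note}


def _multinomial_pmf(counts, probs) -> float:
    n = sum(counts)
    coef = factorial(n)
    p = 1.0
    for c, q in zip(counts, probs):
        coef //= factorial(c)
        if q == 0.0 and c > 0:
            return 0.0
        p *= q**c
    return coef * p


def _exact_multinomial_p(observed, probs) -> float:
    """Two-sided exact multinomial test: total probability of outcomes no
    more probable than the observed one."""
    n = sum(observed)
    p_obs = _multinomial_pmf(observed, probs)
    total = 0.0
    k = len(probs)

    def rec(prefix, remaining):
        nonlocal total
        if len(prefix) == k - 1:
            outcome = prefix + [remaining]
            p = _multinomial_pmf(outcome, probs)
            if p <= p_obs * (1 + 1e-12):
                total += p
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c)

    rec([], n)
    return min(total, 1.0)


def compare_cohorts(
    expected: dict | pd.DataFrame,
    observed: dict,
    min_expected_for_chisq: int = 5,
) -> GoodnessOfFit:
    """Goodness of fit of observed offspring class counts to model frequencies.

    ``expected`` maps class keys to model frequencies (a ``frequencies()``
    table is also accepted); ``observed`` maps class keys to counts.
    Observed classes absent from the model are pooled into an ``other``
    class with the model's leftover probability mass. Two classes use the
    exact binomial test; otherwise the exact multinomial when any expected
    count is small, the chi-square test when all are >= 5.
    """
    if isinstance(expected, pd.DataFrame):
        expected = dict(zip(expected["copy_vector"], expected["frequency"]))
    n_total = sum(observed.values())
    if n_total == 0:
        raise ValueError("observed counts are all zero")

    classes = list(expected)
    probs = [float(expected[c]) for c in classes]
    counts = [int(observed.get(c, 0)) for c in classes]
    extra = n_total - sum(counts)
    leftover = max(0.0, 1.0 - sum(probs))
    if extra > 0 or leftover > 1e-12:
        classes.append("other")
        probs.append(leftover)
        counts.append(extra)
    s = sum(probs)
    if s <= 0:
        raise ValueError("expected frequencies sum to zero")
    if not isclose(s, 1.0, abs_tol=1e-9):
        probs = [p / s for p in probs]

    note = ""
    if len(classes) == 2:
        res_p = probs[0]
        if res_p in (0.0, 1.0):
            pv = 1.0 if counts[0] == round(res_p * n_total) else 0.0
            if pv == 0.0:
                note = "observed mass in a zero-probability class; p below resolution"
            return GoodnessOfFit("exact_binomial", pv, note=note)
        result = binomtest(counts[0], n_total, res_p)
        return GoodnessOfFit("exact_binomial", float(result.pvalue))
    expected_counts = [p * n_total for p in probs]
    if all(e >= min_expected_for_chisq for e in expected_counts):
        stat, pv = chisquare(counts, expected_counts)
        return GoodnessOfFit("chi_square", float(pv), float(stat))
    pv = _exact_multinomial_p(counts, probs)
    if pv == 0.0:
        note = "observed mass in a zero-probability class; p below resolution"
    return GoodnessOfFit("exact_multinomial", pv, note=note)
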