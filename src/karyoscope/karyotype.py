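"""Whole-chromosome copy-number calling from binned coverage.

The model: every chromosome of a strain is present at some integer copy
number in each nucleus; sequencing depth is proportional to the effective
(nucleus-weighted) copy number. The per-chromosome depth fold — robust
chromosome depth divided by the genome baseline — therefore sits on a
discrete grid: 1x for the balanced state, 2x/3x/4x for duplications in a
homokaryon, and half-integer folds (1.5x, 2.5x ...) when only one nucleus
of a heterokaryon (or one nucleus population of a protoplast-derived
strain) carries the extra copy.

``KaryotypeModel`` is built from binned depth data; ``fit()`` estimates the
folds, snaps them onto the grid within a relative tolerance, bootstraps a
per-chromosome assignment confidence, and returns a ``KaryotypeResults``
with the euploid/aneuploid verdict and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from math import ceil, floor, isclose
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, trim_mean

from .depth import ChromosomeDepth, DepthBins, read_depth_table, summarize_chromosome_depth

#: fold multiples observed for whole-chromosome duplications across one or
#: two nuclei, plus half-integer midpoints, so near-miss folds land on
#: "unassigned" rather than the wrong integer.
DEFAULT_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
DEFAULT_TOLERANCE = 0.12
DEFAULT_BOOTSTRAP_REPS = 200


@dataclass
class FoldEstimate:
    """Depth fold of one chromosome relative to the genome baseline."""

    sequence: str
    raw_fold: float
    multiple: float | None = None  # grid value, or None = unassigned
    confidence: float | None = None  # bootstrap agreement with the assignment
    baseline: float | None = None  # x coverage used as 1.0

    @property
    def assigned(self) -> bool:
        return self.multiple is not None


@dataclass
class KaryotypeCall:
    """Strain-level verdict derived from per-chromosome fold assignments."""

    strain_id: str
    estimates: list[FoldEstimate]
    verdict: str  # euploid | aneuploid | ambiguous
    duplicated: dict[str, float]  # sequence -> assigned multiple > 1


def _verdict(estimates: list[FoldEstimate]) -> tuple[str, dict[str, float]]:
    if any(not e.assigned for e in estimates):
        dup = {e.sequence: e.multiple for e in estimates
               if e.assigned and e.multiple > 1}
        return "ambiguous", dup
    dup = {e.sequence: e.multiple for e in estimates if e.multiple > 1}
    return ("aneuploid" if dup else "euploid"), dup


def estimate_baseline(robust_depths: np.ndarray, method: str = "median") -> float:
    """Genome baseline coverage (the 1x level).

    ``median`` assumes duplicated chromosomes are a minority; ``mode`` uses
    a Gaussian kernel density over the per-chromosome depths.
    """
    if method == "median":
        baseline = float(np.median(robust_depths))
    elif method == "mode":
        if len(robust_depths) < 3 or np.ptp(robust_depths) == 0:
            baseline = float(np.median(robust_depths))
        else:
            kde = gaussian_kde(robust_depths)
            grid = np.linspace(robust_depths.min(), robust_depths.max(), 512)
            baseline = float(grid[np.argmax(kde(grid))])
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    if baseline <= 0:
        raise ValueError("baseline depth is zero; cannot form folds")
    return baseline


def estimate_folds(
    summaries: list[ChromosomeDepth],
    baseline_method: str = "median",
) -> list[FoldEstimate]:
    """Raw per-chromosome folds (no grid assignment)."""
    if len(summaries) < 2:
        raise ValueError("fold estimation needs at least 2 chromosomes")
    depths = np.array([s.robust_depth for s in summaries])
    baseline = estimate_baseline(depths, baseline_method)
    return [
        FoldEstimate(s.sequence, raw_fold=float(s.robust_depth / baseline),
                     baseline=baseline)
        for s in summaries
    ]


def assign_multiple(raw_fold: float, grid, tolerance: float) -> float | None:
    """Nearest grid value within relative tolerance, else None."""
    if not grid:
        raise ValueError("grid must be non-empty")
    nearest = min(grid, key=lambda g: abs(raw_fold - g))
    return nearest if abs(raw_fold - nearest) / nearest <= tolerance else None


def classify_folds(
    folds: list[FoldEstimate],
    grid=DEFAULT_GRID,
    tolerance: float = DEFAULT_TOLERANCE,
    strain_id: str = "strain",
) -> KaryotypeCall:
    """Snap raw folds onto the grid and derive the strain verdict.

    Ambiguity is explicit: a fold farther than ``tolerance`` (relative) from
    every grid value stays unassigned and makes the verdict ``ambiguous``.
    For bootstrap confidences, fit through :class:`KaryotypeModel`.
    """
    grid = tuple(sorted(grid))
    if 1.0 not in grid:
        raise ValueError("grid must contain 1.0")
    estimates = [
        FoldEstimate(f.sequence, f.raw_fold,
                     multiple=assign_multiple(f.raw_fold, grid, tolerance),
                     confidence=f.confidence, baseline=f.baseline)
        for f in folds
    ]
    verdict, dup = _verdict(estimates)
    return KaryotypeCall(strain_id, estimates, verdict, dup)


class KaryotypeModel:
    """Karyotype inference model over binned coverage of one strain.

    Parameters
    ----------
    data : DepthBins
        Binned coverage (from ``depth.compute_bins``, a depth table, or the
        synthetic generator).
    strain_id : str
        Label carried into results and summaries.
    trim_fraction, mad_cutoff
        Robust-summary settings passed to the per-chromosome summariser.
    """

    def __init__(
        self,
        data: DepthBins,
        strain_id: str = "strain",
        trim_fraction: float = 0.1,
        mad_cutoff: float = 5.0,
    ):
        self.data = data
        self.strain_id = strain_id
        self.trim_fraction = trim_fraction
        self.mad_cutoff = mad_cutoff
        self.summaries = summarize_chromosome_depth(data, trim_fraction, mad_cutoff)
        if len(self.summaries) < 2:
            raise ValueError("karyotype calling needs at least 2 chromosomes")

    @classmethod
    def from_depth_table(cls, path: str | Path, dialect: str = "karyoscope",
                         strain_id: str | None = None, **kwargs) -> "KaryotypeModel":
        bins = read_depth_table(path, dialect)
        return cls(bins, strain_id or Path(path).stem, **kwargs)

    def _robust(self, depths: np.ndarray) -> float:
        med = np.median(depths)
        mad = np.median(np.abs(depths - med))
        scale = 1.4826 * mad
        keep = np.abs(depths - med) <= self.mad_cutoff * scale if scale > 0 else depths == med
        if not keep.any():
            return float(med)
        return float(trim_mean(depths[keep], self.trim_fraction))

    def fit(
        self,
        grid=DEFAULT_GRID,
        tolerance: float = DEFAULT_TOLERANCE,
        baseline_method: str = "median",
        bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
        seed: int = 0,
    ) -> "KaryotypeResults":
        """Estimate folds, assign grid multiples, bootstrap confidences."""
        grid = tuple(sorted(grid))
        folds = estimate_folds(self.summaries, baseline_method)
        call = classify_folds(folds, grid, tolerance, self.strain_id)

        if bootstrap_reps > 0:
            rng = np.random.default_rng(seed)
            full = self.data.full_bins()
            per_chrom = [
                full.loc[full["sequence"] == s.sequence, "depth"].to_numpy(dtype=float)
                for s in self.summaries
            ]
            agree = np.zeros(len(per_chrom))
            for _ in range(bootstrap_reps):
                boot = np.array([
                    self._robust(rng.choice(d, size=d.size, replace=True))
                    for d in per_chrom
                ])
                base = estimate_baseline(boot, baseline_method)
                for i, est in enumerate(call.estimates):
                    m = assign_multiple(boot[i] / base, grid, tolerance)
                    agree[i] += (m == est.multiple)
            for i, est in enumerate(call.estimates):
                est.confidence = float(agree[i] / bootstrap_reps)

        return KaryotypeResults(self, call, grid, tolerance, baseline_method,
                                bootstrap_reps, seed)


class KaryotypeResults:
    """Fitted karyotype: fold estimates, assignments, verdict, diagnostics."""

    def __init__(self, model, call: KaryotypeCall, grid, tolerance,
                 baseline_method, bootstrap_reps, seed):
        self.model = model
        self.call = call
        self.grid = grid
        self.tolerance = tolerance
        self.baseline_method = baseline_method
        self.bootstrap_reps = bootstrap_reps
        self.seed = seed

    # delegated call attributes
    @property
    def strain_id(self) -> str:
        return self.call.strain_id

    @property
    def estimates(self) -> list[FoldEstimate]:
        return self.call.estimates

    @property
    def verdict(self) -> str:
        return self.call.verdict

    @property
    def duplicated(self) -> dict[str, float]:
        return self.call.duplicated

    @property
    def baseline(self) -> float:
        return self.call.estimates[0].baseline

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [e.sequence for e in self.estimates],
                "robust_depth": [s.robust_depth for s in self.model.summaries],
                "raw_fold": [e.raw_fold for e in self.estimates],
                "multiple": [e.multiple for e in self.estimates],
                "confidence": [e.confidence for e in self.estimates],
            }
        )

    def summary(self) -> str:
        t = self.fold_table()
        lines = [
            f"Karyotype call: {self.strain_id}",
            f"  baseline depth : {self.baseline:.2f}x ({self.baseline_method})",
            f"  grid           : {', '.join(str(g) for g in self.grid)}"
            f"  (tol {self.tolerance:.2f})",
            f"  verdict        : {self.verdict}",
        ]
        if self.duplicated:
            dup = ", ".join(f"{s} at {m}x" for s, m in self.duplicated.items())
            lines.append(f"  duplicated     : {dup}")
        lines.append("")
        header = f"  {'sequence':<10}{'depth':>10}{'fold':>8}{'multiple':>10}{'conf':>8}"
        lines.append(header)
        lines.append("  " + "-" * (len(header) - 2))
        for row in t.itertuples(index=False):
            mult = f"{row.multiple:g}" if row.multiple is not None else "--"
            conf = f"{row.confidence:.2f}" if row.confidence is not None else "--"
            lines.append(
                f"  {row.sequence:<10}{row.robust_depth:>10.2f}"
                f"{row.raw_fold:>8.3f}{mult:>10}{conf:>8}"
            )
        return "\n".join(lines)

    def statements(self) -> list[str]:
        """Paper-style sentences: 'chromosome N has Mx sequencing depth'."""
        return [
            f"{s} has {m:g}x sequencing depth compared to other chromosomes"
            for s, m in self.duplicated.items()
        ]

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "verdict": self.verdict,
            "baseline": self.baseline,
            "grid": list(self.grid),
            "tolerance": self.tolerance,
            "duplicated": self.duplicated,
            "estimates": [
                {"sequence": e.sequence, "raw_fold": e.raw_fold,
                 "multiple": e.multiple, "confidence": e.confidence}
                for e in self.estimates
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def infer_nuclear_composition(self, nucleus_count: int = 1,
                                  allow_mixture: bool = False):
        return infer_nuclear_composition(self.call, nucleus_count, allow_mixture)

    def plot(self, ax=None):
        """Per-chromosome fold bar chart with the grid as guide lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        t = self.fold_table()
        colors = ["#c0504d" if (m is not None and m > 1) else "#4f81bd"
                  for m in t["multiple"]]
        ax.bar(t["sequence"], t["raw_fold"], color=colors)
        for g in self.grid:
            ax.axhline(g, color="grey", lw=0.5, ls="--")
        ax.set_ylabel("depth fold")
        ax.set_title(f"{self.strain_id}: {self.verdict}")
        ax.tick_params(axis="x", rotation=90)
        return ax


# ---------------------------------------------------------------------------
# nuclear composition


@dataclass
class NucleusMixture:
    """Weighted set of nucleus genotypes explaining a fold profile."""

    components: list[tuple[tuple[int, ...], float]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture must have at least one component")
        total = sum(w for _, w in self.components)
        if not isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(c < 1 for vec, _ in self.components for c in vec):
            raise ValueError("each nucleus must carry >= 1 copy of every chromosome")

    def effective_copies(self) -> np.ndarray:
        out = np.zeros(len(self.components[0][0]))
        for vec, w in self.components:
            out += w * np.asarray(vec, dtype=float)
        return out

    @property
    def n_distinct(self) -> int:
        return len({vec for vec, _ in self.components})

    @property
    def max_copy(self) -> int:
        return max(c for vec, _ in self.components for c in vec)


class CompositionInfeasible(ValueError):
    """No per-nucleus integer assignment can realise the requested folds."""


def _compositions(total: int, parts: int):
    """Ordered splits of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_splits(total: int, nuclei: int) -> list[tuple[int, ...]]:
    """Unordered splits (partitions into exactly ``nuclei`` positive parts),
    parsimony-ordered: fewest distinct copy numbers, then smallest maximum."""
    if total < nuclei:
        raise CompositionInfeasible(
            f"cannot place {total} copies into {nuclei} nuclei with >= 1 each"
        )
    parts = sorted({tuple(sorted(c, reverse=True)) for c in _compositions(total, nuclei)})
    parts.sort(key=lambda p: (len(set(p)), max(p), p))
    return parts


def infer_nuclear_composition(
    call: KaryotypeCall | dict[str, float],
    nucleus_count: int = 1,
    allow_mixture: bool = False,
    max_enumeration: int = 200_000,
) -> list[NucleusMixture]:
    """Per-nucleus copy assignments consistent with the assigned multiples.

    The total copy target of a chromosome is ``multiple x nucleus_count``
    (every nucleus contributes one baseline copy). Integer targets are split
    over the nuclei in every possible way (each nucleus keeps >= 1 copy);
    joint assignments across chromosomes are deduplicated up to nucleus
    relabelling and ordered by parsimony (fewest distinct nucleus genotypes,
    then smallest maximum copy number). A non-integer target (e.g. a 1.5x
    fold in a single-nucleus strain) is representable only as a mixture of
    two nucleus populations and requires ``allow_mixture``.
    """
    if isinstance(call, KaryotypeCall):
        if any(not e.assigned for e in call.estimates):
            raise ValueError("all folds must be assigned before composition inference")
        multiples = {e.sequence: e.multiple for e in call.estimates}
    else:
        multiples = dict(call)
    if nucleus_count < 1:
        raise ValueError("nucleus_count must be >= 1")
    seqs = list(multiples)
    targets = {s: multiples[s] * nucleus_count for s in seqs}
    fractional = {s: t for s, t in targets.items() if not isclose(t, round(t), abs_tol=1e-9)}

    if fractional and not allow_mixture:
        raise CompositionInfeasible(
            f"targets {fractional} are non-integer for {nucleus_count} nuclei; "
            "a nucleus-population mixture is required (allow_mixture=True)"
        )

    if not fractional:
        per_chrom = {s: list(_compositions(int(round(t)), nucleus_count))
                     for s, t in targets.items()}
        size = np.prod([len(v) for v in per_chrom.values()], dtype=float)
        if size > max_enumeration:
            raise ValueError(
                f"composition space too large ({size:.0f} joint assignments)"
            )
        seen = set()
        results = []
        for combo in itertools.product(*(per_chrom[s] for s in seqs)):
            nuclei = tuple(sorted(
                tuple(combo[j][i] for j in range(len(seqs)))
                for i in range(nucleus_count)
            ))
            if nuclei in seen:
                continue
            seen.add(nuclei)
            results.append(NucleusMixture([(vec, 1 / nucleus_count) for vec in nuclei]))
        results.sort(key=lambda m: (m.n_distinct, m.max_copy,
                                    tuple(v for v, _ in m.components)))
        return results

    # Mixture of two cell populations: floor targets vs ceil targets, with the
    # population weight solving the fold exactly per fractional chromosome.
    fracs = {t - floor(t) for t in fractional.values()}
    if len(fracs) > 1:
        raise CompositionInfeasible(
            "fractional targets with different fractional parts cannot be met "
            "by a single two-population mixture"
        )
    frac = fracs.pop()
    w_low = 1 - frac  # weight of the floor population
    lo_vecs = {s: enumerate_splits(int(floor(t)) if s in fractional else int(round(t)),
                                   nucleus_count)[0]
               for s, t in targets.items()}
    hi_vecs = {s: enumerate_splits(int(ceil(t)) if s in fractional else int(round(t)),
                                   nucleus_count)[0]
               for s, t in targets.items()}
    components: list[tuple[tuple[int, ...], float]] = []
    for pop_vecs, w in ((lo_vecs, w_low), (hi_vecs, 1 - w_low)):
        for i in range(nucleus_count):
            vec = tuple(pop_vecs[s][i] for s in seqs)
            components.append((vec, w / nucleus_count))
    merged: dict[tuple[int, ...], float] = {}
    for vec, w in components:
        merged[vec] = merged.get(vec, 0.0) + w
    return [NucleusMixture(sorted(merged.items()))]


# ---------------------------------------------------------------------------
# cohort screening


@dataclass
class CohortScreen:
    """Tallies over a set of strain-level karyotype calls."""

    n_strains: int
    verdicts: dict[str, int]
    per_chromosome: dict[str, int]  # duplicated chromosome -> strain count
    per_multiple: dict[tuple[str, float], int]  # (chromosome, multiple) -> count
    table: pd.DataFrame = field(repr=False)

    @property
    def n_aneuploid(self) -> int:
        return self.verdicts.get("aneuploid", 0)

    @property
    def n_euploid(self) -> int:
        return self.verdicts.get("euploid", 0)


def screen_cohort(calls: list[KaryotypeCall | KaryotypeResults]) -> CohortScreen:
    """Exact tallies per verdict, duplicated chromosome and multiple."""
    if not calls:
        raise ValueError("cohort must contain at least one call")
    calls = [c.call if isinstance(c, KaryotypeResults) else c for c in calls]
    ids = [c.strain_id for c in calls]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in cohort")
    verdicts = Counter(c.verdict for c in calls)
    per_chrom: Counter = Counter()
    per_mult: Counter = Counter()
    rows = []
    for c in calls:
        for seq, mult in c.duplicated.items():
            per_chrom[seq] += 1
            per_mult[(seq, mult)] += 1
        rows.append(dict(strain=c.strain_id, verdict=c.verdict,
                         duplicated=";".join(f"{s}:{m:g}" for s, m in c.duplicated.items())))
    return CohortScreen(
        n_strains=len(calls),
        verdicts=dict(verdicts),
        per_chromosome=dict(per_chrom),
        per_multiple=dict(per_mult),
        table=pd.DataFrame(rows),
    )
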