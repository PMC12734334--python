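"""Heuristic M-strategy core-collection selection.

A core collection is a minimal accession subset that retains every
allele class of the full collection.  The maximization (M) strategy is
implemented as a deterministic greedy cover: at each step pick the
accession contributing the most not-yet-covered allele classes, break
ties toward the accession with the larger total band count and then by
input order, and stop at 100 % coverage.  If a larger ``target_size``
is requested the core is extended by accessions that maximize the
running within-core Shannon diversity (summed over markers).

Quantitative traits, when supplied, are discretized into quartile
classes and appended as extra coverage columns so phenotype classes
are retained alongside SSR alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import BandMatrix


@dataclass
class CoreSet:
    selected: list[str]  # in selection order
    coverage_curve: list[float]
    n_total: int
    target_warning: bool = False

    @property
    def retention_rate(self) -> float:
        return len(self.selected) / self.n_total

    @property
    def retention_percent(self) -> float:
        """Retention as a percentage at two decimals (e.g. 24/57 → 42.11)."""
        return round(100.0 * self.retention_rate, 2)


def coverage(core: list[str] | set[str], b: BandMatrix) -> float:
    """Fraction of the collection's allele classes present in ``core``."""
    core = [a for a in b.accessions if a in set(core)]
    if not core:
        return 0.0
    sub = b.data.loc[core].to_numpy()
    covered = (sub.any(axis=0)).sum()
    total = (b.data.to_numpy().any(axis=0)).sum()
    return float(covered / total)


def trait_columns(traits: pd.DataFrame) -> pd.DataFrame:
    """One-hot coverage columns from a trait table (index = accession).

    Numeric traits are binned into quartile classes first; categorical
    traits are used as-is.
    """
    cols = {}
    for name in traits.columns:
        col = traits[name]
        if pd.api.types.is_numeric_dtype(col):
            binned = pd.qcut(col, q=4, duplicates="drop")
            col = binned.astype(str)
        for level, mask in col.groupby(col).groups.items():
            indicator = pd.Series(0, index=traits.index, dtype=np.int8)
            indicator.loc[mask] = 1
            cols[f"trait:{name}={level}"] = indicator
    return pd.DataFrame(cols, index=traits.index)


def _shannon_score(counts: np.ndarray, marker_idx: np.ndarray) -> float:
    """Sum over markers of the Shannon index of within-core band counts."""
    total = 0.0
    for m in np.unique(marker_idx):
        c = counts[marker_idx == m]
        s = c.sum()
        if s == 0:
            continue
        p = c[c > 0] / s
        total += float(-(p * np.log(p)).sum())
    return total


def select_core(
    b: BandMatrix,
    target_size: int | None = None,
    traits: pd.DataFrame | None = None,
) -> CoreSet:
    """Greedy maximal-marginal-coverage core selection.

    Deterministic given the input: ties on marginal coverage go to the
    accession with more total bands, then to input order.
    """
    data = b.data.to_numpy().astype(bool)
    marker_idx = pd.factorize(np.asarray(b.marker_of_column))[0]
    if traits is not None:
        extra = trait_columns(traits.loc[b.accessions])
        data = np.hstack([data, extra.to_numpy().astype(bool)])
        marker_idx = np.concatenate(
            [marker_idx, np.arange(extra.shape[1]) + marker_idx.max() + 1]
        )
    n, c = data.shape
    present = data.any(axis=0)
    if not present.all():
        raise ValueError("every allele class must be carried by >= 1 accession")
    accessions = b.accessions
    band_totals = data.sum(axis=1)

    covered = np.zeros(c, dtype=bool)
    remaining = list(range(n))
    selected: list[int] = []
    curve: list[float] = []
    while covered.sum() < c:
        best = max(
            remaining,
            key=lambda i: ((data[i] & ~covered).sum(), band_totals[i], -i),
        )
        selected.append(best)
        remaining.remove(best)
        covered |= data[best]
        curve.append(float(covered.sum() / c))

    warn = False
    if target_size is not None:
        if target_size < len(selected):
            warnings.warn(
                f"target_size {target_size} is below the minimum achievable "
                f"cover of {len(selected)}; returning the full cover",
                stacklevel=2,
            )
            warn = True
        while len(selected) < min(target_size, n):
            counts = data[selected].sum(axis=0).astype(float)
            best = max(
                remaining,
                key=lambda i: (_shannon_score(counts + data[i], marker_idx), -i),
            )
            selected.append(best)
            remaining.remove(best)
            curve.append(float(covered.sum() / c))

    return CoreSet(
        selected=[accessions[i] for i in selected],
        coverage_curve=curve,
        n_total=n,
        target_warning=warn,
    )


@dataclass
class BaselineComparison:
    size: int
    core_coverage: float
    random_mean_coverage: float
    random_coverages: np.ndarray = field(repr=False)


def compare_baselines(
    b: BandMatrix, size: int, replicates: int = 1000, seed: int = 0
) -> BaselineComparison:
    """Monte-Carlo coverage of uniform random subsets vs the greedy core."""
    if size > len(b.accessions):
        raise ValueError("size exceeds the number of accessions")
    rng = np.random.default_rng(seed)
    accs = np.asarray(b.accessions)
    covs = np.empty(replicates)
    for r in range(replicates):
        subset = rng.choice(accs, size=size, replace=False)
        covs[r] = coverage(list(subset), b)
    core = select_core(b)
    return BaselineComparison(
        size=size,
        core_coverage=coverage(core.selected, b),
        random_mean_coverage=float(covs.mean()),
        random_coverages=covs,
    )


def write_core(core: CoreSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "rank": range(1, len(core.selected) + 1),
            "accession": core.selected,
            "coverage": [round(v, 4) for v in core.coverage_curve],
        }
    ).to_csv(path, sep="\t", index=False)
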