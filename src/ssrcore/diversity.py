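"""Per-locus genetic-diversity statistics for multi-allelic SSR data.

For allele (band) frequencies :math:`p_1..p_k` at one locus:

* ``Na`` — observed allele count :math:`k`
* ``Ne`` — effective allele number :math:`1/\\sum p_j^2`
* ``He`` — Nei gene diversity :math:`1 - \\sum p_j^2` (the plain
  estimator, so the identity ``He = 1 - 1/Ne`` holds exactly)
* ``I``  — Shannon information index :math:`-\\sum p_j \\ln p_j` (nats)
* ``PIC`` — polymorphic information content, Botstein's multi-allele
  form :math:`1 - \\sum p_j^2 - \\sum_{j<k} 2 p_j^2 p_k^2`

Frequencies are band-based: every distinct band an accession carries at
a locus contributes one count, and missing cells are simply excluded
from the denominator.  The table builder mirrors the conventional
per-locus report (one row per marker, a totals row, a means row).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class NoDataError(ValueError):
    """All calls at a locus are missing."""


@dataclass
class AlleleFrequencies:
    locus: str
    freqs: np.ndarray
    n_observations: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1")
        if np.any(self.freqs <= 0):
            raise ValueError("frequencies must be strictly positive")


def allele_frequencies(g: GenotypeMatrix, locus: str) -> AlleleFrequencies:
    """Band-count frequencies at ``locus`` (one count per distinct band)."""
    counts: dict[int, int] = {}
    for acc in g.accessions:
        for size in g.call(acc, locus):
            counts[size] = counts.get(size, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise NoDataError(f"no scored bands at locus {locus!r}")
    sizes = sorted(counts)
    freqs = np.array([counts[s] / total for s in sizes])
    return AlleleFrequencies(locus=locus, freqs=freqs, n_observations=total)


def pic(f: AlleleFrequencies | np.ndarray) -> float:
    """Botstein polymorphic information content; 0 for a monomorphic locus."""
    p = f.freqs if isinstance(f, AlleleFrequencies) else np.asarray(f, dtype=float)
    p2 = p ** 2
    s2 = p2.sum()
    # sum_{j<k} 2 p_j^2 p_k^2 = (sum p^2)^2 - sum p^4
    return float(1.0 - s2 - (s2 ** 2 - (p2 ** 2).sum()))


def effective_alleles(f: AlleleFrequencies | np.ndarray) -> float:
    """Effective allele number Ne = 1 / Σp²."""
    p = f.freqs if isinstance(f, AlleleFrequencies) else np.asarray(f, dtype=float)
    return float(1.0 / (p ** 2).sum())


def expected_het(f: AlleleFrequencies | np.ndarray) -> float:
    """Nei gene diversity He = 1 − Σp²."""
    p = f.freqs if isinstance(f, AlleleFrequencies) else np.asarray(f, dtype=float)
    return float(1.0 - (p ** 2).sum())


def expected_het_from_ne(ne: float) -> float:
    """He implied by an effective allele number under the plain Nei estimator.

    The estimator satisfies He = 1 − 1/Ne identically, so a published Ne
    determines the matching He without access to the raw frequencies.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    return 1.0 - 1.0 / ne


def shannon(f: AlleleFrequencies | np.ndarray) -> float:
    """Shannon information index I = −Σ p ln p in nats."""
    p = f.freqs if isinstance(f, AlleleFrequencies) else np.asarray(f, dtype=float)
    return float(-(p * np.log(p)).sum())


@dataclass
class DiversityTable:
    """Per-locus statistics with totals and means rows."""

    per_locus: pd.DataFrame  # index: locus; columns PIC, Na, Ne, He, I
    skipped: list[str]  # all-missing loci excluded from totals

    @property
    def totals(self) -> pd.Series:
        return self.per_locus.sum()

    @property
    def means(self) -> pd.Series:
        return self.per_locus.mean()

    def to_frame(self) -> pd.DataFrame:
        """Report-shaped frame with Total and Mean rows, rounded for display
        (3 decimals; Na total as integer, Na mean at 2 decimals)."""
        out = self.per_locus.round(3)
        total = self.totals
        mean = self.means
        out.loc["Total"] = total.round(3)
        out.loc["Mean"] = mean.round(3)
        out["Na"] = pd.Series(
            [
                round(v, 2) if idx == "Mean" else int(v)
                for idx, v in zip(out.index, out["Na"])
            ],
            index=out.index,
            dtype=object,  # integer counts except the 2-dp mean
        )
        return out


def table_totals(per_locus: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Totals (column sums) and means (totals / locus count) of a per-locus
    statistics frame — the arithmetic used for the report footer rows."""
    totals = per_locus.sum()
    means = totals / len(per_locus)
    return totals, means


def diversity_table(g: GenotypeMatrix) -> DiversityTable:
    rows = {}
    skipped = []
    for m in g.markers:
        try:
            f = allele_frequencies(g, m.name)
        except NoDataError:
            skipped.append(m.name)
            continue
        rows[m.name] = {
            "PIC": pic(f),
            "Na": float(len(f.freqs)),
            "Ne": effective_alleles(f),
            "He": expected_het(f),
            "I": shannon(f),
        }
    if not rows:
        raise NoDataError("no locus has any scored bands")
    per_locus = pd.DataFrame.from_dict(rows, orient="index")[
        ["PIC", "Na", "Ne", "He", "I"]
    ]
    return DiversityTable(per_locus=per_locus, skipped=skipped)


def write_diversity_table(t: DiversityTable, path: str | Path) -> None:
    t.to_frame().rename_axis("Locus").to_csv(path, sep="\t")
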