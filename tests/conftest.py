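from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ssrcore.genotypes import BandMatrix
from ssrcore.mining import DEFAULT_RULES, is_primitive

# Published per-locus diversity statistics for a 57-accession collection
# typed at 15 SSR loci (PIC, Na, Ne, He, I); used as a regression fixture
# for the internal identities and footer arithmetic of such reports.
PRINTED_TABLE = pd.DataFrame(
    {
        "PIC": [0.476, 0.725, 0.325, 0.436, 0.132, 0.374, 0.339, 0.171,
                0.592, 0.586, 0.323, 0.523, 0.582, 0.360, 0.327],
        "Na": [5, 9, 5, 6, 7, 4, 9, 8, 11, 10, 7, 9, 17, 5, 3],
        "Ne": [2.283, 4.174, 1.690, 2.109, 1.166, 1.988, 1.563, 1.232,
               2.840, 2.658, 1.590, 2.513, 2.909, 1.757, 1.702],
        "He": [0.562, 0.760, 0.408, 0.526, 0.142, 0.497, 0.360, 0.188,
               0.648, 0.624, 0.371, 0.602, 0.656, 0.431, 0.413],
        "I": [0.916, 1.524, 0.598, 0.846, 0.271, 0.690, 0.734, 0.336,
              1.185, 1.241, 0.639, 0.992, 1.082, 0.701, 0.603],
    },
    index=["SSR3", "SSR11", "SSR12", "SSR15", "SSR18", "SSR22", "SSR26",
           "SSR32", "SSR35", "SSR36", "SSR38", "SSR48", "SSR51", "SSR61",
           "SSR65"],
)


def make_bands(rows: dict[str, list[int]], markers: list[str] | None = None,
               missing: dict[str, list[str]] | None = None) -> BandMatrix:
    """Build a BandMatrix from raw 0/1 rows (one marker unless given)."""
    n_cols = len(next(iter(rows.values())))
    if markers is None:
        markers = ["M1"] * n_cols
    columns = [f"{m}:{100 + 2 * i}" for i, m in enumerate(markers)]
    data = pd.DataFrame(
        {c: [rows[acc][i] for acc in rows] for i, c in enumerate(columns)},
        index=list(rows),
    ).astype(np.int8)
    marker_names = list(dict.fromkeys(markers))
    miss = pd.DataFrame(
        False, index=list(rows), columns=marker_names
    )
    if missing:
        for acc, names in missing.items():
            for name in names:
                miss.loc[acc, name] = True
    return BandMatrix(data=data, missing=miss, marker_of_column=markers)


def brute_force_ssrs(seq: str, rules=DEFAULT_RULES) -> set[tuple[int, int, str]]:
    """Independent O(L·36) reference scanner: test every (start, unit) pair."""
    seq = seq.upper()
    found = set()
    for u in range(1, rules.max_unit_length + 1):
        thr = rules.min_repeats_by_unit_length[u]
        for i in range(len(seq) - u + 1):
            unit = seq[i : i + u]
            if "N" in unit or not is_primitive(unit):
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + u]:
                continue  # extendable left, not a tract start
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k >= thr:
                found.add((i, i + k * u, unit))
    return found


@pytest.fixture(scope="session")
def default_population():
    from ssrcore.simulate import PopulationSpec, simulate_population

    return simulate_population(PopulationSpec(seed=0))


@pytest.fixture(scope="session")
def default_bands(default_population):
    from ssrcore.genotypes import to_band_matrix

    return to_band_matrix(default_population[0])
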