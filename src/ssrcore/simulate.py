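"""Synthetic-data generators with stored ground truth for every stage.

Three generators emulate the study conditions of a germplasm survey:

* :func:`simulate_genome` — a random background sequence with planted
  perfect SSR tracts, guaranteed (by flank fixing and rejection
  resampling) to contain *exactly* the planted above-threshold tracts.
* :func:`simulate_population` — a structured population of dikaryotic
  accessions typed at multi-allelic SSR loci.  Each group carries a
  consensus allele pair per locus; accession slots mutate away from the
  consensus at a calibrated rate, and a calibrated subset of
  "discriminating" loci gives each group its own consensus so that the
  expected simple-matching similarity matches the requested
  within-group and between-group levels.  Calibration is closed-form
  (expected agreement under independent slot mutation) plus a root
  solve; no iterative fitting against simulated draws.
* :func:`simulate_traits` — qualitative metadata (fruiting-body color,
  origin, cultivation type) with a configurable color–group
  correlation.

Defaults mirror the dimensions of a 57-accession collection typed at
15 loci with the allele-count vector [5,9,...,3] (115 alleles in
total), five groups, and within/between similarity 0.90/0.72 so that a
similarity cut at 0.76 separates the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import GenotypeMatrix, Marker
from .mining import (
    DEFAULT_RULES,
    MotifRules,
    SSRCatalog,
    SSRLocus,
    canonical_motif,
    find_ssrs,
)
from .molecular_id import IDCodeBook, default_codebook

DEFAULT_MARKER_NAMES = [
    "SSR3", "SSR11", "SSR12", "SSR15", "SSR18", "SSR22", "SSR26", "SSR32",
    "SSR35", "SSR36", "SSR38", "SSR48", "SSR51", "SSR61", "SSR65",
]
DEFAULT_NA = [5, 9, 5, 6, 7, 4, 9, 8, 11, 10, 7, 9, 17, 5, 3]


class SpecError(ValueError):
    """Infeasible generator specification."""


class CalibrationError(ValueError):
    """Similarity targets unattainable under the generative model."""


# ---------------------------------------------------------------------------
# genomes


@dataclass
class GenomeSpec:
    length: int = 10_000
    planted: list[tuple[int, str, int]] = dc_field(default_factory=list)
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        spans = []
        for pos, motif, repeats in self.planted:
            end = pos + len(motif) * repeats
            if pos < 1 or end > self.length - 1:
                raise SpecError(
                    f"planted tract at {pos} does not fit inside the sequence "
                    "(one flank base is needed on each side)"
                )
            spans.append((pos, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1 + 7:
                raise SpecError("planted tracts must be > 6 bp apart")


def simulate_genome(
    spec: GenomeSpec, rules: MotifRules = DEFAULT_RULES, seq_id: str = "sim1"
) -> tuple[list[SeqRecord], SSRCatalog]:
    """Background sequence with planted SSR tracts and its truth catalog.

    Every planted tract must meet its repeat-count threshold; the
    background is resampled until mining reports exactly the planted
    tracts (accidental above-threshold background repeats are rare and
    removed by rejection).
    """
    for _, motif, repeats in spec.planted:
        u = len(motif)
        if repeats < rules.min_repeats_by_unit_length[u]:
            raise SpecError(
                f"planted tract {motif}x{repeats} is below the unit-length-{u} "
                f"threshold {rules.min_repeats_by_unit_length[u]}"
            )
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    truth_loci = [
        SSRLocus(
            seq_id=seq_id,
            start=pos,
            end=pos + len(motif) * repeats,
            motif=motif.upper(),
            motif_class=canonical_motif(motif),
            unit_length=len(motif),
            repeat_count=repeats,
        )
        for pos, motif, repeats in spec.planted
    ]
    truth_keys = {(l.start, l.end, l.motif) for l in truth_loci}
    for _ in range(500):
        seq = rng.choice(bases, size=spec.length, p=p)
        for pos, motif, repeats in spec.planted:
            tract = np.array(list(motif.upper() * repeats))
            end = pos + len(tract)
            seq[pos:end] = tract
            # fix flank bases so the periodic run cannot extend
            u = len(motif)
            if seq[pos - 1] == seq[pos - 1 + u]:
                others = [b for b in "ACGT" if b != seq[pos - 1 + u]]
                seq[pos - 1] = others[rng.integers(len(others))]
            if end < spec.length and seq[end] == seq[end - u]:
                others = [b for b in "ACGT" if b != seq[end - u]]
                seq[end] = others[rng.integers(len(others))]
        text = "".join(seq)
        catalog = find_ssrs([(seq_id, text)], rules)
        if {(l.start, l.end, l.motif) for l in catalog.loci} == truth_keys:
            record = SeqRecord(Seq(text), id=seq_id, description="synthetic")
            return [record], SSRCatalog(loci=truth_loci, genome_length=spec.length)
    raise SpecError("could not realize a background free of accidental tracts")


# ---------------------------------------------------------------------------
# populations


@dataclass
class PopulationSpec:
    n_accessions: int = 57
    na_per_locus: list[int] = dc_field(default_factory=lambda: list(DEFAULT_NA))
    marker_names: list[str] | None = None
    n_groups: int = 5
    within_group_similarity: float = 0.90
    between_group_similarity: float = 0.72
    allele_freq_prior: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_names is None:
            if len(self.na_per_locus) == len(DEFAULT_MARKER_NAMES):
                self.marker_names = list(DEFAULT_MARKER_NAMES)
            else:
                self.marker_names = [
                    f"SSR{i + 1}" for i in range(len(self.na_per_locus))
                ]
        if len(self.marker_names) != len(self.na_per_locus):
            raise SpecError("marker_names and na_per_locus lengths differ")
        if any(na < 1 for na in self.na_per_locus):
            raise SpecError("allele counts must be >= 1")
        if not (0.0 <= self.between_group_similarity
                < self.within_group_similarity <= 1.0):
            raise SpecError("need 0 <= between < within <= 1")
        if not 1 <= self.n_groups <= self.n_accessions:
            raise SpecError("n_groups must be in [1, n_accessions]")
        if self.allele_freq_prior <= 0:
            raise SpecError("Dirichlet concentration must be positive")


@dataclass
class PopulationTruth:
    """Generator-side ground truth for scoring downstream stages."""

    group_labels: dict[str, int]
    consensus: dict[tuple[int, str], tuple[int, ...]]  # (group, marker) -> slots
    presence_probs: dict[tuple[int, str], np.ndarray]  # P(band j present)
    band_freqs: dict[tuple[int, str], np.ndarray]  # normalized presence probs
    allele_sizes: dict[str, np.ndarray]
    mutation_rate: float
    discriminating_loci: list[str]
    expected_within: float
    expected_between: float | None


def _presence_probs(consensus: tuple[int, ...], w: np.ndarray, m: float) -> np.ndarray:
    """P(band j present) for one accession under slot mutation rate m."""
    s1 = m * w.copy()
    s2 = m * w.copy()
    s1[consensus[0]] += 1 - m
    s2[consensus[-1]] += 1 - m
    return 1.0 - (1.0 - s1) * (1.0 - s2)


def _agreement(pi_a: np.ndarray, pi_b: np.ndarray) -> float:
    """Expected number of agreeing band columns for independent accessions."""
    return float((pi_a * pi_b + (1 - pi_a) * (1 - pi_b)).sum())


def simulate_population(
    spec: PopulationSpec,
) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Structured genotypes whose similarity statistics match the spec.

    Returns the genotype matrix and a truth object holding group labels,
    per-group band presence probabilities (pre coverage-patch), and the
    calibrated parameters.  Every one of the ``sum(na_per_locus)``
    alleles is guaranteed to occur in at least one accession.
    """
    rng = np.random.default_rng(spec.seed)
    n, loci, groups = spec.n_accessions, spec.marker_names, spec.n_groups
    n_loci = len(loci)
    total_columns = int(sum(spec.na_per_locus))

    # group membership: contiguous near-equal blocks
    blocks = np.array_split(np.arange(n), groups)
    label_of = np.empty(n, dtype=int)
    for g, block in enumerate(blocks):
        label_of[block] = g
    accessions = [f"HM{i + 1:02d}" for i in range(n)]

    # allele size ladders and locus-level frequency weights
    sizes: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    base_consensus: dict[str, tuple[int, ...]] = {}
    shuffles: dict[str, np.ndarray] = {}
    group_orders: dict[str, np.ndarray] = {}
    for name, na in zip(loci, spec.na_per_locus):
        base = int(rng.integers(100, 300))
        sizes[name] = base + 2 * np.arange(na)
        w = rng.dirichlet(np.full(na, spec.allele_freq_prior))
        weights[name] = w
        if na == 1:
            base_consensus[name] = (0,)
        else:
            pair = rng.choice(na, size=2, replace=False, p=w)
            base_consensus[name] = tuple(int(x) for x in pair)
        shuffles[name] = rng.permutation(na)
        group_orders[name] = rng.permutation(spec.n_groups)

    # --- calibrate mutation rate and discriminating loci
    def cyclic_consensus(name: str, g: int) -> tuple[int, ...]:
        # deal pairs from a shuffled allele ladder, in a per-locus random
        # group order so wraparound overlaps differ from locus to locus
        na = len(sizes[name])
        if na == 1:
            return (0,)
        order = shuffles[name]
        slot = int(group_orders[name][g])
        a = int(order[(2 * slot) % na])
        b = int(order[(2 * slot + 1) % na])
        if a == b:  # odd wrap on tiny ladders
            b = int(order[(2 * slot + 2) % na])
        return (a, b)

    def consensus_of(name: str, g: int, discr: set[str]) -> tuple[int, ...]:
        return cyclic_consensus(name, g) if name in discr else base_consensus[name]

    def expected_within(m: float, discr: set[str]) -> float:
        total = 0.0
        for name in loci:
            for g in range(groups):
                pi = _presence_probs(consensus_of(name, g, discr), weights[name], m)
                total += _agreement(pi, pi)
        return total / (groups * total_columns)

    def expected_between_of(m: float, discr: set[str]) -> float:
        total, n_pairs = 0.0, groups * (groups - 1) // 2
        for name in loci:
            pis = [
                _presence_probs(consensus_of(name, g, discr), weights[name], m)
                for g in range(groups)
            ]
            total += sum(
                _agreement(pis[g], pis[h])
                for g in range(groups)
                for h in range(g + 1, groups)
            )
        return total / (n_pairs * total_columns)

    def solve_m(discr: set[str]) -> float:
        if expected_within(1.0, discr) > target_w:
            raise CalibrationError(
                "within-group similarity target is below the fully random level"
            )
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if expected_within(mid, discr) > target_w:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    target_w = spec.within_group_similarity
    discr: set[str] = set()
    m = solve_m(discr)
    expected_between: float | None = None
    if groups > 1:
        # alternate: pick the discriminating set under the current mutation
        # rate, then re-solve the rate under the chosen set (two passes
        # suffice; the rate moves only slightly with the set)
        for _ in range(2):
            deficits: dict[str, float] = {}
            for name in loci:
                pis = [
                    _presence_probs(cyclic_consensus(name, g), weights[name], m)
                    for g in range(groups)
                ]
                base_pi = _presence_probs(base_consensus[name], weights[name], m)
                within_level = np.mean([_agreement(pi, pi) for pi in pis])
                shared_level = _agreement(base_pi, base_pi)
                between_level = np.mean(
                    [
                        _agreement(pis[g], pis[h])
                        for g in range(groups)
                        for h in range(g + 1, groups)
                    ]
                )
                # switching a locus to its own per-group consensus changes
                # the between-group agreement by (between - shared) and the
                # within-group agreement by (within - shared); the subset
                # sum targets the *gap* between the two similarity levels
                deficits[name] = float(within_level - between_level)
            needed = (target_w - spec.between_group_similarity) * total_columns
            remaining = needed
            discr = set()
            for name in sorted(loci, key=lambda l: -deficits[l]):
                if deficits[name] <= 0:
                    continue
                if abs(remaining - deficits[name]) < abs(remaining):
                    discr.add(name)
                    remaining -= deficits[name]
            if remaining > 0.03 * total_columns:
                raise CalibrationError(
                    "between-group similarity target is unattainable: the "
                    "loci cannot absorb the required consensus divergence"
                )
            m = solve_m(discr)
        expected_between = expected_between_of(m, discr)
    discriminating = sorted(discr)

    consensus: dict[tuple[int, str], tuple[int, ...]] = {}
    for g in range(groups):
        for name in loci:
            consensus[(g, name)] = consensus_of(name, g, discr)

    # --- draw accession genotypes (slot indices per locus)
    slot_calls: dict[tuple[str, str], list[int]] = {}
    for i, acc in enumerate(accessions):
        g = label_of[i]
        for name in loci:
            na = len(sizes[name])
            cons = consensus[(g, name)]
            slots = []
            for c in (cons[0], cons[-1]):
                if rng.random() < m:
                    slots.append(int(rng.choice(na, p=weights[name])))
                else:
                    slots.append(int(c))
            slot_calls[(acc, name)] = slots

    # --- missingness, then patch so every allele class is observed
    if spec.missing_rate > 0:
        for key in list(slot_calls):
            if rng.random() < spec.missing_rate:
                slot_calls[key] = []

    for name in loci:
        na = len(sizes[name])
        counts = np.zeros(na, dtype=int)
        for acc in accessions:
            for j in set(slot_calls[(acc, name)]):
                counts[j] += 1
        for j in np.flatnonzero(counts == 0):
            perm = rng.permutation(n)
            placed = False
            for i in perm:  # prefer single-band cells: add without removing
                acc = accessions[i]
                slots = slot_calls[(acc, name)]
                if slots and len(set(slots)) == 1:
                    slot_calls[(acc, name)] = [slots[0], int(j)]
                    counts[j] += 1
                    placed = True
                    break
            if not placed:
                for i in perm:  # else replace a band that is carried elsewhere
                    acc = accessions[i]
                    slots = slot_calls[(acc, name)]
                    for k, s in enumerate(slots):
                        if counts[s] >= 2 and slots.count(s) == 1:
                            counts[s] -= 1
                            slots[k] = int(j)
                            counts[j] += 1
                            placed = True
                            break
                    if placed:
                        break
            if not placed:
                raise CalibrationError(
                    f"could not place allele {j} of locus {name}"
                )

    markers = [
        Marker(
            name=name,
            forward_primer="".join(rng.choice(list("ACGT"), size=20)),
            reverse_primer="".join(rng.choice(list("ACGT"), size=20)),
            display_order=i + 1,
        )
        for i, name in enumerate(loci)
    ]
    calls = {
        (acc, name): frozenset(int(sizes[name][s]) for s in slots)
        for (acc, name), slots in slot_calls.items()
        if slots
    }
    matrix = GenotypeMatrix(accessions=accessions, markers=markers, calls=calls)

    presence: dict[tuple[int, str], np.ndarray] = {}
    band_freqs: dict[tuple[int, str], np.ndarray] = {}
    for g in range(groups):
        for name in loci:
            pi = _presence_probs(consensus[(g, name)], weights[name], m)
            presence[(g, name)] = pi
            band_freqs[(g, name)] = pi / pi.sum()
    truth = PopulationTruth(
        group_labels={acc: int(label_of[i]) for i, acc in enumerate(accessions)},
        consensus=consensus,
        presence_probs=presence,
        band_freqs=band_freqs,
        allele_sizes=sizes,
        mutation_rate=m,
        discriminating_loci=discriminating,
        expected_within=expected_within(m, discr),
        expected_between=expected_between,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# trait metadata


def simulate_traits(
    n: int,
    codebook: IDCodeBook | None = None,
    group_labels: dict[str, int] | None = None,
    seed: int = 0,
    color_group_correlation: float = 1.0,
    white_fraction: float = 18 / 57,
) -> pd.DataFrame:
    """Qualitative trait metadata, one row per accession.

    The number of white accessions is ``round(n * white_fraction)``
    (18 of 57 by default).  When group labels are supplied, members of
    the largest group are colored white with probability
    ``color_group_correlation`` before the remaining white quota is
    spread over the other accessions, emulating a color-linked cluster.
    Every drawn level is guaranteed to be encodable by the code book.
    """
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(seed)
    if group_labels is not None:
        accessions = list(group_labels)
    else:
        accessions = [f"HM{i + 1:02d}" for i in range(n)]
    if len(accessions) != n:
        raise ValueError("n must match the number of labelled accessions")

    data: dict[str, list[str]] = {}
    for field_name, levels in {
        **codebook.trait_fields,
        **codebook.supplementary_fields,
    }.items():
        level_names = list(levels)
        if field_name == "color" and set(level_names) >= {"brown", "white"}:
            quota = round(n * white_fraction)
            white: set[str] = set()
            if group_labels is not None and quota > 0:
                tally: dict[int, int] = {}
                for g in group_labels.values():
                    tally[g] = tally.get(g, 0) + 1
                designated = max(sorted(tally), key=lambda g: tally[g])
                for acc in accessions:
                    if len(white) >= quota:
                        break
                    if group_labels[acc] == designated and (
                        rng.random() < color_group_correlation
                    ):
                        white.add(acc)
            others = [a for a in accessions if a not in white]
            fill = rng.permutation(len(others))
            for k in fill:
                if len(white) >= quota:
                    break
                white.add(others[k])
            data[field_name] = [
                "white" if a in white else "brown" for a in accessions
            ]
        else:
            k = len(level_names)
            p = np.array([0.55, 0.2, 0.15, 0.1][:k] + [0.0] * max(0, k - 4))
            p = (p if p.sum() else np.ones(k)) / max(p.sum(), 1e-12)
            draws = rng.choice(level_names, size=n, p=p)
            data[field_name] = list(draws)
    return pd.DataFrame(data, index=pd.Index(accessions, name="accession"))
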