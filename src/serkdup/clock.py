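"""Molecular-clock dating of gene duplications from intron alignments.

After a duplication both copies accumulate mutations independently, so the
per-site divergence K between the copies grows at twice the per-lineage
substitution rate μ and the duplication age is T = K / (2μ). The default
rate is μ = 3×10⁻¹⁰ substitutions/site/year, a standard plant nuclear rate.

Mutation counting treats each maximal gap run in the alignment as a single
mutational event (one deletion/insertion, whatever its length) contributing
one site to the denominator; substitutions are mismatch columns. Whether
indel events enter the numerator is configurable (they do by default,
``subs_plus_indel_events``). The raw proportion is used as K by default —
appropriate at the shallow divergences this clock is meant for — with the
Jukes–Cantor multiple-hit correction available as an option.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentParams, AlignmentResult, global_align


class ClockError(ValueError):
    pass


@dataclass(frozen=True)
class MutationCounts:
    substitutions: int
    indel_events: int
    matched_columns: int  # ungapped columns (matches + mismatches)
    gap_columns: int = 0

    def __post_init__(self):
        if min(self.substitutions, self.indel_events, self.matched_columns,
               self.gap_columns) < 0:
            raise ClockError("negative mutation count")
        if self.substitutions > self.matched_columns:
            raise ClockError("substitutions exceed ungapped columns")

    def __add__(self, other: "MutationCounts") -> "MutationCounts":
        return MutationCounts(
            self.substitutions + other.substitutions,
            self.indel_events + other.indel_events,
            self.matched_columns + other.matched_columns,
            self.gap_columns + other.gap_columns,
        )


@dataclass(frozen=True)
class ClockConfig:
    rate_mu: float = 3e-10  # substitutions/site/year, per lineage
    mutation_mode: str = "subs_plus_indel_events"  # or "subs_only"
    correction: str = "raw_p"  # or "jc69"

    def __post_init__(self):
        if self.rate_mu <= 0:
            raise ClockError("rate_mu must be positive")
        if self.mutation_mode not in ("subs_only", "subs_plus_indel_events"):
            raise ClockError(f"unknown mutation_mode {self.mutation_mode!r}")
        if self.correction not in ("raw_p", "jc69"):
            raise ClockError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class DivergenceEstimate:
    K: float          # mutations per site
    T_years: float    # duplication age, K / (2 mu)
    site_count: int   # effective sites (ungapped columns + indel events)

    def __post_init__(self):
        if self.K < 0 or self.T_years < 0:
            raise ClockError("negative divergence")


def count_mutations(alignment: AlignmentResult) -> MutationCounts:
    """Count substitutions and maximal-gap-run indel events from columns."""
    subs = matched = gaps = indels = 0
    in_gap = False
    for cls in alignment.column_classes:
        if cls in ("gap_a", "gap_b"):
            gaps += 1
            if not in_gap:
                indels += 1
                in_gap = True
        else:
            in_gap = False
            matched += 1
            if cls == "mismatch":
                subs += 1
    return MutationCounts(subs, indels, matched, gaps)


def estimate_age(counts: MutationCounts, config: ClockConfig | None = None
                 ) -> DivergenceEstimate:
    """Convert pooled mutation counts into a duplication-age estimate."""
    config = config or ClockConfig()
    sites = counts.matched_columns + counts.indel_events
    if sites <= 0:
        raise ClockError("zero effective sites")
    if config.mutation_mode == "subs_plus_indel_events":
        mutations = counts.substitutions + counts.indel_events
    else:
        mutations = counts.substitutions
    p = mutations / sites
    if config.correction == "jc69":
        if p >= 0.75:
            raise ClockError(f"p = {p:.4f} ≥ 3/4: JC69 distance undefined")
        K = -0.75 * math.log(1 - 4 * p / 3)
    else:
        K = p
    return DivergenceEstimate(K, K / (2 * config.rate_mu), sites)


def pair_counts(
    introns_a: list[str],
    introns_b: list[str],
    params: AlignmentParams | None = None,
) -> MutationCounts:
    """Align corresponding introns (i vs i) and pool mutation counts."""
    if len(introns_a) != len(introns_b):
        raise ClockError(
            f"intron count mismatch: {len(introns_a)} vs {len(introns_b)}"
        )
    total = MutationCounts(0, 0, 0, 0)
    for sa, sb in zip(introns_a, introns_b):
        total = total + count_mutations(global_align(sa, sb, params))
    return total


def pairwise_age_matrix(
    genes: dict[str, list[str]],
    params: AlignmentParams | None = None,
    config: ClockConfig | None = None,
):
    """Pairwise duplication-age matrix from per-gene ordered intron lists.

    Intron i of one gene is aligned against intron i of the other; mutation
    counts and sites are pooled across introns (length-weighted by
    construction, not a mean of per-intron ratios) and converted into one
    age per gene pair. Returns (names, age_matrix_years).
    """
    config = config or ClockConfig()
    names = sorted(genes)
    if len(names) < 2:
        raise ClockError("need at least 2 genes")
    n_introns = {name: len(genes[name]) for name in names}
    if len(set(n_introns.values())) != 1:
        raise ClockError(f"intron count mismatch across genes: {n_introns}")
    n = len(names)
    ages = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        counts = pair_counts(genes[names[i]], genes[names[j]], params)
        est = estimate_age(counts, config)
        ages[i, j] = ages[j, i] = est.T_years
    return names, ages
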