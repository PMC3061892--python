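"""Seeded synthetic-data generators for every pipeline stage.

Three generators, all byte-reproducible under a fixed seed:

* ``simulate_duplication_history`` — a tandem gene family descending from a
  caterpillar series of timed duplication events, evolving intron sequences
  under a Jukes–Cantor substitution process at per-lineage rate μ
  (substitutions/site/year). Default event times 3.25, 3.05, 2.65 and 2.2
  million years and μ = 3×10⁻¹⁰ give a five-gene family whose introns carry
  the divergence signal the clock-dating stage estimates.

* ``make_sv_fixture`` — an 11-exon gene plus seven transcripts (SV1..SV7)
  realizing the canonical structure, intron retention of introns 5/6/8 and
  exon-3 skipping, engineered so retained introns 5 and 8 introduce in-frame
  premature stops and the encoded protein lengths are 586, 271, 562, 247 and
  154 (×3) aa.

* ``simulate_qpcr`` — logistic-saturating amplification curves with known
  true efficiency, plus a Ct-table generator with planted fold-changes for
  validating the Pfaffl quantification stage end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gene_models import GeneModel, GenomeSequence
from .qpcr import AmplificationCurve

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STOPS = {"TAA", "TAG", "TGA"}
# codons free of stop codons and of ATG, for engineered coding sequence
_CODON_POOL = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG"
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Duplication-history simulator


@dataclass(frozen=True)
class SimulationTruth:
    event_times_years: tuple[float, ...]  # descending: oldest first
    gene_names: tuple[str, ...]
    mu: float
    seed: int
    true_age_matrix: np.ndarray  # MRCA event time per gene pair

    @property
    def newick(self) -> str:
        """Caterpillar truth topology with heights in years."""
        names, times = self.gene_names, self.event_times_years

        def build(k: int) -> tuple[str, float]:
            if k == len(times):
                return names[k], 0.0
            inner, h = build(k + 1)
            t = times[k]
            return f"({names[k]}:{t:.10g},{inner}:{t - h:.10g})", t

        s, _ = build(0)
        return s + ";"


def _mutate(seq: np.ndarray, duration: float, mu: float,
            rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor evolution of a base-coded sequence along one lineage.

    Each site substitutes with probability 3/4·(1 − exp(−4μt/3)) — the JC
    transition probability — to a uniformly chosen different base.
    """
    p = 0.75 * (1.0 - math.exp(-4.0 * mu * duration / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def _apply_indels(seq: np.ndarray, duration: float, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Optional Poisson indel events with geometric lengths (mean 2)."""
    n_events = rng.poisson(rate * duration * seq.size)
    for _ in range(n_events):
        length = int(rng.geometric(0.5))
        pos = int(rng.integers(0, seq.size + 1))
        if rng.random() < 0.5 and seq.size > length:  # deletion
            seq = np.delete(seq, slice(min(pos, seq.size - length),
                                       min(pos, seq.size - length) + length))
        else:  # insertion
            ins = rng.integers(0, 4, size=length, dtype=seq.dtype)
            seq = np.insert(seq, min(pos, seq.size), ins)
    return seq


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def simulate_duplication_history(
    event_times: list[float] | None = None,
    mu: float = 3e-10,
    n_introns: int = 10,
    intron_lengths: list[int] | None = None,
    indel_rate: float = 0.0,
    seed: int = 0,
):
    """Simulate a tandem family from a caterpillar duplication history.

    Returns (genes, truth): ``genes`` maps gene name → ordered intron
    sequence list (intron i of every gene is homologous), ``truth`` records
    the event times, μ, seed and the exact pairwise MRCA-age matrix.
    """
    if event_times is None:
        event_times = [3.25e6, 3.05e6, 2.65e6, 2.2e6]
    event_times = [float(t) for t in event_times]
    if any(t < 0 for t in event_times) or mu <= 0 or indel_rate < 0:
        raise SimulationError("negative rate or event time")
    if sorted(event_times, reverse=True) != event_times:
        raise SimulationError("event_times must be sorted descending (oldest first)")
    rng = np.random.default_rng(seed)
    if intron_lengths is None:
        intron_lengths = [int(L) for L in rng.integers(400, 1601, size=n_introns)]
    if len(intron_lengths) != n_introns:
        raise SimulationError("intron_lengths must have n_introns entries")

    n_genes = len(event_times) + 1
    names = tuple(f"G{i+1}" for i in range(n_genes))
    ancestral = [rng.integers(0, 4, size=L, dtype=np.uint8)
                 for L in intron_lengths]

    def evolve(introns, duration):
        out = []
        for s in introns:
            s2 = _mutate(s, duration, mu, rng)
            if indel_rate > 0:
                s2 = _apply_indels(s2, duration, indel_rate, rng)
            out.append(s2)
        return out

    genes: dict[str, list[str]] = {}
    # caterpillar: at event k (time t_k) gene k splits off the backbone
    backbone = ancestral
    prev_t = event_times[0] if event_times else 0.0
    for k, name in enumerate(names):
        if k < len(event_times):
            t_split = event_times[k]
            # advance the backbone from the previous split down to this one
            backbone = evolve(backbone, prev_t - t_split)
            # the new copy evolves independently from t_split to the present
            genes[name] = [_decode(s) for s in evolve(backbone, t_split)]
            prev_t = t_split
        else:
            genes[name] = [_decode(s) for s in evolve(backbone, prev_t)]

    ages = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            ages[i, j] = ages[j, i] = event_times[min(i, j)]
    truth = SimulationTruth(tuple(event_times), names, mu, seed, ages)
    return genes, truth


# ---------------------------------------------------------------------------
# Splice-variant fixture

SV_EXON_LENGTHS = (150, 150, 72, 75, 75, 96, 96, 96, 300, 300, 351)

SV_STRUCTURES: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    # variant -> (skipped exons, retained introns)
    "SV1": ((), ()),
    "SV2": ((), (8,)),
    "SV3": ((3,), ()),
    "SV4": ((3,), (8,)),
    "SV5": ((3,), (5, 6)),
    "SV6": ((3,), (5, 8)),
    "SV7": ((3,), (5,)),
}


@dataclass
class SvFixture:
    genome: GenomeSequence
    model: GeneModel
    transcripts: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def _random_intron(rng: np.random.Generator, length: int,
                   stop: str | None = None, stop_at: int = 0) -> str:
    """Intron text over {C,G,T} (so no ATG and no stop codon can occur in any
    frame), optionally carrying one designed in-frame stop codon."""
    chars = np.array(list("CGT"))
    body = "".join(rng.choice(chars, size=length))
    if stop is None:
        return body
    if stop_at + 4 > length:
        raise SimulationError("intron too short for designed stop")
    # the base after the stop is fixed to C so the stop's trailing A can
    # never seed a spurious ATG across the junction
    return body[:stop_at] + stop + "C" + body[stop_at + 4:]


def make_sv_fixture(seed: int = 0, flank: int = 30) -> SvFixture:
    """Build the default 11-exon splice-variant fixture.

    The CDS is 586 sense codons + TAA assembled from codons that are neither
    stops nor ATG (so the annotated start and the planted exon-9 ATG are the
    only in-frame methionines); exon boundaries fall at the cumulative
    lengths of SV_EXON_LENGTHS. Intron 5 opens with 12 nt of sense codons
    then TGA; intron 8 opens with one sense codon then TAA; all intron text
    otherwise avoids A entirely, so no spurious start or stop codon can
    arise inside an intron. Together these make each PTC variant's
    secondary ORF start at the ATG opening exon 9.
    """
    rng = np.random.default_rng(seed)
    total = sum(SV_EXON_LENGTHS)
    assert total % 3 == 0
    n_codons = total // 3
    pool = np.array(_CODON_POOL)
    codons = list(rng.choice(pool, size=n_codons))
    codons[0] = "ATG"
    exon9_start = sum(SV_EXON_LENGTHS[:8])  # 810, a codon boundary
    codons[exon9_start // 3] = "ATG"  # exon 9 opens with the secondary start
    codons[-1] = "TAA"  # canonical stop ends exon 11
    cds = "".join(codons)

    # split CDS into exons
    exon_seqs = []
    off = 0
    for L in SV_EXON_LENGTHS:
        exon_seqs.append(cds[off:off + L])
        off += L

    intron_lens = [int(L) for L in rng.integers(61, 121, size=10)]
    intron_seqs = []
    for i, L in enumerate(intron_lens, start=1):
        if i == 5:
            intron_seqs.append(_random_intron(rng, L, stop="TGA", stop_at=12))
        elif i == 8:
            intron_seqs.append(_random_intron(rng, L, stop="TAA", stop_at=3))
        else:
            intron_seqs.append(_random_intron(rng, L))

    chars = np.array(list("CGT"))
    flank5 = "".join(rng.choice(chars, size=flank))
    flank3 = "".join(rng.choice(chars, size=flank))

    parts = [flank5]
    exons: list[tuple[int, int]] = []
    pos = len(flank5)
    for k in range(11):
        exons.append((pos, pos + SV_EXON_LENGTHS[k]))
        parts.append(exon_seqs[k])
        pos += SV_EXON_LENGTHS[k]
        if k < 10:
            parts.append(intron_seqs[k])
            pos += intron_lens[k]
    parts.append(flank3)
    genome = GenomeSequence("svfix_chr", "".join(parts))
    model = GeneModel("MtSERK3-like", "svfix_chr", exons, cds_start_offset=0)
    model.validate(genome)

    from .gene_models import TranscriptStructure, splice

    transcripts = {}
    for vid, (skipped, retained) in SV_STRUCTURES.items():
        kept = tuple(i for i in range(1, 12) if i not in skipped)
        structure = TranscriptStructure(kept, retained)
        transcripts[vid] = splice(model, genome, structure)
    return SvFixture(genome, model, transcripts, seed)


# ---------------------------------------------------------------------------
# qPCR curve and Ct-table simulators


def simulate_qpcr(
    e_true: float = 1.9,
    f0: float = 1e-3,
    n_cycles: int = 40,
    plateau: float = 100.0,
    noise_sd: float = 0.0,
    n_wells: int = 1,
    seed: int = 0,
) -> list[AmplificationCurve]:
    """Logistic-saturating amplification curves with known efficiency.

    F_c = plateau / (1 + (plateau/F0 − 1)·E^(−c)), times multiplicative
    Gaussian noise (1 + ε), ε ~ N(0, noise_sd²). E = 1 is allowed and yields
    a flat curve (the no-amplification boundary).
    """
    if not (1.0 <= e_true <= 2.2):
        raise SimulationError(f"e_true {e_true} outside [1, 2.2]")
    if f0 <= 0 or plateau <= f0 or n_cycles < 8 or noise_sd < 0:
        raise SimulationError("invalid curve parameters")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    curves = []
    for w in range(n_wells):
        f = plateau / (1.0 + (plateau / f0 - 1.0) * e_true ** (-cycles.astype(float)))
        if noise_sd > 0:
            f = f * (1.0 + rng.normal(0.0, noise_sd, size=f.size))
        f = np.clip(f, 0.0, None)
        curves.append(AmplificationCurve(f"well{w+1}", tuple(cycles), tuple(f)))
    return curves


def simulate_ct_table(
    fold_changes: dict[str, dict[str, float]],
    efficiency: float = 2.0,
    reference_gene: str = "GAPDH",
    calibrator_timepoint: str = "week0",
    n_repeats: int = 3,
    ct_base: float = 25.0,
    ref_ct: float = 18.0,
):
    """Ct table with planted fold-changes (exact inverse of the Pfaffl ratio).

    ``fold_changes`` maps gene → {timepoint: true ratio vs the calibrator}.
    The reference gene is held constant, so recovered ratios equal the
    planted ones exactly. Returns (DataFrame, efficiencies dict).
    """
    import pandas as pd

    rows = []
    timepoints = [calibrator_timepoint] + [
        tp for tps in fold_changes.values() for tp in tps
        if tp != calibrator_timepoint
    ]
    timepoints = list(dict.fromkeys(timepoints))
    for gene, tps in fold_changes.items():
        for tp in timepoints:
            fold = 1.0 if tp == calibrator_timepoint else tps.get(tp, 1.0)
            # ratio = E^(Ct_cal - Ct_tp) with constant reference
            ct_tp = ct_base - math.log(fold, efficiency)
            for rep in range(1, n_repeats + 1):
                rows.append((gene, tp, rep, ct_tp))
    for tp in timepoints:
        for rep in range(1, n_repeats + 1):
            rows.append((reference_gene, tp, rep, ref_ct))
    df = pd.DataFrame(rows, columns=["gene", "timepoint", "repeat", "Ct"])
    effs = {g: efficiency for g in fold_changes}
    effs[reference_gene] = efficiency
    return df, effs
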