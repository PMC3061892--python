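"""Degenerate-primer arithmetic and in-silico PCR.

A degenerate primer is an oligonucleotide mixture written with IUPAC
ambiguity codes; its degeneracy is the number of concrete sequences the
mixture encodes (the product over positions of ambiguity-set sizes).
Matching is exact IUPAC compatibility — zero mismatches — with the reverse
primer supplied 5'→3' on the antisense strand and matched as its reverse
complement on the template (standard PCR convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    sequence: str
    orientation: str = "forward"  # or "reverse"

    def __post_init__(self):
        seq = self.sequence.replace(" ", "").upper()
        if not seq:
            raise PrimerError(f"primer {self.name!r} is empty")
        for pos, ch in enumerate(seq, start=1):
            if ch not in IUPAC_SETS:
                raise PrimerError(
                    f"primer {self.name!r}: invalid IUPAC code {ch!r} "
                    f"at position {pos}"
                )
        if self.orientation not in ("forward", "reverse"):
            raise PrimerError(f"orientation must be forward/reverse")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    fwd_match_start: int  # 0-based on template
    rev_match_start: int  # 0-based start of the reverse-primer site
    amplicon_length: int  # bp, inclusive of both primer sites


def reverse_complement_iupac(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def degeneracy(primer: DegeneratePrimer | str) -> int:
    """Number of concrete sequences the primer encodes."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    n = 1
    for pos, ch in enumerate(seq.replace(" ", "").upper(), start=1):
        if ch not in IUPAC_SETS:
            raise PrimerError(f"invalid IUPAC code {ch!r} at position {pos}")
        n *= len(IUPAC_SETS[ch])
    return n


def specific_3prime_run(primer: DegeneratePrimer | str) -> int:
    """Length of the maximal non-degenerate (A/C/G/T only) 3' suffix."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    seq = seq.replace(" ", "").upper()
    run = 0
    for ch in reversed(seq):
        if ch in "ACGT":
            run += 1
        else:
            break
    return run


def expand(primer: DegeneratePrimer | str, cap: int = 65_536) -> list[str]:
    """All concrete expansions in lexicographic order; refuses above cap."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer
    seq = seq.replace(" ", "").upper()
    d = degeneracy(seq)
    if d > cap:
        raise PrimerError(f"degeneracy {d} exceeds expansion cap {cap}")
    choices = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return ["".join(p) for p in itertools.product(*choices)]


def matches_at(template: str, primer_seq: str, pos: int) -> bool:
    """IUPAC compatibility at template position ``pos``.

    Template N is permissive (drafts contain N runs); a concrete template
    base must belong to the primer position's IUPAC set.
    """
    if pos < 0 or pos + len(primer_seq) > len(template):
        return False
    for ch_p, ch_t in zip(primer_seq, template[pos : pos + len(primer_seq)]):
        if ch_t == "N":
            continue
        if ch_t not in IUPAC_SETS[ch_p]:
            return False
    return True


def find_sites(template: str, primer_seq: str) -> list[int]:
    """All 0-based template positions where the primer is IUPAC-compatible."""
    m = len(primer_seq)
    return [
        i for i in range(len(template) - m + 1)
        if matches_at(template, primer_seq, i)
    ]


def insilico_pcr(
    template: str,
    fwd: DegeneratePrimer | str,
    rev: DegeneratePrimer | str,
    template_id: str = "template",
    max_product: int = 5_000,
) -> list[AmpliconPrediction]:
    """Predict amplicons: forward sites paired with downstream
    reverse-complemented reverse-primer sites, within max_product bp.

    Results are sorted by amplicon length, then by forward position.
    """
    template = template.upper()
    fseq = fwd.sequence if isinstance(fwd, DegeneratePrimer) else fwd.upper()
    rseq = rev.sequence if isinstance(rev, DegeneratePrimer) else rev.upper()
    rsite = reverse_complement_iupac(rseq)
    fwd_hits = find_sites(template, fseq)
    rev_hits = find_sites(template, rsite)
    out = []
    for f in fwd_hits:
        for r in rev_hits:
            if r < f:  # reverse site must lie downstream of the fwd start
                continue
            length = (r + len(rsite)) - f
            if length <= 0 or length > max_product:
                continue
            out.append(AmpliconPrediction(template_id, f, r, length))
    out.sort(key=lambda a: (a.amplicon_length, a.fwd_match_start))
    return out


# Printed primer sequences from the degenerate-PCR design this package
# reproduces (kinase-domain SERK primers).
FORWARD_1 = DegeneratePrimer("Forward1", "CARTTYCARCANGARGTNGAAATGAT", "forward")
FORWARD_2 = DegeneratePrimer("Forward2", "CARTTYCARCANGARGTNGAGATGAT", "forward")
REVERSE_1 = DegeneratePrimer("Reverse1", "CCRTANCCRAANACRTCNGTYTTTTC", "reverse")
REVERSE_2 = DegeneratePrimer("Reverse2", "CCRTANCCRAANACRTCNGTYTTCTC", "reverse")
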