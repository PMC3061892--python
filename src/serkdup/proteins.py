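"""SERK-diagnostic motif scanning and ProtParam-style protein statistics.

The leucine-zipper consensus scanned here is Leu-X6-Leu-X6-Leu-X6-Leu with X
any residue and Leu strictly leucine; proteins with no full match but at
least one Leu-X6-Leu window are reported as carrying a partial zipper. The
SPP motif defaults to the literal tripeptide "SPP" (configurable, since the
signature is a highlighted region rather than a published regex).

Molecular weight uses average isotopic residue masses plus one water;
isoelectric point is solved by bisection of the net-charge curve with the
Bjellqvist pKa set (the table behind the Expasy ProtParam tool).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.SeqUtils.ProtParam import ProteinAnalysis

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Bjellqvist pKa values: positively charged groups and negatively charged
# groups (N/C termini plus ionizable side chains). The terminal pKa depends
# on which residue carries the terminus.
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                 "V": 7.44, "E": 7.7}
PKA_CTERMINAL = {"D": 4.55, "E": 4.75}


class ProteinError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based position in the protein
    matched_text: str


@dataclass(frozen=True)
class ProteinStats:
    length: int
    mw: float  # Da, average isotopic
    pi: float

    def __post_init__(self):
        if self.length < 1 or self.mw <= 0 or not (0 < self.pi < 14):
            raise ProteinError("invalid protein statistics")


def _clean(protein: str, context: str) -> str:
    protein = protein.upper().replace("*", "")
    if not protein:
        raise ProteinError(f"{context}: empty protein sequence")
    return protein


def find_leucine_zipper(protein: str):
    """Scan for the zipper consensus; returns (hits, status).

    status: "full" when some 22-residue window reads L-X6-L-X6-L-X6-L,
    "partial" when only an L-X6-L window exists, "absent" otherwise.
    Non-standard residues are treated as X, with a warning. All full hits
    (including overlapping ones) are reported.
    """
    protein = _clean(protein, "find_leucine_zipper")
    nonstd = set(protein) - AMINO_ACIDS
    if nonstd:
        warnings.warn(
            f"non-standard residues {sorted(nonstd)} treated as X",
            stacklevel=2,
        )
    hits = []
    n = len(protein)
    for i in range(n - 21):
        if all(protein[i + 7 * k] == "L" for k in range(4)):
            hits.append(MotifHit("leucine_zipper", i + 1, protein[i:i + 22]))
    if hits:
        return hits, "full"
    partial = any(
        protein[i] == "L" and protein[i + 7] == "L" for i in range(n - 7)
    )
    return [], ("partial" if partial else "absent")


def find_spp_motif(protein: str, pattern: str = "SPP"):
    """All occurrences (including overlapping) of the SPP-motif pattern."""
    protein = _clean(protein, "find_spp_motif")
    if not pattern:
        raise ProteinError("empty SPP pattern")
    pattern = pattern.upper()
    hits = []
    start = protein.find(pattern)
    while start != -1:
        hits.append(MotifHit("spp", start + 1, pattern))
        start = protein.find(pattern, start + 1)
    return hits


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH under the Bjellqvist pKa set.

    The N- and C-terminal group pKas are adjusted for the identity of the
    terminal residues, exactly as the Bjellqvist table specifies.
    """
    counts = {aa: protein.count(aa) for aa in "KRHDECY"}
    pk_nterm = PKA_NTERMINAL.get(protein[0], PKA_POSITIVE["Nterm"])
    pk_cterm = PKA_CTERMINAL.get(protein[-1], PKA_NEGATIVE["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - pk_nterm))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    charge -= 1.0 / (1.0 + 10 ** (pk_cterm - ph))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 0.001) -> float:
    """pH at which the net charge vanishes, by bisection to ``tol``."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_stats(protein: str) -> ProteinStats:
    """Length, average molecular weight (Da) and isoelectric point."""
    protein = _clean(protein, "protein_stats")
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ProteinError(f"unknown residues {sorted(bad)}")
    mw = ProteinAnalysis(protein).molecular_weight()
    pi = isoelectric_point(protein)
    return ProteinStats(len(protein), float(mw), round(pi, 3))
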