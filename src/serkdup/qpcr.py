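"""Efficiency-corrected relative qPCR quantification.

Per-run amplification efficiency E (the per-cycle amplification factor,
1 ≤ E ≤ 2.2) is estimated from the raw fluorescence curve by a simplified
window-regression scheme: after baseline subtraction, the 4–6-point window
of consecutive above-baseline cycles whose log10-fluorescence is most
linear (max r²) gives E = 10^slope. Relative expression uses the Pfaffl
ratio, ratio = E_target^ΔCt(target) / E_ref^ΔCt(ref) with
ΔCt = Ct(calibrator) − Ct(sample), normalised to a reference gene and
calibrated to a chosen timepoint; per-timepoint results are the mean ±
standard error (sd/√n) over biological repeats.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class QpcrError(ValueError):
    pass


@dataclass(frozen=True)
class AmplificationCurve:
    well_id: str
    cycles: tuple[int, ...]
    fluorescence: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "cycles", tuple(int(c) for c in self.cycles))
        object.__setattr__(
            self, "fluorescence", tuple(float(f) for f in self.fluorescence)
        )
        if len(self.cycles) != len(self.fluorescence):
            raise QpcrError("cycles and fluorescence differ in length")
        if len(self.cycles) < 8:
            raise QpcrError("need at least 8 cycles")
        if any(b <= a for a, b in zip(self.cycles, self.cycles[1:])):
            raise QpcrError("cycles must be strictly increasing")
        if any(f < 0 for f in self.fluorescence):
            raise QpcrError("negative fluorescence reading")


@dataclass(frozen=True)
class EfficiencyEstimate:
    efficiency: float  # per-cycle amplification factor, in [1, 2.2]
    window: tuple[int, int]  # (first_cycle, last_cycle) of the fit window
    r2: float


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    timepoint: str
    ratio: float
    se: float
    n: int


def estimate_efficiency(
    curve: AmplificationCurve, baseline_cycles: int = 5
) -> EfficiencyEstimate:
    """Per-curve efficiency from the most log-linear exponential window.

    The baseline (mean of the first ``baseline_cycles`` readings) is
    subtracted; candidate points must exceed the baseline noise (3 SD) and a
    small fraction of the curve's dynamic range, which keeps the window out
    of both the noise floor and the plateau. E is clamped to [1, 2.2] with a
    warning when the fitted slope falls outside.
    """
    cyc = np.asarray(curve.cycles, dtype=float)
    flu = np.asarray(curve.fluorescence, dtype=float)
    base = flu[:baseline_cycles]
    corrected = flu - base.mean()
    floor = max(3.0 * base.std(), 1e-3 * corrected.max(), 0.0)
    above = corrected > floor
    if corrected.max() <= 0 or above.sum() < 4:
        raise QpcrError(f"well {curve.well_id!r}: no amplification detected")

    def windows(ceiling):
        out = []
        n = len(cyc)
        for size, start in itertools.product((6, 5, 4), range(n)):
            end = start + size
            if end > n or not above[start:end].all():
                continue
            if corrected[end - 1] > ceiling:
                continue
            # at least one doubling across the window: excludes windows
            # sitting on the plateau, where log-linearity is vacuous
            if corrected[end - 1] < 2.0 * corrected[start]:
                continue
            y = np.log10(corrected[start:end])
            res = stats.linregress(cyc[start:end], y)
            out.append((res.rvalue ** 2, res.slope, start, end))
        return out

    # restrict to the lowest 5% of the dynamic range first (the exponential
    # phase proper); fall back to the full range for curves without plateau
    # headroom
    cands = windows(0.05 * corrected.max()) or windows(np.inf)
    if not cands:
        raise QpcrError(f"well {curve.well_id!r}: no 4-point exponential window")
    best_r2 = max(c[0] for c in cands)
    # among near-optimal fits prefer the earliest, longest window — lowest
    # fluorescence means least saturation bias
    r2, slope, start, end = min(
        (c for c in cands if c[0] >= best_r2 - 5e-4),
        key=lambda c: (c[2], -(c[3] - c[2])),
    )
    # refine the baseline on the chosen window: the crude first-cycles mean
    # contains amplification signal, which steepens the apparent slope; the
    # baseline that maximizes within-window log-linearity removes that bias
    lo, hi = 0.0, float(flu[start:end].min()) * 0.999

    def _neg_r2(b):
        res = stats.linregress(cyc[start:end], np.log10(flu[start:end] - b))
        return -(res.rvalue ** 2)

    opt = optimize.minimize_scalar(_neg_r2, bounds=(lo, hi), method="bounded")
    refined = stats.linregress(cyc[start:end], np.log10(flu[start:end] - opt.x))
    r2, slope = refined.rvalue ** 2, refined.slope
    window = (int(cyc[start]), int(cyc[end - 1]))
    eff = 10.0 ** slope
    if eff < 1.0 or eff > 2.2:
        warnings.warn(
            f"well {curve.well_id!r}: fitted efficiency {eff:.3f} clamped "
            f"to [1, 2.2]",
            stacklevel=2,
        )
        eff = min(max(eff, 1.0), 2.2)
    return EfficiencyEstimate(float(eff), window, float(r2))


def compute_ct(curve: AmplificationCurve, threshold: float) -> float:
    """Quantification cycle by linear interpolation at a fluorescence
    threshold (a helper for synthetic curves; instruments report Ct)."""
    flu = np.asarray(curve.fluorescence, dtype=float)
    cyc = np.asarray(curve.cycles, dtype=float)
    idx = np.nonzero(flu >= threshold)[0]
    if len(idx) == 0 or idx[0] == 0:
        raise QpcrError(f"threshold {threshold} never crossed (or at cycle 1)")
    i = idx[0]
    f0, f1 = flu[i - 1], flu[i]
    return float(cyc[i - 1] + (threshold - f0) / (f1 - f0) * (cyc[i] - cyc[i - 1]))


def pfaffl_ratio(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected expression ratio E_t^ΔCt_t / E_ref^ΔCt_ref,
    with ΔCt = Ct(calibrator) − Ct(sample)."""
    for e in (e_target, e_ref):
        if e <= 0:
            raise QpcrError(f"non-positive efficiency {e}")
    return (e_target ** dct_target) / (e_ref ** dct_ref)


def timecourse_expression(
    ct_table: pd.DataFrame,
    efficiencies: dict[str, float],
    reference_gene: str,
    calibrator_timepoint: str,
) -> list[ExpressionResult]:
    """Pfaffl timecourse: per-repeat ratios vs the calibrator timepoint,
    normalised to the reference gene, then mean ± SE over repeats.

    ``ct_table`` columns: gene, timepoint, repeat, Ct. The reference gene
    must have a Ct for every (timepoint, repeat) cell used.
    """
    required = {"gene", "timepoint", "repeat", "Ct"}
    if not required.issubset(ct_table.columns):
        raise QpcrError(f"ct table must have columns {sorted(required)}")
    df = ct_table.copy()
    df["timepoint"] = df["timepoint"].astype(str)
    ct = df.set_index(["gene", "timepoint", "repeat"])["Ct"]
    if ct.index.duplicated().any():
        raise QpcrError("duplicate (gene, timepoint, repeat) rows")

    def lookup(gene, tp, rep):
        try:
            return float(ct.loc[(gene, tp, rep)])
        except KeyError:
            raise QpcrError(f"missing Ct for ({gene}, {tp}, repeat {rep})")

    genes = [g for g in df["gene"].unique() if g != reference_gene]
    timepoints = list(dict.fromkeys(df["timepoint"]))
    cal = str(calibrator_timepoint)
    if cal not in timepoints:
        raise QpcrError(f"calibrator timepoint {cal!r} not in table")
    e_ref = efficiencies[reference_gene]
    results = []
    for gene in genes:
        e_t = efficiencies[gene]
        sub = df[df["gene"] == gene]
        for tp in timepoints:
            reps = sorted(sub[sub["timepoint"] == tp]["repeat"].unique())
            if not reps:
                continue
            ratios = []
            for rep in reps:
                dct_t = lookup(gene, cal, rep) - lookup(gene, tp, rep)
                dct_r = lookup(reference_gene, cal, rep) - lookup(
                    reference_gene, tp, rep
                )
                ratios.append(pfaffl_ratio(e_t, dct_t, e_ref, dct_r))
            arr = np.asarray(ratios)
            se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            results.append(
                ExpressionResult(gene, tp, float(arr.mean()), se, len(arr))
            )
    return results
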