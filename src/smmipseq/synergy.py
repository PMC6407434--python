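"""Chou-Talalay median-effect analysis: Dm/m fits, CI, DRI, classification.

The median-effect equation fa/fu = (D/Dm)^m links dose D to the fraction
affected fa (fu = 1 - fa), with median-effect dose Dm and sigmoidicity m.
Taking logs gives the median-effect plot: log10(fa/fu) is linear in
log10(D) with slope m and x-intercept log10(Dm).  For a constant-ratio
combination, the combination index at effect level fa is

    CI = d_a / Dx_a(fa) + d_b / Dx_b(fa)

(mutually-exclusive two-term form), where Dx_i is the dose of drug i alone
producing fa and d_i its dose inside the combination producing the same
fa.  The dose-reduction index DRI_i = Dx_i / d_i, so CI = 1/DRI_a +
1/DRI_b identically.  CI below 1 indicates synergism, 1 additivity, above
1 antagonism; the finer verbal bands follow the conventional CompuSyn
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FA_LEVELS_DEFAULT = (0.5, 0.75, 0.9)
FA_CLIP = 1e-6

# (upper bound, label); intervals are half-open [lower, upper)
_CI_BANDS = [
    (0.3, "strong synergism"),  # anything below 0.3 incl. <0.1
    (0.7, "synergism"),
    (0.85, "moderate synergism"),
    (0.9, "slight synergism"),
    (1.1, "additive"),
    (1.2, "slight antagonism"),
    (1.45, "moderate antagonism"),
]
_CI_TOP_LABEL = "antagonism"  # [1.45, inf)

CLASSIFICATIONS = [label for _, label in _CI_BANDS] + [_CI_TOP_LABEL]


class SynergyError(ValueError):
    pass


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters of one dose-response curve."""

    drug_id: str
    dm: float  # median-effect dose, input dose units
    m: float  # sigmoidicity (slope of the median-effect plot)
    r: float  # linear correlation of the median-effect plot
    n_points: int

    def fa(self, dose: float) -> float:
        """Fraction affected predicted at ``dose``."""
        ratio = (dose / self.dm) ** self.m
        return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class CombinationResult:
    drug_a: str
    drug_b: str
    fa_level: float
    ci: float
    dri_a: float
    dri_b: float
    classification: str


def clip_fa(fa) -> np.ndarray:
    """Clip raw fraction-affected readouts into the open unit interval."""
    return np.clip(np.asarray(fa, dtype=float), FA_CLIP, 1.0 - FA_CLIP)


def fit_median_effect(
    doses, fa, drug_id: str = "drug", clip: bool = False
) -> MedianEffectFit:
    """Least-squares fit of the median-effect plot.

    Points with fa exactly 0 or 1 are excluded (the logit is undefined
    there); with ``clip=True`` they are instead clipped just inside the
    unit interval first, the usual treatment of saturated viability
    readouts.  At least two usable points at distinct doses are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise SynergyError("doses and fa must have equal length")
    if np.any(doses <= 0):
        raise SynergyError("doses must be positive")
    if clip:
        fa = clip_fa(fa)
    usable = (fa > 0) & (fa < 1)
    doses, fa = doses[usable], fa[usable]
    if doses.size < 2:
        raise SynergyError("need at least 2 points with fa strictly in (0, 1)")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    if np.all(x == x[0]):
        raise SynergyError("all usable points share one dose; slope undefined")
    fit = stats.linregress(x, y)
    m = fit.slope
    if not np.isfinite(m) or m <= 0:
        raise SynergyError(f"degenerate median-effect slope m={m}")
    dm = 10.0 ** (-fit.intercept / m)
    return MedianEffectFit(
        drug_id=drug_id, dm=float(dm), m=float(m), r=float(fit.rvalue), n_points=int(doses.size)
    )


def fit_dose_response_table(
    table: pd.DataFrame, drug_id: str, clip: bool = True
) -> MedianEffectFit:
    """Fit one drug from a (drug, dose, fa) table, averaging replicate doses."""
    sub = table.loc[table["drug"] == drug_id]
    if sub.empty:
        raise SynergyError(f"no rows for drug {drug_id!r}")
    averaged = sub.groupby("dose", as_index=False)["fa"].mean()
    return fit_median_effect(
        averaged["dose"].values, averaged["fa"].values, drug_id=drug_id, clip=clip
    )


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected ``fa``: Dx = Dm (fa/(1-fa))^(1/m)."""
    if not 0 < fa < 1:
        raise SynergyError(f"fa must lie strictly in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def classify_ci(ci: float) -> str:
    """Verbal synergy class of a combination index (half-open bands)."""
    if not np.isfinite(ci) or ci <= 0:
        raise SynergyError(f"combination index must be positive, got {ci}")
    for upper, label in _CI_BANDS:
        if ci < upper:
            return label
    return _CI_TOP_LABEL


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float],
    fa: float,
    mutually_exclusive: bool = True,
) -> CombinationResult:
    """CI and DRI at one fa level for a constant-ratio combination.

    ``fit_combo`` must be fitted on the total dose (sum of both
    components) of the mixture at ratio ``ratio`` = (parts drug a, parts
    drug b).  The default two-term CI is the classic mutually-exclusive
    form; ``mutually_exclusive=False`` adds the cross term
    (d_a d_b)/(Dx_a Dx_b).
    """
    ra, rb = ratio
    if ra <= 0 or rb <= 0:
        raise SynergyError("ratio components must be positive")
    dx_combo = dose_for_fa(fit_combo, fa)
    d_a = dx_combo * ra / (ra + rb)
    d_b = dx_combo * rb / (ra + rb)
    dx_a = dose_for_fa(fit_a, fa)
    dx_b = dose_for_fa(fit_b, fa)
    ci = d_a / dx_a + d_b / dx_b
    if not mutually_exclusive:
        ci += (d_a * d_b) / (dx_a * dx_b)
    return CombinationResult(
        drug_a=fit_a.drug_id,
        drug_b=fit_b.drug_id,
        fa_level=fa,
        ci=float(ci),
        dri_a=float(dx_a / d_a),
        dri_b=float(dx_b / d_b),
        classification=classify_ci(float(ci)),
    )


def dri_report(result: CombinationResult) -> str:
    """Display form 'CI (DRI_a;DRI_b)' at table precision (2 d.p.; 1 d.p.)."""
    return f"{result.ci:.2f} ({result.dri_a:.1f};{result.dri_b:.1f})"


def analyze_combination(
    table: pd.DataFrame,
    drug_a: str,
    drug_b: str,
    combo_label: str,
    ratio: tuple[float, float],
    fa_levels=FA_LEVELS_DEFAULT,
    mutually_exclusive: bool = True,
) -> pd.DataFrame:
    """Full constant-ratio workup from a (drug, dose, fa) table.

    The table must contain monotherapy rows for ``drug_a`` and ``drug_b``
    and combination rows under ``combo_label`` whose dose column is the
    total dose of the mixture.
    """
    fit_a = fit_dose_response_table(table, drug_a)
    fit_b = fit_dose_response_table(table, drug_b)
    fit_c = fit_dose_response_table(table, combo_label)
    rows = []
    for fa in fa_levels:
        res = combination_index(
            fit_a, fit_b, fit_c, ratio, fa, mutually_exclusive=mutually_exclusive
        )
        rows.append(
            {
                "combination": f"{drug_a} + {drug_b}",
                "fa": fa,
                "CI": res.ci,
                "DRI_a": res.dri_a,
                "DRI_b": res.dri_b,
                "classification": res.classification,
                "report": dri_report(res),
            }
        )
    return pd.DataFrame(rows)
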