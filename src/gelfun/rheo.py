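"""SAOS rheology reduction: sweep tables -> moduli -> Young's modulus.

Small-amplitude oscillatory shear applies gamma(t) = gamma0 * sin(omega*t)
and splits the stress response into the storage modulus G' (elastic,
in-phase) and loss modulus G'' (viscous, out-of-phase).  For these fibrin
gels G' is roughly an order of magnitude above G'' and both show a
low-frequency plateau (omega <~ 10 rad/s), evidence of a stable crosslinked
network; at high frequency (omega >~ 50 rad/s) G' rises abruptly
(thickening).  The axial stiffness follows from the complex shear modulus:

    |G*| = sqrt(G'^2 + G''^2),    E = 2 |G*| (1 + nu),

with Poisson ratio nu ~= 0.25 for fibrin matrices.

Reduction steps implemented here: torque-floor filtering (points measured
below the 2 nN*m instrument limit are unreliable), transient-time detection
on time sweeps, linear-viscoelastic-region checks on strain sweeps, plateau
extraction on frequency sweeps, Young's-modulus computation, grouping of
estimates into developmental stages — early (DIV 1-3), young (DIV 4-8),
mature (DIV 13-20) — and two-sample Student's t-tests between stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModulusSummary",
    "YoungsModulusEstimate",
    "StageComparison",
    "TORQUE_FLOOR_NNM",
    "STAGE_BINS",
    "filter_torque_floor",
    "detect_transient",
    "check_lvr",
    "plateau_modulus",
    "youngs_modulus",
    "stage_group",
    "compare_stages",
]

TORQUE_FLOOR_NNM = 2.0       # instrument lower limit of oscillation torque
PLATEAU_BAND_MAX = 10.0      # rad/s; upper edge of the low-frequency plateau
POISSON_RATIO_FIBRIN = 0.25
STAGE_BINS = {"early": (1, 3), "young": (4, 8), "mature": (13, 20)}


@dataclass
class ModulusSummary:
    """Plateau moduli and spectral features of one frequency sweep."""

    plateau_G1: float            # Pa
    plateau_G2: float            # Pa
    plateau_band: tuple[float, float]   # rad/s
    G1_over_G2: float
    thickening_onset: float | None = None   # rad/s, None if not reached
    transient_time: float | None = None     # s, from a companion time sweep
    DIV: int | None = None


@dataclass
class YoungsModulusEstimate:
    """Young's modulus from the complex shear modulus, E = 2|G*|(1 + nu)."""

    E: float
    G_star_mod: float
    nu: float = POISSON_RATIO_FIBRIN
    DIV: int | None = None
    stage: str | None = None
    replicate: int | None = None


@dataclass
class StageComparison:
    """Stage means/SDs and pairwise Student's t-test p-values."""

    means: dict[str, float]
    sds: dict[str, float]
    n: dict[str, int]
    p_values: dict[str, float]          # keys 'early-young', 'young-mature', 'early-mature'
    test: str = "student-t"
    stars: dict[str, str] = field(default_factory=dict)


# --------------------------------------------------------------------------


def filter_torque_floor(rec: pd.DataFrame, floor: float = TORQUE_FLOOR_NNM) -> pd.DataFrame:
    """Drop rows whose oscillation torque is below the instrument floor.

    Values of G' and G'' measured below 2 nN*m are unreliable and are
    discarded.  If the table has no torque column the data pass through
    with a warning.  Removing every row is an error.
    """
    if "torque_nNm" not in rec.columns:
        warnings.warn("no torque column; torque-floor filter skipped", stacklevel=2)
        return rec
    kept = rec[rec["torque_nNm"] >= floor]
    if len(kept) == 0:
        raise ValueError("torque filter removed every row")
    n_dropped = len(rec) - len(kept)
    if n_dropped:
        kept = kept.reset_index(drop=True)
    kept.attrs["n_dropped_torque"] = n_dropped
    return kept


def detect_transient(rec: pd.DataFrame, band_pct: float = 5.0,
                     smooth_samples: int | None = None) -> tuple[float, bool]:
    """Settling time of a time sweep: earliest time after which G' stays
    within +/-band_pct of the terminal plateau (mean of the last 25% of
    samples) for the remainder of the record.

    Point noise comparable to the band width would push the settling
    estimate arbitrarily late, so the trace is first smoothed with a
    centred rolling mean whose window adapts to the measured noise level
    (robustly estimated from second differences): noise-free records are
    left untouched — the band crossing then matches the analytic one
    exactly — while noisy records get a window wide enough to bring the
    residual noise well inside the band.  A rolling mean leaves a slow
    exponential relaxation essentially unbiased.  Returns
    ``(t_T, settled)``; when the trace never settles, t_T is the record
    duration and ``settled`` is False.
    """
    if "time_s" not in rec.columns:
        raise ValueError("time sweep requires a time_s column")
    df = rec.sort_values("time_s")
    t = df["time_s"].to_numpy(dtype=float)
    g1 = df["G1_Pa"].to_numpy(dtype=float)
    if t.size < 20:
        raise ValueError("need at least 20 samples to detect a transient")
    if smooth_samples is None:
        d2 = g1[2:] - 2 * g1[1:-1] + g1[:-2]
        scale = max(abs(g1[-max(1, t.size // 4):].mean()), 1e-30)
        sigma_rel = 1.4826 * np.median(np.abs(d2)) / np.sqrt(6) / scale
        band_rel = band_pct / 100.0
        if sigma_rel < band_rel / 10:
            smooth_samples = 1
        else:
            smooth_samples = int(np.clip(round((6 * sigma_rel / band_rel) ** 2),
                                         3, max(3, t.size // 6))) | 1
    if smooth_samples > 1:
        kern = np.ones(smooth_samples)
        g1 = np.convolve(g1, kern, "same") / np.convolve(
            np.ones_like(g1), kern, "same")
    tail = g1[-max(1, t.size // 4):]
    target = float(tail.mean())
    band = band_pct / 100.0 * abs(target)
    inside = np.abs(g1 - target) <= band
    # earliest index from which every later sample stays inside the band
    ok_from = np.flatnonzero(~inside[::-1])
    if ok_from.size == 0:
        return float(t[0]), True
    first_bad_from_end = ok_from[0]
    idx = t.size - first_bad_from_end
    if idx >= t.size:
        return float(t[-1]), False
    return float(t[idx]), True


def check_lvr(rec: pd.DataFrame, slope_max: float = 0.1) -> dict:
    """Linear-viscoelastic-region report for a strain sweep.

    Fits the log-log slope of G' against the strain amplitude gamma0.  A
    healthy gel shows only a slight negative trend; ``|slope| > slope_max``
    flags nonlinearity.  Also reports whether G' stays above G'' throughout
    (the moduli should not cross inside the LVR).
    """
    g0 = rec["gamma0_pct"].to_numpy(dtype=float)
    g1 = rec["G1_Pa"].to_numpy(dtype=float)
    g2 = rec["G2_Pa"].to_numpy(dtype=float)
    if np.any(g0 <= 0) or np.any(g1 <= 0):
        raise ValueError("strain sweep requires positive gamma0 and G'")
    res = stats.linregress(np.log10(g0), np.log10(g1))
    crossing = bool(np.any(g2 >= g1))
    return {
        "slope": float(res.slope),
        "slope_stderr": float(res.stderr),
        "linear": bool(abs(res.slope) <= slope_max),
        "moduli_cross": crossing,
        "slope_max": slope_max,
    }


def plateau_modulus(rec: pd.DataFrame,
                    band: tuple[float, float] | None = None,
                    onset_factor: float = 1.5,
                    div: int | None = None) -> ModulusSummary:
    """Low-frequency plateau moduli of a frequency sweep.

    The plateau value is the geometric mean of G' (and G'') over the band
    (default: everything up to 10 rad/s) — moduli scatter multiplicatively
    across replicates, so the geometric mean is the natural average.  The
    thickening onset is the first frequency at which G' exceeds the plateau
    by more than ``onset_factor - 1`` (default +50%).
    """
    omega = rec["omega_rad_s"].to_numpy(dtype=float)
    g1 = rec["G1_Pa"].to_numpy(dtype=float)
    g2 = rec["G2_Pa"].to_numpy(dtype=float)
    lo = float(omega.min()) if band is None else band[0]
    hi = PLATEAU_BAND_MAX if band is None else band[1]
    sel = (omega >= lo) & (omega <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points in the plateau band")
    if np.any(g1[sel] <= 0) or np.any(g2[sel] <= 0):
        raise ValueError("nonpositive moduli in the plateau band")
    p1 = float(np.exp(np.mean(np.log(g1[sel]))))
    p2 = float(np.exp(np.mean(np.log(g2[sel]))))
    above = np.flatnonzero((omega > hi) & (g1 > onset_factor * p1))
    onset = float(omega[above[0]]) if above.size else None
    if div is None and "DIV" in rec.columns and len(rec):
        div = int(rec["DIV"].iloc[0])
    return ModulusSummary(plateau_G1=p1, plateau_G2=p2, plateau_band=(lo, hi),
                          G1_over_G2=p1 / p2, thickening_onset=onset, DIV=div)


def youngs_modulus(G1: float, G2: float, nu: float = POISSON_RATIO_FIBRIN,
                   div: int | None = None,
                   replicate: int | None = None) -> YoungsModulusEstimate:
    """E = 2 |G*| (1 + nu) with |G*| = sqrt(G'^2 + G''^2)."""
    if G1 < 0 or G2 < 0:
        raise ValueError("moduli must be nonnegative")
    if G1 == 0 and G2 == 0:
        raise ValueError("at least one modulus must be positive")
    g_star = float(np.hypot(G1, G2))
    est = YoungsModulusEstimate(E=2.0 * g_star * (1.0 + nu), G_star_mod=g_star,
                                nu=nu, DIV=div, replicate=replicate)
    if div is not None:
        est.stage = _stage_of(div)
    return est


def _stage_of(div: int) -> str | None:
    for name, (lo, hi) in STAGE_BINS.items():
        if lo <= div <= hi:
            return name
    return None


def stage_group(estimates: list[YoungsModulusEstimate]) -> dict[str, list[YoungsModulusEstimate]]:
    """Group estimates into developmental stages by DIV.

    Stages: early DIV 1-3, young DIV 4-8, mature DIV 13-20.  Estimates at
    a DIV outside those bins (e.g. 9-12) go to the ``"unassigned"`` group
    with a warning.
    """
    groups: dict[str, list[YoungsModulusEstimate]] = {
        "early": [], "young": [], "mature": [], "unassigned": []}
    for est in estimates:
        if est.DIV is None:
            raise ValueError("estimate without a DIV label")
        stage = _stage_of(est.DIV)
        if stage is None:
            warnings.warn(f"DIV {est.DIV} falls outside the stage bins; "
                          "left unassigned", stacklevel=2)
            groups["unassigned"].append(est)
        else:
            est.stage = stage
            groups[stage].append(est)
    return groups


def compare_stages(groups: dict[str, list[YoungsModulusEstimate]],
                   welch: bool = False) -> StageComparison:
    """Pairwise two-sided t-tests of E between developmental stages.

    Uses the classic equal-variance Student's t-test by default (``welch``
    switches to Welch's correction).  Significance stars follow the usual
    convention: * for p < 0.05, ** for p < 0.01.
    """
    values = {s: np.array([e.E for e in groups.get(s, [])])
              for s in ("early", "young", "mature")}
    for s, v in values.items():
        if v.size < 2:
            raise ValueError(f"stage {s!r} needs at least 2 estimates")
        if np.ptp(v) == 0:
            raise ValueError(f"stage {s!r} has zero variance; t-test degenerate")
    pairs = [("early", "young"), ("young", "mature"), ("early", "mature")]
    p_values, stars = {}, {}
    for a, b in pairs:
        p = float(stats.ttest_ind(values[a], values[b], equal_var=not welch).pvalue)
        key = f"{a}-{b}"
        p_values[key] = p
        stars[key] = "**" if p < 0.01 else "*" if p < 0.05 else "n.s."
    return StageComparison(
        means={s: float(v.mean()) for s, v in values.items()},
        sds={s: float(v.std(ddof=1)) for s, v in values.items()},
        n={s: int(v.size) for s, v in values.items()},
        p_values=p_values,
        test="welch-t" if welch else "student-t",
        stars=stars,
    )
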