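"""Targeted PRM quantification against SIL spike-in peptides.

Quantification follows the standard SIL workflow: the extracted fragment-ion
chromatograms of the endogenous ("light") and the isotope-labeled spike-in
("heavy") peptide are integrated, summed over a selected y-ion set, and the
light/heavy area ratio times the known spike amount gives the endogenous
concentration. Response curves over a spike-level series determine the
linear range within which that quantification is trusted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Significance stars at p < 0.05, p < 0.01, p < 0.0001.
STAR_THRESHOLDS = ((1e-4, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class TransitionTrace:
    """One fragment-ion chromatogram of one peptide in one replicate."""

    peptide: str
    protein: str
    ion_label: str  # e.g. "y5"
    isotope: str  # "light" | "heavy"
    replicate: int
    rt: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray  # >= 0
    sample_id: str | None = None
    spike_fmol: float | None = None

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must be 1-D and equal length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt grid must be strictly increasing")
        if self.isotope not in ("light", "heavy"):
            raise ValueError("isotope must be 'light' or 'heavy'")


@dataclass
class PeptideQuantResult:
    """Light/heavy quantification of one peptide in one sample replicate."""

    peptide: str
    sample_id: str | None
    replicate: int
    light_auc: float
    heavy_auc: float
    ratio: float  # light / heavy; NaN when heavy_auc == 0
    concentration: float  # pmol/mL (ratio x spike concentration)
    failed: bool = False
    replicate_cv: float | None = None  # % filled by summarize_replicates


@dataclass
class ResponseCurveResult:
    """Linear-range estimate of a spike-level response series."""

    peptide: str
    spike_levels: np.ndarray
    responses: np.ndarray
    linear_low: float | None
    linear_high: float | None
    slope: float | None
    r_squared: float | None

    @property
    def has_linear_range(self) -> bool:
        return self.linear_low is not None


def integrate_transition_peak(
    trace: TransitionTrace, boundaries: tuple[float, float] | None = None
) -> float:
    """Trapezoidal area of the trace over an rt interval (default: all)."""
    if boundaries is None:
        lo, hi = trace.rt[0], trace.rt[-1]
    else:
        lo, hi = boundaries
    mask = (trace.rt >= lo) & (trace.rt <= hi)
    if mask.sum() < 2:
        warnings.warn(
            f"empty integration interval [{lo}, {hi}] for {trace.peptide} "
            f"{trace.ion_label}; area set to 0",
            stacklevel=2,
        )
        return 0.0
    return float(np.trapezoid(trace.intensity[mask], trace.rt[mask]))


def _select_ions(labels: list[str], ion_rule: str) -> list[str]:
    """Pick the quantifier y ions.

    ``"ladder"`` (default) sums y3 up to the last observed y ion, the usual
    PRM practice; ``"third_last"`` takes only the single third-from-last ion
    of the observed series.
    """
    indexed = sorted(
        (int(lbl[1:]), lbl) for lbl in labels if lbl.startswith("y")
    )
    if ion_rule == "ladder":
        chosen = [lbl for k, lbl in indexed if k >= 3]
    elif ion_rule == "third_last":
        if len(indexed) < 3:
            raise ValueError("third_last rule needs >= 3 observed y ions")
        chosen = [indexed[-3][1]]
    else:
        raise ValueError("ion_rule must be 'ladder' or 'third_last'")
    if not chosen:
        raise ValueError("no quantifier y ions selected")
    return chosen


def quantify_peptide(
    traces: list[TransitionTrace],
    spike: float,
    ion_rule: str = "ladder",
    boundaries: tuple[float, float] | None = None,
) -> PeptideQuantResult:
    """Quantify one peptide in one sample replicate from paired traces.

    Sums the selected y-ion areas per isotope, forms the light/heavy ratio
    and converts to concentration via the spike amount. A zero heavy area is
    a quantification failure (flagged), never a division.
    """
    peptides = {t.peptide for t in traces}
    if len(peptides) != 1:
        raise ValueError(f"traces span multiple peptides: {sorted(peptides)}")
    replicates = {t.replicate for t in traces}
    if len(replicates) != 1:
        raise ValueError("traces span multiple replicates; quantify per replicate")
    light = {t.ion_label: t for t in traces if t.isotope == "light"}
    heavy = {t.ion_label: t for t in traces if t.isotope == "heavy"}
    shared = sorted(set(light) & set(heavy))
    if not shared:
        raise ValueError("no y ion present in both isotope channels")
    ions = _select_ions(shared, ion_rule)
    light_auc = sum(integrate_transition_peak(light[i], boundaries) for i in ions)
    heavy_auc = sum(integrate_transition_peak(heavy[i], boundaries) for i in ions)
    sample_id = traces[0].sample_id
    rep = traces[0].replicate
    if heavy_auc <= 0:
        return PeptideQuantResult(
            peptide=peptides.pop(), sample_id=sample_id, replicate=rep,
            light_auc=light_auc, heavy_auc=heavy_auc,
            ratio=float("nan"), concentration=float("nan"), failed=True,
        )
    ratio = light_auc / heavy_auc
    return PeptideQuantResult(
        peptide=peptides.pop(), sample_id=sample_id, replicate=rep,
        light_auc=light_auc, heavy_auc=heavy_auc,
        ratio=ratio, concentration=ratio * spike,
    )


def summarize_replicates(
    results: list[PeptideQuantResult],
) -> tuple[float, float]:
    """Mean concentration and CV% over technical replicates.

    Requires >= 2 usable replicates; a zero mean leaves the CV undefined
    (NaN) rather than raising.
    """
    usable = [r for r in results if not r.failed]
    if len(usable) < 2:
        raise ValueError("need >= 2 non-failed replicates")
    conc = np.array([r.concentration for r in usable])
    mean = float(conc.mean())
    if mean == 0:
        cv = float("nan")
    else:
        cv = float(100.0 * conc.std(ddof=1) / mean)
    for r in usable:
        r.replicate_cv = cv
    return mean, cv


def fit_response_curve(
    peptide: str,
    spike_levels: np.ndarray,
    responses: np.ndarray,
    slope_band: tuple[float, float] = (0.8, 1.2),
    min_r2: float = 0.98,
    min_run: int = 3,
) -> ResponseCurveResult:
    """Find the linear range of a spike-level response series.

    On the log10-log10 scale, scans contiguous runs of spike levels and
    keeps the longest run whose least-squares slope lies in ``slope_band``
    with R^2 >= ``min_r2`` (ties broken by R^2). When no run of length
    >= ``min_run`` qualifies, the result reports no linear range instead of
    raising.
    """
    levels = np.asarray(spike_levels, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if len(levels) < 4:
        raise ValueError("need >= 4 spike levels for a response curve")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("spike levels must be strictly increasing")
    lx, ly = np.log10(levels), np.log10(resp)
    best = None  # (run length, r2, i, j, slope)
    n = len(levels)
    for i in range(n):
        for j in range(i + min_run, n + 1):
            fit = stats.linregress(lx[i:j], ly[i:j])
            r2 = fit.rvalue**2
            if slope_band[0] <= fit.slope <= slope_band[1] and r2 >= min_r2:
                cand = (j - i, r2, i, j, fit.slope)
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is None:
        return ResponseCurveResult(
            peptide=peptide, spike_levels=levels, responses=resp,
            linear_low=None, linear_high=None, slope=None, r_squared=None,
        )
    _, r2, i, j, slope = best
    return ResponseCurveResult(
        peptide=peptide, spike_levels=levels, responses=resp,
        linear_low=float(levels[i]), linear_high=float(levels[j - 1]),
        slope=float(slope), r_squared=float(r2),
    )


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def validation_group_test(
    concentrations: pd.Series, labels: pd.Series, group_order=("ALS", "HC")
) -> dict:
    """Unpaired two-tailed t-test on per-sample mean concentrations.

    Returns p, direction (sign of the ALS-minus-HC difference), significance
    stars, and a degenerate-variance flag.
    """
    g1 = concentrations[labels == group_order[0]].dropna()
    g2 = concentrations[labels == group_order[1]].dropna()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 samples")
    diff = float(g1.mean() - g2.mean())
    pooled_var = np.var(np.concatenate([g1 - g1.mean(), g2 - g2.mean()]), ddof=2)
    degenerate = pooled_var == 0
    if degenerate:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(stats.ttest_ind(g1, g2, equal_var=True).pvalue)
    return {
        "p_value": p,
        "direction": "up" if diff > 0 else ("down" if diff < 0 else "none"),
        "stars": significance_stars(p),
        "degenerate_variance": bool(degenerate),
        "mean_als": float(g1.mean()),
        "mean_hc": float(g2.mean()),
    }


def read_transition_list(path) -> pd.DataFrame:
    """Skyline-style transition-list CSV: peptide, fragment ion, label type.

    Accepts columns (case-insensitive) ``peptide``/``peptide sequence``,
    ``protein``/``protein name``, ``fragment``/``fragment ion`` and
    ``label``/``isotope label type`` plus an optional precursor m/z column,
    and returns a normalized frame with columns peptide, protein, ion_label,
    isotope.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"transition list missing column (one of {names})")

    out = pd.DataFrame(
        {
            "peptide": df[pick("peptide", "peptide sequence", "peptide modified sequence")],
            "protein": df[pick("protein", "protein name")],
            "ion_label": df[pick("fragment", "fragment ion")],
            "isotope": df[pick("label", "isotope", "isotope label type")]
            .str.lower()
            .map({"light": "light", "heavy": "heavy"}),
        }
    )
    if out["isotope"].isna().any():
        raise ValueError("isotope label type must be light or heavy")
    return out
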