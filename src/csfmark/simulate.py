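"""Synthetic discovery (TMT) and validation (PRM) datasets with known truth.

The generator emulates the statistical structure of a two-phase CSF
biomarker study: a 20v20 discovery cohort measured in four 11-plex TMT
batches with a master-pool reference channel, and a 30v31 validation cohort
quantified by PRM against stable-isotope-labeled (SIL) spike-in peptides in
three technical replicates.

Model
-----
Protein log2 abundance in a sample is

    baseline + group_shift + batch_offset + N(0, sigma_log2)

with baselines spread over ~6 orders of magnitude (so that dropout and PRM
detectability are abundance-dependent), group_shift equal to the protein's
true log2 fold change for ALS samples, and additive per-protein, per-batch
offsets removable by master-pool normalization. The master-pool channel of
each batch carries the natural-scale mean of all discovery samples' true
abundances, perturbed only by its own measurement noise and the batch
offset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    MIN_SPIKE_PMOL_PER_ML,
    TMT11_CHANNELS,
    PrmSimSpec,
    SimulationConfig,
)
from .prm import TransitionTrace
from .tmt import TmtBatchMatrix

_AGE_RANGE = (40, 80)
_ALSFRS_RANGE = (25, 48)


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst must recover."""

    protein_log2fc: dict[str, float]
    baseline_log2: pd.Series  # per protein
    batch_offsets: pd.DataFrame  # batches x proteins, log2 units
    #: peptide -> true endogenous concentration per sample (pmol/mL)
    peptide_concentrations: pd.DataFrame | None = None
    #: peptide -> (linear_low_fmol, linear_high_fmol)
    peptide_linear_ranges: pd.DataFrame | None = None
    #: peptide -> SIL spike concentration used in the cohort (pmol/mL)
    peptide_spikes: pd.Series | None = None


def _channel_names(n: int) -> list[str]:
    if n == 11:
        return list(TMT11_CHANNELS)
    return [f"ch{i + 1:02d}" for i in range(n)]


def _make_sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort sheet mirroring a demographics table: discovery samples get a
    batch/channel assignment; validation-only samples do not."""
    n_als_d, n_hc_d = config.n_per_group_discovery
    n_als_v, n_hc_v = config.n_validation
    rows = []
    for i in range(max(n_als_d, n_als_v)):
        role = "discovery+validation" if i < n_als_d else "validation"
        rows.append(("ALS%02d" % (i + 1), "ALS", role))
    for i in range(max(n_hc_d, n_hc_v)):
        role = "discovery+validation" if i < n_hc_d else "validation"
        rows.append(("HC%02d" % (i + 1), "HC", role))
    sheet = pd.DataFrame(rows, columns=["subject_id", "group", "cohort_role"])
    sheet["alsfrs"] = np.where(
        sheet["group"] == "ALS",
        rng.integers(_ALSFRS_RANGE[0], _ALSFRS_RANGE[1] + 1, len(sheet)),
        np.nan,
    )
    sheet["age"] = rng.integers(_AGE_RANGE[0], _AGE_RANGE[1] + 1, len(sheet))
    sheet["sex"] = rng.choice(["Male", "Female"], len(sheet))

    # Alternate ALS/HC into batches so every batch is balanced.
    disc = sheet[sheet["cohort_role"] == "discovery+validation"]
    per_batch = config.channels_per_batch - 1
    channels = _channel_names(config.channels_per_batch)
    import itertools

    order = [
        s
        for pair in itertools.zip_longest(
            disc[disc["group"] == "ALS"]["subject_id"],
            disc[disc["group"] == "HC"]["subject_id"],
        )
        for s in pair
        if s is not None
    ]
    batch_of, channel_of = {}, {}
    for k, sid in enumerate(order):
        b, slot = divmod(k, per_batch)
        batch_of[sid] = f"batch_{b + 1}"
        channel_of[sid] = channels[slot]
    sheet["batch"] = sheet["subject_id"].map(batch_of)
    sheet["channel"] = sheet["subject_id"].map(channel_of)
    return sheet


def simulate_discovery_study(
    config: SimulationConfig,
) -> tuple[list[TmtBatchMatrix], pd.DataFrame, GroundTruth]:
    """Simulate the TMT discovery phase.

    Returns per-batch reporter-intensity matrices (sample channels plus one
    master-pool channel), the cohort sample sheet, and the ground truth.
    Identical config (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_p = config.n_proteins
    effects = dict(config.effect_table)
    if len(effects) > n_p:
        raise ValueError("more effect proteins than proteins simulated")

    # Informative proteins keep their given names; the rest get P-ids.
    names = list(effects) + [
        f"P{i + 1:05d}" for i in range(n_p - len(effects))
    ]
    proteins = pd.Index(names, name="protein_id")

    lo, hi = config.baseline_log2_range
    baselines = pd.Series(rng.uniform(lo, hi, n_p), index=proteins)
    delta = pd.Series(0.0, index=proteins)
    for name, fc in effects.items():
        delta[name] = fc

    sheet = _make_sample_sheet(config, rng)
    disc = sheet[sheet["cohort_role"] == "discovery+validation"].reset_index(drop=True)

    offsets = pd.DataFrame(
        rng.normal(0.0, config.batch_effect_sd, (config.n_batches, n_p)),
        index=[f"batch_{b + 1}" for b in range(config.n_batches)],
        columns=proteins,
    )

    # True (noiseless, batch-free) log2 abundance per sample.
    is_als = (disc["group"] == "ALS").to_numpy()
    truth_log2 = (
        baselines.to_numpy()[:, None]
        + np.where(is_als[None, :], delta.to_numpy()[:, None], 0.0)
    )  # proteins x discovery samples
    mp_truth_natural = np.mean(2.0 ** truth_log2, axis=1)  # per protein

    dropout_p = config.missing_model.dropout_probability(baselines.to_numpy())

    batches: list[TmtBatchMatrix] = []
    mp_channel = _channel_names(config.channels_per_batch)[-1]
    for b, batch_id in enumerate(offsets.index):
        members = disc[disc["batch"] == batch_id]
        eps = rng.normal(0.0, config.sigma_log2, (n_p, len(members)))
        sample_log2 = (
            truth_log2[:, members.index.to_numpy()]
            + offsets.loc[batch_id].to_numpy()[:, None]
            + eps
        )
        intensities = 2.0 ** sample_log2
        mp_eta = rng.normal(0.0, config.mp_noise_sd_log2, n_p)
        mp_col = mp_truth_natural * 2.0 ** (offsets.loc[batch_id].to_numpy() + mp_eta)
        data = pd.DataFrame(intensities, index=proteins, columns=members["channel"])
        data[mp_channel] = mp_col
        dropped = rng.random(n_p) < dropout_p
        data.loc[dropped, :] = np.nan
        batches.append(
            TmtBatchMatrix(
                batch_id=batch_id,
                data=data,
                mp_channel=mp_channel,
                channel_samples=dict(zip(members["channel"], members["subject_id"])),
            )
        )

    truth = GroundTruth(
        protein_log2fc=dict(zip(proteins, delta)),
        baseline_log2=baselines,
        batch_offsets=offsets,
    )
    return batches, sheet, truth


def assign_peptide_concentrations(
    truth: GroundTruth,
    panel: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    sigma_log2: float = 1.0,
    concentration_log2_range: tuple[float, float] = (-3.0, 5.0),
    seed: int = 0,
) -> GroundTruth:
    """Fill in per-sample true endogenous peptide concentrations (pmol/mL).

    ``panel`` needs columns ``peptide`` and ``gene_symbol``. Each peptide
    gets a baseline concentration (log2-uniform over
    ``concentration_log2_range``); ALS samples are shifted by the parent
    protein's true log2FC; per-sample biological variation is
    N(0, sigma_log2) on the log2 scale. The default sigma of 1.0 log2 unit
    reflects between-subject spread of CSF protein levels, a larger
    quantity than the technical within-group SD used for power planning.
    """
    rng = np.random.default_rng(seed)
    validation = sample_sheet[sample_sheet["cohort_role"].str.contains("validation")]
    lo, hi = concentration_log2_range
    base = rng.uniform(lo, hi, len(panel))
    fc = panel["gene_symbol"].map(
        lambda g: truth.protein_log2fc.get(g, 0.0)
    ).to_numpy()
    is_als = (validation["group"] == "ALS").to_numpy()
    noise = rng.normal(0.0, sigma_log2, (len(panel), len(validation)))
    log2_conc = (
        base[:, None] + np.where(is_als[None, :], fc[:, None], 0.0) + noise
    )
    conc = pd.DataFrame(
        2.0 ** log2_conc,
        index=pd.Index(panel["peptide"], name="peptide"),
        columns=validation["subject_id"],
    )
    truth.peptide_concentrations = conc
    spikes = conc.median(axis=1).clip(lower=MIN_SPIKE_PMOL_PER_ML)
    truth.peptide_spikes = spikes
    return truth


def simulate_biomarker_panel(
    effects: pd.DataFrame,
    n_per_group: tuple[int, int] = (30, 31),
    discovery_n: tuple[int, int] = (20, 20),
    measurement_cv: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a validation feature matrix from printed discovery effects.

    ``effects`` needs columns ``gene_symbol``, ``log2fc`` and ``p_value``.
    Each feature's within-group SD is the one *implied* by its discovery
    (log2FC, p) pair at the discovery group sizes: the two-sided p gives
    the t statistic (df = n1 + n2 - 2), and sd = |log2FC| / (t *
    sqrt(1/n1 + 1/n2)). Feature values are then N(0, sd) for HC and
    N(log2FC, sd) for ALS on the log2 scale, with lognormal measurement
    noise of the given CV added — so the per-feature discriminability
    matches what the discovery statistics actually support rather than an
    arbitrary noise level.

    Returns (X, labels): samples x features on the log2 scale.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(seed)
    n1, n2 = discovery_n
    df = n1 + n2 - 2
    t_vals = _stats.t.isf(effects["p_value"].to_numpy(dtype=float) / 2.0, df)
    sd = np.abs(effects["log2fc"].to_numpy(dtype=float)) / (
        t_vals * np.sqrt(1.0 / n1 + 1.0 / n2)
    )
    n_als, n_hc = n_per_group
    labels = pd.Series(
        ["ALS"] * n_als + ["HC"] * n_hc,
        index=[f"V{i + 1:02d}" for i in range(n_als + n_hc)],
        name="group",
    )
    shift = effects["log2fc"].to_numpy(dtype=float)
    is_als = (labels == "ALS").to_numpy()
    X = rng.normal(0.0, sd[None, :], (len(labels), len(effects)))
    X += np.where(is_als[:, None], shift[None, :], 0.0)
    if measurement_cv > 0:
        sd_meas = np.sqrt(np.log1p(measurement_cv**2)) / np.log(2.0)
        X += rng.normal(0.0, sd_meas, X.shape)
    return (
        pd.DataFrame(X, index=labels.index, columns=effects["gene_symbol"]),
        labels,
    )


def _gaussian_peak(rt: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((rt - center) / width) ** 2)


def _ion_weights(n_ions: int, rng: np.random.Generator) -> np.ndarray:
    """Relative fragment efficiencies, identical for light and heavy."""
    w = rng.uniform(0.2, 1.0, n_ions)
    return w / w.sum()


def _make_traces(
    peptide: str,
    protein: str,
    ladder: int,
    light_amount: float,
    heavy_amount: float,
    spec: PrmSimSpec,
    rng: np.random.Generator,
    replicate: int,
    sample_id: str | None,
    spike_fmol: float | None,
    ion_weights: np.ndarray,
) -> list[TransitionTrace]:
    rt = np.arange(0.0, spec.rt_window_sec, spec.rt_step_sec)
    shape = _gaussian_peak(rt, spec.peak_center_sec, spec.peak_width_sec)
    # One injection factor shared by both isotopes (cancels in the ratio)
    # plus a ratio-level factor on the light channel, so the replicate CV of
    # the light/heavy ratio equals the configured noise_cv.
    if spec.noise_cv > 0:
        sd = np.sqrt(np.log1p(spec.noise_cv**2))
        injection = np.exp(rng.normal(-0.5 * sd**2, sd))
        ratio_err = np.exp(rng.normal(-0.5 * sd**2, sd))
    else:
        injection = ratio_err = 1.0
    traces = []
    for isotope, amount in (("light", light_amount), ("heavy", heavy_amount)):
        signal = spec.response_factor * amount
        signal = min(signal, spec.saturation_ceiling) + spec.noise_floor
        signal *= injection * (ratio_err if isotope == "light" else 1.0)
        for k in range(ladder):
            traces.append(
                TransitionTrace(
                    peptide=peptide,
                    protein=protein,
                    ion_label=f"y{k + 3}",
                    isotope=isotope,
                    replicate=replicate,
                    rt=rt,
                    intensity=signal * ion_weights[k] * shape,
                    sample_id=sample_id,
                    spike_fmol=spike_fmol,
                )
            )
    return traces


def simulate_prm_cohort(
    spec: PrmSimSpec,
    sample_sheet: pd.DataFrame,
    truth: GroundTruth,
) -> list[TransitionTrace]:
    """Simulate paired light/heavy transition traces for the validation cohort.

    The SIL spike for each peptide follows the study rule: the endogenous
    estimate, floored at 5 pmol/mL. Each sample x peptide is measured in
    ``spec.replicates`` technical replicates with independent noise.
    """
    if truth.peptide_concentrations is None:
        raise KeyError(
            "ground truth has no peptide concentrations; call "
            "assign_peptide_concentrations first"
        )
    rng = np.random.default_rng(spec.seed)
    conc = truth.peptide_concentrations
    validation = sample_sheet[sample_sheet["cohort_role"].str.contains("validation")]
    traces: list[TransitionTrace] = []
    for peptide, protein, ladder in spec.panel:
        if peptide not in conc.index:
            raise KeyError(f"no ground-truth concentration for peptide {peptide!r}")
        spike = float(truth.peptide_spikes[peptide])
        weights = _ion_weights(ladder, rng)
        for sid in validation["subject_id"]:
            true_c = float(conc.loc[peptide, sid])
            for rep in range(1, spec.replicates + 1):
                traces.extend(
                    _make_traces(
                        peptide, protein, ladder,
                        light_amount=true_c, heavy_amount=spike,
                        spec=spec, rng=rng, replicate=rep,
                        sample_id=sid, spike_fmol=None,
                        ion_weights=weights,
                    )
                )
    return traces


def true_linear_range(
    spec: PrmSimSpec,
    slope_band: tuple[float, float] = (0.8, 1.2),
    min_r2: float = 0.98,
) -> pd.DataFrame:
    """Ground-truth linear range implied by the floor/ceiling of ``spec``.

    Defined as the range an ideal (noise-free) measurement of the expected
    response would be assigned under the default linearity criteria — i.e.
    the linear-range estimator applied to the noiseless expected curve.
    Returns per-peptide (linear_low_fmol, linear_high_fmol), or NaN when no
    run qualifies.
    """
    from .prm import fit_response_curve

    levels = np.asarray(spec.spike_levels_fmol, dtype=float)
    ideal = spec.response_factor * levels
    expected = np.minimum(ideal, spec.saturation_ceiling) + spec.noise_floor
    fit = fit_response_curve(
        "noiseless", levels, expected, slope_band=slope_band, min_r2=min_r2
    )
    low = fit.linear_low if fit.has_linear_range else np.nan
    high = fit.linear_high if fit.has_linear_range else np.nan
    rows = [(peptide, low, high) for peptide, _, _ in spec.panel]
    return pd.DataFrame(
        rows, columns=["peptide", "linear_low_fmol", "linear_high_fmol"]
    ).set_index("peptide")


def simulate_response_series(
    spec: PrmSimSpec,
) -> tuple[list[TransitionTrace], pd.DataFrame]:
    """Simulate SIL-only response-curve measurements over the spike levels.

    The measured signal is the linear response clipped above by the
    saturation ceiling with the noise floor added, so the realized linear
    range is bounded on both sides. Returns the heavy-isotope traces tagged
    with their spike level, plus the ground-truth linear range per peptide.
    """
    rng = np.random.default_rng(spec.seed)
    rt = np.arange(0.0, spec.rt_window_sec, spec.rt_step_sec)
    shape = _gaussian_peak(rt, spec.peak_center_sec, spec.peak_width_sec)
    traces: list[TransitionTrace] = []
    for peptide, protein, ladder in spec.panel:
        weights = _ion_weights(ladder, rng)
        for level in spec.spike_levels_fmol:
            for rep in range(1, spec.replicates + 1):
                signal = spec.response_factor * level
                signal = min(signal, spec.saturation_ceiling) + spec.noise_floor
                if spec.noise_cv > 0:
                    sd = np.sqrt(np.log1p(spec.noise_cv**2))
                    signal *= np.exp(rng.normal(-0.5 * sd**2, sd))
                for k in range(ladder):
                    traces.append(
                        TransitionTrace(
                            peptide=peptide,
                            protein=protein,
                            ion_label=f"y{k + 3}",
                            isotope="heavy",
                            replicate=rep,
                            rt=rt,
                            intensity=signal * weights[k] * shape,
                            sample_id=None,
                            spike_fmol=float(level),
                        )
                    )
    return traces, true_linear_range(spec)


def traces_to_frame(traces: list[TransitionTrace]) -> pd.DataFrame:
    """Long-format table (one row per retention-time point) for TSV export."""
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "peptide": t.peptide,
                    "protein": t.protein,
                    "ion_label": t.ion_label,
                    "isotope": t.isotope,
                    "replicate": t.replicate,
                    "sample_id": t.sample_id if t.sample_id is not None else "",
                    "spike_fmol": t.spike_fmol if t.spike_fmol is not None else np.nan,
                    "rt_sec": t.rt,
                    "intensity": t.intensity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame) -> list[TransitionTrace]:
    frame = frame.copy()
    if "spike_fmol" not in frame:
        frame["spike_fmol"] = np.nan
    keys = [
        "peptide", "protein", "ion_label", "isotope", "replicate",
        "sample_id", "spike_fmol",
    ]
    traces = []
    for key, grp in frame.groupby(keys, sort=True, dropna=False):
        grp = grp.sort_values("rt_sec")
        spike = key[6]
        traces.append(
            TransitionTrace(
                peptide=key[0],
                protein=key[1],
                ion_label=key[2],
                isotope=key[3],
                replicate=int(key[4]),
                rt=grp["rt_sec"].to_numpy(dtype=float),
                intensity=grp["intensity"].to_numpy(dtype=float),
                sample_id=key[5] if key[5] != "" else None,
                spike_fmol=None if pd.isna(spike) else float(spike),
            )
        )
    return traces
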