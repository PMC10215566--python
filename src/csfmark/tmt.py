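"""Multi-batch TMT reporter-intensity normalization.

The normalization chain follows standard master-pool (MP) referenced TMT
practice: each protein's reporter intensity is divided by the MP channel of
its own batch (cancelling per-batch effects), each sample column is divided
by its median (cancelling loading differences), and the matrix is then
log2-transformed and z-scored. The ``AbundanceMatrix`` carries a transform
ledger so the steps can only be applied in that order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The full, ordered ledger of a completely processed matrix.
FULL_LEDGER = ("mp_ratio", "median_scaled", "log2", "zscore")


@dataclass
class TmtBatchMatrix:
    """Raw reporter intensities of one TMT batch (proteins x channels)."""

    batch_id: str
    data: pd.DataFrame  # rows: protein ids, columns: channel ids
    mp_channel: str
    #: optional channel id -> sample id mapping for non-MP channels
    channel_samples: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.mp_channel not in self.data.columns:
            raise ValueError(
                f"batch {self.batch_id}: MP channel {self.mp_channel!r} "
                "not among channels"
            )
        values = self.data.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and finite.min() < 0:
            raise ValueError("reporter intensities must be >= 0 or missing")


@dataclass
class AbundanceMatrix:
    """Proteins x samples relative-abundance matrix with a transform ledger.

    ``log2_values`` holds the pre-z-score log2 matrix once ``log2_zscore``
    has run; fold changes are computed from it because z-scoring destroys
    the abundance scale.
    """

    values: pd.DataFrame
    ledger: tuple[str, ...] = ()
    log2_values: pd.DataFrame | None = None

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def require_ledger_tail(self, step: str) -> None:
        if not self.ledger or self.ledger[-1] != step:
            raise ValueError(
                f"transform ledger {self.ledger} must end with {step!r}"
            )


def normalize_to_master_pool(batch: TmtBatchMatrix) -> AbundanceMatrix:
    """Divide every sample channel by the batch's master-pool channel.

    Protein rows whose MP intensity is zero or missing cannot be referenced;
    they become all-missing and are logged rather than silently dropped.
    """
    mp = batch.data[batch.mp_channel]
    samples = batch.data.drop(columns=[batch.mp_channel])
    bad = ~(mp > 0)
    # rows absent from the whole batch are ordinary dropout, not MP failures
    observed = samples.notna().any(axis=1)
    if (bad & observed).any():
        flagged = bad & observed
        logger.warning(
            "batch %s: %d protein(s) with zero/missing MP intensity set to "
            "missing: %s",
            batch.batch_id,
            int(flagged.sum()),
            ", ".join(map(str, batch.data.index[flagged][:10])),
        )
    ratios = samples.div(mp.where(~bad), axis=0)
    if batch.channel_samples:
        ratios = ratios.rename(columns=batch.channel_samples)
    return AbundanceMatrix(values=ratios, ledger=("mp_ratio",))


def median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample column by its median over non-missing proteins."""
    matrix.require_ledger_tail("mp_ratio")
    counts = matrix.values.notna().sum(axis=0)
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"sample(s) with <2 non-missing values: {list(thin.index)}"
        )
    medians = matrix.values.median(axis=0, skipna=True)
    scaled = matrix.values.div(medians, axis=1)
    return AbundanceMatrix(values=scaled, ledger=matrix.ledger + ("median_scaled",))


def log2_zscore(matrix: AbundanceMatrix, axis: str = "protein") -> AbundanceMatrix:
    """Log2-transform, then z-score (mean 0, sample SD 1, ddof=1).

    ``axis="protein"`` (default) standardizes each protein across samples,
    which keeps group contrasts interpretable; ``axis="sample"`` standardizes
    each sample column instead.
    """
    matrix.require_ledger_tail("median_scaled")
    vals = matrix.values
    nonpos = (vals <= 0).any(axis=None)
    if nonpos:
        stacked = vals.stack()
        cell = stacked[stacked <= 0].index[0]
        raise ValueError(f"non-positive value at (protein={cell[0]!r}, sample={cell[1]!r})")
    logged = np.log2(vals)
    if axis == "protein":
        mean = logged.mean(axis=1, skipna=True)
        sd = logged.std(axis=1, ddof=1, skipna=True)
        degenerate = ~(sd > 0)
        if degenerate.any():
            raise ValueError(
                "zero-variance protein row(s): "
                f"{list(logged.index[degenerate][:10])}"
            )
        z = logged.sub(mean, axis=0).div(sd, axis=0)
    elif axis == "sample":
        mean = logged.mean(axis=0, skipna=True)
        sd = logged.std(axis=0, ddof=1, skipna=True)
        degenerate = ~(sd > 0)
        if degenerate.any():
            raise ValueError(
                "zero-variance sample column(s): "
                f"{list(logged.columns[degenerate][:10])}"
            )
        z = logged.sub(mean, axis=1).div(sd, axis=1)
    else:
        raise ValueError("axis must be 'protein' or 'sample'")
    return AbundanceMatrix(
        values=z,
        ledger=matrix.ledger + ("log2", "zscore"),
        log2_values=logged,
    )


def merge_batches(
    batches: list[AbundanceMatrix],
    mode: str = "intersection",
    impute: bool = False,
    impute_scope: str = "protein",
) -> tuple[AbundanceMatrix, dict]:
    """Concatenate batch columns into one matrix plus overlap counts.

    ``mode="intersection"`` keeps proteins quantified in every batch (the
    all-batch core used for differential testing); ``mode="union"`` keeps
    everything. With ``impute=True``, remaining missing cells are replaced
    by the observed minimum — per protein row by default, falling back to
    (or forced to, with ``impute_scope="global"``) the global matrix
    minimum.
    """
    if not batches:
        raise ValueError("no batches to merge")
    for b in batches[1:]:
        if b.ledger != batches[0].ledger:
            raise ValueError("batches differ in normalization ledger state")
    all_samples = [s for b in batches for s in b.samples]
    dupes = pd.Index(all_samples)[pd.Index(all_samples).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sample ids across batches: {list(dupes.unique())}")

    present = [b.values.dropna(how="all").index for b in batches]
    union = present[0]
    inter = present[0]
    for idx in present[1:]:
        union = union.union(idx)
        inter = inter.intersection(idx)
    counts = {f"batch_{i}": len(idx) for i, idx in enumerate(present, start=1)}
    counts["all_batches"] = len(inter)
    counts["total"] = len(union)

    keep = inter if mode == "intersection" else union
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    merged = pd.concat([b.values.reindex(keep) for b in batches], axis=1)

    if impute:
        if impute_scope not in ("protein", "global"):
            raise ValueError("impute_scope must be 'protein' or 'global'")
        global_min = np.nanmin(merged.to_numpy(dtype=float))
        if impute_scope == "protein":
            row_min = merged.min(axis=1, skipna=True).fillna(global_min)
            fill = pd.DataFrame(
                np.broadcast_to(row_min.to_numpy()[:, None], merged.shape),
                index=merged.index,
                columns=merged.columns,
            )
            merged = merged.where(merged.notna(), fill)
        else:
            merged = merged.fillna(global_min)

    return AbundanceMatrix(values=merged, ledger=batches[0].ledger), counts


def write_matrix_tsv(matrix: AbundanceMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="protein_id")


def read_matrix_tsv(path, ledger: tuple[str, ...] = ()) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    return AbundanceMatrix(values=df, ledger=tuple(ledger))
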