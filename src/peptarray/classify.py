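"""Classification of array peptides as antibody binders.

Each peptide's replicate intensities are collapsed to a median; the
background population is modelled from the lower 70-percentile of the
wild-type medians (assumed to be unspecific binding / auto-fluorescence);
a peptide is called a binder when its median lies more than ten background
standard deviations above the background mean.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIGNAL_COLUMNS = ["peptide_sequence", "class", "replicate", "intensity"]


def validate_signals(signals: pd.DataFrame) -> pd.DataFrame:
    """Check a signal table's schema and value ranges.

    Required columns: peptide_sequence, class (wt|ala), replicate,
    intensity. Intensities must be finite and non-negative; extractions
    that background-subtract below zero must be floored by the caller.
    """
    missing = [c for c in SIGNAL_COLUMNS if c not in signals.columns]
    if missing:
        raise ValueError(f"signal table missing column(s): {', '.join(missing)}")
    bad_class = set(signals["class"].unique()) - {"wt", "ala"}
    if bad_class:
        raise ValueError(f"unknown peptide class(es): {sorted(bad_class)}")
    intensity = signals["intensity"].to_numpy(dtype=float)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("non-finite intensity values")
    if (intensity < 0).any():
        raise ValueError("negative intensity values; floor them before input")
    return signals


def read_signals(path) -> pd.DataFrame:
    """Read a tab-separated signal table and validate it."""
    return validate_signals(pd.read_csv(path, sep="\t"))


def replicate_median(signals: pd.DataFrame, min_replicates: int = 3) -> pd.DataFrame:
    """Collapse replicate intensities to per-peptide medians.

    Returns a frame indexed by peptide sequence with columns ``median``
    (standard median, mean of the middle two for even n), ``sd`` (sample
    standard deviation, n-1 denominator, 0 for a single replicate), ``n``
    and ``class``. Medians are computed for wild-type and alanine-variant
    peptides alike.
    """
    validate_signals(signals)
    grouped = signals.groupby("peptide_sequence", sort=False)
    table = grouped["intensity"].agg(median="median", n="size")
    table["sd"] = grouped["intensity"].std(ddof=1).fillna(0.0)
    table["class"] = grouped["class"].first()
    n_low = int(((table["n"] < min_replicates) & (table["class"] == "wt")).sum())
    if n_low:
        logger.warning(
            "%d wild-type peptide(s) have fewer than %d replicates",
            n_low,
            min_replicates,
        )
    return table[["median", "sd", "n", "class"]]


@dataclass(frozen=True)
class BackgroundModel:
    """Background population estimate for one experiment.

    ``threshold = mean + k * sd`` where mean and sd are taken over the
    ``subset_size`` smallest wild-type medians (the lower ``percentile``
    fraction, nearest-rank).
    """

    percentile: float
    subset_size: int
    mean: float
    sd: float
    k: float
    threshold: float


def estimate_background(
    wt_medians,
    percentile: float = 70.0,
    k: float = 10.0,
    method: str = "nearest_rank",
) -> BackgroundModel:
    """Fit the background model on wild-type peptide medians.

    ``nearest_rank`` (default) takes the ``floor(percentile/100 * N)``
    smallest medians; ``interpolated`` instead keeps every median at or
    below the linearly interpolated percentile value. The subset mean and
    sample standard deviation define ``threshold = mean + k*sd``.
    """
    medians = np.sort(np.asarray(wt_medians, dtype=float))
    n = medians.size
    if n < 10:
        raise ValueError(f"background not estimable from {n} peptides (need >= 10)")
    if method == "nearest_rank":
        subset = medians[: int(np.floor(percentile / 100.0 * n))]
    elif method == "interpolated":
        cut = np.percentile(medians, percentile)
        subset = medians[medians <= cut]
    else:
        raise ValueError(f"unknown percentile method {method!r}")
    mean = float(np.mean(subset))
    sd = float(np.std(subset, ddof=1)) if subset.size > 1 else 0.0
    return BackgroundModel(
        percentile=percentile,
        subset_size=int(subset.size),
        mean=mean,
        sd=sd,
        k=k,
        threshold=mean + k * sd,
    )


@dataclass(frozen=True)
class BinderSet:
    """Wild-type peptides classified as antibody targets in one experiment."""

    experiment_id: str
    peptides: frozenset[str]

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, item: str) -> bool:
        return item in self.peptides


def classify_binders(
    median_table: pd.DataFrame,
    model: BackgroundModel,
    experiment_id: str = "",
) -> BinderSet:
    """Call binders: wild-type peptides with median strictly above threshold.

    Only wild-type peptides are classified; alanine-variant medians feed
    the substitution analysis but are never called binders themselves.
    """
    wt = median_table[median_table["class"] == "wt"]
    hits = wt.index[wt["median"].to_numpy() > model.threshold]
    return BinderSet(experiment_id=experiment_id, peptides=frozenset(hits))


def consensus_binders(set_a: BinderSet, set_b: BinderSet) -> BinderSet:
    """Peptides called in both experiments (the two dilutions of one antivenom)."""
    return BinderSet(
        experiment_id=f"{set_a.experiment_id}&{set_b.experiment_id}",
        peptides=set_a.peptides & set_b.peptides,
    )


def classify_experiment(
    signals: pd.DataFrame,
    experiment_id: str = "",
    percentile: float = 70.0,
    k: float = 10.0,
    min_replicates: int = 3,
    method: str = "nearest_rank",
) -> tuple[pd.DataFrame, BackgroundModel, BinderSet]:
    """Median table, background model and binder set for one experiment."""
    table = replicate_median(signals, min_replicates=min_replicates)
    wt_medians = table.loc[table["class"] == "wt", "median"]
    model = estimate_background(wt_medians, percentile=percentile, k=k, method=method)
    binders = classify_binders(table, model, experiment_id=experiment_id)
    logger.info(
        "%s: background mean %.2f sd %.2f threshold %.2f -> %d binder(s)",
        experiment_id or "experiment",
        model.mean,
        model.sd,
        model.threshold,
        len(binders),
    )
    return table, model, binders


def binder_table(
    median_table: pd.DataFrame,
    model: BackgroundModel,
    binders: BinderSet,
) -> pd.DataFrame:
    """Classification result as a flat table (one row per wild-type peptide)."""
    wt = median_table[median_table["class"] == "wt"]
    return pd.DataFrame(
        {
            "experiment_id": binders.experiment_id,
            "peptide_sequence": wt.index,
            "median": wt["median"].to_numpy(),
            "threshold": model.threshold,
            "is_binder": [p in binders for p in wt.index],
        }
    )
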