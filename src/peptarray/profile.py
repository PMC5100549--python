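"""Mapping peptide-level signals back onto toxin sequences.

Binding profiles place each tile's replicate median at its N-terminal
residue position; the residue score averages the medians of every 12-mer
spanning a residue; the average alanine-substitution effect averages, over
all antibody-binding tiles covering a residue, the log2 fold-change of
replacing that residue with alanine. Profiles can be projected onto a
gapped multiple-sequence alignment so homologous residues line up.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BinderSet
from .library import GAP, ToxinRecord

logger = logging.getLogger(__name__)

OccurrenceMap = dict[str, tuple[tuple[str, int], ...]]


def _occurrences_in(toxin: ToxinRecord, occurrences: OccurrenceMap):
    """Yield (peptide sequence, start) for every tile occurrence in a toxin."""
    found = False
    for seq, occs in occurrences.items():
        for acc, start in occs:
            if acc == toxin.accession:
                found = True
                yield seq, start
    if not found:
        raise KeyError(f"{toxin.accession} absent from the occurrence map")


@dataclass
class BindingProfile:
    """Per-tile medians of one toxin in one experiment, ordered by start."""

    accession: str
    experiment_id: str
    points: pd.DataFrame  # columns: start, peptide_sequence, median, sd


def binding_profile(
    toxin: ToxinRecord,
    occurrences: OccurrenceMap,
    median_table: pd.DataFrame,
    experiment_id: str = "",
) -> BindingProfile:
    """One point per tile occurrence, positioned at the tile's first residue.

    A peptide shared by several homologous toxins contributes a point to
    each toxin's profile.
    """
    rows = []
    for seq, start in _occurrences_in(toxin, occurrences):
        rec = median_table.loc[seq]
        rows.append((start, seq, float(rec["median"]), float(rec["sd"])))
    rows.sort()
    return BindingProfile(
        accession=toxin.accession,
        experiment_id=experiment_id,
        points=pd.DataFrame(
            rows, columns=["start", "peptide_sequence", "median", "sd"]
        ),
    )


def residue_scores(
    toxin: ToxinRecord,
    occurrences: OccurrenceMap,
    median_table: pd.DataFrame,
    k: int = 12,
) -> np.ndarray:
    """Per-residue mean of the medians of all wild-type tiles spanning it.

    Binder and non-binder tiles alike contribute. Residues covered by no
    tile (only possible for toxins shorter than the tile length) are NaN.
    """
    L = len(toxin)
    total = np.zeros(L)
    count = np.zeros(L, dtype=int)
    for seq, start in _occurrences_in(toxin, occurrences):
        med = float(median_table.loc[seq, "median"])
        total[start - 1 : start - 1 + k] += med
        count[start - 1 : start - 1 + k] += 1
    with np.errstate(invalid="ignore"):
        scores = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return scores


def coverage_counts(
    toxin: ToxinRecord,
    occurrences: OccurrenceMap,
    binders: BinderSet | None = None,
    k: int = 12,
) -> np.ndarray:
    """Number of (optionally binder-only) tile occurrences spanning each residue."""
    count = np.zeros(len(toxin), dtype=int)
    for seq, start in _occurrences_in(toxin, occurrences):
        if binders is not None and seq not in binders:
            continue
        count[start - 1 : start - 1 + k] += 1
    return count


def alanine_effects(
    toxin: ToxinRecord,
    occurrences: OccurrenceMap,
    median_table: pd.DataFrame,
    binders: BinderSet,
    k: int = 12,
    epsilon: float = 1.0,
    orientation: str = "variant_over_wt",
) -> np.ndarray:
    """Average alanine-substitution effect per residue (log2 fold-change).

    For every antibody-binding wild-type tile covering residue ``i`` at
    in-peptide offset ``j``, the effect is
    ``log2(median(variant with A at j) / median(wild type))`` so loss of
    binding is negative (``orientation="wt_over_variant"`` flips the
    sign). The residue value averages the effects over all covering
    binder tiles; residues that are already alanine contribute 0 (self
    substitution is the identity); residues covered by no binder tile are
    NaN — rendered gray in epitope maps. Medians at or below 0 are
    floored to ``epsilon`` before the ratio.
    """
    if orientation not in {"variant_over_wt", "wt_over_variant"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = 1.0 if orientation == "variant_over_wt" else -1.0
    L = len(toxin)
    total = np.zeros(L)
    count = np.zeros(L, dtype=int)
    for seq, start in _occurrences_in(toxin, occurrences):
        if seq not in binders:
            continue
        wt_med = float(median_table.loc[seq, "median"])
        for j in range(1, k + 1):  # offset within the peptide, 1-based
            i = start + j - 1  # toxin residue index, 1-based
            if seq[j - 1] == "A":
                count[i - 1] += 1  # effect 0 by convention
                continue
            variant = seq[: j - 1] + "A" + seq[j:]
            try:
                var_med = float(median_table.loc[variant, "median"])
            except KeyError:
                raise KeyError(
                    f"variant {variant} (parent {seq}, position {j}) has no "
                    "measured median"
                ) from None
            num, den = var_med, wt_med
            if num <= 0 or den <= 0:
                logger.warning(
                    "non-positive median for %s/%s floored to epsilon=%g",
                    seq,
                    variant,
                    epsilon,
                )
                num, den = max(num, epsilon), max(den, epsilon)
            total[i - 1] += sign * math.log2(num / den)
            count[i - 1] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


@dataclass
class ResidueProfile:
    """Per-residue scores, alanine effects and coverage for one toxin."""

    accession: str
    experiment_id: str
    sequence: str
    residue_score: np.ndarray
    ala_effect: np.ndarray  # NaN where no covering binder tile
    coverage_wt: np.ndarray
    coverage_binder: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(1, len(self.sequence) + 1)
        return pd.DataFrame(
            {
                "accession": self.accession,
                "residue_index": idx,
                "residue_letter": list(self.sequence),
                "residue_score": self.residue_score,
                "ala_effect": self.ala_effect,
                "coverage_wt": self.coverage_wt,
                "coverage_binder": self.coverage_binder,
                "experiment_id": self.experiment_id,
            }
        )


def compute_residue_profile(
    toxin: ToxinRecord,
    occurrences: OccurrenceMap,
    median_table: pd.DataFrame,
    binders: BinderSet,
    k: int = 12,
    epsilon: float = 1.0,
    orientation: str = "variant_over_wt",
) -> ResidueProfile:
    """Residue scores, alanine effects and coverage in one pass."""
    return ResidueProfile(
        accession=toxin.accession,
        experiment_id=binders.experiment_id,
        sequence=toxin.sequence,
        residue_score=residue_scores(toxin, occurrences, median_table, k=k),
        ala_effect=alanine_effects(
            toxin,
            occurrences,
            median_table,
            binders,
            k=k,
            epsilon=epsilon,
            orientation=orientation,
        ),
        coverage_wt=coverage_counts(toxin, occurrences, None, k=k),
        coverage_binder=coverage_counts(toxin, occurrences, binders, k=k),
    )


@dataclass
class AlignmentProjection:
    """Per-residue values laid out on the columns of a gapped alignment.

    ``values[accession]`` has one entry per alignment column, NaN at gap
    cells; ``column_of[accession][i-1]`` gives the 1-based column of
    residue ``i``. Ungapping a projected row reproduces the residue-space
    values exactly.
    """

    accessions: list[str]
    alignment: dict[str, str]
    values: dict[str, np.ndarray]
    column_of: dict[str, np.ndarray]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.alignment.values())))

    def ungap(self, accession: str) -> np.ndarray:
        """Recover the residue-space vector for one toxin."""
        return self.values[accession][self.column_of[accession] - 1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (acc, col + 1, self.values[acc][col])
            for acc in self.accessions
            for col in range(self.n_columns)
        ]
        return pd.DataFrame(rows, columns=["accession", "column", "value"])


def project_onto_alignment(
    profiles: dict[str, np.ndarray],
    alignment: dict[str, str],
    sequences: dict[str, str],
) -> AlignmentProjection:
    """Place per-residue values at their alignment columns.

    ``alignment`` maps accession to its gapped row; every row must ungap
    to the toxin's sequence. Gap cells carry no value (NaN).
    """
    values: dict[str, np.ndarray] = {}
    column_of: dict[str, np.ndarray] = {}
    lengths = {len(row) for row in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    for acc, row in alignment.items():
        ungapped = row.replace(GAP, "")
        if acc not in sequences or ungapped != sequences[acc]:
            raise ValueError(
                f"{acc}: alignment row does not ungap to the toxin sequence"
            )
        vec = np.asarray(profiles[acc], dtype=float)
        if vec.size != len(ungapped):
            raise ValueError(f"{acc}: profile length != sequence length")
        projected = np.full(len(row), np.nan)
        cols = np.array(
            [c + 1 for c, ch in enumerate(row) if ch != GAP], dtype=int
        )
        projected[cols - 1] = vec
        values[acc] = projected
        column_of[acc] = cols
    return AlignmentProjection(
        accessions=list(alignment),
        alignment=dict(alignment),
        values=values,
        column_of=column_of,
    )
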