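"""In-silico design of overlapping-peptide microarray libraries.

A toxin set is turned into a library of 12-mer peptides tiled at every
second residue, deduplicated globally across all toxins, expanded with
single-position alanine-substitution variants, and laid out at seeded
random array positions with five replicates per wild-type peptide.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

GAP = "-"


@dataclass(frozen=True)
class ToxinRecord:
    """One mature toxin sequence with identity metadata.

    ``sequence`` is the mature chain in one-letter codes, gap-free.
    ``is_fragment`` marks database entries that cover only part of the
    native protein.
    """

    accession: str
    sequence: str
    species: str = ""
    subfamily: str = ""
    sub_subfamily: str = ""
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for offset, ch in enumerate(self.sequence):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.accession}: illegal residue {ch!r} at offset "
                    f"{offset + 1} (1-based)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTile:
    """A unique wild-type peptide and every (toxin, start) that produces it.

    Starts are 1-based; the occurrence span is ``start .. start+len-1``
    inclusive.
    """

    sequence: str
    occurrences: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.occurrences:
            raise ValueError(f"tile {self.sequence}: empty occurrence list")


@dataclass(frozen=True)
class AlaVariant:
    """An alanine-substitution variant of one or more wild-type peptides.

    ``provenance`` lists every (parent sequence, 1-based substituted
    position) that generates this variant sequence; after global
    deduplication a variant can descend from several parents.
    """

    sequence: str
    provenance: tuple[tuple[str, int], ...]

    @property
    def parent_sequence(self) -> str:
        return self.provenance[0][0]

    @property
    def position(self) -> int:
        return self.provenance[0][1]


@dataclass
class PeptideLibrary:
    """A complete array design: unique peptides, variants, and spot layout.

    ``layout`` holds one entry per physical spot as
    ``(array position index, peptide sequence, class)`` with class ``"wt"``
    or ``"ala"``; positions are ``0 .. n_spots-1`` and the spot order is a
    seeded uniform random permutation.
    """

    unique_wt: list[PeptideTile]
    variants: list[AlaVariant]
    replicates_wt: int = 5
    replicates_variant: int = 1
    layout: list[tuple[int, str, str]] = field(default_factory=list)
    seed: int = 0
    redundancy_count: int = 0
    k: int = 12
    step: int = 2
    force_terminal: bool = True

    @property
    def n_spots(self) -> int:
        return len(self.layout)

    def wt_sequences(self) -> set[str]:
        return {t.sequence for t in self.unique_wt}

    def occurrence_map(self) -> dict[str, tuple[tuple[str, int], ...]]:
        """Peptide sequence -> tuple of (accession, 1-based start)."""
        return {t.sequence: t.occurrences for t in self.unique_wt}

    def layout_frame(self) -> pd.DataFrame:
        """Layout as a table with per-spot parent/position provenance."""
        var_by_seq = {v.sequence: v for v in self.variants}
        rows = []
        for pos, seq, klass in self.layout:
            if klass == "ala":
                v = var_by_seq[seq]
                rows.append((pos, seq, klass, v.parent_sequence, v.position))
            else:
                rows.append((pos, seq, klass, "", ""))
        return pd.DataFrame(
            rows,
            columns=[
                "spot_index",
                "peptide_sequence",
                "class",
                "parent_sequence",
                "substituted_position",
            ],
        )

    def occurrence_frame(self) -> pd.DataFrame:
        rows = [
            (t.sequence, acc, start)
            for t in self.unique_wt
            for acc, start in t.occurrences
        ]
        return pd.DataFrame(
            rows, columns=["peptide_sequence", "accession", "start"]
        )


def read_toxins(source, ungap: bool = False) -> list[ToxinRecord]:
    """Read toxin records from FASTA text, a path, or an open handle.

    Headers are ``>accession`` optionally followed by whitespace-separated
    ``key=value`` tags (``species``, ``subfamily``, ``sub_subfamily``,
    ``fragment``); underscores in values are read as spaces. With
    ``ungap=True`` the input may be a gapped alignment and ``-`` characters
    are stripped.
    """
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source
        and "\n" not in source
        and ">" not in source
    ):
        handle = open(source)
    elif isinstance(source, str):
        handle = StringIO(source)
    else:
        handle = source

    records: list[ToxinRecord] = []
    seen: set[str] = set()
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            accession = rec.id
            if accession in seen:
                raise ValueError(f"duplicate accession {accession}")
            seen.add(accession)
            tags = _parse_tags(rec.description)
            seq = str(rec.seq).upper()
            if ungap:
                seq = seq.replace(GAP, "")
            elif GAP in seq:
                raise ValueError(
                    f"{accession}: gap characters present; pass ungap=True "
                    "to read an alignment"
                )
            records.append(
                ToxinRecord(
                    accession=accession,
                    sequence=seq,
                    species=tags.get("species", ""),
                    subfamily=tags.get("subfamily", ""),
                    sub_subfamily=tags.get("sub_subfamily", ""),
                    is_fragment=tags.get("fragment", "").lower()
                    in {"true", "1", "yes"},
                )
            )
    if not records:
        raise ValueError("no FASTA records found")
    return records


def _parse_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            tags[key] = value.replace("_", " ")
    return tags


def tile_sequence(
    sequence: str,
    k: int = 12,
    step: int = 2,
    force_terminal: bool = True,
) -> list[tuple[int, str]]:
    """Cut a sequence into overlapping k-mers on a fixed-step grid.

    Returns ``(start, k-mer)`` pairs with 1-based starts
    ``1, 1+step, 1+2*step, ...``. When ``force_terminal`` is set and the
    grid misses the C-terminus, one extra window at start ``L-k+1`` is
    appended so every residue is covered. Sequences shorter than ``k``
    yield an empty list (with a warning) rather than an error.
    """
    L = len(sequence)
    if L < k:
        logger.warning(
            "sequence of length %d is shorter than k=%d; no tiles generated",
            L,
            k,
        )
        return []
    last = L - k + 1  # 1-based start of the final possible window
    starts = list(range(1, last + 1, step))
    if force_terminal and starts[-1] != last:
        starts.append(last)
    return [(s, sequence[s - 1 : s - 1 + k]) for s in starts]


def build_unique_set(
    toxins: Sequence[ToxinRecord],
    k: int = 12,
    step: int = 2,
    force_terminal: bool = True,
) -> tuple[list[PeptideTile], int]:
    """Tile every toxin and pool the tiles into one globally unique set.

    Deduplication is global across all toxins: a peptide produced by
    several (toxin, start) pairs becomes one tile whose occurrence list
    enumerates them all. Returns the tiles in order of first appearance
    together with ``redundancy_count`` (total tiles generated minus
    unique tiles).
    """
    occurrences: dict[str, list[tuple[str, int]]] = {}
    total = 0
    for toxin in toxins:
        for start, pep in tile_sequence(toxin.sequence, k, step, force_terminal):
            total += 1
            occurrences.setdefault(pep, []).append((toxin.accession, start))
    tiles = [
        PeptideTile(sequence=pep, occurrences=tuple(occ))
        for pep, occ in occurrences.items()
    ]
    redundancy = total - len(tiles)
    logger.info(
        "tiled %d toxins: %d tiles, %d unique, %d redundant removed",
        len(toxins),
        total,
        len(tiles),
        redundancy,
    )
    return tiles, redundancy


def alanine_variants(
    unique_wt: Sequence[PeptideTile],
    drop_wt_collisions: bool = False,
) -> list[AlaVariant]:
    """Generate all single-position alanine substitutions of the unique set.

    One variant per non-alanine position of each wild-type peptide
    (substituting A for A reproduces the parent and is skipped). The
    result is deduplicated on variant sequence, keeping every
    (parent, position) provenance record. Variants whose sequence
    coincides with a wild-type peptide are kept by default — on a real
    array the sequence is synthesised once and measured once — or dropped
    with ``drop_wt_collisions=True``.
    """
    if not unique_wt:
        raise ValueError("unique_wt is empty")
    wt_seqs = {t.sequence for t in unique_wt}
    provenance: dict[str, list[tuple[str, int]]] = {}
    for tile in unique_wt:
        parent = tile.sequence
        for pos in range(1, len(parent) + 1):
            if parent[pos - 1] == "A":
                continue
            variant = parent[: pos - 1] + "A" + parent[pos:]
            if drop_wt_collisions and variant in wt_seqs:
                continue
            provenance.setdefault(variant, []).append((parent, pos))
    return [
        AlaVariant(sequence=seq, provenance=tuple(prov))
        for seq, prov in provenance.items()
    ]


def assemble_layout(
    unique_wt: Sequence[PeptideTile],
    variants: Sequence[AlaVariant],
    replicates_wt: int = 5,
    replicates_variant: int = 1,
    seed: int = 0,
    redundancy_count: int = 0,
    k: int = 12,
    step: int = 2,
    force_terminal: bool = True,
) -> PeptideLibrary:
    """Replicate the peptides and assign seeded random array positions.

    Each wild-type peptide is replicated ``replicates_wt`` times (five on
    the physical array) and each variant ``replicates_variant`` times; the
    pooled spots are shuffled by one seeded generator so local intensity
    biases do not align with peptide identity. Identical inputs and seed
    reproduce an identical layout.
    """
    if replicates_wt < 1 or replicates_variant < 1:
        raise ValueError("replicate counts must be >= 1")
    spots: list[tuple[str, str]] = []
    for tile in unique_wt:
        spots.extend([(tile.sequence, "wt")] * replicates_wt)
    for var in variants:
        spots.extend([(var.sequence, "ala")] * replicates_variant)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(spots))
    layout = [
        (pos, spots[i][0], spots[i][1]) for pos, i in enumerate(order)
    ]
    return PeptideLibrary(
        unique_wt=list(unique_wt),
        variants=list(variants),
        replicates_wt=replicates_wt,
        replicates_variant=replicates_variant,
        layout=layout,
        seed=seed,
        redundancy_count=redundancy_count,
        k=k,
        step=step,
        force_terminal=force_terminal,
    )


def build_library(
    toxins: Sequence[ToxinRecord],
    k: int = 12,
    step: int = 2,
    force_terminal: bool = True,
    replicates_wt: int = 5,
    replicates_variant: int = 1,
    drop_wt_collisions: bool = False,
    seed: int = 0,
) -> PeptideLibrary:
    """Design a complete library from toxin records in one call."""
    tiles, redundancy = build_unique_set(toxins, k, step, force_terminal)
    variants = alanine_variants(tiles, drop_wt_collisions=drop_wt_collisions)
    return assemble_layout(
        tiles,
        variants,
        replicates_wt=replicates_wt,
        replicates_variant=replicates_variant,
        seed=seed,
        redundancy_count=redundancy,
        k=k,
        step=step,
        force_terminal=force_terminal,
    )
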