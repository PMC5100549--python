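"""Metadata for the 82 mamba and cobra toxins of the original study set.

The table lists, for each UniProtKB entry, the snake species, the mature
chain length, the protein subfamily and (where assigned) sub-subfamily,
and whether the entry is a sequence fragment. Sequences themselves are
not redistributed here: ``load_study_fasta`` consumes a user-fetched
FASTA (see ``scripts/fetch_study_sequences.py``) and validates it against
these lengths, and ``reproduce_study_counts`` rebuilds the published
library from it.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .library import ToxinRecord, alanine_variants, build_unique_set, read_toxins


@dataclass(frozen=True)
class StudyEntry:
    species: str
    accession: str
    length: int
    subfamily: str
    sub_subfamily: str = ""
    is_fragment: bool = False


_D = {
    "pol": "Dendroaspis polylepis",
    "ang": "Dendroaspis angusticeps",
    "jam": "Dendroaspis jamesoni",
    "vir": "Dendroaspis viridis",
    "haj": "Naja haje",
    "mel": "Naja melanoleuca",
    "niv": "Naja nivea",
}

# (species key, accession, mature length, subfamily, sub-subfamily, fragment)
_ROWS = [
    ("pol", "P25687", 81, "AVIT (prokineticin)", "", False),
    ("ang", "P28374", 38, "Natriuretic peptide", "", False),
    ("ang", "Q8QGP7", 53, "Natriuretic peptide", "", False),
    ("mel", "P01383", 71, "Long-chain 3FTx", "T2-a-NT", False),
    ("mel", "P01388", 71, "Long-chain 3FTx", "T2-a-NT", False),
    ("niv", "P01390", 71, "Long-chain 3FTx", "T2-a-NT", False),
    ("haj", "P25674", 71, "Long-chain 3FTx", "T2-a-NT", False),
    ("jam", "P01393", 72, "Long-chain 3FTx", "T2-a-NT", False),
    ("vir", "P01394", 72, "Long-chain 3FTx", "T2-a-NT", False),
    ("vir", "P01395", 73, "Long-chain 3FTx", "T2-a-NT", False),
    ("pol", "P01396", 72, "Long-chain 3FTx", "T2-a-NT", False),
    ("pol", "P01397", 72, "Long-chain 3FTx", "T2-a-NT", False),
    ("pol", "P25667", 72, "Long-chain 3FTx", "T2-a-NT", False),
    ("mel", "P01400", 65, "Non-conventional 3FTx", "ORP-II", False),
    ("haj", "P01401", 65, "Non-conventional 3FTx", "ORP-II", False),
    ("niv", "P25680", 65, "Non-conventional 3FTx", "ORP-II", False),
    ("jam", "P25682", 63, "Non-conventional 3FTx", "ORP-XIX", False),
    ("ang", "C0HJB0", 57, "Short-chain 3FTx", "", False),
    ("pol", "P0DKR6", 78, "Short-chain 3FTx", "", False),
    ("pol", "P0DKS3", 57, "Short-chain 3FTx", "", False),
    ("ang", "P0C1Y9", 61, "Short-chain 3FTx", "FAS", False),
    ("ang", "P0C1Z0", 61, "Short-chain 3FTx", "FAS", False),
    ("pol", "P25681", 61, "Short-chain 3FTx", "FAS", False),
    ("ang", "Q9PS08", 30, "Short-chain 3FTx", "FAS", True),
    ("jam", "P01407", 62, "Short-chain 3FTx", "AMI", False),
    ("ang", "P01408", 63, "Short-chain 3FTx", "AMI", False),
    ("ang", "P01409", 63, "Short-chain 3FTx", "AMI", False),
    ("ang", "P01410", 62, "Short-chain 3FTx", "AMI", False),
    ("ang", "P01411", 62, "Short-chain 3FTx", "AMI", False),
    ("ang", "P17696", 86, "Short-chain 3FTx", "AMI", False),
    ("ang", "P18328", 86, "Short-chain 3FTx", "AMI", False),
    ("pol", "P25518", 65, "Short-chain 3FTx", "AMI", False),
    ("ang", "P60234", 65, "Short-chain 3FTx", "AMI", False),
    ("ang", "P60235", 40, "Short-chain 3FTx", "AMI", True),
    ("ang", "P60236", 40, "Short-chain 3FTx", "AMI", True),
    ("pol", "P80494", 66, "Short-chain 3FTx", "AMI", False),
    ("pol", "P80495", 65, "Short-chain 3FTx", "AMI", False),
    ("ang", "P81030", 66, "Short-chain 3FTx", "AMI", False),
    ("ang", "P81031", 65, "Short-chain 3FTx", "AMI", False),
    ("ang", "P85092", 65, "Short-chain 3FTx", "AMI", False),
    ("ang", "P86419", 66, "Short-chain 3FTx", "AMI", False),
    ("ang", "Q8QGR0", 86, "Short-chain 3FTx", "AMI", False),
    ("ang", "Q9PSN1", 66, "Short-chain 3FTx", "AMI", False),
    ("jam", "P01413", 61, "Short-chain 3FTx", "ANP", False),
    ("jam", "P28375", 59, "Short-chain 3FTx", "ANP", False),
    ("ang", "P81946", 59, "Short-chain 3FTx", "ANP", False),
    ("pol", "P01414", 60, "Short-chain 3FTx", "LTC", False),
    ("pol", "P22947", 60, "Short-chain 3FTx", "LTC", False),
    ("jam", "P25683", 60, "Short-chain 3FTx", "LTC", False),
    ("ang", "P25684", 60, "Short-chain 3FTx", "LTC", False),
    ("haj", "P01415", 61, "Short-chain 3FTx", "ORP-VI", False),
    ("ang", "P18329", 80, "Short-chain 3FTx", "ORP-XI", False),
    ("ang", "P01404", 81, "Short-chain 3FTx", "ORP-XI", False),
    ("vir", "P01405", 60, "Short-chain 3FTx", "ORP-XI", False),
    ("jam", "P01406", 60, "Short-chain 3FTx", "ORP-XI", False),
    ("ang", "Q9PS09", 30, "Short-chain 3FTx", "ORP-XI", True),
    ("mel", "P01473", 61, "Short-chain 3FTx", "ORP-XV", False),
    ("mel", "P01474", 61, "Short-chain 3FTx", "ORP-XV", False),
    ("haj", "P62394", 62, "Short-chain 3FTx", "ORP-XV", False),
    ("ang", "P60237", 63, "Short-chain 3FTx", "TB-MUS", False),
    ("niv", "P01423", 61, "Short-chain 3FTx", "T1-a-NT", False),
    ("mel", "P01424", 61, "Short-chain 3FTx", "T1-a-NT", False),
    ("haj", "P25675", 61, "Short-chain 3FTx", "T1-a-NT", False),
    ("haj", "P68418", 61, "Short-chain 3FTx", "T1-a-NT", False),
    ("niv", "P68419", 61, "Short-chain 3FTx", "T1-a-NT", False),
    ("pol", "P01416", 60, "Short-chain 3FTx", "T1-a-NT", False),
    ("jam", "P01417", 60, "Short-chain 3FTx", "T1-a-NT", False),
    ("vir", "P01418", 60, "Short-chain 3FTx", "T1-a-NT", False),
    ("jam", "P01419", 58, "Short-chain 3FTx", "T1-a-NT", False),
    ("mel", "P01448", 60, "Short-chain 3FTx", "T1A-CYT", False),
    ("niv", "P01456", 60, "Short-chain 3FTx", "T1A-CYT", False),
    ("haj", "P01457", 60, "Short-chain 3FTx", "T1A-CYT", False),
    ("niv", "P01458", 60, "Short-chain 3FTx", "T1A-CYT", False),
    ("niv", "P01463", 60, "Short-chain 3FTx", "T1A-CYT", False),
    ("pol", "P00979", 60, "Kunitz-type", "", False),
    ("ang", "P00980", 59, "Kunitz-type", "", False),
    ("pol", "P00981", 79, "Kunitz-type", "", False),
    ("ang", "P00982", 57, "Kunitz-type", "", False),
    ("pol", "P00983", 57, "Kunitz-type", "", False),
    ("pol", "P00984", 59, "Kunitz-type", "", False),
    ("ang", "P0DMJ6", 59, "Kunitz-type", "", False),
    ("ang", "P81658", 60, "Kunitz-type", "", False),
]

#: The 82 toxin entries of the study set.
STUDY_ENTRIES: tuple[StudyEntry, ...] = tuple(
    StudyEntry(_D[sp], acc, length, fam, sub, frag)
    for sp, acc, length, fam, sub, frag in _ROWS
)

#: Library sizes published for this toxin set.
PUBLISHED_COUNTS = {
    "redundant_removed": 562,
    "unique_wt": 1588,
    "unique_variants": 18468,
    "unique_peptides": 20056,
    "total_spots": 26408,
    "mamba_unique_wt": 1026,
}


def entries_by_genus(genus: str) -> list[StudyEntry]:
    return [e for e in STUDY_ENTRIES if e.species.startswith(genus)]


def genus_counts() -> dict[str, int]:
    """Number of study entries per snake genus."""
    counts: dict[str, int] = {}
    for e in STUDY_ENTRIES:
        genus = e.species.split()[0]
        counts[genus] = counts.get(genus, 0) + 1
    return counts


def load_study_fasta(path) -> list[ToxinRecord]:
    """Read a user-fetched FASTA of the study sequences and validate it.

    Requires exactly the 82 accessions, each with the mature-chain length
    recorded in the metadata table (pro-peptides and signal peptides must
    already be removed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: the study sequences are not redistributed "
            "with this package; fetch them once with "
            "scripts/fetch_study_sequences.py (network required)"
        )
    toxins = read_toxins(path)
    by_acc = {t.accession: t for t in toxins}
    expected = {e.accession: e for e in STUDY_ENTRIES}
    missing = sorted(set(expected) - set(by_acc))
    extra = sorted(set(by_acc) - set(expected))
    if missing or extra:
        raise ValueError(f"accession mismatch: missing={missing} extra={extra}")
    bad = [
        (acc, len(by_acc[acc].sequence), expected[acc].length)
        for acc in expected
        if len(by_acc[acc].sequence) != expected[acc].length
    ]
    if bad:
        raise ValueError(
            "mature-chain length mismatch (accession, found, expected): "
            f"{bad}"
        )
    return [by_acc[e.accession] for e in STUDY_ENTRIES]


def reproduce_study_counts(
    toxins: list[ToxinRecord],
    force_terminal: bool = True,
    drop_wt_collisions: bool = False,
) -> dict[str, int]:
    """Rebuild the library from the study sequences and count everything.

    Returns the same keys as ``PUBLISHED_COUNTS`` so the two dictionaries
    can be compared directly.
    """
    tiles, redundancy = build_unique_set(toxins, force_terminal=force_terminal)
    variants = alanine_variants(tiles, drop_wt_collisions=drop_wt_collisions)
    mamba_accessions = {
        e.accession for e in STUDY_ENTRIES if e.species.startswith("Dendroaspis")
    }
    mamba = [t for t in toxins if t.accession in mamba_accessions]
    mamba_tiles, _ = build_unique_set(mamba, force_terminal=force_terminal)
    return {
        "redundant_removed": redundancy,
        "unique_wt": len(tiles),
        "unique_variants": len(variants),
        "unique_peptides": len(tiles) + len(variants),
        "total_spots": 5 * len(tiles) + len(variants),
        "mamba_unique_wt": len(mamba_tiles),
    }
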