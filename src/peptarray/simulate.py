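"""Synthetic peptide-array experiments with planted epitopes.

The generator emulates the signal structure of a real antivenom
experiment: a large near-normal background population of unspecifically
binding peptides, a minority of high-signal peptides whose tiles fully
contain a planted linear epitope core (7-9 residues, as linear epitope
elements typically are), five replicates per wild-type spot, and alanine
variants whose signal collapses when a key binding residue is replaced.
Planted truth (which peptides must classify as binders, which residues
carry which alanine effect) is derived deterministically from the epitope
list and the library alone, so every downstream stage can be tested
without real array data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .library import AMINO_ACIDS, PeptideLibrary, ToxinRecord, build_library


@dataclass(frozen=True)
class PlantedEpitope:
    """A linear epitope core planted in one toxin.

    ``core_span`` is 1-based inclusive; a wild-type tile is elevated by
    ``amplitude`` above background iff its span fully contains the core.
    Substituting a residue in ``key_positions`` to alanine multiplies the
    amplitude by ``knockdown`` (0 = complete loss of binding).
    """

    accession: str
    core_span: tuple[int, int]
    key_positions: tuple[int, ...]
    amplitude: float
    knockdown: float = 0.25

    def __post_init__(self) -> None:
        start, end = self.core_span
        if start > end:
            raise ValueError(f"invalid span {self.core_span}")
        if any(p < start or p > end for p in self.key_positions):
            raise ValueError("key positions must lie inside the core span")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.knockdown < 1:
            raise ValueError("knockdown must be in [0, 1)")


@dataclass(frozen=True)
class NoiseModel:
    """Intensity model: background level, population spread, replicate noise.

    ``background_mean`` and ``background_sd`` describe the unspecific
    binding / auto-fluorescence population; ``replicate_sd`` is the
    spot-to-spot noise around a peptide's expected mean. Intensities are
    clipped at ``floor`` (fluorescence is non-negative).
    """

    background_mean: float = 50.0
    background_sd: float = 8.0
    replicate_sd: float = 8.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.background_sd < 0 or self.replicate_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Expected outcomes derivable from the epitopes and library alone.

    ``expected_binder_wt`` is the set of wild-type peptides whose tiles
    fully contain an epitope core; ``expected_effect`` maps each toxin to
    a per-residue array of expected log2 fold-changes (0 everywhere except
    planted key residues). ``wt_mean`` / ``variant_mean`` are the
    noiseless expected spot means used by the simulator.
    """

    epitopes: list[PlantedEpitope]
    expected_binder_wt: frozenset[str]
    expected_effect: dict[str, np.ndarray]
    wt_mean: dict[str, float] = field(default_factory=dict, repr=False)
    variant_mean: dict[str, float] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        payload = {
            "epitopes": [
                {
                    "accession": e.accession,
                    "core_span": list(e.core_span),
                    "key_positions": list(e.key_positions),
                    "amplitude": e.amplitude,
                    "knockdown": e.knockdown,
                }
                for e in self.epitopes
            ],
            "expected_binder_wt": sorted(self.expected_binder_wt),
            "expected_effect": {
                acc: [None if np.isnan(v) else v for v in arr]
                for acc, arr in self.expected_effect.items()
            },
        }
        return json.dumps(payload, indent=1)


def make_toxins(
    n: int,
    length_range: tuple[int, int] = (55, 70),
    seed: int = 0,
    prefix: str = "SYN",
) -> list[ToxinRecord]:
    """Random toxin-sized synthetic sequences (uniform over the 20 residues)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(sorted(AMINO_ACIDS))
    toxins = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        toxins.append(ToxinRecord(accession=f"{prefix}{i:03d}", sequence=seq))
    return toxins


def plant_epitopes(
    toxins: Sequence[ToxinRecord],
    n_epitopes: int,
    amplitude: float,
    knockdown: float = 0.25,
    core_length_range: tuple[int, int] = (7, 9),
    n_key: int = 2,
    seed: int = 0,
) -> list[PlantedEpitope]:
    """Plant epitope cores in distinct randomly chosen toxins.

    Key positions are drawn from the non-alanine residues of the core
    (an alanine key residue would have no substitution variant to reveal
    it). Toxins shorter than 12 + core length are not used.
    """
    rng = np.random.default_rng(seed)
    eligible = [t for t in toxins if len(t) >= 12 + core_length_range[1]]
    if len(eligible) < n_epitopes:
        raise ValueError("not enough sufficiently long toxins to plant epitopes")
    chosen = rng.choice(len(eligible), size=n_epitopes, replace=False)
    epitopes = []
    for idx in chosen:
        toxin = eligible[int(idx)]
        core_len = int(rng.integers(core_length_range[0], core_length_range[1] + 1))
        start = int(rng.integers(1, len(toxin) - core_len + 2))
        end = start + core_len - 1
        non_ala = [p for p in range(start, end + 1) if toxin.sequence[p - 1] != "A"]
        if len(non_ala) < n_key:  # essentially impossible for random sequences
            non_ala = list(range(start, end + 1))
        keys = rng.choice(non_ala, size=min(n_key, len(non_ala)), replace=False)
        epitopes.append(
            PlantedEpitope(
                accession=toxin.accession,
                core_span=(start, end),
                key_positions=tuple(int(p) for p in sorted(keys)),
                amplitude=amplitude,
                knockdown=knockdown,
            )
        )
    return epitopes


def derive_truth(
    library: PeptideLibrary,
    epitopes: Sequence[PlantedEpitope],
    toxins: Sequence[ToxinRecord],
    noise: NoiseModel | None = None,
) -> SyntheticTruth:
    """Compute the deterministic expected outcome of a planted design.

    A wild-type tile is a binder iff one of its occurrences fully contains
    an epitope core; overlapping epitopes contribute the strongest
    amplitude. A variant inherits its parent's mean unless the substituted
    position maps onto a key residue, in which case that epitope's
    amplitude is multiplied by the knockdown factor. The expected residue
    effect at a key residue follows from the noiseless medians:
    ``log2((knockdown*A + bg) / (A + bg))``; all other residues expect 0.
    """
    by_acc = {t.accession: t for t in toxins}
    for e in epitopes:
        toxin = by_acc.get(e.accession)
        if toxin is None:
            raise ValueError(f"epitope references unknown toxin {e.accession}")
        if e.core_span[1] > len(toxin):
            raise ValueError(
                f"{e.accession}: core span {e.core_span} outside length {len(toxin)}"
            )

    epi_by_acc: dict[str, list[PlantedEpitope]] = {}
    for e in epitopes:
        epi_by_acc.setdefault(e.accession, []).append(e)

    k = library.k
    wt_mean: dict[str, float] = {}
    # For each wt tile: amplitude + the epitope context of each occurrence,
    # kept so variants can resolve whether their position hits a key residue.
    tile_context: dict[str, list[tuple[PlantedEpitope, int]]] = {}
    for tile in library.unique_wt:
        amp = 0.0
        contexts: list[tuple[PlantedEpitope, int]] = []
        for acc, start in tile.occurrences:
            span = (start, start + k - 1)
            for e in epi_by_acc.get(acc, []):
                if span[0] <= e.core_span[0] and e.core_span[1] <= span[1]:
                    contexts.append((e, start))
                    amp = max(amp, e.amplitude)
        wt_mean[tile.sequence] = amp
        if contexts:
            tile_context[tile.sequence] = contexts

    variant_mean: dict[str, float] = {}
    for var in library.variants:
        amp = 0.0
        for parent, pos in var.provenance:
            best = 0.0
            for e, start in tile_context.get(parent, []):
                residue = start + pos - 1  # toxin coordinate of substitution
                a = e.amplitude
                if residue in e.key_positions:
                    a *= e.knockdown
                best = max(best, a)
            amp = max(amp, best)
        variant_mean[var.sequence] = amp

    binders = frozenset(seq for seq, amp in wt_mean.items() if amp > 0)

    bg = (noise or NoiseModel()).background_mean
    effects: dict[str, np.ndarray] = {
        toxin.accession: np.zeros(len(toxin)) for toxin in toxins
    }
    for e in epitopes:
        arr = effects[e.accession]
        value = float(
            np.log2((e.knockdown * e.amplitude + bg) / (e.amplitude + bg))
        )
        for p in e.key_positions:
            arr[p - 1] = value

    return SyntheticTruth(
        epitopes=list(epitopes),
        expected_binder_wt=binders,
        expected_effect=effects,
        wt_mean=wt_mean,
        variant_mean=variant_mean,
    )


def expected_signal(
    peptide: str, klass: str, truth: SyntheticTruth, noise: NoiseModel
) -> float:
    """Noiseless expected spot mean for one peptide (wt or variant)."""
    if klass == "wt":
        if peptide not in truth.wt_mean:
            raise KeyError(f"wild-type peptide {peptide} not in library")
        return noise.background_mean + truth.wt_mean[peptide]
    if klass == "ala":
        if peptide not in truth.variant_mean:
            raise KeyError(f"variant peptide {peptide} not in library")
        return noise.background_mean + truth.variant_mean[peptide]
    raise ValueError(f"unknown class {klass!r}")


def simulate_experiment(
    library: PeptideLibrary,
    truth: SyntheticTruth,
    noise: NoiseModel,
    seed: int = 0,
    experiment_id: str = "synthetic",
) -> pd.DataFrame:
    """Draw one experiment's signal table from the generative model.

    Each layout spot receives ``Normal(expected mean, replicate_sd)``
    clipped at the floor; replicate indices are assigned per peptide in
    layout order. Output schema matches the real-data signal reader:
    peptide_sequence, class, replicate, intensity (plus experiment_id).
    """
    rng = np.random.default_rng(seed)
    seqs = [seq for _, seq, _ in library.layout]
    classes = [klass for _, _, klass in library.layout]
    means = np.array(
        [expected_signal(s, c, truth, noise) for s, c in zip(seqs, classes)]
    )
    intensity = means + rng.normal(0.0, noise.replicate_sd, size=means.size)
    intensity = np.maximum(intensity, noise.floor)
    frame = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "peptide_sequence": seqs,
            "class": classes,
            "replicate": 0,
            "intensity": intensity,
        }
    )
    frame["replicate"] = frame.groupby("peptide_sequence").cumcount() + 1
    return frame


@dataclass
class SimulationBundle:
    """Everything one synthetic experiment consists of."""

    toxins: list[ToxinRecord]
    library: PeptideLibrary
    noise: NoiseModel
    epitopes: list[PlantedEpitope]
    truth: SyntheticTruth
    signals: pd.DataFrame


def simulate_study(
    config=None,
    seed: int = 0,
    n_epitopes: int | None = None,
    experiment_id: str = "synthetic",
) -> SimulationBundle:
    """Generate one complete synthetic experiment under the default conditions.

    Uses the configured number of random toxins, plants ``n_epitopes``
    cores (config default; 0 gives a pure-background null experiment) at
    20-background-SD amplitude, and draws one signal table. All
    randomness derives from ``seed`` through independent sub-streams.
    """
    from .config import RunConfig

    config = config or RunConfig()
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=4)
    toxins = make_toxins(config.n_toxins, seed=int(sub[0]))
    library = build_library(
        toxins,
        k=config.k,
        step=config.step,
        force_terminal=config.force_terminal,
        replicates_wt=config.replicates_wt,
        replicates_variant=config.replicates_variant,
        drop_wt_collisions=config.drop_wt_collisions,
        seed=int(sub[1]),
    )
    noise = NoiseModel(
        background_mean=config.background_mean,
        background_sd=config.background_sd,
        replicate_sd=config.replicate_sd,
    )
    n_epi = config.n_epitopes if n_epitopes is None else n_epitopes
    epitopes = (
        plant_epitopes(
            toxins,
            n_epi,
            amplitude=config.amplitude,
            knockdown=config.knockdown,
            seed=int(sub[2]),
        )
        if n_epi
        else []
    )
    truth = derive_truth(library, epitopes, toxins, noise)
    signals = simulate_experiment(
        library, truth, noise, seed=int(sub[3]), experiment_id=experiment_id
    )
    return SimulationBundle(toxins, library, noise, epitopes, truth, signals)
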