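"""Writing per-residue values into PDB temperature factors.

Residue scores or averaged alanine-substitution effects are written into
the B-factor column (columns 61-66 of ATOM/HETATM records) of a PDB file
so molecular-graphics software can colour structures by epitope signal.
The writer edits only those six columns; every other byte of the file is
preserved, which is why the records are rewritten textually rather than
round-tripped through a structure object.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class ResidueValueMap:
    """Values to write, keyed by author residue number within one chain.

    ``offset`` reconciles sequence numbering with structure numbering
    (structure residue number = sequence index + offset); unmapped
    residues receive ``fill``.
    """

    chain_id: str
    values: dict[int, float]
    fill: float = 0.0
    offset: int = 0

    @classmethod
    def from_profile(
        cls,
        chain_id: str,
        vector,
        fill: float = 0.0,
        offset: int = 0,
    ) -> "ResidueValueMap":
        """Build from a per-residue vector (1-based positions; NaN -> fill)."""
        import math

        values = {
            i + 1 + offset: float(v)
            for i, v in enumerate(vector)
            if not (isinstance(v, float) and math.isnan(v))
        }
        return cls(chain_id=chain_id, values=values, fill=fill, offset=offset)


@dataclass
class ScalingInfo:
    """Sidecar metadata making scaled B-factor values recoverable."""

    mode: str
    vmin: float | None = None
    vmax: float | None = None
    out_range: tuple[float, float] = (0.0, 99.99)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "vmin": self.vmin,
                "vmax": self.vmax,
                "out_range": list(self.out_range),
            },
            indent=1,
        )


def _scale(values: dict[int, float], mode: str) -> tuple[dict[int, float], ScalingInfo]:
    if mode == "none":
        return dict(values), ScalingInfo(mode="none")
    if mode != "minmax":
        raise ValueError(f"unknown scaling mode {mode!r}")
    lo, hi = 0.0, 99.99
    if not values:
        return {}, ScalingInfo(mode="minmax", vmin=None, vmax=None)
    vmin = min(values.values())
    vmax = max(values.values())
    if vmax == vmin:
        scaled = {k: lo for k in values}
    else:
        scaled = {
            k: lo + (v - vmin) / (vmax - vmin) * (hi - lo)
            for k, v in values.items()
        }
    return scaled, ScalingInfo(mode="minmax", vmin=vmin, vmax=vmax)


def annotate_pdb(
    pdb_text: str,
    value_map: ResidueValueMap,
    scaling: str = "minmax",
) -> tuple[str, ScalingInfo]:
    """Return PDB text with mapped residues' B-factors replaced.

    Every atom of a mapped residue in the named chain carries the
    residue's (scaled) value formatted to the fixed-width 6.2 convention;
    unmapped residues in that chain carry the fill value; other chains
    and all non-coordinate records are untouched. Raises if a mapped residue
    number is absent from the chain or a value overflows the field.
    """
    scaled, info = _scale(value_map.values, scaling)
    seen: set[int] = set()
    out_lines = []
    for line in pdb_text.splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            chain = line[21]
            if chain == value_map.chain_id:
                resseq = int(line[22:26])
                if resseq in scaled:
                    value = scaled[resseq]
                    seen.add(resseq)
                else:
                    value = value_map.fill
                if not -999.99 <= value <= 9999.99:
                    raise ValueError(
                        f"B-factor value {value} overflows the 6.2 field "
                        f"(residue {resseq})"
                    )
                line = line[:60] + f"{value:6.2f}" + line[66:]
        out_lines.append(line)
    missing = set(scaled) - seen
    if missing:
        raise ValueError(
            f"residue number(s) absent from chain {value_map.chain_id}: "
            f"{sorted(missing)}"
        )
    return "".join(out_lines), info


def annotate_pdb_file(
    pdb_in,
    value_map: ResidueValueMap,
    pdb_out,
    scaling: str = "minmax",
    sidecar=None,
) -> ScalingInfo:
    """File-level wrapper: annotate and write the scaling sidecar JSON."""
    text, info = annotate_pdb(Path(pdb_in).read_text(), value_map, scaling)
    Path(pdb_out).write_text(text)
    if sidecar is not None:
        Path(sidecar).write_text(info.to_json())
    return info


def read_bfactors(pdb_text: str, chain_id: str) -> dict[int, float]:
    """Per-residue B-factor (first atom of each residue) for one chain."""
    result: dict[int, float] = {}
    for line in pdb_text.splitlines():
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            if line[21] == chain_id:
                resseq = int(line[22:26])
                result.setdefault(resseq, float(line[60:66]))
    return result
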