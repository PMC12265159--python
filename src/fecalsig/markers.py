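"""Cell-type-specific methylation marker panels.

A marker is a short amplicon locus (>=150 bp with >=5 CpG sites in the
default configuration) whose CpG sites are fully unmethylated in exactly
one cell type and methylated everywhere else.  The panel is the reference
for the fully-unmethylated-fraction deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Marker", "MarkerPanel", "PanelError"]


class PanelError(ValueError):
    """Raised for structurally invalid marker panels."""


@dataclass(frozen=True)
class Marker:
    """One amplicon reference with 0-based CpG offsets (position of the C)."""

    marker_id: str
    cell_type: str
    sequence: str
    cpg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        offs = self.cpg_offsets
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise PanelError(f"{self.marker_id}: CpG offsets must be strictly increasing")
        for o in offs:
            if o < 0 or o + 1 >= len(self.sequence):
                raise PanelError(f"{self.marker_id}: CpG offset {o} outside sequence")
            if self.sequence[o : o + 2] != "CG":
                raise PanelError(
                    f"{self.marker_id}: no CG dinucleotide at offset {o} "
                    f"(found {self.sequence[o:o + 2]!r})"
                )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)


@dataclass
class MarkerPanel:
    """Ordered collection of markers; order defines match tie-breaking."""

    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({m.marker_id for m in self.markers}) != len(self.markers):
            raise PanelError("duplicate marker_id in panel")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def cell_types(self) -> list[str]:
        """Cell types in first-appearance order."""
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.cell_type, None)
        return list(seen)

    def markers_for(self, cell_type: str) -> list[Marker]:
        return [m for m in self.markers if m.cell_type == cell_type]

    def get(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    # --- TSV round trip -------------------------------------------------
    # columns: marker_id, cell_type, sequence, cpg_offsets (';'-joined, 0-based)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("marker_id\tcell_type\tsequence\tcpg_offsets\n")
            for m in self.markers:
                offs = ";".join(str(o) for o in m.cpg_offsets)
                fh.write(f"{m.marker_id}\t{m.cell_type}\t{m.sequence}\t{offs}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerPanel":
        markers = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["marker_id", "cell_type", "sequence", "cpg_offsets"]
            if header != expected:
                raise PanelError(f"bad panel header {header!r}, expected {expected!r}")
            for line in fh:
                if not line.strip():
                    continue
                mid, ct, seq, offs = line.rstrip("\n").split("\t")
                markers.append(
                    Marker(mid, ct, seq, tuple(int(o) for o in offs.split(";")))
                )
        return cls(markers)
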