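"""Scaffold layouts: ordered, oriented, positioned contigs."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    orientation: int  # +1 forward, -1 reverse complement
    start: float  # scaffold coordinate of the contig start
    length: int

    @property
    def end(self) -> float:
        return self.start + self.length


@dataclass
class ScaffoldLayout:
    name: str
    contigs: list[ContigPlacement]

    def __post_init__(self) -> None:
        self.contigs = sorted(self.contigs, key=lambda c: (c.start, c.contig_id))

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def span(self) -> float:
        if not self.contigs:
            return 0.0
        return max(c.end for c in self.contigs) - min(c.start for c in self.contigs)

    def shifted(self) -> "ScaffoldLayout":
        """The same layout with the leftmost contig start moved to 0."""
        if not self.contigs:
            return self
        lo = min(c.start for c in self.contigs)
        return ScaffoldLayout(
            self.name,
            [
                ContigPlacement(c.contig_id, c.orientation, c.start - lo, c.length)
                for c in self.contigs
            ],
        )

    def flipped(self) -> "ScaffoldLayout":
        """Reverse the scaffold: x -> -(x + length), orientations negated."""
        return ScaffoldLayout(
            self.name,
            [
                ContigPlacement(c.contig_id, -c.orientation, -(c.start + c.length), c.length)
                for c in self.contigs
            ],
        ).shifted()

    def contig_ids(self) -> list[str]:
        return [c.contig_id for c in self.contigs]
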