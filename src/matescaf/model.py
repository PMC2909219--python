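"""Shared domain records: libraries, read placements and mate pairs.

Conventions used throughout the package:

* A placed read occupies the half-open interval ``[offset, offset+read_len)``
  of its contig (0-based).
* ``same_strand`` (tau) is +1 when the read sequence as sequenced matches the
  contig's forward strand, -1 when it was placed as a reverse complement.
* A SOLiD mate pair has both reads on the same genome strand with the F3 read
  to the right of R3 (going 5' to 3'); an Illumina paired-end has the two
  reads on opposite strands facing each other.
* The insert size is the separation between the genome-orientation start
  coordinates of the two reads of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass

SOLID_MATE = "solid_mate"
ILLUMINA_PE = "illumina_pe"

__all__ = ["SOLID_MATE", "ILLUMINA_PE", "Library", "ReadPlacement", "MatePair"]


@dataclass(frozen=True)
class Library:
    """A mate-pair or paired-end library model.

    ``insert`` is the nominal insert size in bases; ``sigma`` its standard
    deviation (empirically around 20% of the mean for real libraries);
    ``background_fraction`` the fraction of pairs whose separation is uniform
    over the genome rather than peaked at the insert size.
    """

    name: str
    kind: str = SOLID_MATE
    insert: float = 1350.0
    sigma: float | None = None
    read_length: int = 35
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (SOLID_MATE, ILLUMINA_PE):
            raise ValueError(f"unknown library kind {self.kind!r}")
        if self.insert <= 0:
            raise ValueError("insert size must be positive")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    @property
    def sigma_or_default(self) -> float:
        """Empirical sd when known, else the 20%-of-mean rule of thumb."""
        return self.sigma if self.sigma is not None else 0.2 * self.insert


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    contig_id: str
    offset: int
    same_strand: int  # +1 / -1
    read_length: int = 35

    def __post_init__(self) -> None:
        if self.same_strand not in (+1, -1):
            raise ValueError("same_strand must be +1 or -1")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass(frozen=True)
class MatePair:
    """A pair of reads: ``r_read`` is the R3 (SOLiD) or first-sequenced
    (Illumina) read, ``f_read`` its mate."""

    r_read: str
    f_read: str
    library: str
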