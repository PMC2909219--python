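"""Readers and writers for the on-disk formats.

Formats (all plain text):

* contigs / scaffolds — FASTA; scaffold gaps are runs of 'N';
* read placements — TSV ``read_id  contig_id  offset  same_strand`` with
  0-based offsets, same_strand +1/-1, one header line;
* mate pairs — TSV ``r_read_id  f_read_id  library_id`` (column 1 is the R3
  read for SOLiD libraries, the first-sequenced read for Illumina);
* connectivity graph — DOT;
* density profiles and evaluation reports — TSV.
"""

from __future__ import annotations

import os

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig
from .model import MatePair, ReadPlacement

__all__ = [
    "ParseError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_placements",
    "read_pairs",
    "read_inputs",
    "write_outputs",
]


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValidationError(f"duplicate sequence id {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    return contigs


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _rows(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_placements(path, default_read_length: int = 35) -> list[ReadPlacement]:
    placements: list[ReadPlacement] = []
    seen: set[str] = set()
    for lineno, fields in _rows(path):
        if fields[0] == "read_id":  # header
            continue
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        read_id, contig_id, offset_s, strand_s = fields
        try:
            offset = int(offset_s)
            strand = int(strand_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: offset/strand not integers") from None
        if strand not in (+1, -1):
            raise ParseError(f"{path}:{lineno}: same_strand must be +1 or -1")
        if read_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate read id {read_id!r}")
        seen.add(read_id)
        placements.append(
            ReadPlacement(read_id, contig_id, offset, strand, default_read_length)
        )
    return placements


def read_pairs(path) -> list[MatePair]:
    pairs: list[MatePair] = []
    for lineno, fields in _rows(path):
        if fields[0] == "r_read_id":  # header
            continue
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
        pairs.append(MatePair(*fields))
    return pairs


def read_inputs(
    contigs_path, placements_path, pairs_path, config: PipelineConfig
):
    """Read and cross-validate the three input files.

    Checks referential integrity (placements on declared contigs, pairs over
    declared reads, pairs referencing declared libraries) and that every
    placed read lies fully within its contig.
    """
    contigs = read_fasta(contigs_path)
    default_rl = (
        config.libraries[0].read_length if config.libraries else 35
    )
    placements = read_placements(placements_path, default_rl)
    pairs = read_pairs(pairs_path)

    by_read = {p.read_id: p for p in placements}
    lib_names = {lib.name for lib in config.libraries}
    for p in placements:
        if p.contig_id not in contigs:
            raise ValidationError(
                f"placement of {p.read_id!r} references unknown contig {p.contig_id!r}"
            )
        if p.offset >= len(contigs[p.contig_id]):
            raise ValidationError(
                f"read {p.read_id!r} placed at offset {p.offset} on contig "
                f"{p.contig_id!r} of length {len(contigs[p.contig_id])}"
            )
    resolved: list[MatePair] = []
    for pair in pairs:
        for rid in (pair.r_read, pair.f_read):
            if rid not in by_read:
                raise ValidationError(f"pair references undeclared read {rid!r}")
        if pair.library not in lib_names:
            raise ValidationError(f"pair references unknown library id {pair.library!r}")
        resolved.append(pair)
    # pin each placed read's length to its library's read length
    from dataclasses import replace

    lib_by_read: dict[str, int] = {}
    for pair in resolved:
        rl = config.library(pair.library).read_length
        lib_by_read[pair.r_read] = rl
        lib_by_read[pair.f_read] = rl
    placements = [
        replace(p, read_length=lib_by_read.get(p.read_id, default_rl))
        for p in placements
    ]
    for p in placements:
        if p.offset + p.read_length > len(contigs[p.contig_id]):
            raise ValidationError(
                f"read {p.read_id!r} extends past the end of contig {p.contig_id!r}"
            )
    return contigs, placements, resolved


def write_placements(path, placements: list[ReadPlacement]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig_id\toffset\tsame_strand\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.contig_id}\t{p.offset}\t{p.same_strand:+d}\n")


def write_pairs(path, pairs: list[MatePair]) -> None:
    with open(path, "w") as fh:
        fh.write("r_read_id\tf_read_id\tlibrary_id\n")
        for pair in pairs:
            fh.write(f"{pair.r_read}\t{pair.f_read}\t{pair.library}\n")


def write_outputs(result, out_dir) -> list[str]:
    """Write scaffolds, singletons, graph, density profiles and the run log.

    ``result`` is a ``PipelineResult``.  Returns the list of files written.
    """
    from .pairgraph import to_dot
    from .segment import density_profile

    os.makedirs(out_dir, exist_ok=True)
    written = []

    scaffold_seqs = {name: seq for name, (_, seq) in result.scaffolds.items()}
    path = os.path.join(out_dir, "scaffolds.fasta")
    write_fasta(path, scaffold_seqs)
    written.append(path)
    if not scaffold_seqs:
        result.log.append("warning: no scaffolds produced")

    path = os.path.join(out_dir, "singletons.fasta")
    write_fasta(path, result.singletons)
    written.append(path)

    path = os.path.join(out_dir, "connectivity.dot")
    to_dot(result.graph, path)
    written.append(path)

    path = os.path.join(out_dir, "density_profiles.tsv")
    with open(path, "w") as fh:
        fh.write("scaffold\twindow\tmean_density\n")
        for name, (layout, _) in result.scaffolds.items():
            for w, dens in enumerate(density_profile(layout)):
                fh.write(f"{name}\t{w}\t{dens:.3f}\n")
    written.append(path)

    path = os.path.join(out_dir, "removed.tsv")
    with open(path, "w") as fh:
        fh.write("contig_id\treason\n")
        for cid, reason in sorted(result.removed_reasons.items()):
            fh.write(f"{cid}\t{reason}\n")
    written.append(path)

    path = os.path.join(out_dir, "run.log")
    with open(path, "w") as fh:
        fh.write("\n".join(result.log) + "\n")
    written.append(path)
    return written
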