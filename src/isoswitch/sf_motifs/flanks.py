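"""Exon-boundary flank extraction and lost/gained/unregulated categorization.

Transcript structures use 1-based inclusive exon coordinates (GTF
convention).  Flanks span ``flank_width`` nucleotides on each side of an exon
boundary (total ``2 * flank_width``); minus-strand flanks are
reverse-complemented so that sequences read 5' to 3' on the transcript
strand.  First and last exons of every transcript are excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "TranscriptStructure",
    "ExonFlankSet",
    "read_exon_structures_gtf",
    "read_exon_structures_bed12",
    "read_genome_fasta",
    "extract_flanks",
    "categorize_exons",
    "build_flank_sets",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class TranscriptStructure:
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 1-based inclusive, ascending genomic order


@dataclass
class ExonFlankSet:
    """Flank sequences of one exon category at both boundary types."""

    category: str  # lost | gained | unregulated
    five_prime: list[str]
    three_prime: list[str]
    flank_width: int


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_exon_structures_gtf(path: str | Path) -> dict[str, TranscriptStructure]:
    pat_t = re.compile(r'transcript_id "([^"]+)"')
    out: dict[str, TranscriptStructure] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = pat_t.search(f[8])
            if not m:
                continue
            tid = m.group(1)
            st = out.setdefault(tid, TranscriptStructure(tid, f[0], f[6], []))
            st.exons.append((int(f[3]), int(f[4])))
    for st in out.values():
        st.exons.sort()
    return out


def read_exon_structures_bed12(path: str | Path) -> dict[str, TranscriptStructure]:
    out: dict[str, TranscriptStructure] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            chrom, chrom_start, tid, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + s + 1, chrom_start + s + size)  # to 1-based inclusive
                for s, size in zip(starts, sizes)
            ]
            out[tid] = TranscriptStructure(tid, chrom, strand, sorted(exons))
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _boundary_seq(
    genome: Mapping[str, str], chrom: str, pos: int, width: int, side: str
) -> str | None:
    """2*width nucleotides around an exon boundary, ``width`` on each side.

    ``side`` is "start" or "end" (of the exon in genomic coordinates); the
    boundary base itself counts toward the exonic half.
    """
    seq = genome.get(chrom)
    if seq is None:
        return None
    c = pos - 1 if side == "start" else pos  # 0-based inter-base coordinate
    lo, hi = c - width, c + width
    if lo < 0 or hi > len(seq):
        return None  # flank runs off the contig; skip rather than pad
    return seq[lo:hi]


def extract_flanks(
    structure: TranscriptStructure,
    genome: Mapping[str, str],
    flank_width: int = 50,
    exon_subset: set[tuple[int, int]] | None = None,
) -> tuple[list[str], list[str]]:
    """(5' flanks, 3' flanks) of the transcript's internal exons.

    ``exon_subset`` restricts extraction to the given (start, end) exons;
    first and last exons are always excluded.
    """
    internal = structure.exons[1:-1]
    five, three = [], []
    for start, end in internal:
        if exon_subset is not None and (start, end) not in exon_subset:
            continue
        if structure.strand == "-":
            s5 = _boundary_seq(genome, structure.chrom, end, flank_width, "end")
            s3 = _boundary_seq(genome, structure.chrom, start, flank_width, "start")
        else:
            s5 = _boundary_seq(genome, structure.chrom, start, flank_width, "start")
            s3 = _boundary_seq(genome, structure.chrom, end, flank_width, "end")
        if structure.strand == "-":
            s5 = _revcomp(s5) if s5 else None
            s3 = _revcomp(s3) if s3 else None
        if s5:
            five.append(s5)
        if s3:
            three.append(s3)
    return five, three


def categorize_exons(
    old_isoform: str,
    new_isoform: str,
    cluster_isoforms: Iterable[str],
    structures: Mapping[str, TranscriptStructure],
) -> dict[str, set[tuple[str, str, int, int]]]:
    """Classify exons of a switch event into lost / gained / unregulated.

    Lost exons belong to the pre-switch predominant isoform only; gained
    exons to the post-switch isoform only.  Unregulated exons are those
    shared by both plus all exons of the other isoforms in the cluster.
    Exons are keyed as (transcript, chrom, start, end) interval identities,
    de-duplicated per category by genomic interval.
    """

    def exon_keys(tid: str) -> set[tuple[str, str, int, int]]:
        st = structures.get(tid)
        if st is None:
            return set()
        return {(tid, st.chrom, s, e) for s, e in st.exons[1:-1]}

    def intervals(keys: set) -> set[tuple[str, int, int]]:
        return {(c, s, e) for _, c, s, e in keys}

    old_keys, new_keys = exon_keys(old_isoform), exon_keys(new_isoform)
    lost = {k for k in old_keys if (k[1], k[2], k[3]) not in intervals(new_keys)}
    gained = {k for k in new_keys if (k[1], k[2], k[3]) not in intervals(old_keys)}
    regulated = intervals(lost) | intervals(gained)
    # shared exons of the switching pair
    unregulated = {k for k in old_keys if (k[1], k[2], k[3]) in intervals(new_keys)}
    for tid in cluster_isoforms:
        if tid in (old_isoform, new_isoform):
            continue
        unregulated |= {k for k in exon_keys(tid) if (k[1], k[2], k[3]) not in regulated}
    return {"lost": lost, "gained": gained, "unregulated": unregulated}


def build_flank_sets(
    events: Sequence[tuple[str, str]],
    cluster_isoforms: Iterable[str],
    structures: Mapping[str, TranscriptStructure],
    genome: Mapping[str, str],
    flank_width: int = 50,
) -> dict[str, ExonFlankSet]:
    """Flank sets for the three exon categories over a cluster's IS events.

    ``events`` are (old_predominant, new_predominant) isoform pairs.
    """
    acc: dict[str, tuple[list[str], list[str]]] = {
        c: ([], []) for c in ("lost", "gained", "unregulated")
    }
    cluster = set(cluster_isoforms)
    seen: dict[str, set] = {c: set() for c in acc}
    for old, new in events:
        cats = categorize_exons(old, new, cluster, structures)
        for category, keys in cats.items():
            for tid, chrom, start, end in keys:
                ikey = (chrom, start, end)
                if ikey in seen[category]:
                    continue
                seen[category].add(ikey)
                st = structures[tid]
                five, three = extract_flanks(
                    st, genome, flank_width, exon_subset={(start, end)}
                )
                acc[category][0].extend(five)
                acc[category][1].extend(three)
    return {
        c: ExonFlankSet(c, five, three, flank_width)
        for c, (five, three) in acc.items()
    }
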