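"""Gene structures and ortholog-group alignments.

A :class:`GeneStructure` records, for one gene in one species, the spliced
CDS length and the ordered intron positions expressed as nucleotide offsets
within the spliced CDS.  Offsets point at the exon|intron junction, i.e. the
first coding base 3' of the junction; the intron phase is the offset modulo 3.

Structures are either built programmatically (by the simulator) or parsed
from a GFF3 annotation plus a genome FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass(frozen=True)
class IntronRecord:
    """One intron within a spliced CDS.

    cds_offset is the 0-based offset, within the spliced CDS, of the first
    coding nucleotide 3' of the exon|intron junction.
    """

    cds_offset: int
    phase: int
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValueError(
                f"phase {self.phase} inconsistent with cds_offset {self.cds_offset}"
            )
        if self.length < 1:
            raise ValueError("intron length must be >= 1")


@dataclass
class GeneStructure:
    """CDS extent and ordered introns of one gene in one species."""

    gene_id: str
    species: str
    cds_length: int
    introns: tuple[IntronRecord, ...] = ()

    def __post_init__(self) -> None:
        self.introns = tuple(self.introns)
        if self.cds_length < 3:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} < 3")
        if self.cds_length % 3 != 0:
            # Frame-breaking junction indels (imprecise intron losses) can
            # leave a CDS whose annotated length is not a codon multiple.
            logger.warning(
                "%s: CDS length %d not divisible by 3", self.gene_id, self.cds_length
            )
        offsets = [i.cds_offset for i in self.introns]
        if offsets != sorted(set(offsets)):
            raise ValueError(f"{self.gene_id}: intron offsets must be strictly increasing")
        for rec in self.introns:
            if not 0 < rec.cds_offset < self.cds_length:
                raise ValueError(
                    f"{self.gene_id}: intron offset {rec.cds_offset} outside CDS"
                )

    @property
    def intron_count(self) -> int:
        return len(self.introns)


@dataclass
class OrthologGroupAlignment:
    """Aligned coding sequences of one ortholog group, one gene per species."""

    group_id: str
    aligned: Mapping[str, str]            # species -> gapped CDS
    structures: Mapping[str, GeneStructure]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.group_id}: ragged alignment")
        for sp, seq in self.aligned.items():
            ungapped = len(seq) - seq.count(GAP)
            st = self.structures.get(sp)
            if st is None:
                raise ValueError(f"{self.group_id}: no structure for {sp}")
            if ungapped != st.cds_length:
                raise ValueError(
                    f"{self.group_id}/{st.gene_id}: ungapped alignment length "
                    f"{ungapped} != CDS length {st.cds_length}"
                )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.aligned.values())))

    def column_of_offset(self, species: str, cds_offset: int) -> int:
        """Alignment column holding the ``cds_offset``-th ungapped base."""
        seq = self.aligned[species]
        seen = 0
        for col, ch in enumerate(seq):
            if ch != GAP:
                if seen == cds_offset:
                    return col
                seen += 1
        if seen == cds_offset:  # junction at the very end
            return len(seq)
        raise ValueError(f"offset {cds_offset} beyond sequence of {species}")


def read_group_alignment(
    fasta_path: str | Path,
    structures: Mapping[str, GeneStructure],
    group_id: str | None = None,
) -> OrthologGroupAlignment:
    """Read one group's aligned CDS FASTA (records named by species)."""
    fasta_path = Path(fasta_path)
    aligned = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not aligned:
        raise ValueError(f"{fasta_path}: empty alignment")
    gid = group_id or fasta_path.stem
    return OrthologGroupAlignment(gid, aligned, {sp: structures[sp] for sp in aligned})


def gene_structures_from_gff(
    gff_path: str | Path,
    genome_fasta: str | Path,
    species: str,
) -> dict[str, GeneStructure]:
    """Build gene structures from a GFF3 annotation and its genome FASTA.

    Introns are the gaps between consecutive CDS features of each mRNA; the
    intron sequence is cut from the genome (reverse-complemented on the minus
    strand) so that every structure carries its splice-site dinucleotides.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}

    out: dict[str, GeneStructure] = {}
    for mrna in db.features_of_type("mRNA"):
        cds_parts = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_parts:
            continue
        strand = cds_parts[0].strand
        if strand == "-":
            ordered = list(reversed(cds_parts))
        else:
            ordered = cds_parts
        cds_length = sum(f.end - f.start + 1 for f in cds_parts)
        introns: list[IntronRecord] = []
        spliced = 0
        for left, right in zip(ordered[:-1], ordered[1:]):
            spliced += left.end - left.start + 1
            chrom = genome[left.seqid]
            if strand == "-":
                g_start, g_end = right.end + 1, left.start - 1  # 1-based inclusive
                seq = _revcomp(chrom[g_start - 1 : g_end])
            else:
                g_start, g_end = left.end + 1, right.start - 1
                seq = chrom[g_start - 1 : g_end]
            introns.append(
                IntronRecord(
                    cds_offset=spliced,
                    phase=spliced % 3,
                    length=g_end - g_start + 1,
                    sequence=seq,
                )
            )
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        out[gene_id] = GeneStructure(
            gene_id=gene_id, species=species, cds_length=cds_length, introns=tuple(introns)
        )
    return out


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def intron_density(structures: Sequence[GeneStructure]) -> float:
    """Introns per 1 kbp of coding sequence, pooled over genes."""
    if not structures:
        raise ValueError("intron_density requires at least one gene")
    total_cds = sum(s.cds_length for s in structures)
    if total_cds == 0:
        raise ValueError("total CDS length is zero")
    total_introns = sum(s.intron_count for s in structures)
    return 1000.0 * total_introns / total_cds
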