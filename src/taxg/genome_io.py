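"""Genome assemblies, gene annotations and basic assembly statistics.

Coordinates are 1-based inclusive throughout (GFF3 convention); conversion
to half-open slices happens only at extraction time.  Sequences are stored
uppercase over the IUPAC nucleotide alphabet; ambiguity codes other than N
are accepted on input but treated as N wherever identity or G+C content is
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("taxg")

#: IUPAC nucleotide one-letter codes (no U: genomic DNA only).
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")

#: Codes that are ambiguous (not a unique base); counted as N in GC/identity.
AMBIGUOUS_NT = IUPAC_NT - frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A named set of contigs: ``contigs`` is an ordered list of (id, seq)."""

    genome_id: str
    contigs: list[tuple[str, str]]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise ValueError(f"duplicate contig_id {cid!r} in genome {self.genome_id!r}")
            seen.add(cid)
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")

    @property
    def contig_dict(self) -> dict[str, str]:
        return dict(self.contigs)

    def __len__(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class GeneRecord:
    """One annotated feature (CDS / rRNA / tRNA) tied to its assembly.

    ``nt_seq`` is strand-oriented: minus-strand features are stored
    reverse-complemented, so translation always reads 5'→3'.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    product: str = ""
    nt_seq: str = ""
    aa_seq: str | None = None
    feature_type: str = "CDS"
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AssemblyStats:
    """Size, G+C content (ambiguity-excluded, 1 decimal) and contig count."""

    genome_id: str
    size_bp: int
    gc_percent: float
    n_contigs: int


def _validate_sequence(seq: str, contig_id: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_NT:
            raise ValueError(
                f"contig {contig_id!r}: non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Contig ids are the header token before the first whitespace; sequences
    are uppercased and validated against the IUPAC nucleotide alphabet.
    """
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.append((rec.id, _validate_sequence(str(rec.seq), rec.id)))
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return GenomeAssembly(
        genome_id=genome_id or path.stem, contigs=contigs, source=str(path)
    )


def write_genome_fasta(genome: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    """Write an assembly to FASTA (fixed line width)."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def assembly_stats(genome: GenomeAssembly) -> AssemblyStats:
    """Genome size, digital G+C content and contig count.

    G+C is computed over unambiguous bases only: ``100*(G+C)/(A+C+G+T)``,
    rounded to one decimal to match the precision genome tables report.
    """
    counts = {b: 0 for b in "ACGT"}
    size = 0
    for _, seq in genome.contigs:
        size += len(seq)
        for b in "ACGT":
            counts[b] += seq.count(b)
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        raise ValueError(
            f"genome {genome.genome_id!r}: G+C content undefined (no unambiguous bases)"
        )
    gc = 100.0 * (counts["G"] + counts["C"]) / unambiguous
    return AssemblyStats(
        genome_id=genome.genome_id,
        size_bp=size,
        gc_percent=round(gc, 1),
        n_contigs=len(genome.contigs),
    )


def write_stats_table(stats: Sequence[AssemblyStats], path: str | Path) -> None:
    """Emit assembly statistics as TSV."""
    with open(path, "w") as fh:
        fh.write("genome_id\tsize_bp\tgc_percent\tn_contigs\n")
        for s in stats:
            fh.write(f"{s.genome_id}\t{s.size_bp}\t{s.gc_percent}\t{s.n_contigs}\n")


# ---------------------------------------------------------------------------
# Annotation input: GFF3 or a 5+-column delimited table
# ---------------------------------------------------------------------------

_ANNOTATION_TYPES = {"CDS", "rRNA", "tRNA"}


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _iter_gff3(path: Path):
    with open(path) as fh:
        for line in fh:
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line.rstrip()!r}")
            yield fields


def _looks_like_gff3(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            return len(fields) == 9 and fields[3].isdigit() and fields[4].isdigit()
    return False


def _records_from_gff3(path: Path, genome: GenomeAssembly) -> list[GeneRecord]:
    records = []
    auto = 0
    for fields in _iter_gff3(path):
        seqid, _source, ftype, start, end, _score, strand, _frame, attr = fields
        if ftype not in _ANNOTATION_TYPES:
            continue
        attrs = _parse_gff_attributes(attr)
        auto += 1
        records.append(
            GeneRecord(
                gene_id=attrs.get("ID", f"{genome.genome_id}_feat{auto}"),
                genome_id=genome.genome_id,
                contig_id=seqid,
                start=int(start),
                end=int(end),
                strand="+" if strand != "-" else "-",
                product=attrs.get("product", ""),
                feature_type=ftype,
                gene_symbol=attrs.get("gene", ""),
            )
        )
    return records


def _records_from_table(path: Path, genome: GenomeAssembly) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: need >= 5 columns, got {len(fields)}")
            if lineno == 1 and not fields[2].lstrip("-").isdigit():
                continue  # header row
            gene_id, contig_id, start, end, strand = fields[:5]
            product = fields[5] if len(fields) > 5 else ""
            ftype = fields[6] if len(fields) > 6 else "CDS"
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome.genome_id,
                    contig_id=contig_id,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product=product,
                    feature_type=ftype,
                )
            )
    return records


def read_annotation(path: str | Path, genome: GenomeAssembly) -> list[GeneRecord]:
    """Read gene annotations (GFF3 or delimited table) against *genome*.

    Every record is validated against contig bounds and its ``nt_seq``
    extracted from the assembly; minus-strand records are stored
    reverse-complemented.
    """
    path = Path(path)
    if _looks_like_gff3(path):
        records = _records_from_gff3(path, genome)
    else:
        records = _records_from_table(path, genome)
    contig_seqs = genome.contig_dict
    for rec in records:
        if rec.contig_id not in contig_seqs:
            raise ValueError(f"gene {rec.gene_id!r}: unknown contig {rec.contig_id!r}")
        contig = contig_seqs[rec.contig_id]
        if rec.end > len(contig):
            raise ValueError(
                f"gene {rec.gene_id!r}: end {rec.end} beyond contig "
                f"{rec.contig_id!r} length {len(contig)}"
            )
        seq = contig[rec.start - 1 : rec.end]
        rec.nt_seq = reverse_complement(seq) if rec.strand == "-" else seq
    return records


def translate(record_or_seq: GeneRecord | str, *, internal_stop: str = "error") -> str:
    """Translate a CDS with the bacterial genetic code (table 11).

    The terminal stop is removed.  An internal stop raises by default
    (``internal_stop='error'``) or is mapped to ``X`` (``internal_stop='X'``).
    """
    nt = record_or_seq.nt_seq if isinstance(record_or_seq, GeneRecord) else record_or_seq
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        if internal_stop == "X":
            aa = aa.replace("*", "X")
        else:
            raise ValueError(f"internal stop at codon {aa.index('*') + 1}")
    return aa


def attach_translations(records: Iterable[GeneRecord], *, internal_stop: str = "error") -> None:
    """Fill ``aa_seq`` for every CDS record in place."""
    for rec in records:
        if rec.feature_type == "CDS":
            rec.aa_seq = translate(rec, internal_stop=internal_stop)
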