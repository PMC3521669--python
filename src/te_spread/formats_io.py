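"""Readers/writers for external formats and shared coordinate-validated types.

All coordinates are 0-based, half-open everywhere inside the package.  BED is
native; GFF3 is converted on read (1-based inclusive -> 0-based half-open).
Written tabular reports are 0-based half-open and carry a header note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")
VALID_CONTEXTS = ("CG", "CHG", "CHH")
COORD_HEADER_NOTE = "# coordinates: 0-based, half-open"


class FormatError(ValueError):
    """Raised on malformed input; message carries file name and line number."""

    def __init__(self, message: str, path=None, line_no=None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line_no is not None:
                loc += f":{line_no}"
            loc = f"[{loc}] "
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line_no = line_no


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated TE copy with family and superfamily labels."""

    interval: GenomicInterval
    family_id: str
    superfamily: str
    copy_id: str

    def __post_init__(self):
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if not self.copy_id:
            raise ValueError("copy_id must be non-empty")


@dataclass
class ProbeSignal:
    """A tiling-array probe with replicate log2(IP/input) values per sample.

    ``signals`` maps (mark, genotype, tissue) to the list of replicate
    log-ratios; only ``single_copy`` probes are used downstream.
    """

    probe_id: str
    interval: GenomicInterval
    single_copy: bool
    signals: dict = field(default_factory=dict)

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint

    def replicate_mean(self, mark: str, genotype: str, tissue: str) -> float:
        values = self.signals[(mark, genotype, tissue)]
        return sum(values) / len(values)


@dataclass(frozen=True)
class CytosineRecord:
    """Per-cytosine bisulfite counts with sequence context."""

    chrom: str
    position: int  # 0-based
    strand: str
    context: str
    meth_count: int
    total_count: int

    def __post_init__(self):
        if not (0 <= self.meth_count <= self.total_count):
            raise ValueError(
                f"require 0 <= meth_count <= total_count, got "
                f"{self.meth_count}/{self.total_count} at "
                f"{self.chrom}:{self.position}"
            )
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ReadAlignment:
    """One read aligned to the reference, with clip/identity bookkeeping.

    ``left_unaligned``/``right_unaligned`` are the unaligned query tails on
    the reference-left and reference-right side of the aligned span.
    """

    read_id: str
    query_length: int
    interval: GenomicInterval
    identity_pct: float
    left_unaligned: int
    right_unaligned: int
    unique: bool

    def __post_init__(self):
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct out of range: {self.identity_pct}")
        if self.left_unaligned < 0 or self.right_unaligned < 0:
            raise ValueError("unaligned tails must be >= 0")
        if self.left_unaligned + self.right_unaligned >= self.query_length:
            raise ValueError(
                "unaligned tails leave no aligned query bases")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    exons: tuple
    exon_length_bp: int

    def __post_init__(self):
        if self.exon_length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: exon_length_bp must be > 0")

    @property
    def tss(self) -> int:
        """Transcription start: interval.start on +, interval.end on -."""
        if self.interval.strand == "+":
            return self.interval.start
        if self.interval.strand == "-":
            return self.interval.end
        raise ValueError(f"gene {self.gene_id} has no strand")


# ---------------------------------------------------------------------------
# sequence context helper (shared with methylation_context.call_context)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def context_at(seq: str, position: int, strand: str) -> str:
    """Cytosine context (CG/CHG/CHH) at ``position`` of forward ``seq``.

    On the - strand the base must be G on the forward sequence and the
    context is evaluated on the reverse complement reading 5'->3'.

    Raises ValueError if the base is not a C on the requested strand, and
    IndexError if fewer than two read-through bases remain.
    """
    if strand == "+":
        if seq[position].upper() != "C":
            raise ValueError(
                f"base at position {position} is {seq[position]!r}, not C"
            )
        if position + 2 >= len(seq):
            raise IndexError("context undefined at chromosome edge")
        triplet = seq[position : position + 3].upper()
    elif strand == "-":
        if seq[position].upper() != "G":
            raise ValueError(
                f"base at position {position} is {seq[position]!r}, "
                "not G (C on - strand)"
            )
        if position - 2 < 0:
            raise IndexError("context undefined at chromosome edge")
        triplet = reverse_complement(seq[position - 2 : position + 1].upper())
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if triplet[1] == "G":
        return "CG"
    if triplet[2] == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into {name: uppercase sequence}."""
    from Bio import SeqIO

    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        logger.warning("FASTA %s contains no sequences", path)
    return genome


def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# repeats (BED6 / GFF3)
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().strip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_repeats(path, format: str = "BED") -> list:
    """Read TE annotations from BED6 (name = family|superfamily|copy_id)
    or GFF3 (attributes family/superfamily/ID).

    Records missing the family tag are rejected and logged; output is
    sorted by (chrom, start, copy_id).
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unsupported repeat format {format!r}")
    repeats = []
    seen_copy_ids = set()
    n_lines = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    if len(fields) < 4:
                        raise ValueError("BED needs >= 4 columns")
                    chrom, start, end, name = fields[:4]
                    strand = fields[5] if len(fields) > 5 else "."
                    parts = name.split("|")
                    if len(parts) != 3 or not parts[0]:
                        logger.warning(
                            "%s:%d: missing family tag in name %r; record "
                            "rejected", path, line_no, name)
                        continue
                    family_id, superfamily, copy_id = parts
                    interval = GenomicInterval(
                        chrom, int(start), int(end), strand)
                else:
                    if len(fields) != 9:
                        raise ValueError("GFF3 needs 9 columns")
                    chrom, _, _, start, end, _, strand, _, attr_text = fields
                    attrs = _parse_gff3_attributes(attr_text)
                    family_id = attrs.get("family", "")
                    if not family_id:
                        logger.warning(
                            "%s:%d: missing family attribute; record "
                            "rejected", path, line_no)
                        continue
                    superfamily = attrs.get("superfamily", "other")
                    copy_id = attrs.get("ID", f"{family_id}_{line_no}")
                    interval = GenomicInterval(
                        chrom, int(start) - 1, int(end),
                        strand if strand in VALID_STRANDS else ".")
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed repeat line: {exc}",
                                  path=path, line_no=line_no) from exc
            if copy_id in seen_copy_ids:
                raise FormatError(f"duplicate copy_id {copy_id!r}",
                                  path=path, line_no=line_no)
            seen_copy_ids.add(copy_id)
            repeats.append(RepeatAnnotation(interval, family_id,
                                            superfamily, copy_id))
    if n_lines == 0:
        logger.warning("repeat file %s is empty", path)
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.copy_id))
    return repeats


def write_repeats_bed(repeats: Iterable, path) -> None:
    with open(path, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            name = f"{rep.family_id}|{rep.superfamily}|{rep.copy_id}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t"
                     f"{iv.strand}\n")


# ---------------------------------------------------------------------------
# probes and signals (TSV)
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "single_copy"]
SIGNAL_COLUMNS = ["probe_id", "mark", "genotype", "tissue", "replicate",
                  "log_ratio"]


def read_probe_signals(probe_path, signal_path) -> list:
    """Join a probe table and a replicate signal table into ProbeSignal
    records.  Probes without signal rows are retained with an empty map.
    """
    probes_df = pd.read_csv(probe_path, sep="\t", comment="#")
    missing = set(PROBE_COLUMNS) - set(probes_df.columns)
    if missing:
        raise FormatError(f"probe table missing columns {sorted(missing)}",
                          path=probe_path)
    signals_df = pd.read_csv(signal_path, sep="\t", comment="#")
    missing = set(SIGNAL_COLUMNS) - set(signals_df.columns)
    if missing:
        raise FormatError(f"signal table missing columns {sorted(missing)}",
                          path=signal_path)

    dup_mask = signals_df.duplicated(
        subset=["probe_id", "mark", "genotype", "tissue", "replicate"])
    if dup_mask.any():
        dup = signals_df.loc[dup_mask].iloc[0]
        raise FormatError(
            "duplicate signal row for probe "
            f"{dup['probe_id']!r} ({dup['mark']}, {dup['genotype']}, "
            f"{dup['tissue']}, replicate {dup['replicate']})",
            path=signal_path)

    probes = {}
    for row in probes_df.itertuples(index=False):
        single_copy = str(row.single_copy).strip() in ("1", "True", "true")
        probes[str(row.probe_id)] = ProbeSignal(
            probe_id=str(row.probe_id),
            interval=GenomicInterval(str(row.chrom), int(row.start),
                                     int(row.end)),
            single_copy=single_copy,
        )

    unknown = sorted(set(signals_df["probe_id"].astype(str)) - set(probes))
    if unknown:
        raise FormatError(
            f"signal rows reference unknown probe ids: {unknown[:10]}"
            + ("..." if len(unknown) > 10 else ""),
            path=signal_path)

    grouped = signals_df.groupby(
        ["probe_id", "mark", "genotype", "tissue"], sort=True)
    for (probe_id, mark, genotype, tissue), grp in grouped:
        values = [float(v) for _, v in
                  sorted(zip(grp["replicate"], grp["log_ratio"]))]
        probes[str(probe_id)].signals[(mark, genotype, tissue)] = values
    return list(probes.values())


def write_probes_tsv(probes: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER_NOTE + "\n")
        fh.write("\t".join(PROBE_COLUMNS) + "\n")
        for p in probes:
            iv = p.interval
            fh.write(f"{p.probe_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{int(p.single_copy)}\n")


def write_signals_tsv(probes: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SIGNAL_COLUMNS) + "\n")
        for p in probes:
            for (mark, genotype, tissue), values in sorted(p.signals.items()):
                for rep, value in enumerate(values, start=1):
                    fh.write(f"{p.probe_id}\t{mark}\t{genotype}\t{tissue}\t"
                             f"{rep}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# cytosine report (TSV)
# ---------------------------------------------------------------------------

CX_COLUMNS = ["chrom", "position", "strand", "context", "meth_count",
              "total_count"]


def read_cytosine_report(path, genome: dict | None = None) -> list:
    """Read a per-cytosine report.  When ``genome`` is given, contexts are
    recomputed from the sequence and must match the file (missing contexts
    are filled in).
    """
    records = []
    with open(path) as fh:
        header = None
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(CX_COLUMNS) - set(header) - {"context"}
                if missing:
                    raise FormatError(
                        f"cytosine report missing columns {sorted(missing)}",
                        path=path, line_no=line_no)
                idx = {name: header.index(name) for name in header}
                continue
            try:
                chrom = fields[idx["chrom"]]
                position = int(fields[idx["position"]])
                strand = fields[idx["strand"]]
                file_context = (fields[idx["context"]]
                                if "context" in idx else ".")
                meth = int(fields[idx["meth_count"]])
                total = int(fields[idx["total_count"]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed cytosine line: {exc}",
                                  path=path, line_no=line_no) from exc
            context = file_context if file_context != "." else None
            if genome is not None:
                if chrom not in genome:
                    raise FormatError(f"unknown chromosome {chrom!r}",
                                      path=path, line_no=line_no)
                try:
                    seq_context = context_at(genome[chrom], position, strand)
                except IndexError:
                    logger.warning(
                        "%s:%d: context undefined at chromosome edge; "
                        "record skipped", path, line_no)
                    continue
                except ValueError as exc:
                    raise FormatError(str(exc), path=path,
                                      line_no=line_no) from exc
                if context is not None and context != seq_context:
                    raise FormatError(
                        f"context mismatch at {chrom}:{position}{strand}: "
                        f"file says {context}, genome says {seq_context}",
                        path=path, line_no=line_no)
                context = seq_context
            if context is None:
                raise FormatError(
                    "context absent and no genome supplied to fill it",
                    path=path, line_no=line_no)
            try:
                records.append(CytosineRecord(chrom, position, strand,
                                              context, meth, total))
            except ValueError as exc:
                raise FormatError(str(exc), path=path,
                                  line_no=line_no) from exc
    return records


def write_cytosine_report(records: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER_NOTE + "\n")
        fh.write("\t".join(CX_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.context}\t"
                     f"{r.meth_count}\t{r.total_count}\n")


def cytosine_frame(records) -> pd.DataFrame:
    """Tabular view of cytosine records for vectorized region queries."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "position": [r.position for r in records],
            "strand": [r.strand for r in records],
            "context": [r.context for r in records],
            "meth_count": [r.meth_count for r in records],
            "total_count": [r.total_count for r in records],
        }
    )


# ---------------------------------------------------------------------------
# alignments (SAM via pysam, TSV fallback)
# ---------------------------------------------------------------------------

ALN_COLUMNS = ["read_id", "chrom", "ref_start", "ref_end", "query_length",
               "left_unaligned", "right_unaligned", "identity_pct", "unique"]


def read_alignments(path, format: str = "SAM",
                    unique_only: bool = True) -> list:
    """Read alignments from SAM (identity from the NM tag; soft/hard clips
    populate the unaligned tails) or the tabular fallback.
    """
    fmt = format.upper()
    if fmt == "SAM":
        return _read_alignments_sam(path, unique_only)
    if fmt == "TSV":
        return _read_alignments_tsv(path, unique_only)
    raise ValueError(f"unsupported alignment format {format!r}")


def _read_alignments_sam(path, unique_only: bool) -> list:
    import pysam

    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            unique = (not rec.is_secondary and not rec.is_supplementary
                      and rec.mapping_quality > 0)
            if unique_only and not unique:
                continue
            cigar = rec.cigartuples or []
            left = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
            right = cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0
            aligned_len = rec.query_alignment_length
            if cigar and cigar[0][0] == 5:  # hard clip: bases not in SEQ
                aligned_len = sum(n for op, n in cigar if op in (0, 1, 7, 8))
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                raise FormatError(
                    f"read {rec.query_name!r} has no NM tag; identity cannot "
                    "be computed — use the TSV alignment format instead",
                    path=path)
            identity = 100.0 * (aligned_len - nm) / aligned_len
            query_length = left + aligned_len + right
            alignments.append(ReadAlignment(
                read_id=rec.query_name,
                query_length=query_length,
                interval=GenomicInterval(
                    rec.reference_name, rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+"),
                identity_pct=identity,
                left_unaligned=left,
                right_unaligned=right,
                unique=unique,
            ))
    return alignments


def _read_alignments_tsv(path, unique_only: bool) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ALN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"alignment table missing columns "
                          f"{sorted(missing)}", path=path)
    alignments = []
    for row in df.itertuples(index=False):
        unique = str(row.unique).strip() in ("1", "True", "true")
        if unique_only and not unique:
            continue
        alignments.append(ReadAlignment(
            read_id=str(row.read_id),
            query_length=int(row.query_length),
            interval=GenomicInterval(str(row.chrom), int(row.ref_start),
                                     int(row.ref_end)),
            identity_pct=float(row.identity_pct),
            left_unaligned=int(row.left_unaligned),
            right_unaligned=int(row.right_unaligned),
            unique=unique,
        ))
    return alignments


def write_alignments_tsv(alignments: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER_NOTE + "\n")
        fh.write("\t".join(ALN_COLUMNS) + "\n")
        for a in alignments:
            iv = a.interval
            fh.write(f"{a.read_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                     f"{a.query_length}\t{a.left_unaligned}\t"
                     f"{a.right_unaligned}\t{a.identity_pct:.6g}\t"
                     f"{int(a.unique)}\n")


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

def read_genes(path) -> list:
    """Read gene models with exon structure from GFF3."""
    gene_rows = {}
    exon_rows = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError("GFF3 needs 9 columns", path=path,
                                  line_no=line_no)
            chrom, _, ftype, start, end, _, strand, _, attr_text = fields
            attrs = _parse_gff3_attributes(attr_text)
            try:
                interval = GenomicInterval(chrom, int(start) - 1, int(end),
                                           strand)
            except ValueError as exc:
                raise FormatError(str(exc), path=path,
                                  line_no=line_no) from exc
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise FormatError("gene without ID attribute", path=path,
                                      line_no=line_no)
                gene_rows[gene_id] = interval
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError("exon without Parent attribute",
                                      path=path, line_no=line_no)
                exon_rows.setdefault(parent, []).append(interval)
    genes = []
    for gene_id, interval in gene_rows.items():
        exons = sorted(exon_rows.get(gene_id, [interval]),
                       key=lambda e: e.start)
        merged = _merge_intervals(exons)
        exon_length = sum(len(e) for e in merged)
        genes.append(GeneModel(gene_id=gene_id, interval=interval,
                               exons=tuple(merged),
                               exon_length_bp=exon_length))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def _merge_intervals(intervals) -> list:
    merged = []
    for iv in sorted(intervals, key=lambda e: (e.chrom, e.start)):
        if merged and merged[-1].chrom == iv.chrom \
                and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicInterval(last.chrom, last.start,
                                          max(last.end, iv.end), last.strand))
        else:
            merged.append(iv)
    return merged


def write_genes_gff3(genes: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\tte_spread\tgene\t{iv.start + 1}\t{iv.end}"
                     f"\t.\t{iv.strand}\t.\tID={g.gene_id}\n")
            for i, exon in enumerate(g.exons, start=1):
                fh.write(f"{exon.chrom}\tte_spread\texon\t{exon.start + 1}\t"
                         f"{exon.end}\t.\t{iv.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# counts / library sizes (TSV)
# ---------------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_id", "sample", "count"} - set(df.columns)
    if missing:
        raise FormatError(f"count table missing columns {sorted(missing)}",
                          path=path)
    return df


def read_library_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"sample", "library_size"} - set(df.columns)
    if missing:
        raise FormatError(f"library size table missing columns "
                          f"{sorted(missing)}", path=path)
    return {str(r["sample"]): int(r["library_size"])
            for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# small generic BED intervals (small RNA etc.)
# ---------------------------------------------------------------------------

def read_bed_intervals(path) -> list:
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED needs >= 3 columns", path=path,
                                  line_no=line_no)
            try:
                intervals.append(GenomicInterval(fields[0], int(fields[1]),
                                                 int(fields[2])))
            except ValueError as exc:
                raise FormatError(str(exc), path=path,
                                  line_no=line_no) from exc
    return intervals


def write_bed_intervals(intervals: Iterable, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
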