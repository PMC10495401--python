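"""Annotated-genome model and format I/O.

All internal coordinates are 0-based half-open. The 1-based inclusive
convention of GenBank flat files (and of human-readable reports) is
converted exactly once, at the read/write boundary. BED output is 0-based
half-open, as BED requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import revcomp

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "intron", "intergenic")


@dataclass
class GeneFeature:
    """A typed, stranded, possibly multi-exon gene feature.

    ``parts`` are (start, end) 0-based half-open intervals listed in
    transcription order (for minus-strand genes the genomically last part
    comes first). ``phase`` is the number of bases to drop before the first
    complete codon (GenBank ``codon_start`` minus one).
    """

    name: str
    ftype: str
    parts: list[tuple[int, int]]
    strand: int = 1
    phase: int = 0

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")
        if not 0 <= self.phase < 3:
            raise ValueError("phase must be 0, 1 or 2")
        for s, e in self.parts:
            if s >= e:
                raise ValueError(f"empty/inverted part ({s},{e}) in {self.name}")
        ivals = sorted(self.parts)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping parts in {self.name}")
        if self.ftype == "CDS" and self.spliced_length < 3:
            raise ValueError(f"CDS {self.name} shorter than one codon")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.parts)


@dataclass
class PlastomeRecord:
    """A plastome sequence plus its feature annotation."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        for f in self.features:
            if f.start < 0 or f.end > len(self.seq):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}) outside sequence of "
                    f"length {len(self.seq)}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    def get_feature(self, name: str, ftype: str = "CDS") -> GeneFeature:
        for f in self.features:
            if f.name == name and f.ftype == ftype:
                return f
        raise KeyError(f"no {ftype} feature named {name!r} in {self.id}")

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == "CDS"]


@dataclass
class CountsTable:
    """Per-gene mapped-fragment counts (input to FPKM)."""

    counts: dict[str, int]
    total_mapped: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        if self.total_mapped < sum(self.counts.values()):
            raise ValueError("total_mapped smaller than the sum of per-gene counts")


def normalize_seq(seq: str) -> str:
    """Uppercase and map every non-ACGT symbol to N."""
    seq = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in seq)


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Read an annotated genome from a GenBank flat file.

    CDS ``join()``/``complement()`` locations become parts in transcription
    order plus a strand; ``codon_start`` maps to phase. Features lying
    outside the sequence raise a hard error naming the feature.
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq)
    if not seq or set(seq.upper()) <= {"N"}:
        raise ValueError(f"{path}: GenBank record has no usable ORIGIN sequence")
    topology = rec.annotations.get("topology", "linear")
    features: list[GeneFeature] = []
    seen: dict[tuple[str, str], int] = {}
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        strand = -1 if feat.location.strand == -1 else 1
        parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
        # transcription order: genomic order on +, reverse-genomic on -
        parts.sort(key=lambda iv: iv[0], reverse=(strand == -1))
        phase = int(quals.get("codon_start", ["1"])[0]) - 1
        for s, e in parts:
            if s < 0 or e > len(seq):
                raise ValueError(f"{path}: feature {name} outside sequence bounds")
        key = (name, feat.type)
        n = seen.get(key, 0)
        seen[key] = n + 1
        if n:
            name = f"{name}.{n + 1}"
        features.append(
            GeneFeature(name=name, ftype=feat.type, parts=parts, strand=strand,
                        phase=phase if feat.type == "CDS" else 0)
        )
    return PlastomeRecord(id=rec.id, seq=seq, features=features, topology=topology)


# ---------------------------------------------------------------------------
# FASTA / tables / trees


def read_fasta(path: str | Path) -> list[PlastomeRecord]:
    records = [
        PlastomeRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Iterable[PlastomeRecord | tuple[str, str]],
                path: str | Path) -> None:
    out = []
    for r in records:
        if isinstance(r, tuple):
            rid, seq = r
        else:
            rid, seq = r.id, r.seq
        if not seq:
            raise ValueError(f"record {rid}: empty sequence")
        out.append(SeqRecord(Seq(seq), id=rid, description=""))
    if len({r.id for r in out}) != len(out):
        raise ValueError("duplicate record ids")
    SeqIO.write(out, str(path), "fasta")


def write_bed(intervals: Sequence[tuple], path: str | Path, name_col: bool = True) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            fields = [chrom, str(start), str(end)]
            if name_col and len(row) > 3:
                fields.append(str(row[3]))
            fh.write("\t".join(fields) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, total_mapped: int | None = None) -> CountsTable:
    """Read a two-column (gene, count) TSV with header into a CountsTable.

    If the file carries no explicit library size, ``total_mapped`` defaults
    to the column sum (i.e. all mapped fragments fall in annotated genes).
    """
    df = read_tsv(path)
    gene_col, count_col = df.columns[:2]
    counts = dict(zip(df[gene_col].astype(str), df[count_col].astype(int)))
    if total_mapped is None:
        total_mapped = int(sum(counts.values()))
    return CountsTable(counts=counts, total_mapped=total_mapped)


def write_newick(newick: str, path: str | Path) -> None:
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    Path(path).write_text(newick + "\n")


# ---------------------------------------------------------------------------
# CDS extraction


def extract_cds(record: PlastomeRecord, gene_name: str) -> str:
    """Spliced, strand-corrected coding sequence of a named CDS.

    Parts are concatenated in transcription order, reverse-complemented for
    minus-strand genes, the first ``phase`` bases dropped, and any trailing
    1-2 bases beyond the last full codon trimmed (with a warning). An
    internal stop codon triggers a warning, not an error, because consumed
    annotations are not always perfect.
    """
    feat = record.get_feature(gene_name, "CDS")
    pieces = []
    for s, e in feat.parts:
        piece = record.seq[s:e]
        if feat.strand == -1:
            piece = revcomp(piece)
        pieces.append(piece)
    cds = "".join(pieces)
    if feat.phase:
        cds = cds[feat.phase:]
    extra = len(cds) % 3
    if extra:
        warnings.warn(
            f"CDS {gene_name}: length not divisible by 3, trimming {extra} trailing base(s)"
        )
        cds = cds[: len(cds) - extra]
    from .codons import translate_cds  # local import to avoid cycle at module load

    aa = translate_cds(cds)
    if "*" in aa[:-1]:
        warnings.warn(f"CDS {gene_name}: internal stop codon at codon {aa.index('*') + 1}")
    return cds
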