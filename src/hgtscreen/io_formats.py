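"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ go through Bio.SeqIO, GFF3 through gffutils, homology hits
through the 12-column BLAST-style tabular convention, trees through the
newick support in :mod:`hgtscreen.phylo`.  Internal coordinates are 0-based
half-open everywhere; conversion to/from the 1-based inclusive GFF3
convention happens only here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

from ._codon import revcomp

log = logging.getLogger("hgtscreen")

VALID_ROLES = {
    "parasite_transcript",
    "host_cds",
    "outgroup_cds",
    "genomic_read",
    "mrna_read",
}

_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named DNA sequence with a species label and a pipeline role."""

    id: str
    species: str
    seq: str
    role: str = "host_cds"

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self):
        return len(self.seq)


@dataclass
class GeneModel:
    """Exon-intron structure of a gene on a host genome.

    ``exons`` are 0-based half-open intervals in genome coordinates, sorted
    and non-overlapping; ``cds_seq`` is the spliced coding sequence on the
    coding strand.
    """

    gene_id: str
    species: str
    chromosome: str
    strand: str
    exons: list
    cds_seq: str
    complete: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ex = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = ex
        total = sum(e - s for s, e in ex)
        if total != len(self.cds_seq):
            raise ValueError(
                f"{self.gene_id}: exon length {total} != CDS length "
                f"{len(self.cds_seq)}"
            )
        if self.complete and len(self.cds_seq) % 3:
            raise ValueError(f"{self.gene_id}: complete CDS not divisible by 3")

    @property
    def introns(self) -> list:
        """0-based half-open intron intervals between consecutive exons."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def splice(self, chrom_seq: str) -> str:
        """Splice the exons out of a chromosome sequence."""
        s = "".join(chrom_seq[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s.upper()


@dataclass
class HomologyHit:
    """A local alignment between a query transcript and a subject CDS."""

    query_id: str
    subject_id: str
    subject_species: str
    pct_identity: float
    aln_len: int
    matches: int
    mismatches: int
    gaps: int
    score_bits: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self):
        if self.matches + self.mismatches + self.gaps != self.aln_len:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: "
                "matches+mismatches+gaps != aln_len"
            )
        if abs(self.pct_identity - 100.0 * self.matches / self.aln_len) > 0.01:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: "
                "pct_identity inconsistent with matches/aln_len"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_sequences(
    path, fmt: str = "fasta", species: str = "", role: str = "host_cds"
) -> list:
    """Read a FASTA or FASTQ file into SequenceRecords.

    Sequences are uppercased; FASTQ qualities are discarded (no step of the
    pipeline is quality-aware).  An empty file yields an empty list with a
    warning.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    records = []
    seen = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(rec.id, species, str(rec.seq), role=role)
            )
    except ValueError as exc:  # Bio.SeqIO raises ValueError on bad records
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no sequences found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70):
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path):
    """Write reads as FASTQ with uniform placeholder qualities."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(gff_path, genome: Iterable[SequenceRecord]) -> list:
    """Read gene models from a GFF3 file (gene + CDS features).

    CDS intervals are converted from the 1-based inclusive GFF3 convention
    to internal 0-based half-open, spliced out of the genome, and
    reverse-complemented for minus-strand genes.
    """
    import gffutils

    chroms = {rec.id: rec.seq for rec in genome}
    species = {rec.id: rec.species for rec in genome}
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    gene_ids = {g.id for g in db.features_of_type("gene")}
    orphans = set()
    by_gene: dict = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        parent = parents[0] if parents else None
        if parent is None or parent not in gene_ids:
            orphans.add(parent or cds.id)
            continue
        by_gene.setdefault(parent, []).append(cds)
    for gid in orphans:
        warnings.warn(f"{gff_path}: CDS without parent gene near {gid!r}; skipped")
    for gene in db.features_of_type("gene"):
        parts = by_gene.get(gene.id)
        if not parts:
            continue
        chrom = gene.seqid
        if chrom not in chroms:
            raise ParseError(f"{gff_path}: unknown chromosome {chrom!r}")
        chrom_seq = chroms[chrom]
        exons = []
        for cds in parts:
            start, end = cds.start - 1, cds.end  # to 0-based half-open
            if start < 0 or end > len(chrom_seq):
                raise ParseError(
                    f"{gff_path}: exon {start + 1}-{end} of {gene.id} outside "
                    f"chromosome {chrom} (length {len(chrom_seq)})"
                )
            exons.append((start, end))
        strand = gene.strand if gene.strand in "+-" else "+"
        ex = sorted(exons)
        cds_seq = "".join(chrom_seq[a:b] for a, b in ex)
        if strand == "-":
            cds_seq = revcomp(cds_seq)
        models.append(
            GeneModel(
                gene_id=gene.id,
                species=species.get(chrom, ""),
                chromosome=chrom,
                strand=strand,
                exons=ex,
                cds_seq=cds_seq.upper(),
                complete=len(cds_seq) % 3 == 0,
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path):
    """Write gene models as GFF3 (gene + CDS features)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start = m.exons[0][0] + 1
            end = m.exons[-1][1]
            fh.write(
                f"{m.chromosome}\thgtscreen\tgene\t{start}\t{end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for k, (a, b) in enumerate(m.exons):
                fh.write(
                    f"{m.chromosome}\thgtscreen\tCDS\t{a + 1}\t{b}\t.\t"
                    f"{m.strand}\t0\tID={m.gene_id}.cds{k};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# 12-column tabular hits


def parse_subject_species(subject_id: str, sep: str = "|") -> str:
    """Species label from a 'species|gene' style subject id ('' if absent)."""
    return subject_id.split(sep, 1)[0] if sep in subject_id else ""


def read_tabular_hits(path, species_sep: str = "|") -> list:
    """Read BLAST-style 12-column tabular hits.

    Columns: query, subject, pct_identity, aln_len, mismatches, gap_opens,
    q_start, q_end, s_start, s_end, e_value, bit_score.  The 12-column
    format does not carry gap *columns*, so gaps are set to 0 and matches
    are back-computed from identity; the species label is parsed from the
    subject-id prefix convention.
    """
    hits = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                ident = float(cols[2])
                aln_len = int(cols[3])
                mism = int(cols[4])
                bits = float(cols[11])
                qs, qe, ss, se = (int(c) for c in cols[6:10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            matches = int(round(ident * aln_len / 100.0))
            gaps = aln_len - matches - mism
            if gaps < 0:
                mism, gaps = aln_len - matches, 0
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    subject_species=parse_subject_species(cols[1], species_sep),
                    pct_identity=100.0 * matches / aln_len,
                    aln_len=aln_len,
                    matches=matches,
                    mismatches=mism,
                    gaps=gaps,
                    score_bits=bits,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], path):
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_len,
                        h.mismatches,
                        h.gaps,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        "0.0",
                        f"{h.score_bits:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Trees (delegates to hgtscreen.phylo)


def read_tree(source):
    """Read a newick tree from a path or a newick string."""
    from .phylo import Tree

    text = source
    if isinstance(source, (str, Path)):
        p = Path(str(source))
        if not str(source).lstrip().startswith("(") and p.exists():
            text = p.read_text()
    return Tree.from_newick(str(text))


def write_tree(tree, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    """Load a YAML key-value config file."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def setup_logging(level=logging.INFO):
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s [%(stage)s] %(message)s"
    )


class StageLogger(logging.LoggerAdapter):
    """Logger adapter injecting a screening-stage name into log lines."""

    def __init__(self, stage: str):
        super().__init__(log, {"stage": stage})

    def process(self, msg, kwargs):
        kwargs.setdefault("extra", {})["stage"] = self.extra["stage"]
        return msg, kwargs
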