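"""Reading, writing and the in-memory genome model.

All stages of the pipeline operate on a :class:`GenomeSet`: a collection of
:class:`GeneModel` records (one CDS per gene) indexed by gene ID and by
position along each chromosome. Coordinates are 0-based half-open
internally; GFF3 (1-based inclusive) conversion happens only in the reader
and writer here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class FormatError(ValueError):
    """Raised when input files violate the expected structure."""


def has_internal_stop(cds: str) -> bool:
    """True when any codon before the last one is a stop codon."""
    s = cds.upper()
    return any(s[i : i + 3] in STOP_CODONS for i in range(0, len(s) - 3, 3))


@dataclass(frozen=True)
class GeneModel:
    """One gene: species, location on its chromosome, strand and CDS.

    ``rank`` is the 0-based order index of the gene along its chromosome
    (sorted by start, strand-independent).
    """

    gene_id: str
    species: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str
    cds: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class LoadReport:
    """What was dropped during FASTA/GFF3 reconciliation and validation."""

    missing_in_gff: int = 0
    missing_in_fasta: int = 0
    bad_length: int = 0
    internal_stop: int = 0

    @property
    def total_dropped(self) -> int:
        return self.missing_in_gff + self.missing_in_fasta + self.bad_length + self.internal_stop


class GenomeSet:
    """Genes of one or more species, indexed by ID and genomic order."""

    def __init__(self, genes: Iterable[GeneModel], load_report: LoadReport | None = None):
        self.load_report = load_report or LoadReport()
        self._genes: dict[str, GeneModel] = {}
        by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise FormatError(f"duplicate gene ID {g.gene_id!r}")
            self._genes[g.gene_id] = g
            by_chrom.setdefault((g.species, g.chromosome), []).append(g)
        # assign ranks per chromosome by start
        self._by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
        for key, gl in by_chrom.items():
            gl.sort(key=lambda g: (g.start, g.gene_id))
            ranked = [
                GeneModel(g.gene_id, g.species, g.chromosome, g.start, g.end, g.strand, g.cds, rank=i)
                for i, g in enumerate(gl)
            ]
            for g in ranked:
                self._genes[g.gene_id] = g
            self._by_chrom[key] = ranked
        self.species: list[str] = sorted({g.species for g in self._genes.values()})

    # -- access -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def genes(self) -> list[GeneModel]:
        return [self._genes[k] for k in sorted(self._genes)]

    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    def chromosomes(self, species: str) -> list[str]:
        return sorted(c for (s, c) in self._by_chrom if s == species)

    def chromosome_genes(self, species: str, chromosome: str) -> list[GeneModel]:
        """Genes of one chromosome in rank order."""
        return list(self._by_chrom.get((species, chromosome), []))

    def species_genes(self, species: str) -> list[GeneModel]:
        out: list[GeneModel] = []
        for c in self.chromosomes(species):
            out.extend(self._by_chrom[(species, c)])
        return out


def load_genomes(
    fasta_paths: Sequence[str | Path],
    gff_paths: Sequence[str | Path],
    species_names: Sequence[str],
) -> GenomeSet:
    """Read one CDS FASTA + one GFF3 per species into a reconciled GenomeSet.

    Genes present in only one of the two files are dropped with a warning,
    as are genes whose CDS length is not a multiple of 3 or that contain an
    internal stop codon. Drop counts are recorded on ``GenomeSet.load_report``.
    """
    if not (len(fasta_paths) == len(gff_paths) == len(species_names)):
        raise ValueError("fasta_paths, gff_paths and species_names must have equal length")
    report = LoadReport()
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    for fasta, gff, sp in zip(fasta_paths, gff_paths, species_names):
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id in seqs:
                raise FormatError(f"{fasta}: duplicate FASTA ID {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
        db = gffutils.create_db(
            Path(gff).read_text(), dbfn=":memory:", from_string=True,
            force=True, keep_order=True, merge_strategy="error",
        )
        ann: dict[str, gffutils.Feature] = {}
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            if gid in ann:
                raise FormatError(f"{gff}: duplicate gene ID {gid!r}")
            ann[gid] = feat
        common = set(seqs) & set(ann)
        if not common:
            raise FormatError(f"species {sp!r}: FASTA and GFF3 share no gene IDs")
        for gid in set(seqs) - common:
            report.missing_in_gff += 1
            log.warning("%s: FASTA record %s has no annotation; dropped", sp, gid)
        for gid in set(ann) - common:
            report.missing_in_fasta += 1
            log.warning("%s: annotated gene %s has no CDS record; dropped", sp, gid)
        for gid in sorted(common):
            cds = seqs[gid]
            if len(cds) % 3 != 0:
                report.bad_length += 1
                log.warning("%s: CDS length of %s not a multiple of 3; dropped", sp, gid)
                continue
            if has_internal_stop(cds):
                report.internal_stop += 1
                log.warning("%s: CDS of %s contains internal stop codon; dropped", sp, gid)
                continue
            if gid in seen_ids:
                raise FormatError(f"gene ID {gid!r} occurs in more than one species")
            seen_ids.add(gid)
            feat = ann[gid]
            genes.append(
                GeneModel(
                    gene_id=gid, species=sp, chromosome=feat.seqid,
                    start=feat.start - 1, end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+", cds=cds,
                )
            )
    return GenomeSet(genes, load_report=report)


def write_genome(genome: GenomeSet, species: str, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write one species of a GenomeSet as CDS FASTA + GFF3 (genes only)."""
    records = []
    lines = ["##gff-version 3"]
    for chrom in genome.chromosomes(species):
        for g in genome.chromosome_genes(species, chrom):
            records.append(SeqRecord(Seq(g.cds), id=g.gene_id, description=""))
            lines.append(
                f"{g.chromosome}\tyoungdup\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
            )
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    Path(gff_path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Column-stable, header-first TSV with deterministic row order."""
    out = df.copy()
    if sort_by is None:
        sort_by = list(out.columns[:1]) if len(out.columns) else None
    if sort_by and len(out):
        out = out.sort_values(list(sort_by), kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
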