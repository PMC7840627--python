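"""Readers and writers for the standard formats the pipeline consumes.

Dialect decisions, fixed once and applied everywhere:

* Internal coordinates are 0-based, half-open.  Every file reader/writer
  converts at the boundary (PED/MAP, VCF and BED are emitted/consumed with
  their native conventions); HGVS output is 1-based.
* Genotype calls are a four-state scheme: ``0`` hom-ref, ``1`` het, ``2``
  hom-alt, ``-1`` missing.  Missing is a first-class state and is never
  imputed silently.
* VCF v4.2; unphased ``0/1`` and phased ``0|1`` are both accepted but phase
  is discarded at ingest (phase is recomputed from trios downstream).
  Multiallelic records are decomposed into biallelic records sharing the
  position; the per-sample count of each alternate allele is conserved by
  the decomposition.
* Gene models travel as BED12 whose ``name`` column is
  ``transcript_id|gene_id``, with sequence in an accompanying FASTA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers with missing-allowed calls.

    ``calls`` is an ``int8`` array of shape ``(n_samples, n_markers)`` in the
    four-state scheme.  ``pos`` holds 0-based positions, strictly increasing
    within each chromosome.  ``alleles`` carries the two observed allele
    symbols per marker (used when writing PED).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    alleles: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.alleles is None:
            self.alleles = [("A", "B")] * len(self.marker_ids)
        self.validate()

    def validate(self) -> None:
        n_s, n_m = len(self.sample_ids), len(self.marker_ids)
        if self.calls.shape != (n_s, n_m):
            raise FormatError(
                f"calls shape {self.calls.shape} != ({n_s} samples, {n_m} markers)"
            )
        if len(self.chrom) != n_m or len(self.pos) != n_m:
            raise FormatError("chrom/pos length does not match marker count")
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(f"invalid call state at sample {i}, marker {j}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not genotyped") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            calls=self.calls[:, keep].copy(),
            alleles=[self.alleles[i] for i in keep],
        )


def _encode_pair(a: str, b: str, a1: str, a2: str, where: str) -> int:
    if a == "0" or b == "0":
        return MISSING
    for x in (a, b):
        if x not in (a1, a2):
            raise FormatError(f"allele {x!r} not in marker alleles ({a1},{a2}) at {where}")
    n_alt = (a == a2) + (b == a2)
    return (HOM_REF, HET, HOM_ALT)[n_alt]


def read_genotypes(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read a PLINK text PED + MAP pair into a :class:`GenotypeMatrix`.

    PED dialect: 6 leading columns (fam, id, sire, dam, sex, phenotype) then
    two allele columns per marker; ``0 0`` encodes a missing call.  Allele 1
    (``a1``) / allele 2 (``a2``) are taken in order of first appearance per
    marker, so hom/het states are relative to that marker's observed alleles.
    """
    markers: list[str] = []
    chroms: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise FormatError(f"{map_path} line {ln}: expected 4 columns")
            chroms.append(fields[0])
            markers.append(fields[1])
            pos.append(int(fields[3]) - 1)  # MAP is 1-based

    n_m = len(markers)
    sample_ids: list[str] = []
    raw_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_m:
                raise FormatError(
                    f"{ped_path} line {ln}: expected {6 + 2 * n_m} columns, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            raw_rows.append(fields[6:])

    alleles: list[tuple[str, str]] = []
    for j in range(n_m):
        seen: list[str] = []
        for row in raw_rows:
            for x in (row[2 * j], row[2 * j + 1]):
                if x != "0" and x not in seen:
                    seen.append(x)
        seen = sorted(seen)
        if len(seen) > 2:
            raise FormatError(f"marker {markers[j]} has >2 alleles: {seen}")
        while len(seen) < 2:
            seen.append("B" if "A" in seen else chr(ord("A") + len(seen)))
        alleles.append((seen[0], seen[1]))

    calls = np.empty((len(sample_ids), n_m), dtype=np.int8)
    for i, row in enumerate(raw_rows):
        for j in range(n_m):
            a1, a2 = alleles[j]
            calls[i, j] = _encode_pair(
                row[2 * j], row[2 * j + 1], a1, a2,
                f"{ped_path} sample {sample_ids[i]} marker {markers[j]}",
            )
    return GenotypeMatrix(sample_ids, markers, np.array(chroms, dtype=object),
                          np.array(pos), calls, alleles)


def write_genotypes(gm: GenotypeMatrix, ped_path: str, map_path: str,
                    pedigree=None) -> None:
    """Write PED + MAP.  Pedigree columns are filled from ``pedigree`` if given."""
    with open(map_path, "w") as fh:
        for j in range(gm.n_markers):
            fh.write(f"{gm.chrom[j]}\t{gm.marker_ids[j]}\t0\t{gm.pos[j] + 1}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            sire = dam = "0"
            sex = pheno = "0"
            if pedigree is not None and sid in pedigree:
                ind = pedigree[sid]
                sire = ind.sire_id or "0"
                dam = ind.dam_id or "0"
                sex = {"male": "1", "female": "2"}.get(ind.sex, "0")
                pheno = {"unaffected": "1", "affected": "2"}.get(ind.phenotype, "0")
            cols = ["FAM", sid, sire, dam, sex, pheno]
            for j in range(gm.n_markers):
                a1, a2 = gm.alleles[j]
                c = gm.calls[i, j]
                cols += {HOM_REF: [a1, a1], HET: [a1, a2],
                         HOM_ALT: [a2, a2], MISSING: ["0", "0"]}[c]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """A biallelic called variant with per-sample four-state genotypes.

    ``pos`` is 0-based internally; :attr:`pos1` gives the 1-based VCF/HGVS
    position.  ``effect_class`` is one of the funnel's effect vocabulary or
    ``None`` when not yet annotated.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, int] = field(default_factory=dict)
    gene_id: str | None = None
    effect_class: str | None = None
    var_id: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos1}")

    @property
    def pos1(self) -> int:
        return self.pos + 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g in (HET, HOM_ALT)]


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF (4.2, plain text or bgzipped) into biallelic records.

    Multiallelic sites are decomposed into one record per ALT; a sample's
    genotype for ALT *k* is the count of allele *k* it carries, so total
    non-reference allele counts are conserved across the decomposition.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(path)
    samples = list(vcf.samples)
    for n, v in enumerate(vcf):
        try:
            gts = (v.genotypes or []) if samples else []  # [[a, b, phased], ...]
        except Exception as exc:  # pragma: no cover - cyvcf2 internal failures
            raise FormatError(f"{path}: malformed GT in record {n + 1} "
                              f"({v.CHROM}:{v.POS})") from exc
        gene = v.INFO.get("GENE")
        effect = v.INFO.get("EFFECT")
        for k, alt in enumerate(v.ALT, start=1):
            genos: dict[str, int] = {}
            for s, gt in zip(samples, gts):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    genos[s] = MISSING
                else:
                    genos[s] = int(a == k) + int(b == k)
            records.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS - 1, ref=v.REF, alt=alt,
                genotypes=genos, gene_id=gene, effect_class=effect,
                var_id=None if v.ID in (None, ".") else v.ID))
    return records


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(records: list[VariantRecord], path: str,
              sample_ids: list[str] | None = None,
              contigs: list[str] | None = None) -> None:
    """Write biallelic records as a minimal plain-text VCF 4.2."""
    if sample_ids is None:
        seen: list[str] = []
        for r in records:
            for s in r.genotypes:
                if s not in seen:
                    seen.append(s)
        sample_ids = seen
    if contigs is None:
        contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if sample_ids:
            header += "\tFORMAT\t" + "\t".join(sample_ids)
        fh.write(header + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = []
            if r.gene_id:
                info.append(f"GENE={r.gene_id}")
            if r.effect_class:
                info.append(f"EFFECT={r.effect_class}")
            cols = [r.chrom, str(r.pos1), r.var_id or ".", r.ref, r.alt, ".",
                    "PASS", ";".join(info) or "."]
            if sample_ids:
                cols.append("GT")
                cols += [_GT_STR[r.genotypes.get(s, MISSING)] for s in sample_ids]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models (BED12 + FASTA)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Strand-aware exon/CDS structure tied to a reference sequence.

    Exons are 0-based half-open genomic intervals ordered by genomic
    position and non-overlapping; ``cds_start``/``cds_end`` bound the coding
    region in genomic coordinates regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    seq: dict[str, str] | None = None  # chrom -> sequence
    translatable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        ex = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if s1 < e0:
                raise FormatError(f"{self.transcript_id}: overlapping exons")
        self.exons = ex
        if not any(s <= self.cds_start < e for s, e in ex):
            raise FormatError(f"{self.transcript_id}: cds_start outside exons")
        if not any(s < self.cds_end <= e for s, e in ex):
            raise FormatError(f"{self.transcript_id}: cds_end outside exons")

    # -- sequence access ---------------------------------------------------

    def chrom_seq(self) -> str:
        if self.seq is None or self.chrom not in self.seq:
            raise FormatError(f"{self.transcript_id}: no sequence for {self.chrom}")
        return self.seq[self.chrom]

    def spliced_sequence(self, exons: list[tuple[int, int]] | None = None) -> str:
        """Transcript-orientation spliced sequence of the given exon set."""
        g = self.chrom_seq()
        parts = [g[s:e] for s, e in (exons if exons is not None else self.exons)]
        s = "".join(parts)
        return str(Seq(s).reverse_complement()) if self.strand == "-" else s

    def cds_exons(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    def cds_sequence(self) -> str:
        return self.spliced_sequence(self.cds_exons())

    def protein(self) -> str:
        """Reference protein (stops at, and excludes, the terminator)."""
        cds = self.cds_sequence()
        aa = str(Seq(cds).translate())
        return aa.split("*")[0] if "*" in aa else aa


def read_gene_models(bed_path: str, fasta_path: str) -> list[GeneModel]:
    """Read BED12 gene models (name = ``transcript_id|gene_id``) + FASTA.

    A model whose CDS length is not a multiple of 3 is flagged
    non-translatable with a warning rather than rejected.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    models: list[GeneModel] = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if not fields or fields[0].startswith(("#", "track")):
                continue
            if len(fields) < 12:
                raise FormatError(f"{bed_path} line {ln}: expected 12 BED columns")
            chrom, start = fields[0], int(fields[1])
            name, strand = fields[3], fields[5]
            thick_s, thick_e = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{bed_path} line {ln}: block count mismatch")
            tid, _, gid = name.partition("|")
            exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
            m = GeneModel(tid, gid or tid, chrom, strand, exons, thick_s, thick_e,
                          seq=seqs)
            cds_len = sum(e - s for s, e in m.cds_exons())
            if cds_len % 3 != 0:
                warnings.warn(f"{tid}: CDS length {cds_len} not divisible by 3; "
                              "flagged non-translatable")
                m.translatable = False
            models.append(m)
    return models


def write_gene_models(models: list[GeneModel], bed_path: str,
                      fasta_path: str | None = None) -> None:
    with open(bed_path, "w") as fh:
        for m in models:
            start, end = m.exons[0][0], m.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offs = ",".join(str(s - start) for s, e in m.exons)
            fh.write("\t".join(map(str, [
                m.chrom, start, end, f"{m.transcript_id}|{m.gene_id}", 0,
                m.strand, m.cds_start, m.cds_end, "0", len(m.exons),
                sizes, offs])) + "\n")
    if fasta_path is not None:
        seqs: dict[str, str] = {}
        for m in models:
            if m.seq:
                seqs.update(m.seq)
        with open(fasta_path, "w") as fh:
            for name, s in seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(s), 60):
                    fh.write(s[i:i + 60] + "\n")
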