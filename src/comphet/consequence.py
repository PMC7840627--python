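"""Isoform-aware transcript consequence prediction with HGVS nomenclature.

One genomic variant is annotated independently against every transcript
model that covers it, because alternative splicing can change both the
codon context and the reading consequence of the same nucleotide (an
insert-bearing isoform can read a variant as missense where the short
isoform reads a premature stop).

Splice handling is deliberately minimal and auditable: only the canonical
U2-type GT (donor) / AG (acceptor) dinucleotides at intronic positions
+-1/+-2 count as splice-disrupting; positions +-3..8 are annotated
``splice_region`` and treated as non-protein-changing.  When a variant
destroys an acceptor AG, the rescue model moves the exon's 5' boundary to
just after the nearest downstream AG within a 50-base exonic scan window
(no splice-strength scoring); with no AG in the window the exon is skipped.
Donor loss mirrors this with an upstream GT scan and is flagged
lower-confidence.  Truncation is reported as such — nonsense-mediated
decay is never predicted.

HGVS conventions: coding-DNA (c.) positions are 1-based with intronic
offsets (c.210-2A>G); protein (p.) names use three-letter codes and "Ter"
(p.Leu71TrpfsTer3), with "*" accepted on input and normalised on output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from comphet.io_formats import GeneModel, VariantRecord

SCAN_WINDOW_DEFAULT = 50
SPLICE_REGION_RANGE = range(3, 9)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _aa3(aa1: str) -> str:
    return "Ter" if aa1 == "*" else seq3(aa1)


class ConsequenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Transcript model with cached translation
# ---------------------------------------------------------------------------


class TranscriptModel(GeneModel):
    """A gene model whose reference CDS must translate cleanly."""

    @classmethod
    def from_gene_model(cls, m: GeneModel) -> "TranscriptModel":
        t = cls(m.transcript_id, m.gene_id, m.chrom, m.strand, m.exons,
                m.cds_start, m.cds_end, seq=m.seq)
        t.translatable = m.translatable
        return t

    @cached_property
    def cds(self) -> str:
        return self.cds_sequence()

    @cached_property
    def protein_seq(self) -> str:
        aa = str(Seq(self.cds).translate())
        if "*" in aa[:-1]:
            raise ConsequenceError(
                f"{self.transcript_id}: internal stop in reference CDS")
        return aa.rstrip("*")

    def covers(self, chrom: str, g_pos: int) -> bool:
        return (chrom == self.chrom
                and self.exons[0][0] <= g_pos < self.exons[-1][1])


# ---------------------------------------------------------------------------
# Genomic -> cDNA coordinate mapping
# ---------------------------------------------------------------------------


@dataclass
class CdnaCoord:
    """A c. coordinate: base position string plus intronic offset."""
    kind: str            # cds / utr5 / utr3 / intron / out_of_transcript
    base: int = 0        # c. anchor (negative for 5'UTR; *n encoded by kind)
    offset: int = 0      # intronic +/- offset relative to the anchor exon base
    star: bool = False   # anchor lies in the 3' UTR (c.*N)

    def __str__(self) -> str:
        if self.kind == "out_of_transcript":
            return "?"
        s = ("*" if self.star else "") + str(self.base)
        if self.offset:
            s += f"{'+' if self.offset > 0 else '-'}{abs(self.offset)}"
        return f"{s}"


def _tx_exons(t: TranscriptModel) -> list[tuple[int, int]]:
    """Exons in transcript (5'->3') order."""
    return t.exons[::-1] if t.strand == "-" else list(t.exons)


def _g_to_t(t: TranscriptModel, g: int) -> int | None:
    """Spliced-transcript offset (0-based) of an exonic genomic position."""
    off = 0
    for s, e in _tx_exons(t):
        if s <= g < e:
            return off + ((g - s) if t.strand == "+" else (e - 1 - g))
        off += e - s
    return None


def _cds_t_bounds(t: TranscriptModel) -> tuple[int, int]:
    g_first = t.cds_start if t.strand == "+" else t.cds_end - 1
    g_last = t.cds_end - 1 if t.strand == "+" else t.cds_start
    return _g_to_t(t, g_first), _g_to_t(t, g_last) + 1


def _t_to_c(t: TranscriptModel, tpos: int) -> tuple[int, bool]:
    """(base, star) c. anchor for a spliced-transcript offset."""
    c0, c1 = _cds_t_bounds(t)
    if tpos < c0:
        return tpos - c0, False         # negative: 5' UTR
    if tpos >= c1:
        return tpos - c1 + 1, True      # c.*N
    return tpos - c0 + 1, False


def map_genomic_to_cdna(g_pos: int, t: TranscriptModel) -> CdnaCoord:
    """Map a 0-based genomic position to a c. coordinate.

    Exonic positions map directly; intronic positions anchor to the nearest
    exon boundary with a +/- offset (equidistant positions anchor to the
    upstream, donor-side exon, per HGVS).
    """
    if not t.covers(t.chrom, g_pos):
        return CdnaCoord("out_of_transcript")
    tpos = _g_to_t(t, g_pos)
    if tpos is not None:
        base, star = _t_to_c(t, tpos)
        c0, c1 = _cds_t_bounds(t)
        kind = "cds" if c0 <= tpos < c1 else ("utr5" if tpos < c0 else "utr3")
        return CdnaCoord(kind, base, 0, star)
    # intronic: locate the flanking exons in transcript order
    ex = _tx_exons(t)
    for k in range(len(ex) - 1):
        s_up, e_up = ex[k]
        s_dn, e_dn = ex[k + 1]
        if t.strand == "+":
            in_intron = e_up <= g_pos < s_dn
            d_donor = g_pos - e_up + 1        # distance past upstream exon end
            d_accept = s_dn - g_pos           # distance before downstream exon
            t_up, t_dn = _g_to_t(t, e_up - 1), _g_to_t(t, s_dn)
        else:
            in_intron = e_dn <= g_pos < s_up
            d_donor = s_up - g_pos            # transcript-orientation distances
            d_accept = g_pos - e_dn + 1
            t_up, t_dn = _g_to_t(t, s_up), _g_to_t(t, e_dn - 1)
        if not in_intron:
            continue
        if d_donor <= d_accept:
            base, star = _t_to_c(t, t_up)
            return CdnaCoord("intron", base, d_donor, star)
        base, star = _t_to_c(t, t_dn)
        return CdnaCoord("intron", base, -d_accept, star)
    return CdnaCoord("out_of_transcript")  # pragma: no cover


def hgvs_c(variant: VariantRecord, t: TranscriptModel) -> str:
    """HGVS c. name of an SNV; alleles are complemented on reverse strand."""
    coord = map_genomic_to_cdna(variant.pos, t)
    ref, alt = variant.ref, variant.alt
    if t.strand == "-":
        ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    return f"c.{coord}{ref}>{alt}"


# ---------------------------------------------------------------------------
# SNV classification
# ---------------------------------------------------------------------------


def classify_snv(variant: VariantRecord, t: TranscriptModel) -> str:
    """Effect class of an SNV on one transcript."""
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ConsequenceError("classify_snv handles single-nucleotide variants")
    if not t.covers(variant.chrom, variant.pos):
        return "non_coding"
    if not t.translatable:
        return "non_coding"
    coord = map_genomic_to_cdna(variant.pos, t)
    if coord.kind == "intron":
        if abs(coord.offset) in (1, 2):
            return "splice_acceptor" if coord.offset < 0 else "splice_donor"
        if abs(coord.offset) in SPLICE_REGION_RANGE:
            return "splice_region"
        return "non_coding"
    if coord.kind != "cds":
        return "non_coding"
    cds = t.cds
    cpos = coord.base - 1
    ref_t, alt_t = variant.ref, variant.alt
    if t.strand == "-":
        ref_t = ref_t.translate(_COMPLEMENT)
        alt_t = alt_t.translate(_COMPLEMENT)
    if cds[cpos] != ref_t:
        raise ConsequenceError(
            f"reference mismatch at c.{coord.base} of {t.transcript_id}: "
            f"CDS has {cds[cpos]}, variant ref is {ref_t}")
    codon_i = cpos // 3
    codon = cds[codon_i * 3: codon_i * 3 + 3]
    mutant = codon[:cpos % 3] + alt_t + codon[cpos % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref == "*":
        return "stop_lost"
    if aa_alt == "*":
        return "nonsense"
    if codon_i == 0:
        return "start_lost"
    return "missense"


# ---------------------------------------------------------------------------
# Splice-loss rescue models
# ---------------------------------------------------------------------------


@dataclass
class SpliceRescue:
    mode: str                 # cryptic_acceptor / cryptic_donor / exon_skip / no_rescue
    deletion_length: int
    mutant_exons: list[tuple[int, int]] = field(default_factory=list)
    mutant_cds: str = ""
    low_confidence: bool = False


def _acceptor_exon_index(variant: VariantRecord, t: TranscriptModel) -> int:
    """Transcript-order index of the exon whose acceptor the variant destroys."""
    coord = map_genomic_to_cdna(variant.pos, t)
    if coord.kind != "intron" or coord.offset not in (-1, -2):
        raise ConsequenceError(
            "variant does not hit a canonical acceptor position (c.N-1/-2)")
    ex = _tx_exons(t)
    for k in range(1, len(ex)):
        s, e = ex[k]
        g_first = s if t.strand == "+" else e - 1
        d = (g_first - variant.pos) if t.strand == "+" else (variant.pos - g_first)
        if d in (1, 2):
            return k
    raise ConsequenceError("no exon acceptor adjacent to the variant")


def _rebuild_cds(t: TranscriptModel, exons_tx: list[tuple[int, int]]) -> str:
    genomic = sorted(exons_tx)
    clipped = []
    for s, e in genomic:
        s2, e2 = max(s, t.cds_start), min(e, t.cds_end)
        if s2 < e2:
            clipped.append((s2, e2))
    return t.spliced_sequence(clipped)


def apply_acceptor_loss(variant: VariantRecord, t: TranscriptModel,
                        scan_window: int = SCAN_WINDOW_DEFAULT) -> SpliceRescue:
    """Cryptic-acceptor rescue after loss of a canonical acceptor AG.

    The affected exon's 5' boundary moves to just past the nearest
    downstream AG within ``scan_window`` exonic bases; without one the exon
    is skipped, and if skipping removes the CDS start no rescue is modelled.
    """
    k = _acceptor_exon_index(variant, t)
    ex = _tx_exons(t)
    s, e = ex[k]
    exon_seq = t.chrom_seq()[s:e]
    if t.strand == "-":
        exon_seq = _revcomp(exon_seq)
    hit = exon_seq.find("AG", 0, scan_window)
    if hit >= 0:
        cut = hit + 2  # exon now starts just after the AG
        if t.strand == "+":
            new_exon = (s + cut, e)
        else:
            new_exon = (s, e - cut)
        mut = [new_exon if i == k else x for i, x in enumerate(ex)]
        cds = _rebuild_cds(t, mut)
        return SpliceRescue("cryptic_acceptor", cut, mut, cds)
    # fallback: skip the exon entirely
    mut = [x for i, x in enumerate(ex) if i != k]
    cds_overlap = max(0, min(e, t.cds_end) - max(s, t.cds_start))
    cds_start_in_exon = s <= t.cds_start < e if t.strand == "+" \
        else s < t.cds_end <= e
    if cds_start_in_exon:
        return SpliceRescue("no_rescue", 0, [], "", low_confidence=True)
    cds = _rebuild_cds(t, mut)
    return SpliceRescue("exon_skip", cds_overlap, mut, cds)


def apply_donor_loss(variant: VariantRecord, t: TranscriptModel,
                     scan_window: int = SCAN_WINDOW_DEFAULT) -> SpliceRescue:
    """Mirror of acceptor rescue: upstream GT scan at a lost donor.

    Flagged low-confidence: cryptic-donor activation is modelled by the
    same nearest-site rule but is not anchored by an experimental case.
    """
    coord = map_genomic_to_cdna(variant.pos, t)
    if coord.kind != "intron" or coord.offset not in (1, 2):
        raise ConsequenceError("variant does not hit a canonical donor position")
    ex = _tx_exons(t)
    for k in range(len(ex) - 1):
        s, e = ex[k]
        g_last = e - 1 if t.strand == "+" else s
        d = (variant.pos - g_last) if t.strand == "+" else (g_last - variant.pos)
        if d in (1, 2):
            exon_seq = t.chrom_seq()[s:e]
            if t.strand == "-":
                exon_seq = _revcomp(exon_seq)
            region = exon_seq[-scan_window:] if scan_window < len(exon_seq) else exon_seq
            hit = region.rfind("GT")
            if hit >= 0:
                cut = len(region) - hit  # bases removed from the exon 3' end
                new_exon = (s, e - cut) if t.strand == "+" else (s + cut, e)
                mut = [new_exon if i == k else x for i, x in enumerate(ex)]
                return SpliceRescue("cryptic_donor", cut, mut,
                                    _rebuild_cds(t, mut), low_confidence=True)
            mut = [x for i, x in enumerate(ex) if i != k]
            cds_overlap = max(0, min(e, t.cds_end) - max(s, t.cds_start))
            return SpliceRescue("exon_skip", cds_overlap, mut,
                                _rebuild_cds(t, mut), low_confidence=True)
    raise ConsequenceError("no exon donor adjacent to the variant")


# ---------------------------------------------------------------------------
# Mutant translation and HGVS p. naming
# ---------------------------------------------------------------------------


@dataclass
class MutantProtein:
    hgvs_p: str
    mutant_protein_length: int | None
    fraction_truncated: float | None
    no_stop: bool = False


def translate_mutant(mutant_cds: str, reference_protein: str) -> MutantProtein:
    """Translate a mutant CDS and name the protein change.

    Frameshift naming follows HGVS: first divergent residue (reference
    amino acid + position), the new residue, then ``fsTer`` + the stop's
    index in the new frame counting the divergent residue as 1.  A mutant
    with no stop before the sequence end is reported ``fsTer?`` and
    flagged.
    """
    aa = str(Seq(mutant_cds[:len(mutant_cds) - len(mutant_cds) % 3]).translate())
    no_stop = "*" not in aa
    mut = aa.split("*")[0]
    ref = reference_protein
    ref_len = len(ref)
    if mut == ref:
        return MutantProtein("p.(=)", ref_len, 0.0)
    i = 0
    while i < min(len(mut), ref_len) and mut[i] == ref[i]:
        i += 1
    if i == len(mut):
        # premature stop with intact upstream sequence: nonsense-style
        return MutantProtein(f"p.{_aa3(ref[i])}{i + 1}Ter", i,
                             1.0 - i / ref_len, no_stop)
    if len(mut) == ref_len and mut[i + 1:] == ref[i + 1:]:
        return MutantProtein(f"p.{_aa3(ref[i])}{i + 1}{_aa3(mut[i])}",
                             ref_len, 0.0)
    if i >= ref_len:
        # stop-lost style extension; report the first novel residue
        return MutantProtein(f"p.Ter{ref_len + 1}{_aa3(mut[i])}extTer"
                             f"{'?' if no_stop else len(mut) - ref_len + 1}",
                             len(mut), 0.0, no_stop)
    ter = "?" if no_stop else str(len(mut) - i + 1)
    return MutantProtein(f"p.{_aa3(ref[i])}{i + 1}{_aa3(mut[i])}fsTer{ter}",
                         len(mut), 1.0 - len(mut) / ref_len, no_stop)


# ---------------------------------------------------------------------------
# HGVS parsing (round-trip support)
# ---------------------------------------------------------------------------

_C_RE = re.compile(
    r"^c\.(?P<star>\*)?(?P<base>-?\d+)"
    r"(?P<off>[+-]\d+)?(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_P_FS_RE = re.compile(
    r"^p\.(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2})"
    r"fsTer(?P<ter>\d+|\?)$")
_P_SUB_RE = re.compile(
    r"^p\.(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|Ter|\*)$")


def parse_hgvs_c(s: str) -> dict:
    m = _C_RE.match(s)
    if not m:
        raise ConsequenceError(f"unparseable c. name: {s!r}")
    return {"base": int(m["base"]), "star": bool(m["star"]),
            "offset": int(m["off"]) if m["off"] else 0,
            "ref": m["ref"], "alt": m["alt"]}


def format_hgvs_c(d: dict) -> str:
    coord = CdnaCoord("cds", d["base"], d["offset"], d["star"])
    return f"c.{coord}{d['ref']}>{d['alt']}"


def parse_hgvs_p(s: str) -> dict:
    if s == "p.(=)":
        return {"kind": "identity"}
    m = _P_FS_RE.match(s)
    if m:
        return {"kind": "frameshift", "ref": m["ref"], "pos": int(m["pos"]),
                "alt": m["alt"],
                "ter": None if m["ter"] == "?" else int(m["ter"])}
    m = _P_SUB_RE.match(s)
    if m:
        alt = "Ter" if m["alt"] == "*" else m["alt"]
        return {"kind": "substitution", "ref": m["ref"], "pos": int(m["pos"]),
                "alt": alt}
    raise ConsequenceError(f"unparseable p. name: {s!r}")


def format_hgvs_p(d: dict) -> str:
    if d["kind"] == "identity":
        return "p.(=)"
    if d["kind"] == "frameshift":
        ter = "?" if d["ter"] is None else str(d["ter"])
        return f"p.{d['ref']}{d['pos']}{d['alt']}fsTer{ter}"
    return f"p.{d['ref']}{d['pos']}{d['alt']}"


# ---------------------------------------------------------------------------
# Per-isoform annotation
# ---------------------------------------------------------------------------


@dataclass
class ConsequenceCall:
    transcript_id: str
    effect_class: str
    hgvs_c: str
    hgvs_p: str | None = None
    mutant_protein_length: int | None = None
    fraction_truncated: float | None = None
    flags: list[str] = field(default_factory=list)


def annotate_variant(variant: VariantRecord, t: TranscriptModel,
                     scan_window: int = SCAN_WINDOW_DEFAULT) -> ConsequenceCall:
    effect = classify_snv(variant, t)
    call = ConsequenceCall(t.transcript_id, effect, hgvs_c(variant, t))
    ref_prot = t.protein_seq
    if effect == "splice_acceptor":
        rescue = apply_acceptor_loss(variant, t, scan_window)
        call.flags.append(rescue.mode)
        if rescue.mode == "no_rescue":
            call.hgvs_p = "p.?"
            return call
        mp = translate_mutant(rescue.mutant_cds, ref_prot)
        call.hgvs_p = mp.hgvs_p
        call.mutant_protein_length = mp.mutant_protein_length
        call.fraction_truncated = mp.fraction_truncated
        if mp.no_stop:
            call.flags.append("no_stop")
    elif effect == "splice_donor":
        rescue = apply_donor_loss(variant, t, scan_window)
        call.flags.append(rescue.mode)
        call.flags.append("low_confidence")
        if rescue.mutant_cds:
            mp = translate_mutant(rescue.mutant_cds, ref_prot)
            call.hgvs_p = mp.hgvs_p
            call.mutant_protein_length = mp.mutant_protein_length
            call.fraction_truncated = mp.fraction_truncated
    elif effect in ("missense", "nonsense", "synonymous", "stop_lost", "start_lost"):
        coord = map_genomic_to_cdna(variant.pos, t)
        cpos = coord.base - 1
        alt_t = variant.alt if t.strand == "+" else variant.alt.translate(_COMPLEMENT)
        mutant_cds = t.cds[:cpos] + alt_t + t.cds[cpos + 1:]
        mp = translate_mutant(mutant_cds, ref_prot)
        call.hgvs_p = mp.hgvs_p
        call.mutant_protein_length = mp.mutant_protein_length
        call.fraction_truncated = mp.fraction_truncated
    return call


def annotate_all_isoforms(variant: VariantRecord,
                          transcripts: list[TranscriptModel],
                          scan_window: int = SCAN_WINDOW_DEFAULT
                          ) -> list[ConsequenceCall]:
    """One :class:`ConsequenceCall` per transcript covering the variant."""
    calls = []
    for t in transcripts:
        if t.covers(variant.chrom, variant.pos):
            calls.append(annotate_variant(variant, t, scan_window))
    return calls
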