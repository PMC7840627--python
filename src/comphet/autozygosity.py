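"""Runs-of-homozygosity (autozygosity) detection and shared-segment mapping.

A rule-based consecutive-run scanner, not a sliding-window heuristic: a run
is a maximal stretch of markers beginning and ending with homozygous calls
that accumulates at most ``max_het`` heterozygous and ``max_miss`` missing
calls; it is reported when it spans at least ``min_snps`` markers and
``min_length`` bases.  Default parameters (40 SNPs, 2 Mb, 1 het, 2 missing)
are calibrated to a ~50k-marker array on a ~2.6 Gb genome;
:meth:`ROHParams.scaled_to` rescales the SNP counts for sparser panels.

Shared autozygosity across affected animals is stricter than segment
overlap: within the intersection of everyone's ROH, every non-missing
marker must be homozygous for the *same* allele in all cases, so two
animals homozygous for opposite alleles never share a segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from comphet.io_formats import GenotypeMatrix, HET, MISSING


@dataclass
class ROHParams:
    min_snps: int = 40
    min_length: int = 2_000_000
    max_het: int = 1
    max_miss: int = 2

    def scaled_to(self, n_markers: int, genome_bp: int = 2_600_000_000) -> "ROHParams":
        """Rescale SNP-count thresholds to a different marker density.

        The reference calibration is 50 000 markers on 2.6 Gb; physical
        ``min_length`` is kept, ``min_snps``/``max_miss`` shrink or grow with
        the expected markers per base.
        """
        ratio = (n_markers / genome_bp) / (50_000 / 2_600_000_000)
        min_snps = max(10, round(self.min_snps * ratio))
        return replace(self, min_snps=min_snps,
                       max_miss=max(self.max_miss, min_snps // 3))


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start: int  # 0-based half-open genomic span
    end: int
    n_snps: int
    n_het_allowed_used: int = 0
    n_missing_used: int = 0

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def _scan_chrom(calls: np.ndarray, pos: np.ndarray, chrom: str, sample: str,
                p: ROHParams) -> list[ROHSegment]:
    segs: list[ROHSegment] = []
    n = len(calls)
    hom = (calls == 0) | (calls == 2)
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        # grow a run from the homozygous anchor at i
        het_used = miss_used = 0
        last_hom = i
        j = i + 1
        while j < n:
            c = calls[j]
            if hom[j]:
                last_hom = j
            elif c == HET:
                if het_used + 1 > p.max_het:
                    break
                het_used += 1
            elif c == MISSING:
                if miss_used + 1 > p.max_miss:
                    break
                miss_used += 1
            j += 1
        # trim trailing tolerated calls; run is [i, last_hom]
        run = calls[i:last_hom + 1]
        n_snps = last_hom - i + 1
        span = int(pos[last_hom] - pos[i] + 1)
        if n_snps >= p.min_snps and span >= p.min_length:
            segs.append(ROHSegment(
                sample_id=sample, chrom=chrom,
                start=int(pos[i]), end=int(pos[last_hom]) + 1,
                n_snps=n_snps,
                n_het_allowed_used=int((run == HET).sum()),
                n_missing_used=int((run == MISSING).sum())))
        i = last_hom + 1
    return segs


def detect_roh(gm: GenotypeMatrix, sample: str,
               params: ROHParams | None = None) -> list[ROHSegment]:
    """Maximal tolerant homozygous runs for one sample, per chromosome."""
    p = params or ROHParams()
    row = gm.row(sample)
    segs: list[ROHSegment] = []
    for chrom in dict.fromkeys(gm.chrom):  # preserve order
        idx = np.flatnonzero(gm.chrom == chrom)
        segs += _scan_chrom(row[idx], gm.pos[idx], str(chrom), sample, p)
    return segs


def shared_autozygosity(segments: dict[str, list[ROHSegment]],
                        gm: GenotypeMatrix, cases: list[str],
                        params: ROHParams | None = None,
                        bridge_markers: int = 3) -> list[dict]:
    """Intervals where all cases are autozygous for the same allele.

    ``segments`` maps each case to its ROH list.  Candidate intervals are
    the intersections of everyone's segments; they are then split at any
    marker where some case is heterozygous or two cases are homozygous for
    opposite alleles, and surviving pieces must retain ``min_snps``
    supporting markers (the physical-length floor applies to single-animal
    segments, not to their intersection).  Before intersecting, each case's
    segments are bridged across micro-gaps of at most ``bridge_markers``
    markers: the run scanner splits a long segment when its tolerance
    counters overflow, leaving 1-3-marker holes that would otherwise
    fragment the intersection; the allele-match scan below still vetoes any
    bridged marker that contradicts sharing.
    """
    if len(cases) < 2:
        raise ValueError("shared autozygosity needs >= 2 cases")
    p = params or ROHParams()
    rows = {c: gm.row(c) for c in cases}
    out: list[dict] = []
    for chrom in dict.fromkeys(gm.chrom):
        chrom = str(chrom)
        # intersect the per-case interval sets on this chromosome
        chrom_pos = gm.pos[np.flatnonzero(gm.chrom == chrom)]
        pieces = [(0, np.iinfo(np.int64).max)]
        for c in cases:
            case_iv = sorted((s.start, s.end) for s in segments.get(c, [])
                             if s.chrom == chrom)
            merged: list[tuple[int, int]] = []
            for s, e in case_iv:
                if merged:
                    gap_n = int(((chrom_pos >= merged[-1][1])
                                 & (chrom_pos < s)).sum())
                    if gap_n <= bridge_markers:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                        continue
                merged.append((s, e))
            case_iv = merged
            new = []
            for (a, b) in pieces:
                for (s, e) in case_iv:
                    lo, hi = max(a, s), min(b, e)
                    if lo < hi:
                        new.append((lo, hi))
            pieces = new
            if not pieces:
                break
        idx = np.flatnonzero(gm.chrom == chrom)
        pos = gm.pos[idx]
        for (a, b) in pieces:
            in_iv = idx[(pos >= a) & (pos < b)]
            if len(in_iv) == 0:
                continue
            # marker-wise allele agreement across cases (missing ignored)
            ok = np.ones(len(in_iv), dtype=bool)
            ref_allele = np.full(len(in_iv), -9, dtype=np.int8)
            for c in cases:
                g = rows[c][in_iv]
                ok &= g != HET
                hom = (g == 0) | (g == 2)
                first = hom & (ref_allele == -9)
                ref_allele[first] = g[first]
                ok &= ~hom | (g == ref_allele)
            # maximal consecutive ok-runs
            k = 0
            while k < len(in_iv):
                if not ok[k]:
                    k += 1
                    continue
                j = k
                while j + 1 < len(in_iv) and ok[j + 1]:
                    j += 1
                n_snps = j - k + 1
                s0 = int(gm.pos[in_iv[k]])
                e0 = int(gm.pos[in_iv[j]]) + 1
                # marker support only: the intersection of several animals'
                # segments is legitimately shorter than any single-animal
                # ROH, so the physical-length floor does not apply here
                if n_snps >= p.min_snps:
                    out.append({"chrom": chrom, "start": s0, "end": e0,
                                "n_snps": n_snps})
                k = j + 1
    return out


def write_bed(segments, path: str) -> None:
    """BED output for ROH segments or shared intervals."""
    with open(path, "w") as fh:
        for s in segments:
            if isinstance(s, ROHSegment):
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample_id}\t{s.n_snps}\n")
            else:
                fh.write(f"{s['chrom']}\t{s['start']}\t{s['end']}\tshared\t{s['n_snps']}\n")
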