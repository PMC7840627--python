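"""Pedigree representation, parentage verification and trio construction.

Single-parent parentage checks count *opposing homozygotes* — markers where
child and candidate are homozygous for different alleles — which are the
only single-parent Mendelian impossibilities (a heterozygous child can
always have received either allele).  Verdicts use conventional SNP-array
thresholds on the opposing-homozygote rate: ``confirmed`` below 0.001,
``excluded`` above 0.01, ``ambiguous`` between (all overridable).

Ungenotyped ancestors (e.g. a shared maternal grandsire) are representable
as *phantom* individuals: present in the pedigree, absent from genotype
data.  Their genotypes are never imputed; carrier status is deduced
downstream from descendants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from comphet.io_formats import GenotypeMatrix, HOM_ALT, HOM_REF

CONFIRM_THRESHOLD = 0.001
EXCLUDE_THRESHOLD = 0.01


@dataclass
class Individual:
    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"          # male / female / unknown
    phenotype: str = "unknown"    # affected / unaffected / unknown
    phantom: bool = False         # known to exist but never sampled


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Collection of individuals keyed by id, with sire/dam links."""

    def __init__(self, individuals: list[Individual] | None = None):
        self._ind: dict[str, Individual] = {}
        for ind in individuals or []:
            self.add(ind)
        self.validate()

    def add(self, ind: Individual) -> None:
        if ind.id in self._ind:
            raise PedigreeError(f"duplicate individual id {ind.id!r}")
        self._ind[ind.id] = ind

    def __contains__(self, iid: str) -> bool:
        return iid in self._ind

    def __getitem__(self, iid: str) -> Individual:
        return self._ind[iid]

    def __iter__(self):
        return iter(self._ind.values())

    def __len__(self) -> int:
        return len(self._ind)

    @property
    def ids(self) -> list[str]:
        return list(self._ind)

    def validate(self) -> None:
        for ind in self:
            for pid, role, sex in ((ind.sire_id, "sire", "male"),
                                   (ind.dam_id, "dam", "female")):
                if pid is None:
                    continue
                if pid in self._ind:
                    psex = self._ind[pid].sex
                    if psex not in ("unknown", sex):
                        raise PedigreeError(
                            f"{role} {pid} of {ind.id} has sex {psex}")
        # no individual is its own ancestor
        for ind in self:
            if ind.id in self.ancestors(ind.id):
                raise PedigreeError(f"{ind.id} is its own ancestor")

    def ancestors(self, iid: str) -> set[str]:
        out: set[str] = set()
        stack = [p for p in (self._ind[iid].sire_id, self._ind[iid].dam_id) if p]
        while stack:
            a = stack.pop()
            if a in out:
                continue
            out.add(a)
            if a in self._ind:
                ind = self._ind[a]
                stack += [p for p in (ind.sire_id, ind.dam_id) if p]
        return out

    def affected(self) -> list[str]:
        return [i.id for i in self if i.phenotype == "affected"]

    def founders(self) -> list[str]:
        return [i.id for i in self if i.sire_id is None and i.dam_id is None]


# ---------------------------------------------------------------------------
# FAM I/O
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female"}
_PHENO = {"1": "unaffected", "2": "affected"}


def read_fam(path: str) -> Pedigree:
    inds = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) < 6:
                raise PedigreeError(f"{path} line {ln}: expected 6 FAM columns")
            inds.append(Individual(
                id=f[1],
                sire_id=None if f[2] == "0" else f[2],
                dam_id=None if f[3] == "0" else f[3],
                sex=_SEX.get(f[4], "unknown"),
                phenotype=_PHENO.get(f[5], "unknown")))
    return Pedigree(inds)


def write_fam(ped: Pedigree, path: str) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    ph_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(" ".join(["FAM", ind.id, ind.sire_id or "0",
                               ind.dam_id or "0", sex_code[ind.sex],
                               ph_code[ind.phenotype]]) + "\n")


# ---------------------------------------------------------------------------
# Parentage verification
# ---------------------------------------------------------------------------


@dataclass
class ParentageVerdict:
    child_id: str
    parent_id: str
    n_informative_markers: int
    n_opposing_homozygotes: int
    verdict: str  # confirmed / excluded / ambiguous
    tied: bool = False

    @property
    def error_rate(self) -> float:
        if self.n_informative_markers == 0:
            return float("nan")
        return self.n_opposing_homozygotes / self.n_informative_markers


def verify_parentage(gm: GenotypeMatrix, child: str, candidate: str,
                     confirm_threshold: float = CONFIRM_THRESHOLD,
                     exclude_threshold: float = EXCLUDE_THRESHOLD) -> ParentageVerdict:
    """Opposing-homozygote parentage test for one candidate parent.

    Informative markers are those where both individuals are non-missing;
    opposing homozygotes are symmetric in the two individuals.
    """
    c = gm.row(child)
    p = gm.row(candidate)
    both = (c >= 0) & (p >= 0)
    n_inf = int(both.sum())
    opp = both & (((c == HOM_REF) & (p == HOM_ALT)) | ((c == HOM_ALT) & (p == HOM_REF)))
    n_opp = int(opp.sum())
    if n_inf == 0:
        verdict = "ambiguous"
    else:
        rate = n_opp / n_inf
        if rate < confirm_threshold:
            verdict = "confirmed"
        elif rate > exclude_threshold:
            verdict = "excluded"
        else:
            verdict = "ambiguous"
    return ParentageVerdict(child, candidate, n_inf, n_opp, verdict)


def assign_maternity(gm: GenotypeMatrix, child: str,
                     candidate_dams: list[str], **thresholds) -> list[ParentageVerdict]:
    """Rank candidate dams by opposing-homozygote rate, ascending.

    At most one candidate keeps a ``confirmed`` verdict; if the best rate is
    tied between several candidates, all tied verdicts are demoted to
    ambiguous and flagged.  Candidates with no informative markers sort last.
    """
    if not candidate_dams:
        raise PedigreeError("assign_maternity requires >= 1 candidate")
    verdicts = [verify_parentage(gm, child, d, **thresholds) for d in candidate_dams]
    verdicts.sort(key=lambda v: (np.isnan(v.error_rate), v.error_rate))
    best = verdicts[0]
    if not np.isnan(best.error_rate):
        tied = [v for v in verdicts
                if not np.isnan(v.error_rate) and v.error_rate == best.error_rate]
        if len(tied) > 1:
            for v in tied:
                v.tied = True
                if v.verdict == "confirmed":
                    v.verdict = "ambiguous"
    for v in verdicts[1:]:
        if v.verdict == "confirmed" and not v.tied:
            v.verdict = "ambiguous"
    return verdicts


def build_trios(ped: Pedigree, gm: GenotypeMatrix) -> list[tuple[str, str, str]]:
    """(child, sire, dam) triples whose three members are all genotyped.

    Affected children are listed first; order is otherwise pedigree order.
    """
    genotyped = set(gm.sample_ids)
    trios = []
    for ind in ped:
        if (ind.id in genotyped and ind.sire_id in genotyped
                and ind.dam_id in genotyped):
            trios.append((ind.id, ind.sire_id, ind.dam_id))
    trios.sort(key=lambda t: 0 if ped[t[0]].phenotype == "affected" else 1)
    return trios
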