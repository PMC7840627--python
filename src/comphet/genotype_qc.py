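"""Sample- and marker-level quality control for array genotypes.

Two filters, mirroring standard family-study practice: flag samples whose
call rate falls below 90%, and prune markers whose missing-call fraction
exceeds 10% (strictly greater; a marker missing in exactly 10% of samples
is retained).  No minor-allele-frequency or Hardy-Weinberg filters are
applied — they are meaningless within a single family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from comphet.io_formats import GenotypeMatrix, MISSING

DEFAULT_MIN_SAMPLE_CALL_RATE = 0.90
DEFAULT_MAX_MARKER_MISSING = 0.10


class QCError(ValueError):
    pass


@dataclass
class SampleCallRates:
    sample_ids: list[str]
    rates: np.ndarray
    flagged: list[str]  # below threshold


def sample_call_rates(gm: GenotypeMatrix,
                      min_rate: float = DEFAULT_MIN_SAMPLE_CALL_RATE) -> SampleCallRates:
    """Per-sample fraction of non-missing calls, flagging low-call samples."""
    if gm.n_markers == 0:
        raise QCError("call rates need at least one marker")
    rates = (gm.calls != MISSING).mean(axis=1)
    flagged = [s for s, r in zip(gm.sample_ids, rates) if r < min_rate]
    return SampleCallRates(list(gm.sample_ids), rates, flagged)


def marker_missing_fraction(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.calls == MISSING).mean(axis=0)


def prune_markers_by_missingness(
        gm: GenotypeMatrix,
        max_missing: float = DEFAULT_MAX_MARKER_MISSING) -> GenotypeMatrix:
    """Drop markers with missing fraction strictly above ``max_missing``.

    Sample set, marker order and every retained call are unchanged;
    applying the filter twice equals applying it once.
    """
    keep = marker_missing_fraction(gm) <= max_missing
    if not keep.any():
        raise QCError(
            f"all {gm.n_markers} markers exceed missingness {max_missing}; "
            "review the threshold or the genotyping run")
    return gm.subset_markers(keep)
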