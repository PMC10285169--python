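"""CSF-vs-serum differential filter for intrathecally produced IgG.

A chain group's IgG is considered CSF-enriched when both the absolute iBAQ
difference and the CSF/serum iBAQ ratio clear their thresholds (strictly):

    iBAQ_CSF - iBAQ_serum > 5e4   and   iBAQ_CSF / iBAQ_serum > 1.2

When no serum signal is detected at all (iBAQ_serum = 0) the ratio is
undefined; any detected CSF abundance is then maximally CSF-enriched, so
the ratio test is deemed satisfied and the difference test alone decides.

A clonotype is called intrathecal when a heavy and a light chain group of
that clonotype both pass (rule "pair"), or when a heavy chain group passes
with at least three unique CSF peptides (rule "single_heavy").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import InputError
from .ig_proteome import ChainQuant

logger = logging.getLogger(__name__)

DEFAULT_DELTA_MIN = 5e4
DEFAULT_RATIO_MIN = 1.2
DEFAULT_MIN_UNIQUE = 3


@dataclass(frozen=True)
class IntrathecalCall:
    """Clonotype-level verdict with the chain evidence behind it."""

    clonotype_id: str
    called: bool
    rule: str  # "pair" | "single_heavy" | "none"
    evidence: tuple[ChainQuant, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert self.called == (self.rule != "none")


def chain_passes(
    q: ChainQuant,
    delta_min: float = DEFAULT_DELTA_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
) -> bool:
    """True iff the chain group's iBAQ values show strict CSF enrichment."""
    if q.ibaq_csf < 0 or q.ibaq_serum < 0:
        raise InputError(
            f"negative iBAQ for chain group {q.chain_group_id}: "
            f"csf={q.ibaq_csf}, serum={q.ibaq_serum}"
        )
    if not q.ibaq_csf - q.ibaq_serum > delta_min:
        return False
    if q.ibaq_serum == 0.0:
        return q.ibaq_csf > delta_min
    return q.ibaq_csf / q.ibaq_serum > ratio_min


def call_intrathecal(
    quants_by_clonotype: dict[str, list[ChainQuant]],
    delta_min: float = DEFAULT_DELTA_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
    min_unique: int = DEFAULT_MIN_UNIQUE,
) -> list[IntrathecalCall]:
    """Apply the pair / single-heavy decision rules per clonotype.

    A locus passes when any of the clonotype's chain groups at that locus
    passes.  Clonotypes without a heavy-chain quant are not callable and are
    logged.
    """
    calls: list[IntrathecalCall] = []
    for clonotype_id in sorted(quants_by_clonotype):
        quants = quants_by_clonotype[clonotype_id]
        heavy = [q for q in quants if q.locus == "IGH"]
        light = [q for q in quants if q.locus in ("IGK", "IGL")]
        if not heavy:
            logger.warning(
                "clonotype %s has no heavy chain quant; not callable", clonotype_id
            )
            calls.append(IntrathecalCall(clonotype_id, False, "none", tuple(quants)))
            continue
        heavy_pass = [q for q in heavy if chain_passes(q, delta_min, ratio_min)]
        light_pass = [q for q in light if chain_passes(q, delta_min, ratio_min)]
        if heavy_pass and light_pass:
            calls.append(
                IntrathecalCall(
                    clonotype_id, True, "pair", (heavy_pass[0], light_pass[0])
                )
            )
        elif any(q.n_unique_peptides_csf >= min_unique for q in heavy_pass):
            best = next(q for q in heavy_pass if q.n_unique_peptides_csf >= min_unique)
            calls.append(IntrathecalCall(clonotype_id, True, "single_heavy", (best,)))
        else:
            calls.append(IntrathecalCall(clonotype_id, False, "none", tuple(quants)))
    return calls


def called_set(calls: list[IntrathecalCall]) -> set[str]:
    return {c.clonotype_id for c in calls if c.called}
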