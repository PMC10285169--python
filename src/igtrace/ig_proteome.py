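"""Patient-specific Ig protein libraries, in-silico digestion and iBAQ.

The translated heavy- and light-chain sequences of one patient's cells are
deduplicated into chain groups, digested in silico with trypsin, and the
observed peptide intensities are assigned back to every chain group whose
theoretical digest contains them.  Chain-group abundance per compartment is
summarized as iBAQ: summed assigned intensity divided by the number of
theoretically observable fully tryptic peptides.

Conventions:

* trypsin cleaves C-terminal to K or R except when the next residue is P;
* peptides of 0..``missed_cleavages`` missed sites within a configurable
  length window are considered matchable (default 2 missed, 7-30 residues);
* the iBAQ denominator counts only fully tryptic (0-missed) peptides in the
  window;
* matching is exact string equality (I and L distinct unless the optional
  I=L mode is enabled);
* a shared peptide's intensity is counted for every matching chain group,
  and peptide uniqueness is evaluated at clonotype scope within a patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .clonotyping import Clonotype
from .errors import InputError
from .repertoire_io import ChainRecord, PeptideObservation, dedupe_chain_sequences

logger = logging.getLogger(__name__)

DEFAULT_MISSED_CLEAVAGES = 2
DEFAULT_MIN_PEPTIDE_LEN = 7
DEFAULT_MAX_PEPTIDE_LEN = 30
CONSTANT_EXTENSION_NT = 24


@dataclass
class ChainGroup:
    """All of one patient's cells whose chains translate to one amino-acid sequence."""

    chain_group_id: str
    patient_id: str
    locus: str
    sequence_aa: str
    member_cell_ids: tuple[str, ...]
    clonotype_ids: tuple[str, ...]
    short_extension: bool = False  # nucleotide record shorter than junction end + 24

    @property
    def is_heavy(self) -> bool:
        return self.locus == "IGH"


@dataclass
class PeptideAssignment:
    """One observed peptide mapped onto the chain library."""

    peptide_sequence: str
    chain_group_ids: tuple[str, ...]
    unique: bool  # matches chain groups of exactly one clonotype
    intensity_by_compartment: dict[str, float] = field(default_factory=dict)


@dataclass
class ChainQuant:
    """Per-chain-group iBAQ abundances and unique-peptide evidence."""

    chain_group_id: str
    locus: str
    ibaq_csf: float
    ibaq_serum: float
    n_unique_peptides_csf: int
    n_theoretical_peptides: int
    clonotype_ids: tuple[str, ...] = ()


def digest(
    sequence_aa: str,
    missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> list[str]:
    """In-silico tryptic digest of one protein sequence.

    Cleaves C-terminal to K or R unless followed by P; emits every peptide
    with 0..``missed_cleavages`` missed sites whose length falls in
    [``min_len``, ``max_len``].  Order is deterministic: N- to C-terminal by
    start position, then by missed-cleavage count.
    """
    if not sequence_aa:
        raise InputError("cannot digest an empty sequence")
    n = len(sequence_aa)
    # cut after position i (0-based) when residue is K/R and next is not P
    cuts = [
        i + 1
        for i in range(n - 1)
        if sequence_aa[i] in "KR" and sequence_aa[i + 1] != "P"
    ]
    bounds = [0] + cuts + [n]
    peptides: list[str] = []
    for si in range(len(bounds) - 1):
        for mc in range(missed_cleavages + 1):
            ei = si + 1 + mc
            if ei >= len(bounds):
                break
            pep = sequence_aa[bounds[si] : bounds[ei]]
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


def count_theoretical_peptides(
    sequence_aa: str,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> int:
    """Number of fully tryptic (0-missed) peptides in the observable window."""
    return len(digest(sequence_aa, 0, min_len, max_len))


def build_chain_library(
    chains: list[ChainRecord], clonotypes: list[Clonotype]
) -> list[ChainGroup]:
    """Deduplicate one patient's translated chains into linked chain groups.

    Chains are expected to carry the constant-region extension already; a
    chain whose nucleotide record is shorter than its junction end plus the
    24-nt extension is kept but flagged with a validation warning.
    """
    clonotype_of_cell: dict[str, str] = {}
    for ct in clonotypes:
        for cell in ct.cell_ids:
            clonotype_of_cell[cell] = ct.clonotype_id

    groups: list[ChainGroup] = []
    for group_id, locus, aa, members in dedupe_chain_sequences(chains):
        short = any(
            len(c.sequence_nt) < c.junction_end + CONSTANT_EXTENSION_NT for c in members
        )
        if short:
            logger.warning(
                "chain group %s: record shorter than junction end + %d nt "
                "(missing constant-region extension?)",
                group_id,
                CONSTANT_EXTENSION_NT,
            )
        owning = sorted(
            {
                clonotype_of_cell[c.cell_id]
                for c in members
                if c.cell_id in clonotype_of_cell
            }
        )
        groups.append(
            ChainGroup(
                chain_group_id=group_id,
                patient_id=members[0].patient_id,
                locus=locus,
                sequence_aa=aa,
                member_cell_ids=tuple(sorted({c.cell_id for c in members})),
                clonotype_ids=tuple(owning),
                short_extension=short,
            )
        )
    return groups


def match_peptides(
    observations: list[PeptideObservation],
    library: list[ChainGroup],
    missed_cleavages: int = DEFAULT_MISSED_CLEAVAGES,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
    equate_il: bool = False,
) -> tuple[list[PeptideAssignment], list[PeptideObservation]]:
    """Assign observed peptides to every chain group whose digest contains them.

    Returns (assignments, unassigned observations).  An assignment is unique
    when its matching chain groups belong to exactly one clonotype.
    Observations matching no chain group are retained for reporting.
    """
    if not library:
        raise InputError("cannot match peptides against an empty library")

    def canon(p: str) -> str:
        return p.replace("I", "L") if equate_il else p

    peptide_to_groups: dict[str, set[str]] = {}
    group_by_id = {g.chain_group_id: g for g in library}
    for g in library:
        for pep in set(digest(g.sequence_aa, missed_cleavages, min_len, max_len)):
            peptide_to_groups.setdefault(canon(pep), set()).add(g.chain_group_id)

    assignments: dict[str, PeptideAssignment] = {}
    unassigned: list[PeptideObservation] = []
    for obs in observations:
        groups = peptide_to_groups.get(canon(obs.peptide_sequence))
        if not groups:
            unassigned.append(obs)
            continue
        key = obs.peptide_sequence
        if key not in assignments:
            owning_clonotypes = {
                ct for gid in groups for ct in group_by_id[gid].clonotype_ids
            }
            assignments[key] = PeptideAssignment(
                peptide_sequence=key,
                chain_group_ids=tuple(sorted(groups)),
                unique=len(owning_clonotypes) == 1,
            )
        asg = assignments[key]
        asg.intensity_by_compartment[obs.compartment] = (
            asg.intensity_by_compartment.get(obs.compartment, 0.0) + obs.intensity
        )
    return [assignments[k] for k in sorted(assignments)], unassigned


def compute_ibaq(
    assignments: list[PeptideAssignment],
    library: list[ChainGroup],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> list[ChainQuant]:
    """iBAQ per chain group and compartment.

    iBAQ = (summed assigned intensity in the compartment, shared peptides
    counted for every matching group) / (number of theoretical fully tryptic
    peptides in the observable window).  Groups with no assigned peptides get
    iBAQ 0; groups with zero theoretical peptides are excluded and logged.
    """
    sums: dict[str, dict[str, float]] = {g.chain_group_id: {} for g in library}
    n_unique_csf: dict[str, int] = {g.chain_group_id: 0 for g in library}
    for asg in assignments:
        for gid in asg.chain_group_ids:
            if gid not in sums:
                continue
            for compartment, intensity in asg.intensity_by_compartment.items():
                sums[gid][compartment] = sums[gid].get(compartment, 0.0) + intensity
            if asg.unique and asg.intensity_by_compartment.get("CSF", 0.0) > 0:
                n_unique_csf[gid] += 1

    quants: list[ChainQuant] = []
    for g in library:
        n_theo = count_theoretical_peptides(g.sequence_aa, min_len, max_len)
        if n_theo == 0:
            logger.warning(
                "chain group %s has no theoretical peptides in [%d, %d]; "
                "iBAQ undefined, excluded from calling",
                g.chain_group_id,
                min_len,
                max_len,
            )
            continue
        s = sums[g.chain_group_id]
        quants.append(
            ChainQuant(
                chain_group_id=g.chain_group_id,
                locus=g.locus,
                ibaq_csf=s.get("CSF", 0.0) / n_theo,
                ibaq_serum=s.get("serum", 0.0) / n_theo,
                n_unique_peptides_csf=n_unique_csf[g.chain_group_id],
                n_theoretical_peptides=n_theo,
                clonotype_ids=g.clonotype_ids,
            )
        )
    return quants
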