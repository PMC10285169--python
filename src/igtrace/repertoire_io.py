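"""Readers and writers for the pipeline's external formats.

Three formats cross the package boundary:

* a cell table — an AIRR-rearrangement-style TSV with one row per sequenced
  immunoglobulin chain (heavy or light) plus per-cell metadata columns,
* per-patient peptide intensity tables for the CSF and serum compartments
  (a simplified peptides-level dialect of label-free search output),
* the per-patient protein library as FASTA of translated chain sequences.

All tables are tab-separated UTF-8 with a mandatory header row and no
quoting.  Parsing is strict: rows that violate an invariant are dropped and
counted, never silently coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

VALID_LOCI = frozenset({"IGH", "IGK", "IGL"})
LIGHT_LOCI = frozenset({"IGK", "IGL"})
VALID_COMPARTMENTS = frozenset({"CSF", "serum"})
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

CELL_TABLE_COLUMNS = (
    "cell_id",
    "patient_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "sequence",
    "ig_read_fraction",
    "cd27_high",
    "cd38_high",
    "sort_label",
)

PEPTIDE_TABLE_COLUMNS = ("patient_id", "compartment", "peptide_sequence", "intensity")

_TRUE_TOKENS = {"T", "TRUE", "1", "Y", "YES"}
_FALSE_TOKENS = {"F", "FALSE", "0", "N", "NO"}


@dataclass(frozen=True)
class ChainRecord:
    """One sequenced immunoglobulin chain of one cell.

    ``sequence_nt`` is the full recombined V region extended 24 nt into the
    constant region; ``junction_nt`` (the CDR3 plus flanking codons) is a
    substring of it.  ``sequence_aa`` is the frame-1 translation.
    """

    cell_id: str
    patient_id: str
    locus: str
    v_call: str
    j_call: str
    junction_nt: str
    sequence_nt: str
    sequence_aa: str

    @property
    def is_heavy(self) -> bool:
        return self.locus == "IGH"

    @property
    def junction_end(self) -> int:
        """0-based nt position one past the junction within sequence_nt."""
        return self.sequence_nt.index(self.junction_nt) + len(self.junction_nt)


@dataclass(frozen=True)
class CellMeta:
    """Per-cell metadata used for cell-type annotation."""

    cell_id: str
    patient_id: str
    ig_read_fraction: float
    cd27_high: bool
    cd38_high: bool
    sort_label: str


@dataclass(frozen=True)
class PeptideObservation:
    """One quantified peptide in one compartment of one patient."""

    patient_id: str
    compartment: str
    peptide_sequence: str
    intensity: float


@dataclass
class ReadReport:
    """Counters surfaced in the run report; parsing never drops rows silently."""

    n_rows: int = 0
    n_unproductive: int = 0
    n_invariant_rejected: int = 0
    n_extra_chains_dropped: int = 0
    n_duplicates_summed: int = 0
    messages: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.messages.append(msg)
        logger.warning(msg)


def translate_frame1(nt: str) -> str:
    """Frame-1 translation; trailing partial codon ignored."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def has_internal_stop(aa: str) -> bool:
    return "*" in aa[:-1] if aa else False


def _parse_flag(token: object, column: str) -> bool:
    s = str(token).strip().upper()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise FormatError(f"unrecognized boolean token {token!r} in column {column}")


def _read_tsv(
    path: str | Path, required: tuple[str, ...], allow_empty: bool = False
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    if df.empty and not allow_empty:
        raise FormatError(f"empty file: {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)} in {path}")
    return df


def read_cell_table(
    path: str | Path, report: ReadReport | None = None
) -> tuple[list[ChainRecord], list[CellMeta]]:
    """Parse an AIRR-style cell table into chain records and cell metadata.

    Unproductive chains (internal stop codon in the frame-1 translation) and
    rows whose junction is not a substring of the sequence are rejected with
    a logged count.  A cell contributes at most one heavy and one light
    chain: supernumerary chains per locus class are dropped, preferring the
    highest ``duplicate_count`` when that column exists, else keeping the
    first occurrence.
    """
    report = report if report is not None else ReadReport()
    df = _read_tsv(path, CELL_TABLE_COLUMNS)
    report.n_rows = len(df)

    chains: list[ChainRecord] = []
    meta_by_cell: dict[str, CellMeta] = {}
    has_support = "duplicate_count" in df.columns
    # (cell_id, chain_class) -> (support, row_order, ChainRecord)
    best: dict[tuple[str, str], tuple[float, int, ChainRecord]] = {}

    for order, row in enumerate(df.itertuples(index=False)):
        locus = str(row.locus)
        if locus not in VALID_LOCI:
            report.n_invariant_rejected += 1
            report.note(f"row {order}: invalid locus {locus!r}; rejected")
            continue
        junction = str(row.junction).upper()
        sequence = str(row.sequence).upper()
        if not junction or junction not in sequence:
            report.n_invariant_rejected += 1
            report.note(
                f"row {order} (cell {row.cell_id}): junction not a substring "
                "of sequence; rejected"
            )
            continue
        aa = translate_frame1(sequence)
        if has_internal_stop(aa):
            report.n_unproductive += 1
            report.note(
                f"row {order} (cell {row.cell_id}): internal stop codon "
                "(unproductive); rejected"
            )
            continue
        rec = ChainRecord(
            cell_id=str(row.cell_id),
            patient_id=str(row.patient_id),
            locus=locus,
            v_call=str(row.v_call),
            j_call=str(row.j_call),
            junction_nt=junction,
            sequence_nt=sequence,
            sequence_aa=aa,
        )
        chain_class = "heavy" if locus == "IGH" else "light"
        key = (rec.cell_id, chain_class)
        support = float(getattr(row, "duplicate_count")) if has_support else 0.0
        if key in best:
            report.n_extra_chains_dropped += 1
            prev_support, prev_order, _ = best[key]
            # keep highest support; ties and no-support files keep first seen
            if has_support and support > prev_support:
                report.note(
                    f"cell {rec.cell_id}: replacing {chain_class} chain from row "
                    f"{prev_order} with higher-support row {order}"
                )
                best[key] = (support, order, rec)
            else:
                report.note(
                    f"cell {rec.cell_id}: extra {chain_class} chain in row "
                    f"{order} dropped"
                )
            continue
        best[key] = (support, order, rec)

        if rec.cell_id not in meta_by_cell:
            try:
                frac = float(row.ig_read_fraction)
            except ValueError:
                raise FormatError(
                    f"non-numeric ig_read_fraction {row.ig_read_fraction!r} "
                    f"for cell {rec.cell_id}"
                ) from None
            if not 0.0 <= frac <= 1.0:
                raise FormatError(
                    f"ig_read_fraction {frac} outside [0, 1] for cell {rec.cell_id}"
                )
            meta_by_cell[rec.cell_id] = CellMeta(
                cell_id=rec.cell_id,
                patient_id=rec.patient_id,
                ig_read_fraction=frac,
                cd27_high=_parse_flag(row.cd27_high, "cd27_high"),
                cd38_high=_parse_flag(row.cd38_high, "cd38_high"),
                sort_label=str(row.sort_label),
            )

    chains = [rec for _, _, rec in sorted(best.values(), key=lambda t: t[1])]
    meta = list(meta_by_cell.values())
    if report.n_unproductive or report.n_invariant_rejected:
        logger.info(
            "read_cell_table: %d rows, %d unproductive, %d invariant-rejected, "
            "%d extra chains dropped",
            report.n_rows,
            report.n_unproductive,
            report.n_invariant_rejected,
            report.n_extra_chains_dropped,
        )
    return chains, meta


def dedupe_chain_sequences(
    chains: list[ChainRecord],
) -> list[tuple[str, str, str, list[ChainRecord]]]:
    """Collapse chains of one patient to unique (locus, sequence_aa) groups.

    Returns ``(chain_group_id, locus, sequence_aa, members)`` tuples in a
    deterministic order (locus, then sequence).  Group ids are stable for a
    given chain set: ``<patient>_<locus>_G<i>``.
    """
    patients = {c.patient_id for c in chains}
    if len(patients) != 1:
        raise InputError(f"expected chains from a single patient, got {sorted(patients)}")
    patient = patients.pop()
    groups: dict[tuple[str, str], list[ChainRecord]] = {}
    for c in chains:
        groups.setdefault((c.locus, c.sequence_aa), []).append(c)
    out = []
    for i, ((locus, aa), members) in enumerate(sorted(groups.items())):
        out.append((f"{patient}_{locus}_G{i:04d}", locus, aa, members))
    return out


def write_library_fasta(chains: list[ChainRecord], path: str | Path) -> None:
    """Write one patient's deduplicated amino-acid chain library as FASTA.

    Headers encode patient, chain-group id, locus and V/J calls of the first
    member chain, ``|``-separated.
    """
    if not chains:
        raise InputError("cannot write a library from an empty chain list")
    path = Path(path)
    with path.open("w") as fh:
        for group_id, locus, aa, members in dedupe_chain_sequences(chains):
            first = members[0]
            fh.write(
                f">{first.patient_id}|{group_id}|{locus}|{first.v_call}|{first.j_call}\n"
            )
            for i in range(0, len(aa), 60):
                fh.write(aa[i : i + 60] + "\n")


def read_library_fasta(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """Read a library FASTA back as {chain_group_id: (patient, locus, sequence_aa)}."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) < 3:
            raise FormatError(f"malformed library FASTA header: {rec.description!r}")
        patient, group_id, locus = parts[0], parts[1], parts[2]
        out[group_id] = (patient, locus, str(rec.seq))
    return out


def read_peptide_table(
    path: str | Path, report: ReadReport | None = None
) -> list[PeptideObservation]:
    """Parse a peptide intensity TSV; duplicate observations are summed."""
    report = report if report is not None else ReadReport()
    # a header-only table is a legitimate "nothing detected" input
    df = _read_tsv(path, PEPTIDE_TABLE_COLUMNS, allow_empty=True)
    report.n_rows = len(df)

    summed: dict[tuple[str, str, str], float] = {}
    for order, row in enumerate(df.itertuples(index=False)):
        compartment = str(row.compartment)
        if compartment not in VALID_COMPARTMENTS:
            raise FormatError(
                f"unknown compartment {compartment!r} in row {order} "
                f"(expected CSF or serum)"
            )
        peptide = str(row.peptide_sequence)
        if not peptide or not set(peptide) <= STANDARD_AA:
            raise FormatError(
                f"peptide sequence {peptide!r} in row {order} is not composed "
                "of the 20 standard residues"
            )
        try:
            intensity = float(row.intensity)
        except ValueError:
            raise FormatError(f"non-numeric intensity in row {order}") from None
        if intensity < 0:
            raise FormatError(f"negative intensity {intensity} in row {order}")
        key = (str(row.patient_id), compartment, peptide)
        if key in summed:
            report.n_duplicates_summed += 1
            report.note(
                f"duplicate observation {key} summed ({summed[key]} + {intensity})"
            )
        summed[key] = summed.get(key, 0.0) + intensity

    return [
        PeptideObservation(p, c, pep, inten)
        for (p, c, pep), inten in summed.items()
    ]


def write_cell_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table TSV with the canonical column order."""
    cols = [c for c in CELL_TABLE_COLUMNS if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    rows.to_csv(path, sep="\t", index=False, columns=cols)


def write_peptide_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False, columns=list(PEPTIDE_TABLE_COLUMNS))
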