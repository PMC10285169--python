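"""Per-patient match-fraction statistics over clonally collapsed units.

Clonally related cells are collapsed and treated as a single unit.  For each
patient, the fraction of units matching intrathecally produced IgG is
computed overall, per cell type (a clonotype spanning several cell types
contributes one unit to each type it spans) and by expansion status
(expanded = two or more member cells vs singleton).  Paired per-patient
fractions are compared with a two-tailed Wilcoxon signed-rank test, exact
for small cohorts.

The exact test conditions on the observed multiset of absolute differences:
zero differences are dropped, absolute differences receive average ranks,
and the two-sided p-value doubles the smaller tail probability of the
positive-rank sum W over all 2^n equiprobable sign assignments (capped at
1).  Enumeration is carried out as a dynamic-programming convolution over
doubled ranks (integers even under midpoint ties), which is exactly the
2^n sum.  For n above the exact cutoff a normal approximation with
continuity and tie correction is used.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from . import cell_annotation, clonotyping, ig_proteome, intrathecal_filter, repertoire_io
from .cell_annotation import CELL_TYPES, CellTypeLabel
from .clonotyping import Clonotype, MismatchWeights, UNIFORM_WEIGHTS
from .errors import InputError
from .intrathecal_filter import IntrathecalCall
from .repertoire_io import ReadReport

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25
MIN_UNITS_PER_STRATUM = 2
STRATA_COMPARISONS = (("ASC", "memory"), ("ASC", "naive"), ("expanded", "singleton"))


@dataclass(frozen=True)
class StratumFraction:
    """Matched / total collapsed units in one stratum of one patient."""

    n_matched: int
    n_units: int

    @property
    def fraction(self) -> float | None:
        return self.n_matched / self.n_units if self.n_units else None


@dataclass
class PatientFractions:
    patient_id: str
    by_cell_type: dict[str, StratumFraction]
    expanded: StratumFraction
    singleton: StratumFraction
    overall: StratumFraction

    def stratum(self, name: str) -> StratumFraction:
        if name == "expanded":
            return self.expanded
        if name == "singleton":
            return self.singleton
        if name == "overall":
            return self.overall
        return self.by_cell_type[name]


@dataclass(frozen=True)
class TestResult:
    statistic: float  # signed-rank sum W (positive ranks)
    n_effective: int  # pairs with non-zero difference
    p_two_sided: float
    degenerate: bool = False  # all differences zero
    method: str = "exact"


def wilcoxon_signed_rank_exact(x, y) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired vectors.

    Exact by full enumeration of sign assignments for n <= 25 non-zero
    differences; normal approximation with continuity correction beyond.
    All-zero differences give the degenerate result p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired vectors must be one-dimensional and equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 0, 1.0, degenerate=True, method="degenerate")
    ranks = rankdata(np.abs(d))  # average ranks for ties
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_two_sided_p(ranks, w_pos)
        return TestResult(w_pos, n, p, method="exact")
    p = _normal_two_sided_p(ranks, w_pos, n)
    return TestResult(w_pos, n, p, method="normal_approx")


def _exact_two_sided_p(ranks: np.ndarray, w_pos: float) -> float:
    # doubled ranks are integers even with .5 average ranks
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_pos))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _normal_two_sided_p(ranks: np.ndarray, w_pos: float, n: int) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the rank variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return 1.0
    # continuity correction toward the mean
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def match_fractions(
    calls: list[IntrathecalCall],
    clonotypes: list[Clonotype],
    labels: list[CellTypeLabel],
) -> list[PatientFractions]:
    """Per-patient matched fractions of collapsed units, by stratum.

    A unit is matched iff its clonotype is called intrathecal.  A clonotype
    counts once per cell-type stratum it has members of, once in expanded or
    singleton, and once overall.  Empty strata are undefined (fraction
    ``None``) and excluded from downstream tests.
    """
    called = intrathecal_filter.called_set(calls)
    type_of_cell = {lab.cell_id: lab.cell_type for lab in labels}
    by_patient: dict[str, list[Clonotype]] = {}
    for ct in clonotypes:
        by_patient.setdefault(ct.patient_id, []).append(ct)

    out: list[PatientFractions] = []
    for patient in sorted(by_patient):
        cts = by_patient[patient]
        type_counts = {t: [0, 0] for t in CELL_TYPES}  # [matched, total]
        exp_counts, sing_counts, all_counts = [0, 0], [0, 0], [0, 0]
        for ct in cts:
            hit = ct.clonotype_id in called
            types_present = {
                type_of_cell[c] for c in ct.cell_ids if c in type_of_cell
            }
            for t in types_present:
                type_counts[t][1] += 1
                type_counts[t][0] += hit
            bucket = exp_counts if ct.expanded else sing_counts
            bucket[1] += 1
            bucket[0] += hit
            all_counts[1] += 1
            all_counts[0] += hit
        out.append(
            PatientFractions(
                patient_id=patient,
                by_cell_type={
                    t: StratumFraction(m, n) for t, (m, n) in type_counts.items()
                },
                expanded=StratumFraction(*exp_counts),
                singleton=StratumFraction(*sing_counts),
                overall=StratumFraction(*all_counts),
            )
        )
    return out


@dataclass
class StrataComparison:
    stratum_a: str
    stratum_b: str
    n_pairs: int
    excluded_patients: list[str]
    test: TestResult | None
    median_a: float | None = None
    median_b: float | None = None
    range_a: tuple[float, float] | None = None
    range_b: tuple[float, float] | None = None
    message: str = ""


def compare_strata(
    fractions: list[PatientFractions],
    min_units: int = MIN_UNITS_PER_STRATUM,
) -> list[StrataComparison]:
    """Paired exact tests on per-patient fractions for the three stratum pairs.

    Patients whose stratum is undefined or has fewer than ``min_units``
    collapsed units are excluded pairwise (mirroring the exclusion of a
    single-cell outlier stratum from the statistical analysis).
    """
    out: list[StrataComparison] = []
    for a, b in STRATA_COMPARISONS:
        xs, ys, excluded = [], [], []
        for pf in fractions:
            sa, sb = pf.stratum(a), pf.stratum(b)
            if sa.n_units >= min_units and sb.n_units >= min_units:
                xs.append(sa.fraction)
                ys.append(sb.fraction)
            else:
                excluded.append(pf.patient_id)
        if len(xs) < 2:
            out.append(
                StrataComparison(
                    a, b, len(xs), excluded, None,
                    message=f"skipped: only {len(xs)} usable pair(s)",
                )
            )
            continue
        test = wilcoxon_signed_rank_exact(xs, ys)
        out.append(
            StrataComparison(
                a,
                b,
                len(xs),
                excluded,
                test,
                median_a=float(np.median(xs)),
                median_b=float(np.median(ys)),
                range_a=(float(min(xs)), float(max(xs))),
                range_b=(float(min(ys)), float(max(ys))),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (defaults are the published decision rules)."""

    distance_threshold: float = clonotyping.DEFAULT_DISTANCE_THRESHOLD
    ig_threshold: float = cell_annotation.DEFAULT_IG_THRESHOLD
    delta_min: float = intrathecal_filter.DEFAULT_DELTA_MIN
    ratio_min: float = intrathecal_filter.DEFAULT_RATIO_MIN
    min_unique: int = intrathecal_filter.DEFAULT_MIN_UNIQUE
    missed_cleavages: int = ig_proteome.DEFAULT_MISSED_CLEAVAGES
    min_peptide_len: int = ig_proteome.DEFAULT_MIN_PEPTIDE_LEN
    max_peptide_len: int = ig_proteome.DEFAULT_MAX_PEPTIDE_LEN
    equate_il: bool = False
    weights: MismatchWeights = field(default_factory=MismatchWeights)


@dataclass
class RunResult:
    fractions: list[PatientFractions]
    comparisons: list[StrataComparison]
    calls: list[IntrathecalCall]
    clonotypes: list[Clonotype]
    labels: list[CellTypeLabel]
    report: ReadReport
    summary: dict


def run_pipeline(
    cells_path: str | Path,
    csf_path: str | Path,
    serum_path: str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> RunResult:
    """Execute the full tracing pipeline on external input tables.

    read -> annotate -> clonotype -> library -> digest/match -> iBAQ ->
    intrathecal calls -> match-fraction statistics.  When ``out_dir`` is
    given, all intermediate TSVs, a structured summary and the run report
    are written there deterministically.
    """
    cfg = config or PipelineConfig()
    report = ReadReport()
    chains, meta = repertoire_io.read_cell_table(cells_path, report)
    observations = repertoire_io.read_peptide_table(csf_path, report)
    observations += repertoire_io.read_peptide_table(serum_path, report)

    labels = cell_annotation.annotate_cells(meta, cfg.ig_threshold)

    patients = sorted({c.patient_id for c in chains})
    all_clonotypes: list[Clonotype] = []
    all_calls: list[IntrathecalCall] = []
    quant_rows: list[dict] = []
    n_unassigned = 0
    obs_by_patient: dict[str, list] = {}
    for obs in observations:
        obs_by_patient.setdefault(obs.patient_id, []).append(obs)

    for patient in patients:
        p_chains = [c for c in chains if c.patient_id == patient]
        assignment, clonotypes_p, excluded = clonotyping.clonotype_patient(
            p_chains, cfg.distance_threshold, cfg.weights
        )
        if excluded:
            report.note(
                f"patient {patient}: {len(excluded)} cell(s) without a "
                f"productive heavy chain excluded from clonotyping"
            )
        all_clonotypes.extend(clonotypes_p)
        library = ig_proteome.build_chain_library(p_chains, clonotypes_p)
        p_obs = obs_by_patient.get(patient, [])
        if library and p_obs:
            assignments, unassigned = ig_proteome.match_peptides(
                p_obs,
                library,
                cfg.missed_cleavages,
                cfg.min_peptide_len,
                cfg.max_peptide_len,
                cfg.equate_il,
            )
            n_unassigned += len(unassigned)
        else:
            assignments = []
        quants = ig_proteome.compute_ibaq(
            assignments, library, cfg.min_peptide_len, cfg.max_peptide_len
        )
        by_clonotype: dict[str, list] = {ct.clonotype_id: [] for ct in clonotypes_p}
        for q in quants:
            for ct_id in q.clonotype_ids:
                by_clonotype.setdefault(ct_id, []).append(q)
            quant_rows.append(
                {
                    "patient_id": patient,
                    "chain_group_id": q.chain_group_id,
                    "locus": q.locus,
                    "ibaq_csf": q.ibaq_csf,
                    "ibaq_serum": q.ibaq_serum,
                    "n_unique_peptides_csf": q.n_unique_peptides_csf,
                    "n_theoretical_peptides": q.n_theoretical_peptides,
                }
            )
        all_calls.extend(
            intrathecal_filter.call_intrathecal(
                by_clonotype, cfg.delta_min, cfg.ratio_min, cfg.min_unique
            )
        )

    fractions = match_fractions(all_calls, all_clonotypes, labels)
    comparisons = compare_strata(fractions)

    overall = [pf.overall.fraction for pf in fractions if pf.overall.fraction is not None]
    summary = {
        "n_patients": len(patients),
        "n_cells": len(meta),
        "n_clonotypes": len(all_clonotypes),
        "n_called": len(intrathecal_filter.called_set(all_calls)),
        "n_unassigned_peptides": n_unassigned,
        "overall_matched_fraction_median": float(np.median(overall)) if overall else None,
        "overall_matched_fraction_range": (
            [float(min(overall)), float(max(overall))] if overall else None
        ),
        "comparisons": {
            f"{c.stratum_a}_vs_{c.stratum_b}": {
                "n_pairs": c.n_pairs,
                "excluded_patients": c.excluded_patients,
                "W": c.test.statistic if c.test else None,
                "p_two_sided": c.test.p_two_sided if c.test else None,
                "median_a": c.median_a,
                "median_b": c.median_b,
                "message": c.message,
            }
            for c in comparisons
        },
    }

    result = RunResult(
        fractions, comparisons, all_calls, all_clonotypes, labels, report, summary
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), result, quant_rows)
    return result


def _write_outputs(out_dir: Path, result: RunResult, quant_rows: list[dict]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    type_of_cell = {lab.cell_id: lab.cell_type for lab in result.labels}
    clone_rows = [
        {
            "cell_id": cell,
            "patient_id": ct.patient_id,
            "clone_id": ct.clonotype_id,
            "expanded": ct.expanded,
            "cell_type": type_of_cell.get(cell, "NA"),
        }
        for ct in sorted(result.clonotypes, key=lambda c: c.clonotype_id)
        for cell in ct.cell_ids
    ]
    pd.DataFrame(clone_rows).to_csv(out_dir / "clones.tsv", sep="\t", index=False)
    pd.DataFrame(quant_rows).to_csv(out_dir / "chain_quant.tsv", sep="\t", index=False)
    call_rows = [
        {
            "clonotype_id": c.clonotype_id,
            "called": c.called,
            "rule": c.rule,
            "evidence_ibaq_csf": ";".join(f"{q.ibaq_csf:.6g}" for q in c.evidence),
            "evidence_ibaq_serum": ";".join(f"{q.ibaq_serum:.6g}" for q in c.evidence),
        }
        for c in sorted(result.calls, key=lambda c: c.clonotype_id)
    ]
    pd.DataFrame(call_rows).to_csv(out_dir / "calls.tsv", sep="\t", index=False)
    frac_rows = []
    for pf in result.fractions:
        row = {"patient_id": pf.patient_id}
        for name in (*CELL_TYPES, "expanded", "singleton", "overall"):
            s = pf.stratum(name)
            row[f"{name}_matched"] = s.n_matched
            row[f"{name}_units"] = s.n_units
            row[f"{name}_fraction"] = "" if s.fraction is None else f"{s.fraction:.6g}"
        frac_rows.append(row)
    pd.DataFrame(frac_rows).to_csv(out_dir / "fractions.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )
    report_lines = [
        f"rows_read\t{result.report.n_rows}",
        f"unproductive_dropped\t{result.report.n_unproductive}",
        f"invariant_rejected\t{result.report.n_invariant_rejected}",
        f"extra_chains_dropped\t{result.report.n_extra_chains_dropped}",
        f"duplicate_peptides_summed\t{result.report.n_duplicates_summed}",
        *result.report.messages,
    ]
    (out_dir / "run_report.txt").write_text("\n".join(report_lines) + "\n")
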