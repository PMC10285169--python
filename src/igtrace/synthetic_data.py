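"""Synthetic multi-patient cohorts for exercising the tracing pipeline.

The generator emits the two pipeline inputs — a per-cell BCR chain table
and CSF/serum peptide intensity tables — plus the ground truth needed to
score recovery, with the statistical structure the analysis assumes:

* paired heavy/light single cells organized into clonal lineages, clone
  sizes geometric, lineages diversified by somatic hypermutation with the
  junction mutation load capped so clone members stay recoverable at the
  0.2 junction-distance threshold;
* a planted subset of antibody-secreting-cell clonotypes whose IgG appears
  in CSF (optionally with secretion probability proportional to clone
  size, emulating preferential secretion by expanded clones);
* serum-dominant background IgG from decoy chains built on germline
  segments never used by any sequenced cell;
* lognormal peptide intensities with compartment-specific abundance and an
  optional detection noise floor.

Germline segments are synthesized rather than downloaded: V segments are
in-frame, stop-free, and carry all tryptic cleavage sites, while junctions,
J segments and the constant-region extension are K/R-free.  Every
observable tryptic peptide therefore overlaps the V segment, and because
each clone in a patient draws a distinct heavy V segment, heavy-chain
peptides identify their clonotype unambiguously — which is what makes the
planted ground truth exactly recoverable.  Light V segments are shared
across clones, preserving realistic light-chain homology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ig_proteome
from .errors import ConfigurationError, InputError
from .repertoire_io import translate_frame1, write_cell_table, write_peptide_table

HEAVY_LOCUS = "IGH"
LIGHT_LOCI = ("IGK", "IGL")
DECOY_V_RESERVE = 8  # V segments per locus reserved for decoy chains
LIGHT_V_POOL = 12  # cell-derived light chains draw from this many V segments

# codons for the 17 amino acids excluding K, R, P (and stops)
_SAFE_AA = "ACDEFGHILMNQSTVWY"
_CODON_TABLE = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "Q": ["CAA", "CAG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_SAFE_CODONS = [c for aa in _SAFE_AA for c in _CODON_TABLE[aa]]
_KR_CODONS = ["AAA", "AAG", "CGT", "CGC", "CGA", "CGG", "AGA", "AGG"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate a ten-patient CSF B-lineage cohort dominated by
    antibody-secreting cells, with a handful of clonotypes per patient
    secreting IgG into the CSF.
    """

    n_patients: int = 10
    cells_per_patient: int = 90
    cell_type_proportions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    clone_size_distribution: float = 0.5  # geometric success parameter in (0, 1)
    shm_rate: float = 0.02  # per-site substitution probability, [0, 0.2]
    n_secretor_clonotypes: int = 6
    secretion_coupling: bool = True
    csf_intensity_mu: float = 13.0  # log-intensity location of secreted peptides
    csf_intensity_sigma: float = 0.5
    serum_background_chains: int = 20
    noise_floor: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "cells_per_patient": self.cells_per_patient,
            "n_secretor_clonotypes": self.n_secretor_clonotypes,
            "serum_background_chains": self.serum_background_chains,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if abs(sum(self.cell_type_proportions) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"cell_type_proportions must sum to 1, got "
                f"{self.cell_type_proportions}"
            )
        if any(p < 0 for p in self.cell_type_proportions):
            raise ConfigurationError("cell_type_proportions must be non-negative")
        if not 0.0 < self.clone_size_distribution < 1.0:
            raise ConfigurationError(
                "clone_size_distribution (geometric parameter) must be in (0, 1)"
            )
        if not 0.0 <= self.shm_rate <= 0.2:
            raise ConfigurationError("shm_rate must be within [0, 0.2]")
        if self.noise_floor < 0:
            raise ConfigurationError("noise_floor must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cell_type_proportions"] = list(self.cell_type_proportions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cell_type_proportions" in d:
            d["cell_type_proportions"] = tuple(d["cell_type_proportions"])
        return cls(**d)


@dataclass(frozen=True)
class Segment:
    name: str
    seq: str


@dataclass(frozen=True)
class LocusGermlines:
    v: tuple[Segment, ...]
    j: tuple[Segment, ...]
    constant_extension: str  # 24 nt shared by every chain of the locus


@dataclass(frozen=True)
class GermlineSet:
    by_locus: dict[str, LocusGermlines]


@dataclass
class GroundTruth:
    """What the generator planted, for scoring pipeline recovery."""

    secretor_clones: dict[str, list[str]]  # patient -> true clone ids
    decoy_chains: dict[str, list[str]]  # patient -> decoy chain ids
    cell_type: dict[str, str]  # cell id -> ASC | memory | naive
    clone_of_cell: dict[str, str]  # cell id -> true clone id
    n_clones: dict[str, int] = field(default_factory=dict)  # patient -> clone count

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n)
    )


def _make_v_segment(rng: np.random.Generator) -> str:
    """An in-frame V segment, 270-300 nt, K/R cut sites every 9-13 codons."""
    n_codons = int(rng.integers(90, 101))
    cut_positions = set()
    pos = int(rng.integers(8, 14))
    while pos < n_codons - 3:
        cut_positions.add(pos)
        pos += int(rng.integers(9, 14))
    codons = []
    for i in range(n_codons):
        if i in cut_positions:
            codons.append(_KR_CODONS[int(rng.integers(0, len(_KR_CODONS)))])
        else:
            codons.append(_SAFE_CODONS[int(rng.integers(0, len(_SAFE_CODONS)))])
    return "".join(codons)


def make_germline_set(seed: int, n_v: int = 24, n_j: int = 6) -> GermlineSet:
    """Synthesize named germline V/J segments for the heavy and light loci.

    V segments are in-frame and stop-free with internal tryptic sites; J
    segments (45-60 nt) and the per-locus constant extension (24 nt) are
    K/R-free.  Names follow the IMGT-style ``IGHV<family>-<number>*01``
    convention so allele stripping is exercised downstream.
    """
    if n_v < 2 or n_j < 2:
        raise ConfigurationError(f"need n_v >= 2 and n_j >= 2, got {n_v}, {n_j}")
    rng = np.random.default_rng(seed)
    by_locus = {}
    for locus in (HEAVY_LOCUS, *LIGHT_LOCI):
        short = locus[2]  # H, K, L
        vs = tuple(
            Segment(f"IG{short}V{(i % 7) + 1}-{i // 7 + 1}*01", _make_v_segment(rng))
            for i in range(n_v)
        )
        js = tuple(
            Segment(
                f"IG{short}J{i + 1}*01",
                _random_codons(rng, int(rng.integers(15, 21))),
            )
            for i in range(n_j)
        )
        by_locus[locus] = LocusGermlines(
            v=vs, j=js, constant_extension=_random_codons(rng, 8)
        )
    return GermlineSet(by_locus=by_locus)


def load_germline_fasta(path: str | Path) -> GermlineSet:
    """Load a user-supplied germline FASTA (IMGT-style names, e.g. IGHV1-2*02).

    Records are routed to loci and V/J roles from their names.  A K/R-free
    24-nt constant extension placeholder is synthesized per locus; supply
    real constant sequences via the cohort generator if needed.
    """
    from Bio import SeqIO

    buckets: dict[str, dict[str, list[Segment]]] = {
        loc: {"V": [], "J": []} for loc in (HEAVY_LOCUS, *LIGHT_LOCI)
    }
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        locus = name[:3]
        if locus not in buckets or len(name) < 4 or name[3] not in "VJ":
            raise ConfigurationError(f"cannot route germline record {name!r}")
        buckets[locus][name[3]].append(Segment(name, str(rec.seq).upper()))
    rng = np.random.default_rng(0)
    by_locus = {}
    for locus, b in buckets.items():
        if not b["V"] or not b["J"]:
            raise ConfigurationError(f"locus {locus}: need at least one V and one J")
        by_locus[locus] = LocusGermlines(
            v=tuple(b["V"]), j=tuple(b["J"]), constant_extension=_random_codons(rng, 8)
        )
    return GermlineSet(by_locus=by_locus)


@dataclass(frozen=True)
class ChainDraft:
    """A simulated chain before cell ids are attached."""

    locus: str
    v_call: str
    j_call: str
    junction_nt: str
    sequence_nt: str
    v_len: int
    junction_len: int


def _founder_chain(
    germlines: GermlineSet,
    locus: str,
    v_idx: int,
    j_idx: int,
    junction_codons: int,
    rng: np.random.Generator,
) -> ChainDraft:
    g = germlines.by_locus[locus]
    v, j = g.v[v_idx], g.j[j_idx]
    terminal = "TGG" if locus == HEAVY_LOCUS else "TTC"  # Trp / Phe anchor
    junction = "TGC" + _random_codons(rng, junction_codons) + terminal
    seq = v.seq + junction + j.seq + g.constant_extension
    return ChainDraft(
        locus=locus,
        v_call=v.name,
        j_call=j.name,
        junction_nt=junction,
        sequence_nt=seq,
        v_len=len(v.seq),
        junction_len=len(junction),
    )


_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


def _mutate_chain(
    founder: ChainDraft, shm_rate: float, rng: np.random.Generator
) -> ChainDraft:
    """Per-site substitutions at ``shm_rate``, junction load capped below 0.1.

    The cap guarantees every member's normalized junction distance to the
    lineage founder stays strictly below 0.1, hence pairwise below the 0.2
    clustering threshold.  Draws producing an internal stop codon are
    redrawn (bounded), falling back to the founder.
    """
    if shm_rate == 0.0:
        return founder
    seq = founder.sequence_nt
    j_start, j_len = founder.v_len, founder.junction_len
    max_junction_mut = max(0, math.ceil(0.1 * j_len) - 1)
    for _ in range(200):
        positions = np.flatnonzero(rng.random(len(seq)) < shm_rate)
        in_junction = positions[(positions >= j_start) & (positions < j_start + j_len)]
        if in_junction.size > max_junction_mut:
            keep = set(
                rng.choice(in_junction, size=max_junction_mut, replace=False).tolist()
            )
            positions = np.array(
                [
                    p
                    for p in positions.tolist()
                    if p < j_start or p >= j_start + j_len or p in keep
                ],
                dtype=int,
            )
        chars = list(seq)
        for p in positions.tolist():
            chars[p] = _OTHER[chars[p]][int(rng.integers(0, 3))]
        mutated = "".join(chars)
        aa = translate_frame1(mutated)
        if "*" not in aa[:-1]:
            junction = mutated[j_start : j_start + j_len]
            return ChainDraft(
                locus=founder.locus,
                v_call=founder.v_call,
                j_call=founder.j_call,
                junction_nt=junction,
                sequence_nt=mutated,
                v_len=founder.v_len,
                junction_len=founder.junction_len,
            )
    return founder


def simulate_lineage(
    germlines: GermlineSet,
    n_cells: int,
    shm_rate: float,
    rng: np.random.Generator,
    *,
    heavy_v_idx: int | None = None,
    heavy_j_idx: int | None = None,
    light_locus: str | None = None,
    light_v_idx: int | None = None,
    light_j_idx: int | None = None,
) -> list[dict[str, ChainDraft]]:
    """One clonal lineage of paired heavy/light cells.

    All cells share one heavy V/J pick, one light V/J pick and one fixed
    junction length per locus; substitutions are applied independently per
    site, with the junction mutation load capped (see ``_mutate_chain``).
    Segment indices may be pinned by the caller; unset picks are drawn.
    """
    if n_cells < 1:
        raise InputError(f"n_cells must be >= 1, got {n_cells}")
    gh = germlines.by_locus[HEAVY_LOCUS]
    if heavy_v_idx is None:
        heavy_v_idx = int(rng.integers(0, len(gh.v)))
    if heavy_j_idx is None:
        heavy_j_idx = int(rng.integers(0, len(gh.j)))
    if light_locus is None:
        light_locus = LIGHT_LOCI[int(rng.integers(0, 2))]
    gl = germlines.by_locus[light_locus]
    if light_v_idx is None:
        light_v_idx = int(rng.integers(0, len(gl.v)))
    if light_j_idx is None:
        light_j_idx = int(rng.integers(0, len(gl.j)))

    heavy_founder = _founder_chain(
        germlines, HEAVY_LOCUS, heavy_v_idx, heavy_j_idx, int(rng.integers(8, 14)), rng
    )
    light_founder = _founder_chain(
        germlines, light_locus, light_v_idx, light_j_idx, int(rng.integers(7, 12)), rng
    )
    return [
        {
            "heavy": _mutate_chain(heavy_founder, shm_rate, rng),
            "light": _mutate_chain(light_founder, shm_rate, rng),
        }
        for _ in range(n_cells)
    ]


@dataclass(frozen=True)
class SecretionLevel:
    """Per-chain compartment abundance for the peptide intensity model.

    ``csf`` and ``serum`` scale the lognormal log-location multiplicatively
    (level 0 = absent from the compartment).  When ``csf_serum_ratio`` is
    set, the serum intensity is drawn and the CSF intensity is that value
    times the ratio — used for serum-dominant decoy chains whose CSF/serum
    ratio must sit in a prescribed band.
    """

    csf: float = 0.0
    serum: float = 0.0
    csf_serum_ratio: float | None = None


def simulate_peptides(
    chains: list[str],
    secretion: list[SecretionLevel],
    config: SimConfig,
    rng: np.random.Generator,
    patient_id: str = "P1",
) -> pd.DataFrame:
    """Peptide intensity table for one patient's secreted / background chains.

    Each chain's fully tryptic peptides (0 missed cleavages, observable
    length window) receive lognormal intensities per compartment; identical
    peptide sequences within a compartment are summed; draws below the
    noise floor are dropped.
    """
    if not chains:
        raise InputError("simulate_peptides requires at least one chain")
    if len(secretion) != len(chains):
        raise InputError("secretion levels must align with chains")
    mu, sigma = config.csf_intensity_mu, config.csf_intensity_sigma
    rows: dict[tuple[str, str], float] = {}

    def emit(compartment: str, peptide: str, intensity: float) -> None:
        if intensity < config.noise_floor:
            return
        key = (compartment, peptide)
        rows[key] = rows.get(key, 0.0) + intensity

    for aa, level in zip(chains, secretion):
        if not aa:
            raise InputError("empty chain sequence")
        peptides = sorted(set(ig_proteome.digest(aa, missed_cleavages=0)))
        for pep in peptides:
            if level.csf_serum_ratio is not None:
                if level.serum > 0:
                    serum_i = float(np.exp(rng.normal(mu * level.serum, sigma)))
                    emit("serum", pep, serum_i)
                    emit("CSF", pep, serum_i * level.csf_serum_ratio)
                continue
            if level.csf > 0:
                emit("CSF", pep, float(np.exp(rng.normal(mu * level.csf, sigma))))
            if level.serum > 0:
                emit("serum", pep, float(np.exp(rng.normal(mu * level.serum, sigma))))

    records = [
        {
            "patient_id": patient_id,
            "compartment": comp,
            "peptide_sequence": pep,
            "intensity": intensity,
        }
        for (comp, pep), intensity in sorted(rows.items())
    ]
    return pd.DataFrame(
        records, columns=["patient_id", "compartment", "peptide_sequence", "intensity"]
    )


@dataclass
class Cohort:
    cells: pd.DataFrame
    peptides_csf: pd.DataFrame
    peptides_serum: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


def _allocate_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n cells to the type proportions."""
    raw = [p * n for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _clone_sizes(rng: np.random.Generator, n_cells: int, p: float) -> list[int]:
    sizes = []
    remaining = n_cells
    while remaining > 0:
        s = min(int(rng.geometric(p)), remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort: cell table, peptide tables and ground truth.

    Under noise-free settings (``shm_rate=0``, ``noise_floor=0``) every
    planted secretor clonotype passes the intrathecal filter and no decoy
    does: secretor chains appear in CSF only, while decoys are serum-
    dominant with a per-chain CSF/serum ratio drawn uniformly in
    [0.5, 1.1] — below the 1.2 ratio threshold.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = ("ASC", "memory", "naive")

    # plan clones first so the germline pool can be sized to give every
    # clone a distinct heavy V segment
    plans = []  # per patient: list of (cell_type, clone_size)
    for _ in range(config.n_patients):
        budgets = _allocate_counts(config.cells_per_patient, config.cell_type_proportions)
        clones = []
        for cell_type, budget in zip(types, budgets):
            for size in _clone_sizes(rng, budget, config.clone_size_distribution):
                clones.append((cell_type, size))
        n_asc_clones = sum(1 for t, _ in clones if t == "ASC")
        if config.n_secretor_clonotypes > n_asc_clones:
            raise ConfigurationError(
                f"n_secretor_clonotypes={config.n_secretor_clonotypes} exceeds "
                f"the {n_asc_clones} ASC clonotypes available for a patient; "
                "increase cells_per_patient or the ASC proportion"
            )
        plans.append(clones)

    max_clones = max((len(p) for p in plans), default=0)
    n_v = max(max_clones + DECOY_V_RESERVE, 10)
    germlines = make_germline_set(int(rng.integers(2**31)), n_v=n_v, n_j=6)
    n_cell_v = n_v - DECOY_V_RESERVE

    cell_rows: list[dict] = []
    csf_frames: list[pd.DataFrame] = []
    serum_frames: list[pd.DataFrame] = []
    truth = GroundTruth(
        secretor_clones={}, decoy_chains={}, cell_type={}, clone_of_cell={}
    )

    for pi, clones in enumerate(plans):
        patient = f"P{pi + 1}"
        heavy_v_order = rng.permutation(n_cell_v)[: len(clones)]
        cell_counter = 0
        clone_records: list[tuple[str, str, int, list[str]]] = []
        secreted_chains: list[str] = []
        secreted_levels: list[SecretionLevel] = []
        clone_first_cells: dict[str, tuple[str, str]] = {}  # clone -> (heavy aa, light aa)

        for ci, (cell_type, size) in enumerate(clones):
            clone_id = f"{patient}_t{ci:04d}"
            cells = simulate_lineage(
                germlines,
                size,
                config.shm_rate,
                rng,
                heavy_v_idx=int(heavy_v_order[ci]),
                heavy_j_idx=int(rng.integers(0, 6)),
                light_locus=LIGHT_LOCI[int(rng.integers(0, 2))],
                light_v_idx=int(rng.integers(0, min(LIGHT_V_POOL, n_cell_v))),
                light_j_idx=int(rng.integers(0, 6)),
            )
            member_ids = []
            for drafts in cells:
                cell_id = f"{patient}_C{cell_counter:04d}"
                cell_counter += 1
                member_ids.append(cell_id)
                truth.cell_type[cell_id] = cell_type
                truth.clone_of_cell[cell_id] = clone_id
                if cell_type == "ASC":
                    frac = float(rng.uniform(0.10, 0.95))
                    while frac <= 0.10:
                        frac = float(rng.uniform(0.10, 0.95))
                    cd27, cd38 = True, True
                else:
                    frac = float(rng.uniform(0.0, 0.10))
                    cd27, cd38 = (cell_type == "memory"), False
                for chain in (drafts["heavy"], drafts["light"]):
                    cell_rows.append(
                        {
                            "cell_id": cell_id,
                            "patient_id": patient,
                            "locus": chain.locus,
                            "v_call": chain.v_call,
                            "j_call": chain.j_call,
                            "junction": chain.junction_nt,
                            "sequence": chain.sequence_nt,
                            "ig_read_fraction": round(frac, 6),
                            "cd27_high": "T" if cd27 else "F",
                            "cd38_high": "T" if cd38 else "F",
                            "sort_label": cell_type,
                        }
                    )
                if clone_id not in clone_first_cells:
                    clone_first_cells[clone_id] = (
                        translate_frame1(drafts["heavy"].sequence_nt),
                        translate_frame1(drafts["light"].sequence_nt),
                    )
            clone_records.append((clone_id, cell_type, size, member_ids))

        truth.n_clones[patient] = len(clone_records)

        asc_clone_ids = [cid for cid, t, _, _ in clone_records if t == "ASC"]
        sizes = {cid: s for cid, _, s, _ in clone_records}
        if config.n_secretor_clonotypes > 0:
            if config.secretion_coupling:
                weights = np.array([sizes[c] for c in asc_clone_ids], dtype=float)
                weights /= weights.sum()
                secretors = rng.choice(
                    asc_clone_ids,
                    size=config.n_secretor_clonotypes,
                    replace=False,
                    p=weights,
                )
            else:
                secretors = rng.choice(
                    asc_clone_ids, size=config.n_secretor_clonotypes, replace=False
                )
            secretors = sorted(str(s) for s in secretors)
        else:
            secretors = []
        truth.secretor_clones[patient] = list(secretors)

        for cid in secretors:
            heavy_aa, light_aa = clone_first_cells[cid]
            secreted_chains.extend([heavy_aa, light_aa])
            secreted_levels.extend(
                [SecretionLevel(csf=1.0), SecretionLevel(csf=1.0)]
            )

        decoy_ids = []
        for di in range(config.serum_background_chains):
            locus = (HEAVY_LOCUS, *LIGHT_LOCI)[di % 3]
            v_idx = n_cell_v + int(rng.integers(0, DECOY_V_RESERVE))
            decoy = _founder_chain(
                germlines, locus, v_idx, int(rng.integers(0, 6)),
                int(rng.integers(8, 14)), rng,
            )
            decoy_ids.append(f"{patient}_decoy{di:03d}")
            secreted_chains.append(translate_frame1(decoy.sequence_nt))
            secreted_levels.append(
                SecretionLevel(
                    serum=1.0, csf_serum_ratio=float(rng.uniform(0.5, 1.1))
                )
            )
        truth.decoy_chains[patient] = decoy_ids

        if secreted_chains:
            table = simulate_peptides(
                secreted_chains, secreted_levels, config, rng, patient_id=patient
            )
            csf_frames.append(table[table.compartment == "CSF"])
            serum_frames.append(table[table.compartment == "serum"])

    columns = [
        "patient_id", "compartment", "peptide_sequence", "intensity",
    ]
    empty = pd.DataFrame(columns=columns)
    return Cohort(
        cells=pd.DataFrame(cell_rows),
        peptides_csf=(
            pd.concat(csf_frames, ignore_index=True) if csf_frames else empty.copy()
        ),
        peptides_serum=(
            pd.concat(serum_frames, ignore_index=True) if serum_frames else empty.copy()
        ),
        truth=truth,
        config=config,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort's external files; byte-identical for identical configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / "cells.tsv",
        "peptides_csf": out / "peptides_csf.tsv",
        "peptides_serum": out / "peptides_serum.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.yaml",
    }
    write_cell_table(cohort.cells, paths["cells"])
    write_peptide_table(cohort.peptides_csf, paths["peptides_csf"])
    write_peptide_table(cohort.peptides_serum, paths["peptides_serum"])
    cohort.truth.save(paths["ground_truth"])
    cohort.config.to_yaml(paths["config"])
    return paths


def evaluate_calls(truth: GroundTruth, clonotypes, calls) -> dict:
    """Score pipeline calls against the planted ground truth.

    Each pipeline clonotype is mapped to the true clone(s) of its member
    cells.  A called clonotype is a true positive when all its members
    belong to one planted secretor clone; any other called clonotype is a
    false call.  Sensitivity counts secretor clones hit by at least one
    called clonotype.
    """
    secretors = {c for ids in truth.secretor_clones.values() for c in ids}
    called = {c.clonotype_id for c in calls if c.called}
    hit_secretors: set[str] = set()
    n_false = 0
    for ct in clonotypes:
        if ct.clonotype_id not in called:
            continue
        true_ids = {truth.clone_of_cell.get(cell) for cell in ct.cell_ids}
        if len(true_ids) == 1 and next(iter(true_ids)) in secretors:
            hit_secretors.add(next(iter(true_ids)))
        else:
            n_false += 1
    sensitivity = len(hit_secretors) / len(secretors) if secretors else 1.0
    return {
        "n_secretors": len(secretors),
        "n_called": len(called),
        "n_recovered": len(hit_secretors),
        "n_false_calls": n_false,
        "sensitivity": sensitivity,
        "exact_recovery": n_false == 0 and len(hit_secretors) == len(secretors),
    }
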