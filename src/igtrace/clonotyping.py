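"""Clonal grouping of B-cell receptor chains.

Cells are grouped into clones from their heavy chains in three steps that
mirror hierarchical-by-threshold ("bygroup") clonal clustering:

1. partition by allele-stripped V/J gene sets and junction length
   (comma-separated ambiguous calls are treated as sets; two chains share a
   partition when their V sets intersect, their J sets intersect and their
   junctions are equally long, resolved transitively),
2. single-linkage clustering within each partition at a normalized junction
   nucleotide distance strictly below 0.2,
3. refinement by light-chain compatibility, which may split a heavy-chain
   clone but never merges clones.

The distance is a length-normalized mismatch count; mismatch weights are
uniform by default or, optionally, drawn from a user-supplied 5-mer context
weight table emulating sequence-context-biased somatic hypermutation
targeting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError
from .repertoire_io import LIGHT_LOCI, ChainRecord

DEFAULT_DISTANCE_THRESHOLD = 0.2


def strip_allele(call: str) -> frozenset[str]:
    """``"IGHV1-2*02,IGHV1-3*01"`` -> frozenset({"IGHV1-2", "IGHV1-3"})."""
    genes = []
    for token in call.split(","):
        token = token.strip()
        if token:
            genes.append(token.split("*")[0])
    return frozenset(genes)


@dataclass(frozen=True)
class MismatchWeights:
    """Per-position mismatch weights for the junction distance.

    ``uniform`` mode scores every mismatch 1 (normalized Hamming).
    ``targeting`` mode looks up the 5-mer centred on the mismatching
    position in each sequence and averages the two context weights
    (symmetrizing the lookup); absent 5-mers score 1.  Weight tables are
    expected mean-normalized to 1 and strictly positive.
    """

    mode: str = "uniform"
    table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "targeting"):
            raise InputError(f"unknown mismatch weight mode {self.mode!r}")
        if self.mode == "targeting":
            if any(w <= 0 for w in self.table.values()):
                raise InputError("targeting weights must be strictly positive")

    def _context_weight(self, seq: str, i: int) -> float:
        fivemer = ("NN" + seq + "NN")[i : i + 5]
        return self.table.get(fivemer, 1.0)

    def weight(self, a: str, b: str, i: int) -> float:
        if self.mode == "uniform":
            return 1.0
        return 0.5 * (self._context_weight(a, i) + self._context_weight(b, i))

    @classmethod
    def from_table_file(cls, path: str | Path) -> "MismatchWeights":
        """Load a two-column (fivemer, weight) TSV and mean-normalize to 1."""
        table: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("fivemer"):
                continue
            fivemer, value = line.split("\t")[:2]
            table[fivemer.upper()] = float(value)
        if not table:
            raise InputError(f"empty 5-mer weight table: {path}")
        mean = sum(table.values()) / len(table)
        return cls(mode="targeting", table={k: v / mean for k, v in table.items()})


UNIFORM_WEIGHTS = MismatchWeights()


def junction_distance(a: str, b: str, weights: MismatchWeights = UNIFORM_WEIGHTS) -> float:
    """Normalized junction nucleotide distance in [0, 1] (0 iff identical)."""
    if len(a) != len(b) or not a:
        raise InputError(
            f"junctions must be non-empty and equal length, got {len(a)} vs {len(b)}"
        )
    total = 0.0
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            total += weights.weight(a, b, i)
    return total / len(a)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def groups(self) -> list[list[int]]:
        by_root: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            by_root.setdefault(self.find(i), []).append(i)
        return [by_root[r] for r in sorted(by_root)]


def partition_by_vj_len(chains: list[ChainRecord]) -> list[list[ChainRecord]]:
    """Partition one patient's heavy chains by shared V/J genes and junction length.

    Two chains land in one partition when their allele-stripped V gene sets
    intersect, their J gene sets intersect and their junction lengths are
    equal; the relation is closed transitively.  Partitions are returned in
    a deterministic order (sorted by member cell ids).
    """
    if not chains:
        return []
    patients = {c.patient_id for c in chains}
    if len(patients) != 1:
        raise InputError("partition_by_vj_len expects chains of a single patient")
    non_heavy = [c for c in chains if not c.is_heavy]
    if non_heavy:
        raise InputError("partition_by_vj_len expects heavy (IGH) chains only")
    uf = _connect_by_vj_len(chains)
    parts = [[chains[i] for i in grp] for grp in uf.groups()]
    return sorted(parts, key=lambda grp: min(c.cell_id for c in grp))


def _connect_by_vj_len(chains: list[ChainRecord]) -> _UnionFind:
    """Union-find over chains sharing any (V gene, J gene, junction length) triple.

    V sets intersect and J sets intersect iff the cross products of the two
    chains' gene sets share a (v, j) pair, so indexing on those pairs gives
    the transitive closure without pairwise comparison.
    """
    uf = _UnionFind(len(chains))
    index: dict[tuple[str, str, int], int] = {}
    for i, c in enumerate(chains):
        vs, js = strip_allele(c.v_call), strip_allele(c.j_call)
        for v in vs:
            for j in js:
                key = (v, j, len(c.junction_nt))
                if key in index:
                    uf.union(i, index[key])
                else:
                    index[key] = i
    return uf


def cluster_clones(
    group: list[ChainRecord],
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    weights: MismatchWeights = UNIFORM_WEIGHTS,
) -> list[list[ChainRecord]]:
    """Single-linkage clusters within one V/J/length partition.

    Two chains belong to one clone iff they are connected by a path of
    pairwise junction distances strictly below ``threshold``.  Output order
    is independent of input order (clusters and members sorted by cell id).
    """
    order = sorted(range(len(group)), key=lambda i: group[i].cell_id)
    chains = [group[i] for i in order]
    uf = _UnionFind(len(chains))
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            if uf.find(i) == uf.find(j):
                continue
            if junction_distance(chains[i].junction_nt, chains[j].junction_nt, weights) < threshold:
                uf.union(i, j)
    clusters = [[chains[i] for i in grp] for grp in uf.groups()]
    return sorted(clusters, key=lambda grp: grp[0].cell_id)


@dataclass
class CloneAssignment:
    """Patient-scoped cell -> clone_id map with per-clone member lists."""

    patient_id: str
    cell_to_clone: dict[str, str]
    members: dict[str, list[str]]

    def clone_of(self, cell_id: str) -> str | None:
        return self.cell_to_clone.get(cell_id)


@dataclass(frozen=True)
class Clonotype:
    """A collapsed clonal unit: the cells of one clone treated as a single unit."""

    clonotype_id: str
    patient_id: str
    cell_ids: tuple[str, ...]

    @property
    def expanded(self) -> bool:
        return len(self.cell_ids) >= 2

    @property
    def singleton(self) -> bool:
        return len(self.cell_ids) == 1


def assign_heavy_clones(
    heavy_chains: list[ChainRecord],
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    weights: MismatchWeights = UNIFORM_WEIGHTS,
) -> CloneAssignment:
    """Partition + cluster one patient's heavy chains into clones."""
    if not heavy_chains:
        raise InputError("no heavy chains to clonotype")
    patient = heavy_chains[0].patient_id
    cell_to_clone: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    counter = 0
    for part in partition_by_vj_len(heavy_chains):
        for cluster in cluster_clones(part, threshold, weights):
            clone_id = f"{patient}_c{counter:04d}"
            counter += 1
            members[clone_id] = sorted(c.cell_id for c in cluster)
            for c in cluster:
                cell_to_clone[c.cell_id] = clone_id
    return CloneAssignment(patient_id=patient, cell_to_clone=cell_to_clone, members=members)


def _light_compatible_clusters(
    lights: list[ChainRecord],
    threshold: float,
    weights: MismatchWeights,
) -> list[list[ChainRecord]]:
    """Single-linkage clusters of light chains under the compatibility relation.

    Compatible = same locus, intersecting allele-stripped V and J gene sets,
    equal junction length, junction distance strictly below the threshold.
    """
    order = sorted(range(len(lights)), key=lambda i: lights[i].cell_id)
    chains = [lights[i] for i in order]
    uf = _UnionFind(len(chains))
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            a, b = chains[i], chains[j]
            if a.locus != b.locus:
                continue
            if len(a.junction_nt) != len(b.junction_nt):
                continue
            if not (strip_allele(a.v_call) & strip_allele(b.v_call)):
                continue
            if not (strip_allele(a.j_call) & strip_allele(b.j_call)):
                continue
            if junction_distance(a.junction_nt, b.junction_nt, weights) < threshold:
                uf.union(i, j)
    clusters = [[chains[i] for i in grp] for grp in uf.groups()]
    return sorted(clusters, key=lambda grp: grp[0].cell_id)


def refine_by_light_chain(
    assignment: CloneAssignment,
    light_chains: list[ChainRecord],
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    weights: MismatchWeights = UNIFORM_WEIGHTS,
) -> CloneAssignment:
    """Split heavy-chain clones whose members carry incompatible light chains.

    Within each heavy-chain clone, cells are re-clustered by light-chain
    compatibility (single linkage).  Cells without a light chain stay with
    the largest compatible sub-clone (ties broken toward the lowest
    clone_id).  Refinement only ever splits clones, never merges them.
    """
    light_by_cell = {c.cell_id: c for c in light_chains}
    cell_to_clone: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for clone_id in sorted(assignment.members):
        cells = assignment.members[clone_id]
        with_light = [light_by_cell[c] for c in cells if c in light_by_cell]
        without_light = [c for c in cells if c not in light_by_cell]
        if not with_light:
            sub_groups: list[list[str]] = [list(cells)]
        else:
            clusters = _light_compatible_clusters(with_light, threshold, weights)
            sub_groups = [sorted(c.cell_id for c in grp) for grp in clusters]
            if without_light:
                # ties -> first (lowest-index, hence lowest clone_id) largest group
                target = max(range(len(sub_groups)), key=lambda i: (len(sub_groups[i]), -i))
                sub_groups[target] = sorted(sub_groups[target] + without_light)
        if len(sub_groups) == 1:
            new_ids = [clone_id]
        else:
            new_ids = [f"{clone_id}.{k}" for k in range(len(sub_groups))]
        for new_id, grp in zip(new_ids, sub_groups):
            members[new_id] = grp
            for cell in grp:
                cell_to_clone[cell] = new_id
    return CloneAssignment(
        patient_id=assignment.patient_id, cell_to_clone=cell_to_clone, members=members
    )


def collapse_clonotypes(assignment: CloneAssignment) -> list[Clonotype]:
    """One clonotype per clone; expanded iff two or more member cells."""
    return [
        Clonotype(
            clonotype_id=clone_id,
            patient_id=assignment.patient_id,
            cell_ids=tuple(assignment.members[clone_id]),
        )
        for clone_id in sorted(assignment.members)
    ]


def clonotype_patient(
    chains: list[ChainRecord],
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    weights: MismatchWeights = UNIFORM_WEIGHTS,
) -> tuple[CloneAssignment, list[Clonotype], list[str]]:
    """Full clonotyping of one patient's chains.

    Returns the refined assignment, the collapsed clonotypes, and the cell
    ids excluded for lacking a productive heavy chain.
    """
    heavy = [c for c in chains if c.is_heavy]
    light = [c for c in chains if c.locus in LIGHT_LOCI]
    cells_with_heavy = {c.cell_id for c in heavy}
    excluded = sorted({c.cell_id for c in light} - cells_with_heavy)
    if not heavy:
        patient = chains[0].patient_id if chains else ""
        return CloneAssignment(patient, {}, {}), [], excluded
    assignment = assign_heavy_clones(heavy, threshold, weights)
    assignment = refine_by_light_chain(
        assignment, [c for c in light if c.cell_id in cells_with_heavy], threshold, weights
    )
    return assignment, collapse_clonotypes(assignment), excluded
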