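"""Cell-type annotation: antibody-secreting vs memory vs naive B cells.

An antibody-secreting cell (ASC: plasmablast/plasma cell) is defined by high
surface expression of both CD27 and CD38 together with an immunoglobulin
read fraction strictly above 10% of the total transcriptome.  Cells failing
the ASC rule fall back to their flow-cytometry index-sort gate label, which
distinguishes memory from naive B cells; that distinction is not
re-derivable from the transcript table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import AnnotationError
from .repertoire_io import CellMeta

logger = logging.getLogger(__name__)

DEFAULT_IG_THRESHOLD = 0.10

ASC = "ASC"
MEMORY = "memory"
NAIVE = "naive"
CELL_TYPES = (ASC, MEMORY, NAIVE)


@dataclass(frozen=True)
class CellTypeLabel:
    cell_id: str
    cell_type: str
    basis: str  # which rule fired: "asc_rule" | "sort_gate" | "demoted"


def annotate_cells(
    meta: list[CellMeta], ig_threshold: float = DEFAULT_IG_THRESHOLD
) -> list[CellTypeLabel]:
    """Assign exactly one label per cell.

    ASC iff CD27-high AND CD38-high AND ig_read_fraction strictly above the
    threshold.  Otherwise the sort gate decides memory vs naive; a cell
    sorted as ASC that fails the ASC rule is demoted to memory with a
    warning.  An unrecognizable sort label on a non-ASC cell is an error.
    """
    labels: list[CellTypeLabel] = []
    for m in meta:
        if m.cd27_high and m.cd38_high and m.ig_read_fraction > ig_threshold:
            labels.append(CellTypeLabel(m.cell_id, ASC, "asc_rule"))
            continue
        gate = m.sort_label.strip().lower()
        if gate == MEMORY:
            labels.append(CellTypeLabel(m.cell_id, MEMORY, "sort_gate"))
        elif gate == NAIVE:
            labels.append(CellTypeLabel(m.cell_id, NAIVE, "sort_gate"))
        elif gate == ASC.lower():
            logger.warning(
                "cell %s sorted as ASC but fails the ASC rule "
                "(cd27=%s cd38=%s ig_fraction=%.3f); demoted to memory",
                m.cell_id,
                m.cd27_high,
                m.cd38_high,
                m.ig_read_fraction,
            )
            labels.append(CellTypeLabel(m.cell_id, MEMORY, "demoted"))
        else:
            raise AnnotationError(
                f"cell {m.cell_id}: unknown sort label {m.sort_label!r} "
                "on a cell failing the ASC rule"
            )
    return labels
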