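"""Palmitoylation-site counting.

S-palmitoylation happens on cytoplasmic-facing cysteines at the membrane
interface. The model consumes only a count, n_palm, taken as the number of
Cys residues within a window anchored on the cytoplasmic terminus of the
TMD and extending into the membrane-proximal cytoplasmic (juxtamembrane)
sequence. Exoplasmic cysteines are never counted.

The default window is 15 residues, split symmetrically across the
cytoplasmic TMD boundary: 7 residues of the cytoplasmic end of the TMD
(including the terminal residue) and 7 of the juxtamembrane region. Any
callable mapping a record to an integer can replace this rule, e.g. to
inject the output of an external predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

from .seqio import TMDRecord

logger = logging.getLogger(__name__)

PalmPredictor = Callable[[TMDRecord], int]


@dataclass(frozen=True)
class PalmConfig:
    """Window geometry for the Cys-counting rule.

    cyto_window: total residues scanned (default 15).
    include_tmd_cyto_half: when True the window reaches
        ``cyto_window // 2`` residues into the TMD from its cytoplasmic
        terminus; when False it covers juxtamembrane sequence only.
    """

    cyto_window: int = 15
    include_tmd_cyto_half: bool = True

    def __post_init__(self) -> None:
        if self.cyto_window < 0:
            raise ValueError(f"cyto_window must be >= 0, got {self.cyto_window}")


def palm_window(record: TMDRecord, config: PalmConfig = PalmConfig()) -> list[int]:
    """1-based positions scanned by the counting rule (exposed for audit).

    The window is anchored on the cytoplasmic terminus of the TMD and runs
    in the cytoplasmic direction; it is clamped at the sequence terminus
    (logged, not an error) and never reaches past the exoplasmic end of
    the TMD.
    """
    if config.cyto_window == 0:
        return []
    c = record.cyto_terminus
    step = 1 if record.orientation == "exo_to_cyto" else -1  # cytoplasmic direction
    half_in = config.cyto_window // 2 if config.include_tmd_cyto_half else 0
    half_in = min(half_in, record.tmd_len - 1)  # stay within the TMD
    anchor = c - step * half_in
    positions = [anchor + step * i for i in range(config.cyto_window)]
    clamped = [p for p in positions if 1 <= p <= len(record.sequence)]
    if len(clamped) < len(positions):
        logger.debug(
            "record %s: palmitoylation window clamped to sequence bounds "
            "(%d of %d positions kept)", record.id, len(clamped), len(positions)
        )
    return clamped


def count_palm_sites(record: TMDRecord, config: PalmConfig = PalmConfig()) -> int:
    """n_palm for a record: override if set, else the Cys-count rule."""
    if record.n_palm_override is not None:
        return int(record.n_palm_override)
    return sum(1 for p in palm_window(record, config) if record.sequence[p - 1] == "C")
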