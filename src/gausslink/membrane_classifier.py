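"""Membrane-protein labels from database annotation records.

Each chain carries annotation evidence gathered from the four membrane
protein databases (PDBTM, MemProtMD as boolean flags; mpstruc and OPM as
free annotation text).  Two independent labels are derived:

* topology - does the chain span the bilayer (transmembrane) or interact
  with one leaflet only (monotopic)?
* persistence - is the membrane association permanent (integral) or
  transient (peripheral)?

Keyword matching is case-insensitive on word boundaries.  When the rules
for both values of a label fire, or neither does, the label is
``unclassified``; conflicting records are surfaced rather than resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = ["AnnotationRecord", "MembraneLabel", "classify", "classify_table"]

TOPOLOGIES = ("transmembrane", "monotopic", "unclassified")
PERSISTENCES = ("integral", "peripheral", "unclassified")


@dataclass(frozen=True)
class AnnotationRecord:
    chain_id: str
    pdbtm: bool = False
    memprotmd: bool = False
    mpstruc_text: str = ""
    opm_text: str = ""

    @property
    def text(self) -> str:
        return f"{self.mpstruc_text} {self.opm_text}"


@dataclass(frozen=True)
class MembraneLabel:
    topology: str
    persistence: str

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"bad topology {self.topology!r}")
        if self.persistence not in PERSISTENCES:
            raise ValueError(f"bad persistence {self.persistence!r}")


def _has_word(text: str, word: str) -> bool:
    return re.search(rf"\b{word}\b", text, flags=re.IGNORECASE) is not None


def classify(record: AnnotationRecord) -> MembraneLabel:
    """Assign (topology, persistence) labels to one annotation record."""
    tm = record.pdbtm or _has_word(record.text, "transmembrane")
    mono = _has_word(record.text, "monotopic")
    if tm and not mono:
        topology = "transmembrane"
    elif mono and not tm:
        topology = "monotopic"
    else:
        topology = "unclassified"

    integral = (
        record.pdbtm
        or record.memprotmd
        or any(_has_word(record.text, w) for w in ("transmembrane", "intrinsic", "integral"))
    )
    peripheral = _has_word(record.text, "peripheral")
    if integral and not peripheral:
        persistence = "integral"
    elif peripheral and not integral:
        persistence = "peripheral"
    else:
        persistence = "unclassified"
    return MembraneLabel(topology, persistence)


def classify_table(records: pd.DataFrame) -> pd.DataFrame:
    """Classify a table with columns chain_id, pdbtm, memprotmd, mpstruc_text, opm_text.

    Returns the input plus ``topology`` and ``persistence`` columns.
    """
    out = records.copy()
    labels = [
        classify(
            AnnotationRecord(
                chain_id=str(row.get("chain_id", "")),
                pdbtm=_as_bool(row.get("pdbtm", False)),
                memprotmd=_as_bool(row.get("memprotmd", False)),
                mpstruc_text=str(row.get("mpstruc_text", "") or ""),
                opm_text=str(row.get("opm_text", "") or ""),
            )
        )
        for _, row in records.iterrows()
    ]
    out["topology"] = [lb.topology for lb in labels]
    out["persistence"] = [lb.persistence for lb in labels]
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "t")
    return bool(value)
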