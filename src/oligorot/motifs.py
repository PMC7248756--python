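"""Scan repressor-family sequences for the three mutually exclusive
group-defining charged-residue motifs and assign phylogenetic groups.

Patterns (``x`` = any standard residue):

* ``Ec``: ``LIARxxD``  — ligand-pocket helix motif
* ``Bs``: ``KxxRxxxD`` — linker-helix triad (spacing from residues 75/78/82)
* ``Mt``: ``RxxRxxxE`` — linker-helix triad (spacing from residues 97/100/104)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MotifPattern",
    "MotifHit",
    "GroupAssignment",
    "PATTERNS",
    "PRECEDENCE",
    "scan_motif",
    "classify_group",
    "batch_classify",
]

#: Standard one-letter amino-acid codes matched by wildcard positions.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_LEGAL = set(STANDARD_AA) | {"X"}


@dataclass(frozen=True)
class MotifPattern:
    group: str                 # "Ec" | "Bs" | "Mt"
    pattern: str               # e.g. "KxxRxxxD"
    region_hint: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.pattern or any(
                c != "x" and c not in STANDARD_AA for c in self.pattern):
            raise ValueError(f"bad motif pattern {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def regex(self) -> re.Pattern:
        body = "".join(f"[{STANDARD_AA}]" if c == "x" else re.escape(c)
                       for c in self.pattern)
        # lookahead keeps overlapping matches
        return re.compile(f"(?=({body}))")


PATTERNS: dict[str, MotifPattern] = {
    "Ec": MotifPattern("Ec", "LIARxxD"),
    "Bs": MotifPattern("Bs", "KxxRxxxD"),
    "Mt": MotifPattern("Mt", "RxxRxxxE"),
}

#: Group precedence for the (rare) multi-hit case.
PRECEDENCE = ("Ec", "Bs", "Mt")


@dataclass(frozen=True)
class MotifHit:
    group: str
    start: int                 # 1-based position of the first motif residue
    matched: str


@dataclass
class GroupAssignment:
    sequence_id: str
    group: str                 # "Ec" | "Bs" | "Mt" | "unassigned"
    hits: list[MotifHit] = field(default_factory=list)
    outlier_flag: bool = False
    clade_label: str | None = None

    @property
    def multi_group(self) -> bool:
        return len({h.group for h in self.hits}) > 1


def _check_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - _LEGAL
    if bad:
        raise ValueError(f"illegal residue code(s) in sequence: {sorted(bad)}")
    return sequence


def scan_motif(sequence: str, pattern: MotifPattern,
               region: tuple[int, int] | None = None) -> list[MotifHit]:
    """All (possibly overlapping) matches of ``pattern``, 1-based positions.

    ``X`` in the sequence never matches a fixed position, and wildcards
    match standard residues only.  ``region`` (or the pattern's own hint)
    restricts the scan to a 1-based inclusive residue interval.
    """
    sequence = _check_sequence(sequence)
    region = region or pattern.region_hint
    offset = 0
    if region is not None:
        lo, hi = region
        offset = max(lo - 1, 0)
        sequence = sequence[offset:hi]
    return [MotifHit(pattern.group, m.start() + offset + 1, m.group(1))
            for m in pattern.regex.finditer(sequence)]


def classify_group(sequence: str, sequence_id: str = "",
                   clade_label: str | None = None,
                   patterns: dict[str, MotifPattern] = PATTERNS,
                   precedence: tuple[str, ...] = PRECEDENCE) -> GroupAssignment:
    """Assign the first group in precedence order with at least one motif hit.

    All hits from all patterns are retained in the report; a sequence with
    no hit is ``unassigned``; a clade label disagreeing with the motif
    group raises the outlier flag.
    """
    hits: list[MotifHit] = []
    for grp in precedence:
        hits.extend(scan_motif(sequence, patterns[grp]))
    group = next((g for g in precedence if any(h.group == g for h in hits)),
                 "unassigned")
    outlier = clade_label is not None and clade_label != group
    return GroupAssignment(sequence_id=sequence_id, group=group, hits=hits,
                           outlier_flag=outlier, clade_label=clade_label)


def batch_classify(fasta_path, clade_labels: dict[str, str] | None = None
                   ) -> pd.DataFrame:
    """Classify every record of a FASTA file; one row per record.

    Columns: id, group, hit position / matched substring of the assigned
    group's first hit, multi-group flag, outlier flag.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {fasta_path}")
    clade_labels = clade_labels or {}
    rows = []
    for rec in records:
        asg = classify_group(str(rec.seq), sequence_id=rec.id,
                             clade_label=clade_labels.get(rec.id))
        first = next((h for h in asg.hits if h.group == asg.group), None)
        rows.append({
            "id": asg.sequence_id,
            "group": asg.group,
            "hit_position": first.start if first else pd.NA,
            "matched": first.matched if first else "",
            "multi_group": asg.multi_group,
            "outlier_flag": asg.outlier_flag,
        })
    return pd.DataFrame(rows)
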