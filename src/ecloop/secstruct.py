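"""Three-state secondary-structure strings and their consensus.

Loop sampling can be biased by a per-residue secondary-structure assignment
over the three states H (alpha-helical), E (extended/strand) and C (coil).
Assignments come from external sequence-based predictors; this module only
combines and validates them.  The consensus rule is per-position strict
majority, with ties resolving to C — over-predicting regular structure is
more damaging to loop modeling than under-predicting it, so ambiguity
defaults to coil.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

from .structure_io import LoopDefinition

SS_ALPHABET = frozenset("HEC")


def _check_alphabet(ss: str) -> None:
    bad = set(ss) - SS_ALPHABET
    if bad:
        raise ValueError(f"secondary-structure labels must be H/E/C, got {sorted(bad)}")


def consensus_ss(predictions: Sequence[str]) -> str:
    """Per-position majority consensus of H/E/C strings.

    Requires at least two equal-length predictions.  A position with no
    strict majority label becomes C.
    """
    if len(predictions) < 2:
        raise ValueError("need at least two predictions for a consensus")
    length = len(predictions[0])
    if any(len(p) != length for p in predictions):
        raise ValueError("predictions differ in length")
    for p in predictions:
        _check_alphabet(p)
    out = []
    for labels in zip(*predictions):
        (label, count), = Counter(labels).most_common(1)
        out.append(label if count > len(labels) / 2 else "C")
    return "".join(out)


def validate_ss(ss: str, loop: LoopDefinition) -> str:
    """Check that an SS string matches a loop definition; returns it unchanged."""
    _check_alphabet(ss)
    if len(ss) != len(loop.sequence):
        raise ValueError(
            f"{loop.loop_id}: SS string length {len(ss)} != loop length "
            f"{len(loop.sequence)}"
        )
    return ss


def read_ss_file(path: str | Path) -> dict[str, str]:
    """Read 'loop_id<TAB>HEC-string' records, one per line."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        loop_id, ss = line.split("\t")
        _check_alphabet(ss)
        out[loop_id] = ss
    return out


def write_ss_file(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loop_id, ss in records.items():
            _check_alphabet(ss)
            fh.write(f"{loop_id}\t{ss}\n")
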