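"""PHQ-9 scoring and dichotomization into depressed / nondepressed."""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DEPRESSED = "depressed"
NONDEPRESSED = "nondepressed"

DEFAULT_CUTOFF = 10
N_ITEMS = 9


class Phq9Error(ValueError):
    pass


def score(items: Sequence[int]) -> int:
    """Sum the 9 item responses (each 0-3) into a 0-27 total."""
    if len(items) != N_ITEMS:
        raise Phq9Error(f"expected {N_ITEMS} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not isinstance(v, (int,)) or isinstance(v, bool) or not 0 <= v <= 3:
            raise Phq9Error(f"item {i} must be an integer in 0-3, got {v!r}")
    return sum(items)


def classify(total: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Label a total: depressed iff total >= cutoff."""
    if not 0 <= total <= 27:
        raise Phq9Error(f"total must be in 0-27, got {total}")
    return DEPRESSED if total >= cutoff else NONDEPRESSED


@dataclass(frozen=True)
class Phq9Response:
    participant_id: str
    items: tuple[int, ...]
    cutoff: int = DEFAULT_CUTOFF
    total: int = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "total", score(self.items))
        object.__setattr__(self, "label", classify(self.total, self.cutoff))


def score_phq8(items: Sequence[int], cutoff: int = DEFAULT_CUTOFF) -> tuple[int, str]:
    """Alternate 8-item mode: drop item 9, keep the same cutoff."""
    if len(items) != N_ITEMS:
        raise Phq9Error(f"expected {N_ITEMS} items, got {len(items)}")
    total = score(tuple(items[:8]) + (0,))
    label = DEPRESSED if total >= cutoff else NONDEPRESSED
    return total, label


def read_phq9(path: str | Path, cutoff: int = DEFAULT_CUTOFF) -> list[Phq9Response]:
    """Read a PHQ-9 CSV with columns participant_id,item1..item9."""
    cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    out: list[Phq9Response] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(["participant_id", *cols]) <= set(
            reader.fieldnames
        ):
            raise Phq9Error("PHQ-9 CSV requires columns participant_id,item1..item9")
        for row in reader:
            items = tuple(int(row[c]) for c in cols)
            out.append(Phq9Response(row["participant_id"], items, cutoff=cutoff))
    return out


def binary_labels(responses: Iterable[Phq9Response]) -> dict[str, int]:
    """Map participant_id -> 1 (depressed) / 0 (nondepressed)."""
    return {r.participant_id: int(r.label == DEPRESSED) for r in responses}
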