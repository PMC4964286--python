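"""Containers and I/O for 2x2x2 cross-classified diagnostic count tables.

Three binary tests applied to every subject give eight response patterns
(t1, t2, t3).  The canonical pattern order used throughout the package is

    (1,1,1), (1,1,0), (1,0,1), (1,0,0), (0,1,1), (0,1,0), (0,0,1), (0,0,0)

i.e. the first test varies slowest.  All vectors, files and reports follow
this order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

Pattern = tuple[int, int, int]

#: Canonical pattern order for all 8-vectors in the package.
PATTERNS: tuple[Pattern, ...] = (
    (1, 1, 1), (1, 1, 0), (1, 0, 1), (1, 0, 0),
    (0, 1, 1), (0, 1, 0), (0, 0, 1), (0, 0, 0),
)

_PATTERN_INDEX: dict[Pattern, int] = {p: i for i, p in enumerate(PATTERNS)}


def pattern_index(t1: int, t2: int, t3: int) -> int:
    """Position of pattern (t1, t2, t3) in the canonical order."""
    return _PATTERN_INDEX[(t1, t2, t3)]


@dataclass(frozen=True)
class CrossClassifiedCounts:
    """Observed counts of the 8 joint response patterns of three binary tests.

    Parameters
    ----------
    counts : tuple of 8 ints
        Cell counts in canonical pattern order (missing patterns must be
        stored as explicit zeros).
    labels : tuple of 3 str
        Names of the three tests.
    """

    counts: tuple[int, ...]
    labels: tuple[str, str, str] = ("T1", "T2", "T3")

    def __post_init__(self) -> None:
        if len(self.counts) != 8:
            raise ValueError(f"expected 8 cell counts, got {len(self.counts)}")
        for p, c in zip(PATTERNS, self.counts):
            if int(c) != c or c < 0:
                raise ValueError(
                    f"count for pattern {''.join(map(str, p))} must be a "
                    f"nonnegative integer, got {c!r}"
                )
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.labels) != 3:
            raise ValueError("exactly three test labels are required")
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))

    @property
    def n(self) -> int:
        """Total number of subjects."""
        return sum(self.counts)

    def __getitem__(self, pattern: Pattern) -> int:
        return self.counts[_PATTERN_INDEX[tuple(pattern)]]

    def as_dict(self) -> dict[str, int]:
        """Counts keyed by pattern strings '111' ... '000'."""
        return {"".join(map(str, p)): c for p, c in zip(PATTERNS, self.counts)}

    @classmethod
    def from_dict(
        cls,
        counts: Mapping[str, int] | Mapping[Pattern, int],
        labels: Iterable[str] | None = None,
    ) -> "CrossClassifiedCounts":
        """Build from a mapping keyed by '111'-style strings or (1,1,1) tuples.

        All eight patterns must be present; a missing pattern raises a
        ``ValueError`` naming it.
        """
        norm: dict[Pattern, int] = {}
        for key, value in counts.items():
            if isinstance(key, str):
                if len(key) != 3 or any(ch not in "01" for ch in key):
                    raise ValueError(f"unknown pattern key {key!r}")
                pat = tuple(int(ch) for ch in key)
            else:
                pat = tuple(int(b) for b in key)
            if pat not in _PATTERN_INDEX:
                raise ValueError(f"unknown pattern key {key!r}")
            norm[pat] = value
        missing = [p for p in PATTERNS if p not in norm]
        if missing:
            names = ", ".join("".join(map(str, p)) for p in missing)
            raise ValueError(f"missing pattern(s): {names}")
        vec = tuple(norm[p] for p in PATTERNS)
        if labels is not None:
            return cls(vec, tuple(labels))
        return cls(vec)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns t1, t2, t3, count."""
        return pd.DataFrame(
            {
                "t1": [p[0] for p in PATTERNS],
                "t2": [p[1] for p in PATTERNS],
                "t3": [p[2] for p in PATTERNS],
                "count": list(self.counts),
            }
        )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"counts": self.as_dict(), "labels": list(self.labels)}
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrossClassifiedCounts":
        df = pd.read_csv(path)
        required = {"t1", "t2", "t3", "count"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: CSV must have columns t1,t2,t3,count "
                f"(found {list(df.columns)})"
            )
        mapping = {}
        for _, row in df.iterrows():
            pat = (int(row["t1"]), int(row["t2"]), int(row["t3"]))
            if float(row["count"]) != int(row["count"]):
                raise ValueError(
                    f"{path}: non-integer count {row['count']} for pattern "
                    f"{''.join(map(str, pat))}"
                )
            mapping[pat] = int(row["count"])
        return cls.from_dict(mapping)

    @classmethod
    def from_json(cls, path: str | Path) -> "CrossClassifiedCounts":
        payload = json.loads(Path(path).read_text())
        if "counts" not in payload:
            raise ValueError(f"{path}: JSON must contain a 'counts' object")
        labels = payload.get("labels")
        return cls.from_dict(payload["counts"], labels=labels)

    @classmethod
    def from_file(cls, path: str | Path) -> "CrossClassifiedCounts":
        """Dispatch on extension: .csv or .json."""
        path = Path(path)
        if path.suffix.lower() == ".csv":
            return cls.from_csv(path)
        if path.suffix.lower() == ".json":
            return cls.from_json(path)
        raise ValueError(f"unsupported counts format: {path.suffix!r}")


def internal_wind_stroke() -> CrossClassifiedCounts:
    """The packaged internal-wind syndrome dataset (204 ischemic stroke patients).

    Three binary diagnoses per patient: the SSDC scale (T1), the ISDS scale
    (T2) and expert syndrome differentiation, ESD (T3).  Counts in canonical
    pattern order are Y = (69, 19, 7, 12, 32, 9, 5, 51).
    """
    ref = resources.files("latentdx").joinpath("datasets/internal_wind.json")
    with resources.as_file(ref) as path:
        return CrossClassifiedCounts.from_json(path)
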