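"""Clonal-family partitions: the common currency of delimiters and metrics.

A :class:`Partition` maps every sequence id to an inferred (or true) family
label. Labels are arbitrary strings; only the grouping matters. Partitions
round-trip through two-column AIRR-style TSV (sequence_id, clone_id).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Partition:
    assignment: dict[str, str]

    def __len__(self) -> int:
        return len(self.assignment)

    def ids(self) -> set[str]:
        return set(self.assignment)

    def clusters(self) -> dict[str, list[str]]:
        """Family label -> sorted list of member sequence ids."""
        out: dict[str, list[str]] = {}
        for sid, label in self.assignment.items():
            out.setdefault(label, []).append(sid)
        for members in out.values():
            members.sort()
        return out

    @classmethod
    def from_clusters(cls, clusters: dict[str, list[str]] | list[list[str]]) -> "Partition":
        if isinstance(clusters, dict):
            items = clusters.items()
        else:
            items = ((f"C{i}", members) for i, members in enumerate(clusters))
        assignment: dict[str, str] = {}
        for label, members in items:
            for sid in members:
                if sid in assignment:
                    raise ValueError(f"sequence id {sid!r} appears in two clusters")
                assignment[sid] = str(label)
        return cls(assignment)

    @property
    def n_families(self) -> int:
        return len(set(self.assignment.values()))

    def sizes(self) -> list[int]:
        return sorted(
            pd.Series(list(self.assignment.values())).value_counts().tolist(),
            reverse=True,
        )

    def median_size(self) -> float:
        """Median family size; for an even count, the mean of the two central values."""
        sizes = self.sizes()
        if not sizes:
            raise ValueError("empty partition has no median family size")
        return float(np.median(sizes))

    def restrict(self, ids) -> "Partition":
        keep = set(ids)
        missing = keep - self.ids()
        if missing:
            raise KeyError(f"ids not in partition: {sorted(missing)[:5]}")
        return Partition({sid: lab for sid, lab in self.assignment.items() if sid in keep})

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"sequence_id": list(self.assignment), "clone_id": list(self.assignment.values())}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sequence_id", "clone_id"} <= set(df.columns):
            raise ValueError(f"{path} lacks sequence_id/clone_id columns")
        if df["sequence_id"].duplicated().any():
            raise ValueError(f"{path} contains duplicate sequence ids")
        return cls(dict(zip(df["sequence_id"], df["clone_id"])))
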