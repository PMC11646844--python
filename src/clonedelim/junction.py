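"""Annotation-based clonal delimiters: the junction-clustering comparators.

Two rules, both operating on AIRR-style annotated records (v_call, j_call,
junction):

* ``identical`` — sequences sharing V gene, J gene and an *identical*
  junction string form one family (the strict grouping used when no
  similarity threshold is given).
* ``threshold`` — sequences sharing V gene, J gene and junction length are
  single-linkage clustered on normalized Hamming distance between
  junctions; the conventional human-repertoire cutoff 0.15 corresponds to
  85% junction similarity.

Junctions are compared at the nucleotide level. Records of different
junction length are never merged in threshold mode (the substitution-only
simulator cannot produce such variation within a family).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .partition import Partition


@dataclass(frozen=True)
class AnnotatedRecord:
    sequence_id: str
    v_call: str
    j_call: str
    junction: str

    def __post_init__(self) -> None:
        if not self.v_call or not self.j_call:
            raise ValueError(f"record {self.sequence_id!r} lacks V/J annotation")

    @property
    def junction_length(self) -> int:
        return len(self.junction)


def _strip_allele(call: str) -> str:
    return call.split("*", 1)[0]


def records_from_table(df: pd.DataFrame, normalize_alleles: bool = False) -> list[AnnotatedRecord]:
    """Build annotated records from an AIRR-style DataFrame."""
    required = {"sequence_id", "v_call", "j_call", "junction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples():
        v, j = row.v_call, row.j_call
        if normalize_alleles:
            v, j = _strip_allele(v), _strip_allele(j)
        out.append(AnnotatedRecord(str(row.sequence_id), v, j, str(row.junction)))
    return out


def group_records(
    records: list[AnnotatedRecord], keys: str = "vj"
) -> dict[tuple, list[AnnotatedRecord]]:
    """Partition records by shared V/J calls (``vj``) or V/J + junction length (``vj_len``)."""
    if keys not in ("vj", "vj_len"):
        raise ValueError(f"unknown grouping keys {keys!r}")
    groups: dict[tuple, list[AnnotatedRecord]] = {}
    for rec in records:
        key = (rec.v_call, rec.j_call)
        if keys == "vj_len":
            key = key + (rec.junction_length,)
        groups.setdefault(key, []).append(rec)
    return groups


def single_linkage_clusters(junctions: list[str], threshold: float) -> list[list[int]]:
    """Single-linkage clusters of equal-length strings at a normalized Hamming cutoff.

    Clusters merge while the minimum inter-cluster distance is <= threshold.
    Returns index lists into the input.
    """
    if not junctions:
        return []
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    lengths = {len(s) for s in junctions}
    if len(lengths) > 1:
        raise ValueError("single-linkage clustering requires equal-length junctions")
    n = len(junctions)
    if n == 1:
        return [[0]]
    arr = np.frombuffer("".join(junctions).encode(), dtype=np.uint8).reshape(n, -1)
    dists = pdist(arr, metric="hamming")
    z = linkage(dists, method="single")
    labels = fcluster(z, t=threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    return [clusters[lab] for lab in sorted(clusters)]


def delimit_by_junction(
    records: list[AnnotatedRecord] | pd.DataFrame,
    mode: str = "threshold",
    threshold: float = 0.15,
    normalize_alleles: bool = False,
) -> Partition:
    """Delimit clonal families from junction annotations.

    ``identical``: same (v_call, j_call) and byte-identical junction.
    ``threshold``: same (v_call, j_call, junction_length), then
    single-linkage clustering of junctions at the given normalized Hamming
    cutoff (default 0.15, i.e. 85% similarity).
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_table(records, normalize_alleles=normalize_alleles)
    assignment: dict[str, str] = {}
    label = 0
    if mode == "identical":
        groups = group_records(records, keys="vj")
        for key in sorted(groups):
            by_junction: dict[str, list[AnnotatedRecord]] = {}
            for rec in groups[key]:
                by_junction.setdefault(rec.junction, []).append(rec)
            for junction in sorted(by_junction):
                label += 1
                for rec in by_junction[junction]:
                    assignment[rec.sequence_id] = f"J{label}"
    elif mode == "threshold":
        if not (0.0 < threshold < 1.0):
            raise ValueError("threshold mode requires 0 < threshold < 1")
        groups = group_records(records, keys="vj_len")
        for key in sorted(groups):
            members = groups[key]
            clusters = single_linkage_clusters([r.junction for r in members], threshold)
            for idx_list in clusters:
                label += 1
                for i in idx_list:
                    assignment[members[i].sequence_id] = f"J{label}"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Partition(assignment)
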