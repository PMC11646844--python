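"""Germline gene sets for heavy-chain V(D)J recombination.

A germline set holds the V, D and J gene segments that naive rearrangements
are built from. Sets can be loaded from FASTA (e.g. an IMGT-style reference
directory), generated synthetically at the scale of the human heavy-chain
locus, or perturbed into "fake" V genes that no longer match any reference —
the scenario in which annotation-dependent delimiters lose sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"

#: default synthetic segment length ranges (nt), matching human IGH segments
DEFAULT_LENGTH_RANGES = {"V": (290, 320), "D": (10, 37), "J": (48, 63)}


@dataclass(frozen=True)
class GermlineGene:
    """A single named germline segment (V, D or J)."""

    name: str
    segment: str  # one of "V", "D", "J"
    sequence: str

    def __post_init__(self) -> None:
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"segment must be V, D or J, got {self.segment!r}")
        if not self.sequence:
            raise ValueError(f"gene {self.name!r} has an empty sequence")
        if set(self.sequence) - set(NUCLEOTIDES):
            bad = sorted(set(self.sequence) - set(NUCLEOTIDES))
            raise ValueError(f"gene {self.name!r} contains non-ACGT characters: {bad}")


@dataclass
class GermlineSet:
    """V/D/J germline genes available for recombination."""

    v_genes: list[GermlineGene] = field(default_factory=list)
    d_genes: list[GermlineGene] = field(default_factory=list)
    j_genes: list[GermlineGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seg, genes in (("V", self.v_genes), ("D", self.d_genes), ("J", self.j_genes)):
            if not genes:
                raise ValueError(f"germline set has no {seg} genes")
        names = [g.name for g in self.all_genes()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names in germline set: {dupes}")

    def all_genes(self) -> list[GermlineGene]:
        return [*self.v_genes, *self.d_genes, *self.j_genes]

    def counts(self) -> tuple[int, int, int]:
        return (len(self.v_genes), len(self.d_genes), len(self.j_genes))


def default_segment_rule(header: str) -> str | None:
    """Infer the segment from a FASTA header by IGHV/IGHD/IGHJ substring."""
    for tag, seg in (("IGHV", "V"), ("IGHD", "D"), ("IGHJ", "J")):
        if tag in header:
            return seg
    return None


def load_germline_fasta(
    path: str | Path,
    segment_rule: Callable[[str], str | None] = default_segment_rule,
) -> GermlineSet:
    """Read a germline FASTA, assigning each record to a segment class.

    ``segment_rule`` maps a FASTA header to "V", "D" or "J" (or None when
    the header matches no class, which is an error). Record order within
    each segment is preserved.
    """
    by_segment: dict[str, list[GermlineGene]] = {"V": [], "D": [], "J": []}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    for rec in records:
        seg = segment_rule(rec.description)
        if seg not in by_segment:
            raise ValueError(f"header {rec.description!r} matches no segment class")
        seq = str(rec.seq).upper().replace("U", "T")
        by_segment[seg].append(GermlineGene(rec.id, seg, seq))
    return GermlineSet(by_segment["V"], by_segment["D"], by_segment["J"])


def write_germline_fasta(germline: GermlineSet, path: str | Path) -> None:
    """Write all genes of a set as FASTA (one record per gene)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="")
        for g in germline.all_genes()
    ]
    SeqIO.write(records, str(path), "fasta")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def generate_synthetic_germline_set(
    n_v: int,
    n_d: int,
    n_j: int,
    length_ranges: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> GermlineSet:
    """Generate a random germline set with realistic segment lengths.

    Sequences are uniform over ACGT with lengths uniform in the per-segment
    range (defaults match human IGHV/IGHD/IGHJ lengths). Deterministic for
    a given seed. Gene names embed the segment tag (IGHV/IGHD/IGHJ) so the
    default FASTA segment rule round-trips.
    """
    ranges = dict(DEFAULT_LENGTH_RANGES)
    if length_ranges:
        ranges.update(length_ranges)
    for seg, (lo, hi) in ranges.items():
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range for {seg}: [{lo}, {hi}]")
    for label, n in (("n_v", n_v), ("n_d", n_d), ("n_j", n_j)):
        if n < 1:
            raise ValueError(f"{label} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out: dict[str, list[GermlineGene]] = {}
    for seg, n in (("V", n_v), ("D", n_d), ("J", n_j)):
        lo, hi = ranges[seg]
        genes = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            genes.append(
                GermlineGene(f"IGH{seg}-s{i + 1}", seg, _random_sequence(rng, length))
            )
        out[seg] = genes
    return GermlineSet(out["V"], out["D"], out["J"])


def _non_overlapping_intervals(
    rng: np.random.Generator, seq_len: int, sizes: list[int], max_tries: int = 1000
) -> list[tuple[int, int]]:
    """Draw non-overlapping [start, end) intervals of the given sizes."""
    for _ in range(max_tries):
        intervals = []
        for size in sizes:
            if seq_len - size < 0:
                break
            start = int(rng.integers(0, seq_len - size + 1))
            intervals.append((start, start + size))
        else:
            if all(
                a[1] <= b[0] or b[1] <= a[0]
                for i, a in enumerate(intervals)
                for b in intervals[i + 1 :]
            ):
                return intervals
            continue
        break
    raise ValueError(f"cannot place edits of sizes {sizes} in a sequence of length {seq_len}")


def make_fake_v_genes(
    germline: GermlineSet,
    seed: int,
    n_deletions: int = 3,
    n_insertions: int = 3,
    indel_size_range: tuple[int, int] = (1, 4),
    n_point_range: tuple[int, int] = (20, 40),
) -> GermlineSet:
    """Corrupt every V gene so it no longer matches a reference directory.

    Each V gene independently receives ``n_deletions`` deletions and
    ``n_insertions`` insertions (sizes uniform in ``indel_size_range``, at
    non-overlapping positions of the original sequence, applied right to
    left), followed by a uniform count of point substitutions drawn from
    ``n_point_range``, each at a distinct position and each guaranteed to
    change the base. D and J genes pass through untouched.
    """
    rng = np.random.default_rng(seed)
    lo, hi = indel_size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid indel size range [{lo}, {hi}]")
    fake_vs = []
    for gene in germline.v_genes:
        seq = gene.sequence
        n_edits = n_deletions + n_insertions
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_edits)]
        intervals = _non_overlapping_intervals(rng, len(seq), sizes)
        # first n_deletions intervals are deletions, the rest insertion anchors
        edits = [
            (iv, "del" if k < n_deletions else "ins") for k, iv in enumerate(intervals)
        ]
        chars = list(seq)
        for (start, end), kind in sorted(edits, reverse=True):
            if kind == "del":
                del chars[start:end]
            else:
                chars[start:start] = list(_random_sequence(rng, end - start))
        n_points = int(rng.integers(n_point_range[0], n_point_range[1] + 1))
        if n_points > len(chars):
            raise ValueError(
                f"V gene {gene.name!r} too short for {n_points} point mutations"
            )
        positions = rng.choice(len(chars), size=n_points, replace=False)
        for pos in positions:
            alternatives = [b for b in NUCLEOTIDES if b != chars[pos]]
            chars[pos] = alternatives[int(rng.integers(0, 3))]
        fake_vs.append(GermlineGene(gene.name + "_fake", "V", "".join(chars)))
    return GermlineSet(fake_vs, list(germline.d_genes), list(germline.j_genes))
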