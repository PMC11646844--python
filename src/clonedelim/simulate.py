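"""Simulation of heavy-chain B-cell repertoires with known clonal families.

Each clonal family starts from one naive V(D)J rearrangement: a uniformly
sampled V, D and J gene joined with fixed-length uniform-random junctional
insertions (N/P nucleotides, default 6 on each side of D). The family then
expands along a random-join lineage tree whose edge lengths are exponential
with mean equal to the somatic-hypermutation (SHM) rate, interpreted as the
expected number of substitutions per site per edge. Substitution-only SHM
keeps every leaf the same length as its naive ancestor, so within-family
comparisons are alignment-free.

The junction region is defined operationally as np1 + D + np2 (0-based
half-open coordinates into the naive sequence). A junction-only SHM scope
restricts mutation to that interval, emulating simulations that stress the
junction-focused delimiters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .germline import NUCLEOTIDES, GermlineSet
from .partition import Partition
from .trees import PhyloTree, write_newick

#: SHM-rate grid and leaf-count grid used by the default experiment design
DEFAULT_SHM_RATES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2)
DEFAULT_MEAN_LEAVES = (10, 20, 50, 100)

_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class NaiveRearrangement:
    """An unmutated V(D)J rearrangement, the root of one clonal family."""

    v_name: str
    d_name: str
    j_name: str
    np1: str
    np2: str
    naive_sequence: str
    junction_interval: tuple[int, int]  # 0-based half-open; np1 + D + np2 (+ flanks)
    core_interval: tuple[int, int] | None = None  # np1 + D + np2 without flanks

    @property
    def junction(self) -> str:
        start, end = self.junction_interval
        return self.naive_sequence[start:end]

    @property
    def d_interval(self) -> tuple[int, int]:
        """0-based half-open coordinates of the D gene within the naive sequence."""
        start, end = self.core_interval or self.junction_interval
        return (start + len(self.np1), end - len(self.np2))


@dataclass
class ClonalFamily:
    """Ground truth for one family: rearrangement, lineage tree, leaf sequences."""

    family_id: str
    rearrangement: NaiveRearrangement
    lineage: PhyloTree
    leaf_sequences: dict[str, str]

    @property
    def size(self) -> int:
        return len(self.leaf_sequences)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated repertoire."""

    n_families: int = 16
    mean_leaves: float = 10.0
    shm_rate: float = 0.01
    shm_scope: Literal["whole_sequence", "junction_only"] = "whole_sequence"
    junction_shm_include_d: bool = True
    np_length: int = 6
    junction_flank: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.mean_leaves < 1:
            raise ValueError("mean_leaves must be >= 1")
        if not (0 < self.shm_rate <= 0.75):
            raise ValueError("shm_rate must be in (0, 0.75]")
        if self.shm_scope not in ("whole_sequence", "junction_only"):
            raise ValueError(f"unknown shm_scope {self.shm_scope!r}")
        if self.np_length < 0:
            raise ValueError("np_length must be >= 0")
        if self.junction_flank < 0:
            raise ValueError("junction_flank must be >= 0")


@dataclass
class Repertoire:
    """A simulated repertoire: families plus the flat AIRR-style record table."""

    families: list[ClonalFamily]
    config: SimulationConfig | None = None
    records: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for fam in self.families:
            r = fam.rearrangement
            start, end = r.junction_interval
            for sid, seq in fam.leaf_sequences.items():
                junction = seq[start:end]
                rows.append(
                    {
                        "sequence_id": sid,
                        "sequence": seq,
                        "v_call": r.v_name,
                        "d_call": r.d_name,
                        "j_call": r.j_name,
                        "junction": junction,
                        "junction_length": len(junction),
                        "clone_id": fam.family_id,
                    }
                )
        self.records = pd.DataFrame(rows)
        if self.records["sequence_id"].duplicated().any():
            raise ValueError("leaf labels are not unique across the repertoire")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def truth_partition(self) -> Partition:
        return Partition(dict(zip(self.records["sequence_id"], self.records["clone_id"])))

    def sequences(self) -> dict[str, str]:
        return dict(zip(self.records["sequence_id"], self.records["sequence"]))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])


def recombine(
    germline: GermlineSet,
    rng: np.random.Generator,
    np_length: int = 6,
    junction_flank: int = 0,
) -> NaiveRearrangement:
    """Sample one naive rearrangement: uniform V, D, J plus junctional insertions.

    The junction interval covers np1 + D + np2; ``junction_flank`` extends it
    symmetrically into the V and J genes (clipped at the sequence ends), for
    junction definitions that include flanking gene residues.
    """
    v = germline.v_genes[int(rng.integers(0, len(germline.v_genes)))]
    d = germline.d_genes[int(rng.integers(0, len(germline.d_genes)))]
    j = germline.j_genes[int(rng.integers(0, len(germline.j_genes)))]
    np1 = _random_nt(rng, np_length)
    np2 = _random_nt(rng, np_length)
    naive = v.sequence + np1 + d.sequence + np2 + j.sequence
    core = (
        len(v.sequence),
        len(v.sequence) + len(np1) + len(d.sequence) + len(np2),
    )
    start = max(0, core[0] - junction_flank)
    end = min(len(naive), core[1] + junction_flank)
    return NaiveRearrangement(
        v.name, d.name, j.name, np1, np2, naive, (start, end), core
    )


def sample_family_size(mean_leaves: float, rng: np.random.Generator) -> int:
    """Draw a family size from a geometric distribution on {1, 2, ...}.

    Success probability p = 1/mean_leaves, so the expectation is mean_leaves.
    """
    if mean_leaves < 1:
        raise ValueError("mean_leaves must be >= 1")
    return int(rng.geometric(1.0 / mean_leaves))


def _random_join_topology(
    n_leaves: int, leaf_labels: list[str], rng: np.random.Generator, shm_rate: float
) -> PhyloTree:
    """Random-join (Kingman-shaped) rooted binary lineage.

    Edge lengths are i.i.d. exponential and the whole tree is rescaled so
    the mean root-to-leaf path length equals ``shm_rate``: the SHM rate is
    the expected per-site substitution load of a sampled sequence relative
    to its naive ancestor, which keeps simulated divergence in the
    biologically quoted range across tree sizes.
    """
    nodes = [PhyloTree(name=lab) for lab in leaf_labels]
    while len(nodes) > 1:
        i, jj = rng.choice(len(nodes), size=2, replace=False)
        i, jj = int(min(i, jj)), int(max(i, jj))
        right = nodes.pop(jj)
        left = nodes.pop(i)
        left.length = float(rng.exponential(1.0))
        right.length = float(rng.exponential(1.0))
        parent = PhyloTree(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None

    def depths(node: PhyloTree, acc: float, out: list[float]) -> None:
        acc += node.length or 0.0
        if node.is_tip():
            out.append(acc)
        for child in node.children:
            depths(child, acc, out)

    leaf_depths: list[float] = []
    depths(root, 0.0, leaf_depths)
    mean_depth = sum(leaf_depths) / len(leaf_depths)
    scale = shm_rate / mean_depth if mean_depth > 0 else 0.0
    for node in root.traverse(include_self=False):
        node.length = (node.length or 0.0) * scale
    return root


def _evolve_on_tree(
    tree: PhyloTree,
    naive: str,
    mutable: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve the naive sequence down the tree by per-edge substitutions.

    On an edge of length t each mutable site substitutes with probability
    1 - exp(-t); the replacement base is uniform over the 3 alternatives.
    """
    codes = np.frombuffer(naive.encode(), dtype=np.uint8)
    nt_codes = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
    code_to_idx = np.zeros(256, dtype=np.int8)
    for i, c in enumerate(nt_codes):
        code_to_idx[c] = i
    leaves: dict[str, str] = {}

    def descend(node: PhyloTree, seq_idx: np.ndarray) -> None:
        if node.length:  # root has no edge; zero-length edges mutate nothing
            p = 1.0 - np.exp(-node.length)
            hits = np.flatnonzero((rng.random(seq_idx.size) < p) & mutable)
            if hits.size:
                seq_idx = seq_idx.copy()
                # uniform among the 3 alternative bases
                shift = rng.integers(1, 4, size=hits.size)
                seq_idx[hits] = (seq_idx[hits] + shift) % 4
        if node.is_tip():
            leaves[node.name] = "".join(NUCLEOTIDES[i] for i in seq_idx)
        else:
            for child in node.children:
                descend(child, seq_idx)

    descend(tree, code_to_idx[codes].astype(np.int64))
    return leaves


def simulate_clonal_family(
    rearrangement: NaiveRearrangement,
    n_leaves: int,
    shm_rate: float,
    shm_scope: str,
    rng: np.random.Generator,
    family_id: str = "F0",
    leaf_labels: list[str] | None = None,
    junction_shm_include_d: bool = True,
) -> ClonalFamily:
    """Expand one rearrangement into a clonal family of ``n_leaves`` sequences."""
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if not (0 < shm_rate <= 0.75):
        raise ValueError("shm_rate must be in (0, 0.75]")
    if leaf_labels is None:
        leaf_labels = [f"{family_id}_leaf{i + 1}" for i in range(n_leaves)]
    if len(leaf_labels) != n_leaves:
        raise ValueError("leaf_labels length must equal n_leaves")

    naive = rearrangement.naive_sequence
    mutable = np.ones(len(naive), dtype=bool)
    if shm_scope == "junction_only":
        mutable[:] = False
        start, end = rearrangement.junction_interval
        mutable[start:end] = True
        if not junction_shm_include_d:
            d_start, d_end = rearrangement.d_interval
            mutable[d_start:d_end] = False
    elif shm_scope != "whole_sequence":
        raise ValueError(f"unknown shm_scope {shm_scope!r}")

    if n_leaves == 1:
        tree = PhyloTree(name=leaf_labels[0])
        return ClonalFamily(family_id, rearrangement, tree, {leaf_labels[0]: naive})

    tree = _random_join_topology(n_leaves, leaf_labels, rng, shm_rate)
    leaf_sequences = _evolve_on_tree(tree, naive, mutable, rng)
    return ClonalFamily(family_id, rearrangement, tree, leaf_sequences)


def simulate_repertoire(config: SimulationConfig, germline: GermlineSet) -> Repertoire:
    """Simulate a full repertoire of independent clonal families.

    One RNG substream per family (spawned from the master seed by family
    index) makes each family reproducible independently of the others.
    Sequence ids are sequential across the repertoire and do not encode the
    true family; the ground truth lives in the record table's clone_id.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_families)
    families = []
    next_seq = 1
    for k in range(config.n_families):
        rng = np.random.default_rng(streams[k])
        rearr = recombine(germline, rng, config.np_length, config.junction_flank)
        size = sample_family_size(config.mean_leaves, rng)
        labels = [f"seq{next_seq + i:06d}" for i in range(size)]
        next_seq += size
        fam = simulate_clonal_family(
            rearr,
            size,
            config.shm_rate,
            config.shm_scope,
            rng,
            family_id=f"F{k + 1:03d}",
            leaf_labels=labels,
            junction_shm_include_d=config.junction_shm_include_d,
        )
        families.append(fam)
    return Repertoire(families, config)


AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_length",
    "clone_id",
]


def export_repertoire(
    repertoire: Repertoire,
    fasta_path: str | Path,
    truth_tsv_path: str | Path,
    metadata_path: str | Path | None = None,
    newick_dir: str | Path | None = None,
) -> None:
    """Write the repertoire as FASTA + AIRR-style truth TSV (+ metadata, trees)."""
    records = [
        SeqRecord(Seq(row.sequence), id=row.sequence_id, description="")
        for row in repertoire.records.itertuples()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    repertoire.records[AIRR_COLUMNS].to_csv(truth_tsv_path, sep="\t", index=False)
    if metadata_path is not None and repertoire.config is not None:
        cfg = repertoire.config
        lines = [
            f"n_families = {cfg.n_families}",
            f"mean_leaves = {cfg.mean_leaves}",
            f"shm_rate = {cfg.shm_rate}",
            f"shm_scope = {cfg.shm_scope}",
            f"junction_shm_include_d = {cfg.junction_shm_include_d}",
            f"np_length = {cfg.np_length}",
            f"seed = {cfg.seed}",
            "lineage_topology = random_join",
            "edge_lengths = exponential(mean = shm_rate)",
        ]
        Path(metadata_path).write_text("\n".join(lines) + "\n")
    if newick_dir is not None:
        out = Path(newick_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fam in repertoire.families:
            (out / f"{fam.family_id}.nwk").write_text(write_newick(fam.lineage))


def load_repertoire_tsv(path: str | Path) -> pd.DataFrame:
    """Read an AIRR-style rearrangement TSV (as written by export_repertoire)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "clone_id": str})
    missing = set(AIRR_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required AIRR columns: {sorted(missing)}")
    return df
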