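"""Distance-based phylogeny construction for repertoire sequences.

The delimitation stage needs only the backbone branching structure of the
repertoire, so trees are built with neighbor-joining on pairwise distances
(Hamming, Jukes-Cantor-corrected, or normalized edit distance for sequences
of unequal length) and rooted at the midpoint of the longest tip-to-tip
path. Externally built Newick trees (e.g. from a maximum-likelihood tool)
can be supplied instead at every entry point that takes a tree.

Trees are scikit-bio ``TreeNode`` objects throughout; ``PhyloTree`` is an
alias for that type.
"""

from __future__ import annotations

import io
from typing import Sequence

import edlib
import numpy as np
from skbio import DistanceMatrix as _SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

PhyloTree = TreeNode
DistanceMatrix = _SkbioDistanceMatrix

#: distance assigned when the Jukes-Cantor correction saturates (p >= 0.75)
JC_SATURATION_CEILING = 5.0


def _hamming_matrix(seqs: list[str]) -> np.ndarray:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(
            "hamming/jc distances require equal-length sequences; "
            f"got lengths {sorted(lengths)}"
        )
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    n = len(seqs)
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i + 1 :] = (arr[i + 1 :] != arr[i]).mean(axis=1)
    return out + out.T


def pairwise_distances(
    records: dict[str, str] | Sequence[tuple[str, str]],
    model: str = "hamming",
    jc_ceiling: float = JC_SATURATION_CEILING,
) -> DistanceMatrix:
    """Pairwise distances between labelled sequences.

    Models: ``hamming`` (mismatch proportion), ``jc_corrected``
    (-(3/4) ln(1 - 4p/3), with saturated pairs set to ``jc_ceiling``), and
    ``edit`` (unit-cost global-alignment distance normalized by the longer
    sequence length; tolerates unequal lengths).
    """
    items = list(records.items()) if isinstance(records, dict) else list(records)
    if not items:
        raise ValueError("no sequences given")
    labels = [lab for lab, _ in items]
    seqs = [seq for _, seq in items]
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be unique")

    if model in ("hamming", "jc_corrected"):
        d = _hamming_matrix(seqs)
        if model == "jc_corrected":
            with np.errstate(invalid="ignore", divide="ignore"):
                corrected = -0.75 * np.log(1.0 - (4.0 / 3.0) * d)
            corrected[d >= 0.75] = jc_ceiling
            d = corrected
            np.fill_diagonal(d, 0.0)
    elif model == "edit":
        n = len(seqs)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist = edlib.align(seqs[i], seqs[j], mode="NW")["editDistance"]
                d[i, j] = d[j, i] = dist / max(len(seqs[i]), len(seqs[j]))
    else:
        raise ValueError(f"unknown distance model {model!r}")
    return DistanceMatrix(d, labels)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (unrooted; negative branch estimates clipped to 0).

    Degenerate inputs: one label gives a single leaf, two labels a single
    edge carrying the full distance.
    """
    labels = list(dm.ids)
    if len(labels) == 1:
        return TreeNode(name=labels[0])
    if len(labels) == 2:
        a = TreeNode(name=labels[0], length=0.0)
        b = TreeNode(name=labels[1], length=float(dm[labels[0], labels[1]]))
        return TreeNode(children=[a, b])
    tree = _skbio_nj(dm)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest tip-to-tip path (strictly binary result)."""
    n_tips = tree.count(tips=True)
    if n_tips == 0:
        raise ValueError("cannot midpoint-root an empty tree")
    if n_tips == 1:
        return tree.copy()
    if n_tips == 2:
        a, b = tree.tips()
        half = (a.distance(b)) / 2.0
        return TreeNode(
            children=[TreeNode(name=a.name, length=half), TreeNode(name=b.name, length=half)]
        )
    try:
        return tree.copy().root_at_midpoint()
    except (TypeError, ZeroDivisionError):
        # degenerate case (e.g. every tip-to-tip distance zero): the midpoint
        # is undefined, so root above an arbitrary tip instead
        first_tip = next(tree.tips()).name
        return tree.copy().root_at(first_tip, above=True)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; duplicate leaf labels are rejected."""
    tree = TreeNode.read(io.StringIO(text))
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf labels in Newick input: {dupes}")
    return tree


def write_newick(tree: PhyloTree) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue()


def tip_to_tip_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Path length between two named tips."""
    return float(tree.find(a).distance(tree.find(b)))


def write_phylip_matrix(dm: DistanceMatrix, path) -> None:
    """Tab-separated square PHYLIP-style matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for lab in dm.ids:
            row = "\t".join(f"{dm[lab, other]:.10g}" for other in dm.ids)
            fh.write(f"{lab}\t{row}\n")


def root_to_tip_depths(tree: PhyloTree) -> dict[str, float]:
    depths = {}
    for tip in tree.tips():
        depths[tip.name] = float(tip.accumulate_to_ancestor(tree))
    return depths


def is_binary_rooted(tree: PhyloTree) -> bool:
    if len(tree.children) != 2:
        return False
    return all(
        len(n.children) in (0, 2) for n in tree.traverse(include_self=False)
    )
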