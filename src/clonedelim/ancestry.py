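"""Naive-sequence (root) reconstruction for inferred clonal families.

The downstream check on a delimitation: for each inferred family of more
than two sequences, build a neighbor-joining tree from Hamming distances,
midpoint-root it, reconstruct the per-site marginal maximum-likelihood root
state under the Jukes-Cantor model (Felsenstein pruning with the tree's
branch lengths), and compare the reconstruction to the true naive sequence
by Hamming distance. Ties in the root posterior break lexicographically
(A < C < G < T). Families whose members differ in length (possible when a
delimiter merges distinct true families) are projected onto the coordinates
of their longest member via global alignment; projected-gap columns are
treated as missing data and excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .trees import PhyloTree, midpoint_root, nj_tree, pairwise_distances

_NT = "ACGT"
_NT_INDEX = {b: i for i, b in enumerate(_NT)}
GAP = "-"


@dataclass
class AncestorResult:
    family_label: str
    inferred_root_sequence: str | None
    hamming_distance: int | None
    similarity: float | None
    n_sequences: int
    n_sites_scored: int = 0
    skipped_reason: str | None = None


def _jc_transition(t: float) -> np.ndarray:
    """Jukes-Cantor transition matrix for branch length t (substitutions/site)."""
    e = np.exp(-4.0 * max(t, 0.0) / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def reconstruct_root_sequence(sequences: dict[str, str], tree: PhyloTree) -> str:
    """Per-site marginal ML root states under Jukes-Cantor pruning.

    ``sequences`` may contain ``-`` (missing data); such sites carry a flat
    likelihood. Leaf labels of the tree must match the sequence labels and
    all sequences must have equal length.
    """
    tip_names = {tip.name for tip in tree.tips()}
    if tip_names != set(sequences):
        raise ValueError("tree leaf labels do not match sequence labels")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    n_sites = lengths.pop()

    def partial(node: PhyloTree) -> np.ndarray:
        """(n_sites, 4) conditional likelihoods at this node."""
        if node.is_tip():
            lik = np.zeros((n_sites, 4))
            for i, base in enumerate(sequences[node.name]):
                if base in _NT_INDEX:
                    lik[i, _NT_INDEX[base]] = 1.0
                else:  # gap / ambiguous: missing data
                    lik[i, :] = 1.0
            return lik
        lik = np.ones((n_sites, 4))
        for child in node.children:
            p = _jc_transition(float(child.length or 0.0))
            lik *= partial(child) @ p.T
        return lik

    root_post = partial(tree) * 0.25  # uniform root prior
    # argmax with lexicographic tie-break: np.argmax returns the first maximum
    best = np.argmax(root_post, axis=1)
    return "".join(_NT[i] for i in best)


def _project_to_reference(seq: str, ref: str) -> str:
    """Project ``seq`` onto ``ref`` coordinates by unit-cost global alignment.

    Positions of ``ref`` not covered by ``seq`` become gaps; insertions in
    ``seq`` relative to ``ref`` are dropped. Result has len(ref).
    """
    if seq == ref:
        return seq
    aln = edlib.align(seq, ref, mode="NW", task="path")
    out = []
    i = 0  # position in seq
    for run, op in _parse_cigar(aln["cigar"]):
        if op in ("=", "X", "M"):
            out.append(seq[i : i + run])
            i += run
        elif op == "I":  # present in seq, absent in ref
            i += run
        elif op == "D":  # absent in seq, present in ref
            out.append(GAP * run)
    projected = "".join(out)
    assert len(projected) == len(ref)
    return projected


def _parse_cigar(cigar: str):
    run = 0
    for ch in cigar:
        if ch.isdigit():
            run = run * 10 + int(ch)
        else:
            yield run, ch
            run = 0


def family_ancestor_similarity(
    family_sequences: dict[str, str],
    true_naive: str,
    family_label: str = "family",
) -> AncestorResult:
    """Reconstruct a family's root sequence and score it against the true naive.

    Pipeline: Hamming distances -> neighbor joining -> midpoint rooting ->
    Jukes-Cantor marginal root reconstruction -> Hamming distance and
    similarity (1 - hamming/length) to ``true_naive``. Families of two or
    fewer sequences are skipped with a recorded reason. Mixed-length
    families are projected onto their longest member first; gap columns and
    positions beyond the true naive are excluded from scoring.
    """
    n = len(family_sequences)
    if n <= 2:
        return AncestorResult(
            family_label=family_label,
            inferred_root_sequence=None,
            hamming_distance=None,
            similarity=None,
            n_sequences=n,
            skipped_reason="family has <= 2 sequences",
        )
    lengths = {len(s) for s in family_sequences.values()}
    seqs = dict(family_sequences)
    if len(lengths) > 1:
        ref_label = max(seqs, key=lambda k: (len(seqs[k]), k))
        ref = seqs[ref_label]
        seqs = {lab: _project_to_reference(s, ref) for lab, s in seqs.items()}

    dm = pairwise_distances(seqs, model="hamming")
    tree = midpoint_root(nj_tree(dm))
    root_seq = reconstruct_root_sequence(seqs, tree)

    # score only sites that exist in both the reconstruction and the true naive
    span = min(len(root_seq), len(true_naive))
    gap_free = [
        i for i in range(span) if not any(s[i] == GAP for s in seqs.values())
    ]
    hamming = sum(1 for i in gap_free if root_seq[i] != true_naive[i])
    n_scored = len(gap_free)  # similarity is defined over the scored sites only
    similarity = 1.0 - hamming / n_scored if n_scored else float("nan")
    return AncestorResult(
        family_label=family_label,
        inferred_root_sequence=root_seq,
        hamming_distance=hamming,
        similarity=similarity,
        n_sequences=n,
        n_sites_scored=n_scored,
    )


def partition_ancestor_results(
    partition, sequences: dict[str, str], true_naives: dict[str, str]
) -> list[AncestorResult]:
    """Run the ancestor check for every family of an inferred partition.

    ``true_naives`` maps each sequence id to the naive sequence of its true
    family; within an inferred family the most common true naive is used as
    the comparison target (families mixing several true families are scored
    against the majority naive).
    """
    results = []
    for label, members in sorted(partition.clusters().items()):
        fam_seqs = {sid: sequences[sid] for sid in members}
        naives = [true_naives[sid] for sid in members]
        target = max(set(naives), key=lambda s: (naives.count(s), s))
        results.append(family_ancestor_similarity(fam_seqs, target, family_label=label))
    return results
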