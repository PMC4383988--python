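"""Sequence identity and greedy identity clustering of assembly chains.

Chains of a biological assembly are grouped at a percent-identity threshold:
95% groups essentially-identical subunits (engineered mutants, minor
variation), 30% groups homologous subunits for pseudo-symmetry detection,
and 90% is used to propagate annotations (e.g. membrane-protein class)
across near-identical chains.

Identity is measured on a global alignment with affine gap penalties, with
the denominator counting alignment columns excluding terminal-gap columns —
tolerant of truncated constructs. The scoring scheme is exposed as module
constants so independent re-implementations can mirror it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .superpose import Alignment

logger = logging.getLogger(__name__)

# identity-oriented scoring; declared constants so a DP oracle can mirror them
MATCH_SCORE = 1.0
MISMATCH_SCORE = 0.0
GAP_OPEN = -10.0       # cost of the first residue of a gap
GAP_EXTEND = -0.5      # cost of each further residue


@dataclass(frozen=True)
class IdentityScore:
    percent_identity: float
    aligned_length: int
    matches: int

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if self.matches > self.aligned_length:
            raise ValueError("matches exceed aligned length")


@dataclass
class ClusterSet:
    """Partition of chain instances into identity clusters at one threshold."""

    threshold: float
    clusters: list[list[str]] = field(default_factory=list)
    representatives: list[str] = field(default_factory=list)

    def cluster_of(self, chain_id: str) -> int:
        for i, members in enumerate(self.clusters):
            if chain_id in members:
                return i
        raise KeyError(chain_id)

    def as_index_map(self) -> dict[str, int]:
        return {m: i for i, members in enumerate(self.clusters) for m in members}

    def __len__(self) -> int:
        return len(self.clusters)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def global_alignment(seq_a: str, seq_b: str) -> Alignment:
    """Best global affine-gap alignment of two one-letter sequences."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(seq_a, seq_b)[0]
    return Alignment(str(aln[0]), str(aln[1]), float(aln.score))


def align_identity(seq_a: str, seq_b: str) -> IdentityScore:
    """Percent identity of two sequences under global affine-gap alignment.

    percent_identity = 100 × matches / (alignment columns excluding
    terminal-gap columns). Terminal gaps are overhangs at either end of the
    alignment where one sequence has not started or has already ended.
    The pair is put in canonical order before aligning, so the score is
    exactly symmetric even when co-optimal alignments differ in their
    match counts.
    """
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aln = global_alignment(seq_a, seq_b)
    a, b = aln.gapped_a, aln.gapped_b
    # trim leading/trailing columns where either row is gapped
    start = 0
    while start < len(a) and (a[start] == "-" or b[start] == "-"):
        start += 1
    end = len(a)
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    columns = end - start
    if columns <= 0:
        return IdentityScore(0.0, 0, 0)
    matches = sum(1 for ca, cb in zip(a[start:end], b[start:end]) if ca == cb and ca != "-")
    return IdentityScore(100.0 * matches / columns, columns, matches)


def cluster_chains(chains, threshold: float, min_length: int = 20) -> ClusterSet:
    """Greedy identity clustering of chains at a percent-identity threshold.

    Chains with fewer than ``min_length`` Cα-bearing residues are excluded
    before clustering. The longest unassigned chain (ties broken by
    lexicographic chain id) seeds a cluster; every remaining chain with
    identity ≥ threshold to the seed joins it. Deterministic for a given
    input set.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    eligible = [c for c in chains if len(c.ca_coords) >= min_length]
    order = sorted(eligible, key=lambda c: (-len(c.ca_coords), c.chain_id))

    result = ClusterSet(threshold=threshold)
    unassigned = list(order)
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed.chain_id]
        rest = []
        for c in unassigned:
            if c.sequence == seed.sequence:
                ident = 100.0
            else:
                ident = align_identity(seed.sequence, c.sequence).percent_identity
            if ident >= threshold:
                members.append(c.chain_id)
            else:
                rest.append(c)
        unassigned = rest
        result.clusters.append(members)
        result.representatives.append(seed.chain_id)
    return result


def propagate_annotations(
    clusters: ClusterSet, labels: dict[str, str]
) -> tuple[dict[str, str], set[str]]:
    """Spread per-chain labels across identity clusters.

    Every chain sharing a cluster with a labeled chain receives that label;
    pre-existing labels are never overwritten. When one cluster contains
    members with conflicting labels, its unlabeled members are flagged
    ambiguous instead of labeled. Labels naming unknown chains are skipped
    with a warning.

    Returns (propagated labels, set of ambiguous chain ids).
    """
    known = {m for members in clusters.clusters for m in members}
    out = {}
    for cid, label in labels.items():
        if cid not in known:
            logger.warning("label for unknown chain %r skipped", cid)
            continue
        out[cid] = label

    ambiguous: set[str] = set()
    for members in clusters.clusters:
        present = {out[m] for m in members if m in out}
        if len(present) == 1:
            label = next(iter(present))
            for m in members:
                out.setdefault(m, label)
        elif len(present) > 1:
            ambiguous.update(m for m in members if m not in out)
    return out, ambiguous


def write_cluster_tsv(clusters: ClusterSet, chains_by_id, path) -> None:
    """TSV cluster report: cluster_index, representative, member, percent_identity."""
    with open(path, "w") as fh:
        fh.write("cluster_index\trepresentative\tmember\tpercent_identity\n")
        for i, (rep, members) in enumerate(
            zip(clusters.representatives, clusters.clusters)
        ):
            rep_seq = chains_by_id[rep].sequence
            for m in members:
                seq = chains_by_id[m].sequence
                ident = 100.0 if seq == rep_seq else align_identity(rep_seq, seq).percent_identity
                fh.write(f"{i}\t{rep}\t{m}\t{ident:.1f}\n")
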