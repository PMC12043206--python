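"""Isolate dereplication, greedy 97% OTU clustering, and ASV matching.

Identity uses a semi-global alignment (end gaps free; match +1, mismatch -1,
gap -2) and is counted over aligned columns excluding terminal gaps; N never
counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align, SeqIO

_VALID = set("ACGTN")


@dataclass
class SequenceRecord:
    id: str
    seq: str
    size: int = 1

    def __post_init__(self):
        seq = self.seq.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters: {sorted(bad)}")
        self.seq = seq


def read_fasta(path) -> list:
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id};size={rec.size}\n{rec.seq}\n")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # end gaps free: V3-V4 amplicons may differ slightly in trimming
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # biopython < 1.88
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord, min_coverage: float = 0.5) -> float:
    """Fraction of matching columns over the end-gap-trimmed alignment.

    With free end gaps, unrelated sequences optimally align as tiny perfect
    overlaps; an alignment covering less than ``min_coverage`` of the
    shorter sequence is therefore treated as non-homologous (identity 0).
    """
    if a.seq == b.seq and "N" not in a.seq:
        return 1.0
    # canonical argument order: co-optimal alignments may differ in identity,
    # and symmetry of the result matters more than which tie is reported
    if b.seq < a.seq:
        a, b = b, a
    aln = _ALIGNER.align(a.seq, b.seq)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    first1 = len(s1) - len(s1.lstrip("-"))
    first2 = len(s2) - len(s2.lstrip("-"))
    last1 = len(s1.rstrip("-"))
    last2 = len(s2.rstrip("-"))
    start, end = max(first1, first2), min(last1, last2)
    if end <= start:
        return 0.0
    if (end - start) < min_coverage * min(len(a.seq), len(b.seq)):
        return 0.0
    matches = sum(
        1
        for c1, c2 in zip(s1[start:end], s2[start:end])
        if c1 == c2 and c1 in "ACGT"
    )
    return matches / (end - start)


@dataclass
class OtuCluster:
    centroid: SequenceRecord
    members: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(m.size for m in self.members)


def dereplicate(seqs) -> list:
    """Collapse exact duplicates, accumulating sizes; first id wins."""
    by_seq: dict = {}
    order = []
    for rec in seqs:
        if rec.seq in by_seq:
            by_seq[rec.seq].size += rec.size
        else:
            by_seq[rec.seq] = SequenceRecord(rec.id, rec.seq, rec.size)
            order.append(rec.seq)
    return [by_seq[s] for s in order]


def dereplicate_and_cluster(seqs, id_min: float = 0.97) -> list:
    """Greedy centroid clustering (UPARSE convention) at ``id_min``.

    Unique sequences are processed in decreasing size order (ties by id);
    each joins the best centroid with identity >= id_min (inclusive
    boundary), else founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    unique = dereplicate(seqs)
    unique.sort(key=lambda r: (-r.size, r.id))
    clusters: list = []
    for rec in unique:
        best, best_id = None, -1.0
        for cl in clusters:
            ident = pairwise_identity(rec, cl.centroid)
            if ident > best_id:
                best, best_id = cl, ident
        if best is not None and best_id >= id_min:
            best.members.append(rec)
        else:
            clusters.append(OtuCluster(centroid=rec, members=[rec]))
    return clusters


def cluster_frame(clusters) -> pd.DataFrame:
    """UC-like membership table."""
    rows = []
    for k, cl in enumerate(clusters):
        for rec in cl.members:
            rows.append(
                {
                    "cluster": k,
                    "member": rec.id,
                    "size": rec.size,
                    "centroid": cl.centroid.id,
                    "is_centroid": rec.id == cl.centroid.id,
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "member", "size", "centroid", "is_centroid"])


def match_asvs(asvs, clusters, id_min: float = 0.97) -> pd.DataFrame:
    """Best-identity cluster representative per ASV.

    Ties break by larger cluster size, then lexicographic representative id.
    ``matched`` requires identity >= id_min.
    """
    if not asvs or not clusters:
        raise ValueError("both ASV and representative sets must be non-empty")
    rows = []
    for asv in asvs:
        best = None
        for cl in clusters:
            ident = pairwise_identity(asv, cl.centroid)
            key = (ident, cl.size, _neg_lex(cl.centroid.id))
            if best is None or key > best[0]:
                best = (key, cl)
        (ident, _, _), cl = best
        rows.append(
            {
                "asv": asv.id,
                "best_hit": cl.centroid.id,
                "identity": ident,
                "matched": ident >= id_min,
            }
        )
    return pd.DataFrame(rows, columns=["asv", "best_hit", "identity", "matched"])


class _neg_lex(str):
    """Orders lexicographically smaller strings as larger (for max() keys)."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
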