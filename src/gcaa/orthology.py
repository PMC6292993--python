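"""Reciprocal-best-hit orthology between a reference and target proteome.

Hits are scored with affine-gap pairwise alignment (BLOSUM62, gap open 11,
extend 1 — BLAST-like defaults) via Biopython's PairwiseAligner, or read
from pre-computed BLAST tabular (outfmt 6) files. A pair is an ortholog
call iff each gene is the other's best-scoring hit and it passes the
identity / coverage (and, in BLAST mode, E-value) thresholds.

Coverage (``aligned_fraction``) is measured relative to the reference-role
sequence by default; which sequence anchors the 80%-residues criterion is
configurable since either convention is defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import GeneRecord

DEFAULT_IDENTITY_MIN = 30.0  # percent over aligned columns
DEFAULT_COVERAGE_MIN = 0.80  # fraction of reference residues aligned
DEFAULT_EVALUE_MAX = 1e-5  # BLAST-tabular mode only


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    identity_percent: float
    aligned_fraction: float
    aligned_query: str
    aligned_subject: str


@dataclass(frozen=True)
class OrthologPair:
    ref_gene: GeneRecord
    target_gene: GeneRecord
    alignment: AlignmentResult
    evalue: float | None = None


def make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    mode: str = "local",
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_proteins(
    a: str,
    b: str,
    aligner: Align.PairwiseAligner | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Pairwise protein alignment (local by default) with summary statistics.

    Identity is computed over aligned (both-residue) columns; coverage is the
    fraction of the *first* sequence's residues inside the alignment. Ties in
    the dynamic program are broken deterministically by taking the first
    alignment in Biopython's canonical traceback order.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(a, b)
    best = alignments[0]
    ga, gb = str(best[0]), str(best[1])
    matches = aligned = 0
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            aligned += 1
            if ca == cb:
                matches += 1
    identity = 100.0 * matches / aligned if aligned else 0.0
    covered = sum(1 for c in ga if c != "-")
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=float(best.score),
        identity_percent=identity,
        aligned_fraction=covered / len(a),
        aligned_query=ga,
        aligned_subject=gb,
    )


def _check_unique_ids(genes: Sequence[GeneRecord], label: str) -> None:
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})[0]
        raise ValueError(f"duplicate gene_id {dup!r} in {label} proteome")


def _best_hits(
    queries: Sequence[GeneRecord],
    subjects: Sequence[GeneRecord],
    aligner: Align.PairwiseAligner,
) -> dict[str, str]:
    """Best-scoring subject per query; ties broken by smallest subject id."""
    best: dict[str, str] = {}
    for q in queries:
        top_score, top_id = None, None
        for s in subjects:
            if s.gene_id == q.gene_id and s.genome_id == q.genome_id:
                continue  # self-hit in a self-comparison
            score = aligner.score(q.protein, s.protein)
            if (
                top_score is None
                or score > top_score
                or (score == top_score and s.gene_id < top_id)
            ):
                top_score, top_id = score, s.gene_id
        if top_id is not None:
            best[q.gene_id] = top_id
    return best


def reciprocal_best_hits(
    ref: Sequence[GeneRecord],
    target: Sequence[GeneRecord],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    aligner: Align.PairwiseAligner | None = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    A pair (r, t) is kept iff t is r's best hit among targets, r is t's best
    hit among refs, identity >= ``identity_min`` percent, and at least
    ``coverage_min`` of the reference residues are aligned. Output is sorted
    by reference gene_id.
    """
    if not ref or not target:
        raise ValueError("both proteomes must be non-empty")
    _check_unique_ids(ref, "reference")
    _check_unique_ids(target, "target")
    if aligner is None:
        aligner = make_aligner()
    fwd = _best_hits(ref, target, aligner)
    rev = _best_hits(target, ref, aligner)
    by_id = {t.gene_id: t for t in target}
    pairs = []
    for r in sorted(ref, key=lambda g: g.gene_id):
        t_id = fwd.get(r.gene_id)
        if t_id is None or rev.get(t_id) != r.gene_id:
            continue
        t = by_id[t_id]
        aln = align_proteins(
            r.protein, t.protein, aligner, query_id=r.gene_id, subject_id=t_id
        )
        if aln.identity_percent >= identity_min and aln.aligned_fraction >= coverage_min:
            pairs.append(OrthologPair(ref_gene=r, target_gene=t, alignment=aln))
    return pairs


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) support

@dataclass(frozen=True)
class BlastHit:
    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular (outfmt 6) file."""
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(
                BlastHit(
                    qseqid=fields[0],
                    sseqid=fields[1],
                    pident=float(fields[2]),
                    length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def best_blast_hits(hits: Sequence[BlastHit]) -> dict[str, BlastHit]:
    """Best hit per query: max bitscore, ties by min evalue then sseqid."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.qseqid)
        if (
            cur is None
            or h.bitscore > cur.bitscore
            or (h.bitscore == cur.bitscore and (h.evalue, h.sseqid) < (cur.evalue, cur.sseqid))
        ):
            best[h.qseqid] = h
    return best


def reciprocal_best_hits_blast(
    fwd_hits: Sequence[BlastHit],
    rev_hits: Sequence[BlastHit],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    ref_lengths: dict[str, int] | None = None,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> list[tuple[str, str, BlastHit]]:
    """RBH pairs (ref_id, target_id, forward hit) from pre-computed BLAST tables.

    E-value and identity thresholds always apply; the coverage threshold
    applies when reference sequence lengths are supplied (alignment length /
    reference length, a tabular-output approximation).
    """
    fwd = best_blast_hits(fwd_hits)
    rev = best_blast_hits(rev_hits)
    pairs = []
    for r_id in sorted(fwd):
        hit = fwd[r_id]
        back = rev.get(hit.sseqid)
        if back is None or back.sseqid != r_id:
            continue
        if hit.evalue >= evalue_max or hit.pident < identity_min:
            continue
        if ref_lengths is not None:
            if r_id not in ref_lengths:
                warnings.warn(f"no length for reference {r_id}; skipping coverage check")
            elif hit.length / ref_lengths[r_id] < coverage_min:
                continue
        pairs.append((r_id, hit.sseqid, hit))
    return pairs
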