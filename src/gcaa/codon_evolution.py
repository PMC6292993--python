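"""Protein-guided codon alignment and NG86 Ka/Ks estimation.

The Nei–Gojobori (1986) counting method: each sense codon contributes
fractional synonymous (S) and nonsynonymous (N) site counts from its nine
single-nucleotide neighbours (changes creating a stop codon count as
nonsynonymous); observed differences in multi-hit codons are averaged over
all mutational orderings, excluding paths that pass through a stop codon
(falling back to all paths when every path is blocked); the raw proportions
pN = Nd/N and pS = Sd/S are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4)·ln(1 - 4p/3). The correction is undefined
for p >= 3/4 and is then reported as a flag, never a number.

A reader for PAML yn00 output is provided for parity checks against the
Yang–Nielsen (2000) method when PAML results are available.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
GAP_CODON = "---"
_BASES = "ACGT"


@dataclass(frozen=True)
class CodonAlignment:
    """Two equal-length lists of codon-or-gap ('---') tokens."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignments must have equal length")


@dataclass(frozen=True)
class KaKsResult:
    """NG86 site/difference counts and Jukes–Cantor-corrected rates.

    ``ka``/``ks`` are None when the correction is undefined (p >= 3/4);
    the corresponding flag records why.
    """

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    n_codons: int
    ka_flag: str = ""
    ks_flag: str = ""


def back_translate(
    aligned_a: str, aligned_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Map a gapped protein alignment back onto the source codons.

    Each residue column becomes the corresponding codon of its CDS; each gap
    column becomes '---'. The CDS must be stop-stripped and exactly 3x the
    ungapped protein length, and each codon must translate to its aligned
    residue.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned protein strings must have equal length")
    out: dict[str, list[str]] = {"a": [], "b": []}
    for label, aligned, cds in (("a", aligned_a, cds_a), ("b", aligned_b, cds_b)):
        n_res = sum(1 for c in aligned if c != "-")
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"sequence {label}: CDS length {len(cds)} is not 3 x "
                f"{n_res} aligned residues"
            )
        pos = 0
        for col, residue in enumerate(aligned):
            if residue == "-":
                out[label].append(GAP_CODON)
                continue
            codon = cds[3 * pos : 3 * pos + 3]
            aa = CODON_TO_AA.get(codon)
            if aa != residue:
                raise ValueError(
                    f"sequence {label}: codon {codon!r} at column {col + 1} "
                    f"translates to {aa!r}, alignment has {residue!r}"
                )
            out[label].append(codon)
            pos += 1
    return CodonAlignment(tuple(out["a"]), tuple(out["b"]))


@lru_cache(maxsize=None)
def count_codon_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts (S, N) of one sense codon.

    Each of the nine single-nucleotide neighbours is classified; changes to
    stop codons are nonsynonymous. S + N = 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if CODON_TO_AA.get(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational orderings.

    Orderings that pass through a stop codon are excluded; if every ordering
    is blocked, all are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        steps = []
        blocked = False
        for i in order:
            nxt = current[:i] + codon_b[i] + current[i + 1 :]
            steps.append((current, nxt))
            if nxt in STOP_CODONS:
                blocked = True
            current = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for frm, to in steps:
            if CODON_TO_AA.get(frm) == CODON_TO_AA.get(to):
                syn += 1
            else:
                nonsyn += 1
    k = len(usable)
    return syn / k, nonsyn / k


def _jc_correct(p: float) -> tuple[float | None, str]:
    if p >= 0.75:
        return None, f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
    return -0.75 * math.log1p(-4.0 * p / 3.0), ""


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for one pairwise codon alignment.

    Columns with a gap or a non-sense codon in either sequence are excluded
    (pairwise deletion). Site counts are averaged over the two sequences.
    """
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    n_codons = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if GAP_CODON in (ca, cb) or ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue
        n_codons += 1
        sa, na = count_codon_sites(ca)
        sb, nb = count_codon_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        syn, nonsyn = _path_counts(ca, cb)
        sd += syn
        nd += nonsyn
    if n_codons == 0:
        raise ValueError("no comparable (gap-free sense-codon) columns")
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka, ka_flag = _jc_correct(pn)
    ks, ks_flag = _jc_correct(ps)
    if ka_flag or ks_flag:
        warnings.warn((ka_flag or ks_flag))
    return KaKsResult(
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        n_codons=n_codons,
        ka_flag=ka_flag,
        ks_flag=ks_flag,
    )


def kaks_from_genes(cds_a: str, cds_b: str, aligned_a: str, aligned_b: str) -> KaKsResult:
    """Convenience: back-translate a protein alignment and run NG86."""
    return ng86_kaks(back_translate(aligned_a, aligned_b, cds_a, cds_b))


# ---------------------------------------------------------------------------
# PAML yn00 output reader (parity input only)

_YN_HEADER = re.compile(r"\(B\)\s+Yang\s*&\s*Nielsen\s*\(2000\)", re.IGNORECASE)
_YN_ROW = re.compile(
    r"^\s*(\d+)\s+(\d+)\s+"  # seq indices
    r"([\d.]+)\s+([\d.]+)\s+([\d.-]+)\s+([\d.-]+)\s+([\d.-]+)\s+"  # S N t kappa omega
    r"([\d.-]+)\s*\+-\s*[\d.-]+\s+([\d.-]+)\s*\+-\s*[\d.-]+"  # dN +- SE dS +- SE
)


def read_yn00(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Parse dN (Ka) and dS (Ks) pairs from PAML yn00 main output.

    Reads the Yang & Nielsen (2000) block; sequence indices are mapped to
    names via the numbered name list yn00 prints, falling back to the indices
    themselves. Returns {(name_i, name_j): (ka, ks)}.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    if not _YN_HEADER.search(text):
        raise ValueError(f"{path}: no Yang & Nielsen (2000) result block found")
    names: dict[int, str] = {}
    # "2 (geneB) vs. 1 (geneA)" pairwise-comparison headers
    for m in re.finditer(r"(\d+)\s+\((\S+?)\)", text):
        names.setdefault(int(m.group(1)), m.group(2))
    # bare numbered name lists
    for m in re.finditer(r"^\s*(\d+)\s+([A-Za-z_]\S*)\s*$", text, flags=re.MULTILINE):
        names.setdefault(int(m.group(1)), m.group(2))
    block = text[_YN_HEADER.search(text).start() :]
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for line in block.splitlines():
        m = _YN_ROW.match(line)
        if m:
            i, j = int(m.group(1)), int(m.group(2))
            dn, ds = float(m.group(8)), float(m.group(9))
            key = (names.get(i, str(i)), names.get(j, str(j)))
            out[key] = (dn, ds)
    if not out:
        raise ValueError(f"{path}: Yang & Nielsen block contains no pairwise rows")
    return out
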