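"""Gene records, FASTA input/output, and gene-name lists.

A :class:`GeneRecord` couples a protein-coding nucleotide sequence (CDS)
with its translation and the identifiers needed to track it across genomes.
Terminal stop codons are stripped on construction; internal stops and
frame errors are rejected, since every downstream step (codon alignment,
back-translation, site counting) assumes a clean coding frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"
_NUC_RE = re.compile(r"^[ACGT]+$")
_AA_RE = re.compile(f"^[{STANDARD_AAS}]+$")


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: CDS, translation, and identity.

    ``cds`` is stop-stripped and validated at construction time via
    :func:`make_gene_record`; instances built directly bypass validation.
    """

    gene_id: str
    genome_id: str
    gene_name: str
    cds: str
    protein: str


def translate_cds(cds: str) -> str:
    """Translate a stop-stripped CDS under the standard genetic code."""
    return str(Seq(cds).translate(table=1))


def strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def make_gene_record(
    gene_id: str,
    genome_id: str,
    gene_name: str,
    cds: str,
    protein: str | None = None,
) -> GeneRecord:
    """Validate and build a :class:`GeneRecord`.

    Strips one terminal stop codon, requires an in-frame ACGT-only CDS with
    no internal stop, and checks the translation against ``protein`` when
    given (otherwise derives it).
    """
    cds = cds.upper()
    if not cds:
        raise ValueError(f"{gene_id}: empty CDS")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(
            f"{gene_id}: non-ACGT character {sorted(bad)[0]!r} in CDS"
        )
    cds = strip_terminal_stop(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not a multiple of 3")
    if not cds:
        raise ValueError(f"{gene_id}: CDS is a bare stop codon")
    aa = translate_cds(cds)
    if "*" in aa:
        pos = aa.index("*")
        raise ValueError(f"{gene_id}: internal stop codon at codon {pos + 1}")
    if protein is not None and aa != protein.upper():
        raise ValueError(f"{gene_id}: CDS translation does not match protein")
    return GeneRecord(gene_id, genome_id, gene_name, cds, aa)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file; ids are the first whitespace-delimited header token."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqrecs = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    SeqIO.write(seqrecs, str(path), "fasta")


def read_gene_records(
    cds_path: str | Path,
    genome_id: str,
    protein_path: str | Path | None = None,
) -> list[GeneRecord]:
    """Load GeneRecords from a CDS FASTA (and optional protein FASTA).

    FASTA ids are taken as gene names; gene_id is ``<genome>|<name>``.
    When a protein file is given, its sequences must match the translations.
    """
    proteins = dict(read_fasta(protein_path)) if protein_path else {}
    out = []
    for name, cds in read_fasta(cds_path):
        out.append(
            make_gene_record(
                f"{genome_id}|{name}", genome_id, name, cds, proteins.get(name)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene-name lists

@dataclass(frozen=True)
class GeneListIntersection:
    list_a_name: str
    list_b_name: str
    members: tuple[str, ...]
    n_a: int
    n_b: int

    @property
    def n_common(self) -> int:
        return len(self.members)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene name per line; '#' starts a comment; names case-normalized."""
    names = []
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip().lower()
        if name:
            names.append(name)
    return names


def intersect_gene_lists(
    a: Sequence[str], b: Sequence[str], name_a: str = "a", name_b: str = "b"
) -> GeneListIntersection:
    """Exact-match intersection after whitespace/case normalization."""
    if not a or not b:
        raise ValueError("gene lists must be non-empty")
    sa = {x.strip().lower() for x in a}
    sb = {x.strip().lower() for x in b}
    return GeneListIntersection(
        name_a, name_b, tuple(sorted(sa & sb)), len(sa), len(sb)
    )
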