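"""Simulator of homologous CDS families under GC-biased codon evolution.

Each gene family starts from an ancestor drawn from the stationary codon
distribution of an independent-site nucleotide model with a chosen
equilibrium GC fraction (stop codons rejected). Each descendant genome
evolves the ancestor toward its own mutational GC target: proposals pick a
site uniformly and a replacement base from the genome's stationary
distribution; proposals creating a stop codon are rejected; nonsynonymous
proposals are accepted with probability omega (purifying selection proxy),
synonymous ones always. Branch length is measured in accepted
substitutions per nucleotide site, so the ground-truth event ledger is
exact and the descendant can be replayed from the ancestor.

This is the test harness standing in for a large comparative-genomics
download: it reproduces the GC spread across genomes and its coupling to
amino-acid composition, not genome structure, codon-usage selection,
indels, or shared phylogenetic history (descendants form a star).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .codon_evolution import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, count_codon_sites
from .records import GeneRecord, make_gene_record, write_fasta

_BASES = np.array(list("ACGT"))
REFERENCE_GENOME_ID = "REF"


@dataclass(frozen=True)
class SimParams:
    """Study-level simulation parameters.

    gc_targets are mutational-equilibrium GC fractions per target genome;
    when omitted they span ``gc_span`` evenly. The reference genome evolves
    toward ``reference_gc_target`` (the low-GC reference-organism role).
    """

    n_codons: int = 150
    n_genomes: int = 30
    n_families: int = 20
    reference_gc_target: float = 0.33
    gc_targets: tuple[float, ...] | None = None
    gc_span: tuple[float, float] = (0.30, 0.70)
    omega: float = 0.2
    branch_length: float = 0.15
    divergence_slope: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 < self.reference_gc_target < 1:
            raise ValueError("reference_gc_target must be in (0,1)")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must be in [0,1]")
        if self.branch_length < 0:
            raise ValueError("branch_length must be >= 0")
        if self.divergence_slope < 0:
            raise ValueError("divergence_slope must be >= 0")
        if self.gc_targets is not None:
            if len(self.gc_targets) != self.n_genomes:
                raise ValueError("gc_targets length must equal n_genomes")
            if not all(0 < g < 1 for g in self.gc_targets):
                raise ValueError("gc_targets must be in (0,1)")

    def resolved_gc_targets(self) -> tuple[float, ...]:
        if self.gc_targets is not None:
            return tuple(self.gc_targets)
        lo, hi = self.gc_span
        return tuple(np.linspace(lo, hi, self.n_genomes))

    def genome_branch_length(self, gc_target: float) -> float:
        """Per-genome divergence: base branch length plus a term growing with
        the genome's mutational GC displacement from the reference.

        Lineages whose composition must travel farther fix more substitutions
        over the same evolutionary time; ``divergence_slope`` (substitutions
        per site per unit GC displacement) encodes that coupling and is the
        mechanism behind GC-dependent divergence across genomes.
        """
        return self.branch_length + self.divergence_slope * abs(
            gc_target - self.reference_gc_target
        )


@dataclass(frozen=True)
class SubstitutionEvent:
    site: int
    from_base: str
    to_base: str
    synonymous: bool


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth ledger for one descendant."""

    syn_count: int
    nonsyn_count: int
    true_ks: float  # accepted synonymous substitutions per ancestral S site
    true_ka: float  # accepted nonsynonymous substitutions per ancestral N site
    events: tuple[SubstitutionEvent, ...]


@dataclass(frozen=True)
class EvolvedFamily:
    gene_name: str
    ancestor: GeneRecord
    descendants: tuple[GeneRecord, ...]
    truth: dict[str, TruthRecord] = field(default_factory=dict)


def _base_probs(gc_target: float) -> np.ndarray:
    g = gc_target
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T


def _expected_gc_given_sense(g: float) -> float:
    """Expected GC fraction of a codon drawn i.i.d. at base GC g, given non-stop."""
    probs = dict(zip("ACGT", _base_probs(g)))
    total = expect = 0.0
    for codon in SENSE_CODONS:
        p = probs[codon[0]] * probs[codon[1]] * probs[codon[2]]
        total += p
        expect += p * sum(c in "GC" for c in codon) / 3.0
    return expect / total


@lru_cache(maxsize=None)
def _calibrated_base_gc(gc_target: float) -> float:
    """Base-level GC whose non-stop conditional codon distribution has the
    requested expected GC. Stop codons are AT-rich, so rejecting them inflates
    realized GC slightly; this inverts that bias."""
    return float(brentq(lambda g: _expected_gc_given_sense(g) - gc_target, 1e-6, 1 - 1e-6))


def sample_ancestor(
    n_codons: int, gc_target: float, rng: np.random.Generator, gene_name: str = "anc"
) -> GeneRecord:
    """Draw an ancestor CDS of i.i.d. sense codons with expected GC = target."""
    if n_codons < 1:
        raise ValueError("n_codons must be positive")
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0,1)")
    probs = _base_probs(_calibrated_base_gc(gc_target))
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(_BASES, size=3, p=probs))
        if codon not in STOP_CODONS:
            codons.append(codon)
    cds = "".join(codons)
    return make_gene_record(f"anc|{gene_name}", "ANCESTOR", gene_name, cds)


def ancestral_site_counts(cds: str) -> tuple[float, float]:
    """NG86 (S, N) site totals of a stop-free CDS."""
    s = n = 0.0
    for i in range(0, len(cds), 3):
        si, ni = count_codon_sites(cds[i : i + 3])
        s += si
        n += ni
    return s, n


def evolve(
    ancestor_cds: str,
    gc_target: float,
    omega: float,
    branch_length: float,
    rng: np.random.Generator,
) -> tuple[str, tuple[SubstitutionEvent, ...]]:
    """Evolve a CDS until ``round(branch_length * length)`` substitutions fix.

    Proposal: uniform site, replacement base drawn from the stationary
    distribution conditioned on differing from the current base. Stops are
    rejected outright; nonsynonymous proposals are accepted with probability
    omega. Every accepted event is logged.
    """
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0,1)")
    if not 0 <= omega <= 1:
        raise ValueError("omega must be in [0,1]")
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    seq = np.array(list(ancestor_cds))
    length = len(seq)
    probs = _base_probs(gc_target)
    base_index = {b: i for i, b in enumerate(_BASES)}
    n_target = int(round(branch_length * length))
    events: list[SubstitutionEvent] = []
    while len(events) < n_target:
        site = int(rng.integers(length))
        cur = seq[site]
        p = probs.copy()
        p[base_index[cur]] = 0.0
        p /= p.sum()
        new = rng.choice(_BASES, p=p)
        c0 = 3 * (site // 3)
        codon = "".join(seq[c0 : c0 + 3])
        mutant = codon[: site - c0] + new + codon[site - c0 + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[codon] == CODON_TO_AA[mutant]
        if not synonymous and rng.random() >= omega:
            continue
        seq[site] = new
        events.append(SubstitutionEvent(site, cur, str(new), synonymous))
    return "".join(seq), tuple(events)


def replay_events(ancestor_cds: str, events: Sequence[SubstitutionEvent]) -> str:
    """Apply an event log to the ancestor; must reproduce the descendant."""
    seq = list(ancestor_cds)
    for ev in events:
        if seq[ev.site] != ev.from_base:
            raise ValueError(f"event at site {ev.site} does not match sequence state")
        seq[ev.site] = ev.to_base
    return "".join(seq)


def _genome_ids(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def simulate_family(
    gene_name: str, params: SimParams, rng: np.random.Generator
) -> EvolvedFamily:
    """One ancestor plus one descendant per genome (star phylogeny).

    Random-stream discipline: the ancestor is drawn first, then descendants
    in genome order (reference genome last), all from the single supplied
    generator.
    """
    ancestor = sample_ancestor(params.n_codons, params.reference_gc_target, rng, gene_name)
    s_anc, n_anc = ancestral_site_counts(ancestor.cds)
    descendants = []
    truth: dict[str, TruthRecord] = {}
    targets = list(zip(_genome_ids(params.n_genomes), params.resolved_gc_targets()))
    targets.append((REFERENCE_GENOME_ID, params.reference_gc_target))
    for genome_id, gc_target in targets:
        cds, events = evolve(
            ancestor.cds, gc_target, params.omega,
            params.genome_branch_length(gc_target), rng,
        )
        rec = make_gene_record(f"{genome_id}|{gene_name}", genome_id, gene_name, cds)
        descendants.append(rec)
        syn = sum(e.synonymous for e in events)
        nonsyn = len(events) - syn
        truth[genome_id] = TruthRecord(
            syn_count=syn,
            nonsyn_count=nonsyn,
            true_ks=syn / s_anc,
            true_ka=nonsyn / n_anc,
            events=events,
        )
    return EvolvedFamily(gene_name, ancestor, tuple(descendants), truth)


def simulate_study(
    params: SimParams, out_dir: str | Path | None = None, force: bool = False
) -> list[EvolvedFamily]:
    """Simulate all gene families; optionally write FASTA + truth + manifest.

    Families are seeded from spawned child seeds of ``params.seed``, so the
    study is reproducible as a whole and per family.
    """
    children = np.random.SeedSequence(params.seed).spawn(params.n_families)
    families = [
        simulate_family(f"fam{i:03d}", params, np.random.default_rng(child))
        for i, child in enumerate(children)
    ]
    if out_dir is not None:
        write_study(families, params, out_dir, force=force)
    return families


def write_study(
    families: Sequence[EvolvedFamily],
    params: SimParams,
    out_dir: str | Path,
    force: bool = False,
) -> None:
    """Write per-genome CDS/protein FASTA, a truth TSV, and a JSON manifest."""
    out = Path(out_dir)
    genomes_dir = out / "genomes"
    if genomes_dir.exists() and not force:
        raise FileExistsError(f"{genomes_dir} exists; pass force=True to overwrite")
    genomes_dir.mkdir(parents=True, exist_ok=True)
    genome_ids = sorted({d.genome_id for f in families for d in f.descendants})
    for gid in genome_ids:
        cds, prot = [], []
        for fam in families:
            for d in fam.descendants:
                if d.genome_id == gid:
                    cds.append((d.gene_name, d.cds))
                    prot.append((d.gene_name, d.protein))
        write_fasta(genomes_dir / f"{gid}_cds.fasta", cds)
        write_fasta(genomes_dir / f"{gid}_protein.fasta", prot)
    write_fasta(out / "ancestors_cds.fasta", [(f.gene_name, f.ancestor.cds) for f in families])
    lines = ["family\tgenome\tsyn_count\tnonsyn_count\ttrue_ka\ttrue_ks"]
    for fam in families:
        for gid in sorted(fam.truth):
            t = fam.truth[gid]
            lines.append(
                f"{fam.gene_name}\t{gid}\t{t.syn_count}\t{t.nonsyn_count}"
                f"\t{t.true_ka:.10g}\t{t.true_ks:.10g}"
            )
    (out / "truth.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "n_codons": params.n_codons,
        "n_genomes": params.n_genomes,
        "n_families": params.n_families,
        "reference_gc_target": params.reference_gc_target,
        "gc_targets": list(params.resolved_gc_targets()),
        "omega": params.omega,
        "branch_length": params.branch_length,
        "divergence_slope": params.divergence_slope,
        "seed": params.seed,
        "reference_genome": REFERENCE_GENOME_ID,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
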