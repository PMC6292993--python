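"""Pipeline orchestration: simulate/load -> orthologs -> Ka/Ks -> deviations
-> association models -> report.

Every stage is a pure function of (inputs, config, seed); re-running a
configuration over the same inputs produces byte-identical TSV outputs.
A JSON manifest records the config hash, seeds, and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .association_models import (
    GeneFamilyMatrix,
    MIN_FAMILY_ROWS,
    feature_table_tests,
    gene_gc_ka_table,
    pca_regression,
    ridge_fit,
)
from .codon_evolution import back_translate, ng86_kaks
from .deviation_stats import DEFAULT_BIN_EDGES, bin_by_delta_gc, deviation, records_frame
from .features import AA_ORDER, aa_composition, gc_content
from .orthology import align_proteins, make_aligner, reciprocal_best_hits
from .records import GeneRecord, read_gene_records
from .synthetic_data import REFERENCE_GENOME_ID, SimParams, simulate_study

log = logging.getLogger("gcaa.pipeline")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    out_dir: str = "gcaa_run"
    study_dir: str | None = None  # existing study; None = simulate into out_dir
    simulate: SimParams | None = field(default_factory=SimParams)
    reference_genome: str = REFERENCE_GENOME_ID
    orthology_mode: str = "rbh"  # "rbh" (full reciprocal search) or "name"
    identity_min: float = 30.0
    coverage_min: float = 0.80
    min_family_rows: int = MIN_FAMILY_ROWS
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    n_components: int = 6
    run_ridge: bool = True
    ridge_n_perm: int = 300
    seed: int = 0
    force: bool = False

    def validate(self) -> None:
        if self.orthology_mode not in ("rbh", "name"):
            raise ValueError("orthology_mode must be 'rbh' or 'name'")
        if not 0 <= self.identity_min <= 100:
            raise ValueError("identity_min out of range")
        if not 0 <= self.coverage_min <= 1:
            raise ValueError("coverage_min out of range")
        if self.min_family_rows < 3:
            raise ValueError("min_family_rows must be >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimParams(**sim) if isinstance(sim, dict) else sim
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_genomes(genomes_dir: str | Path) -> dict[str, list[GeneRecord]]:
    """Load every ``<genome>_cds.fasta`` (plus optional protein FASTA)."""
    genomes: dict[str, list[GeneRecord]] = {}
    gdir = Path(genomes_dir)
    for cds_path in sorted(gdir.glob("*_cds.fasta")):
        gid = cds_path.name[: -len("_cds.fasta")]
        prot_path = gdir / f"{gid}_protein.fasta"
        genomes[gid] = read_gene_records(
            cds_path, gid, prot_path if prot_path.exists() else None
        )
    if not genomes:
        raise FileNotFoundError(f"no *_cds.fasta files under {gdir}")
    return genomes


def _pairs_for_genome(
    ref: Sequence[GeneRecord],
    target: Sequence[GeneRecord],
    cfg: PipelineConfig,
    aligner,
) -> list[tuple[GeneRecord, GeneRecord, float, float]]:
    """(ref_gene, target_gene, identity, coverage) ortholog pairs."""
    if cfg.orthology_mode == "rbh":
        pairs = reciprocal_best_hits(
            ref, target, identity_min=cfg.identity_min,
            coverage_min=cfg.coverage_min, aligner=aligner,
        )
        return [
            (p.ref_gene, p.target_gene, p.alignment.identity_percent,
             p.alignment.aligned_fraction)
            for p in pairs
        ]
    by_name = {t.gene_name: t for t in target}
    out = []
    for r in sorted(ref, key=lambda g: g.gene_id):
        t = by_name.get(r.gene_name)
        if t is None:
            continue
        aln = align_proteins(r.protein, t.protein, aligner)
        if aln.identity_percent >= cfg.identity_min and aln.aligned_fraction >= cfg.coverage_min:
            out.append((r, t, aln.identity_percent, aln.aligned_fraction))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle under ``cfg.out_dir``.

    Returns a summary dict (also written as summary.json).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage: simulate or load
    if cfg.study_dir is None:
        if cfg.simulate is None:
            raise ValueError("either study_dir or simulate parameters required")
        log.info("simulating study into %s", out / "study")
        simulate_study(cfg.simulate, out / "study", force=cfg.force)
        study_dir = out / "study"
    else:
        study_dir = Path(cfg.study_dir)
    genomes = load_genomes(study_dir / "genomes")
    if cfg.reference_genome not in genomes:
        raise ValueError(f"reference genome {cfg.reference_genome!r} not in study")
    ref = genomes[cfg.reference_genome]
    ref_by_name = {g.gene_name: g for g in ref}
    targets = {gid: recs for gid, recs in genomes.items() if gid != cfg.reference_genome}
    log.info("loaded %d genomes x %d reference genes", len(genomes), len(ref))

    # stage: orthologs
    local_aligner = make_aligner(mode="local")
    global_aligner = make_aligner(mode="global")
    pair_rows, pairs = [], []
    for gid in sorted(targets):
        for r, t, ident, cov in _pairs_for_genome(ref, targets[gid], cfg, local_aligner):
            pairs.append((r, t))
            pair_rows.append(
                {"ref_gene": r.gene_id, "target_gene": t.gene_id,
                 "genome_id": gid, "gene_name": r.gene_name,
                 "identity": ident, "coverage": cov}
            )
    pairs_df = pd.DataFrame(pair_rows)
    pairs_df.to_csv(out / "orthologs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    log.info("orthologs: %d pairs", len(pairs))

    # stage: Ka/Ks (reference-anchored NG86)
    kaks_rows = []
    for r, t in pairs:
        aln = align_proteins(r.protein, t.protein, global_aligner)
        res = ng86_kaks(back_translate(aln.aligned_query, aln.aligned_subject, r.cds, t.cds))
        kaks_rows.append(
            {"gene_name": r.gene_name, "genome_id": t.genome_id,
             "n_sites": res.n_sites, "s_sites": res.s_sites,
             "nd": res.nd, "sd": res.sd, "pn": res.pn, "ps": res.ps,
             "ka": res.ka, "ks": res.ks,
             "flags": ";".join(f for f in (res.ka_flag, res.ks_flag) if f)}
        )
    kaks_df = pd.DataFrame(kaks_rows)
    kaks_df.to_csv(out / "kaks.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # per-target composition/GC profiles (input to the association stage)
    prof_rows = []
    for r, t in pairs:
        row = {"gene_name": r.gene_name, "genome_id": t.genome_id,
               "gc_percent": gc_content(t.cds).gc_percent}
        row.update({f"f_{aa}": v for aa, v in aa_composition(t.protein).items()})
        prof_rows.append(row)
    pd.DataFrame(prof_rows).to_csv(out / "profiles.tsv", sep="\t", index=False,
                                   float_format=_FLOAT_FMT)

    # stage: deviations
    dev_records = [deviation(t, ref_by_name[r.gene_name]) for r, t in pairs]
    dev_df = records_frame(dev_records)
    dev_df.to_csv(out / "deviations.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    binned = bin_by_delta_gc(dev_records, cfg.bin_edges)
    binned.table.to_csv(out / "deviation_bins.tsv", sep="\t", float_format=_FLOAT_FMT)

    # stage: associations
    families = _assemble_families(pairs, kaks_df)
    gc_ka = gene_gc_ka_table(families, min_rows=cfg.min_family_rows)
    gc_ka.to_csv(out / "gc_ka_table.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    pcr_rows, ridge_rows = [], []
    for fam in families:
        if len(fam.fit_data) < max(cfg.n_components + 2, cfg.min_family_rows):
            continue
        p = pca_regression(fam, n_components=cfg.n_components)
        pcr_rows.append(
            {"gene_name": fam.gene_name, "method": "pcr", "r_squared": p.r_squared,
             "pc1_gc_r": p.pc1_gc_correlation,
             "positive": ",".join(sorted(p.pc1_positive_aas)),
             "negative": ",".join(sorted(p.pc1_negative_aas))}
        )
        if cfg.run_ridge and len(fam.fit_data) >= 10:
            rg = ridge_fit(fam, n_perm=cfg.ridge_n_perm, seed=cfg.seed)
            ridge_rows.append(
                {"gene_name": fam.gene_name, "method": "ridge", "r_squared": rg.r_squared,
                 "positive": ",".join(sorted(rg.selected_positive)),
                 "negative": ",".join(sorted(rg.selected_negative))}
            )
    models_df = pd.DataFrame(pcr_rows + ridge_rows)
    models_df.to_csv(out / "models.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    feats = feature_table_tests()
    feats.correlations.to_csv(out / "feature_correlations.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)

    # stage: report
    summary = {
        "gcaa_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_genomes": len(genomes),
        "n_reference_genes": len(ref),
        "n_ortholog_pairs": len(pairs),
        "n_kaks_rows": len(kaks_df),
        "n_deviation_records": len(dev_records),
        "n_families_tested": int(len(gc_ka)),
        "frac_families_positive_significant": (
            float(((gc_ka["r"] > 0) & (gc_ka["p"] < 0.05)).mean()) if len(gc_ka) else None
        ),
        "mean_abs_pc1_gc_r": (
            float(pd.DataFrame(pcr_rows)["pc1_gc_r"].abs().mean()) if pcr_rows else None
        ),
        "cost_contrast_p": feats.cost_contrast_p,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("report written to %s", out)
    return summary


def _assemble_families(
    pairs: Sequence[tuple[GeneRecord, GeneRecord]], kaks_df: pd.DataFrame
) -> list[GeneFamilyMatrix]:
    """Per-gene matrices of target composition, GC percent, and Ka."""
    if len(kaks_df) == 0:
        return []
    ka_map = {
        (row.gene_name, row.genome_id): row.ka for row in kaks_df.itertuples()
    }
    rows_by_gene: dict[str, list[dict]] = {}
    for r, t in pairs:
        prof = aa_composition(t.protein)
        row = {f"f_{aa}": prof[aa] for aa in AA_ORDER}
        row["gc_percent"] = gc_content(t.cds).gc_percent
        row["ka"] = ka_map.get((r.gene_name, t.genome_id))
        rows_by_gene.setdefault(r.gene_name, []).append(row)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # size-floor warnings surface downstream
        return [
            GeneFamilyMatrix(name, pd.DataFrame(rows))
            for name, rows in sorted(rows_by_gene.items())
        ]
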