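"""Amino-acid and GC deviations of homologs relative to a reference gene.

The deviation of amino acids (dAA) is the composition vector of a target
homolog minus that of the reference homolog (positive = gained during
evolution away from the reference); the deviation of GC (dGC) is the
difference in gene GC percent, in percentage points. Group sums over
GC-rich / AT-rich / old / new amino-acid sets, binning by dGC, group
gain/loss contrasts, and per-record correlations of dAA against
amino-acid features are the analyses built on these records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import AA_ORDER, AAFeatureTable, aa_composition, default_feature_table, gc_content
from .records import GeneRecord

DEFAULT_BIN_EDGES = (0.0, 5.0, 10.0)


@dataclass(frozen=True)
class DeviationRecord:
    gene_name: str
    genome_id: str
    delta_gc: float
    delta_aa: tuple[float, ...]  # canonical (alphabetical) amino-acid order
    group_sums: Mapping[str, float] = field(default_factory=dict)

    def delta(self, aa: str) -> float:
        return self.delta_aa[AA_ORDER.index(aa)]


def group_sum(delta_aa: Sequence[float], members: Iterable[str]) -> float:
    return float(sum(delta_aa[AA_ORDER.index(aa)] for aa in members))


def deviation(
    target: GeneRecord,
    reference: GeneRecord,
    groups: Mapping[str, frozenset[str]] | None = None,
) -> DeviationRecord:
    """dAA and dGC of one target homolog relative to the reference gene."""
    if groups is None:
        groups = default_feature_table().default_groups
    prof_t = aa_composition(target.protein)
    prof_r = aa_composition(reference.protein)
    delta_aa = tuple(prof_t[aa] - prof_r[aa] for aa in AA_ORDER)
    delta_gc = gc_content(target.cds).gc_percent - gc_content(reference.cds).gc_percent
    sums = {name: group_sum(delta_aa, members) for name, members in groups.items()}
    return DeviationRecord(
        gene_name=target.gene_name,
        genome_id=target.genome_id,
        delta_gc=delta_gc,
        delta_aa=delta_aa,
        group_sums=sums,
    )


def records_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    """Flat table: genome, gene, delta_gc, 20 dAA columns, group sums."""
    rows = []
    for r in records:
        row = {"genome_id": r.genome_id, "gene_name": r.gene_name, "delta_gc": r.delta_gc}
        row.update({f"d_{aa}": v for aa, v in zip(AA_ORDER, r.delta_aa)})
        row.update(r.group_sums)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BinnedDeviation:
    bin_edges: tuple[float, ...]
    labels: tuple[str, ...]
    table: pd.DataFrame  # index = bin label; columns = n and per-group mean/sd


def bin_by_delta_gc(
    records: Sequence[DeviationRecord],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> BinnedDeviation:
    """Per-bin summary of group sums across dGC bins.

    Default edges (0, 5, 10) give the bins (-inf, 0), [0, 5), [5, 10),
    [10, inf) in percentage points. Empty bins have n = 0 and NaN summaries.
    """
    if not records:
        raise ValueError("no records to bin")
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    full = [-np.inf, *edges, np.inf]
    labels = tuple(
        f"[{lo:g},{hi:g})" if np.isfinite(lo) else f"(-inf,{hi:g})"
        for lo, hi in zip(full[:-1], full[1:])
    )
    frame = records_frame(records)
    group_cols = [c for c in frame.columns if c not in ("genome_id", "gene_name", "delta_gc") and not c.startswith("d_")]
    frame["bin"] = pd.cut(frame["delta_gc"], bins=full, labels=labels, right=False)
    out = {}
    for label in labels:
        sub = frame[frame["bin"] == label]
        row: dict[str, float] = {"n": len(sub)}
        for g in group_cols:
            row[f"{g}_mean"] = sub[g].mean() if len(sub) else np.nan
            row[f"{g}_sd"] = sub[g].std(ddof=1) if len(sub) > 1 else np.nan
        out[label] = row
    table = pd.DataFrame(out).T
    table["n"] = table["n"].astype(int)
    return BinnedDeviation(tuple(edges), labels, table)


@dataclass(frozen=True)
class ContrastSummary:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float


def gain_loss_contrast(
    records: Sequence[DeviationRecord],
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> ContrastSummary:
    """Welch t-test comparing pooled dAA values of two amino-acid groups.

    Values are pooled one per record per member amino acid (e.g. old
    {D,V,S,E,L,T} vs new {Q,H,C,W}).
    """
    ga, gb = frozenset(group_a), frozenset(group_b)
    if not ga or not gb or ga & gb:
        raise ValueError("groups must be non-empty and disjoint")
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    vals_a = [r.delta(aa) for r in records for aa in sorted(ga)]
    vals_b = [r.delta(aa) for r in records for aa in sorted(gb)]
    if np.var(vals_a) == 0 and np.var(vals_b) == 0:
        # e.g. all targets identical to the reference: no spread, no signal
        if np.mean(vals_a) != np.mean(vals_b):
            raise ValueError("degenerate variance: t-test undefined")
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(vals_a, vals_b, equal_var=False)
        t = float(res.statistic)
        p = float(res.pvalue)
    if np.isnan(t):
        raise ValueError("degenerate variance: t-test undefined")
    return ContrastSummary(
        mean_a=float(np.mean(vals_a)),
        mean_b=float(np.mean(vals_b)),
        n_a=len(vals_a),
        n_b=len(vals_b),
        t_statistic=t,
        p_value=p,
    )


def per_aa_order_correlation(
    records: Sequence[DeviationRecord],
    table: AAFeatureTable | None = None,
    features: Sequence[str] = ("recruit_order", "gc_class"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-record Pearson R between the 20 dAA values and feature vectors.

    Returns (per-record table with R and p per feature, summary of the
    fraction of records with p < 0.05 per feature). Records with a constant
    dAA vector are skipped with a warning.
    """
    if table is None:
        table = default_feature_table()
    rows = []
    for r in records:
        da = np.asarray(r.delta_aa)
        if np.allclose(da, da[0]):
            warnings.warn(
                f"record {r.genome_id}/{r.gene_name}: constant deviation vector, skipped"
            )
            continue
        row = {"genome_id": r.genome_id, "gene_name": r.gene_name}
        for feat in features:
            vec = np.asarray(table.vector(feat), dtype=float)
            res = stats.pearsonr(da, vec)
            row[f"{feat}_r"] = float(res.statistic)
            row[f"{feat}_p"] = float(res.pvalue)
        rows.append(row)
    frame = pd.DataFrame(rows)
    summary = {
        feat: float((frame[f"{feat}_p"] < 0.05).mean()) if len(frame) else float("nan")
        for feat in features
    }
    return frame, summary
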