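"""Sequence descriptors and the amino-acid feature table.

GC content (overall and per codon position), amino-acid composition
profiles, the coefficient of variation, and the fixed per-amino-acid
feature table: GC class of the encoding codons (0 = AT-rich, 1 =
intermediate, 2 = GC-rich), recruitment order into the genetic code
(Trifonov consensus rank, 1 = oldest), biosynthetic cost (ATP
equivalents, E. coli scale), and molecular weight (Da).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .records import STANDARD_AAS

AA_ORDER: tuple[str, ...] = tuple(STANDARD_AAS)

FEATURE_NAMES = ("gc_class", "recruit_order", "cost", "mol_weight")


@dataclass(frozen=True)
class GCStats:
    """GC percentages of a CDS, overall and per codon position (0-100)."""

    gc_percent: float
    gc1: float | None
    gc2: float | None
    gc3: float | None


def gc_content(cds: str) -> GCStats:
    """GC percentage of a nucleotide sequence, with codon-position breakdown.

    Positional values gc1/gc2/gc3 require the length to be a multiple of 3
    and are ``None`` otherwise. Ambiguity codes are rejected.
    """
    if not cds:
        raise ValueError("empty input")
    cds = cds.upper()
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character {sorted(bad)[0]!r} in sequence")
    total = 100.0 * sum(c in "GC" for c in cds) / len(cds)
    if len(cds) % 3:
        return GCStats(total, None, None, None)
    pos = []
    for i in range(3):
        sub = cds[i::3]
        pos.append(100.0 * sum(c in "GC" for c in sub) / len(sub))
    return GCStats(total, *pos)


def aa_composition(protein: str, nonstandard: str = "drop") -> dict[str, float]:
    """Amino-acid frequency profile: count/length over the 20 standard letters.

    Non-standard letters (B, J, O, U, X, Z) are dropped with a warning by
    default; pass ``nonstandard='error'`` to reject them.
    """
    if not protein:
        raise ValueError("empty input")
    protein = protein.upper()
    kept = [c for c in protein if c in STANDARD_AAS]
    if len(kept) != len(protein):
        extra = sorted(set(protein) - set(STANDARD_AAS))
        if nonstandard == "error":
            raise ValueError(f"non-standard amino acid(s): {extra}")
        warnings.warn(f"dropping non-standard amino acid(s): {extra}")
        if not kept:
            raise ValueError("no standard amino acids in input")
    n = len(kept)
    counts = {aa: 0 for aa in AA_ORDER}
    for c in kept:
        counts[c] += 1
    return {aa: counts[aa] / n for aa in AA_ORDER}


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    vals = [float(v) for v in values]
    n = len(vals)
    if n < 2:
        raise ValueError("CV requires at least 2 values")
    mean = sum(vals) / n
    if mean == 0:
        raise ValueError("CV undefined: mean is zero")
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return math.sqrt(var) / mean


class AAFeatureTable:
    """The 20-row amino-acid feature table and its derived groupings.

    Groups:
      * ``gc_rich``  — gc_class == 2: {A, G, P, R}
      * ``at_rich``  — gc_class == 0: {F, I, K, M, N, Y}
      * ``old``      — intermediate GC class recruited early (order <= 10):
        {D, V, S, E, L, T}
      * ``new``      — intermediate GC class recruited late (order >= 11):
        {Q, H, C, W}
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"aa", *FEATURE_NAMES}
        if not required.issubset(frame.columns):
            raise ValueError(f"feature table must have columns {sorted(required)}")
        frame = frame.set_index("aa") if "aa" in frame.columns else frame
        if sorted(frame.index) != sorted(AA_ORDER):
            raise ValueError("feature table must have exactly the 20 standard amino acids")
        if sorted(frame["recruit_order"]) != list(range(1, 21)):
            raise ValueError("recruit_order must be a permutation of 1..20")
        if not set(frame["gc_class"]) <= {0, 1, 2}:
            raise ValueError("gc_class values must be in {0,1,2}")
        if (frame["cost"] <= 0).any() or (frame["mol_weight"] <= 0).any():
            raise ValueError("cost and mol_weight must be positive")
        self.frame = frame.loc[list(AA_ORDER)]

    @classmethod
    def load(cls, path=None) -> "AAFeatureTable":
        """Load the packaged feature TSV (or a user-supplied one)."""
        if path is None:
            with resources.files("gcaa.data").joinpath("aa_features.tsv").open() as fh:
                frame = pd.read_csv(fh, sep="\t")
        else:
            frame = pd.read_csv(path, sep="\t")
        return cls(frame)

    def value(self, aa: str, feature: str) -> float:
        if feature not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {feature!r}")
        if aa not in self.frame.index:
            raise KeyError(f"unknown amino acid {aa!r}")
        return float(self.frame.at[aa, feature])

    def vector(self, feature: str) -> list[float]:
        """Feature values in canonical (alphabetical) amino-acid order."""
        if feature not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {feature!r}")
        return [float(v) for v in self.frame[feature]]

    def group(self, name: str) -> frozenset[str]:
        f = self.frame
        if name == "gc_rich":
            members = f.index[f["gc_class"] == 2]
        elif name == "at_rich":
            members = f.index[f["gc_class"] == 0]
        elif name == "old":
            members = f.index[(f["gc_class"] == 1) & (f["recruit_order"] <= 10)]
        elif name == "new":
            members = f.index[(f["gc_class"] == 1) & (f["recruit_order"] >= 11)]
        else:
            raise KeyError(f"unknown group {name!r}")
        return frozenset(members)

    @property
    def default_groups(self) -> dict[str, frozenset[str]]:
        return {g: self.group(g) for g in ("gc_rich", "at_rich", "old", "new")}


_DEFAULT_TABLE: AAFeatureTable | None = None


def default_feature_table() -> AAFeatureTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AAFeatureTable.load()
    return _DEFAULT_TABLE


def aa_feature(aa: str, feature: str) -> float:
    """Value of one feature for one amino acid from the packaged table."""
    return default_feature_table().value(aa, feature)
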