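"""Functional summaries of gene annotation tables.

Annotation tables are the tabular output of upstream orthology/pathway
alignment (eggNOG-style functional category letters, KEGG-style KO/EC labels
and pathway memberships), split by *fraction*: ``virome`` (genes recovered
from purified virus particles) versus ``microbiome`` (genes from the cellular
fraction of the same sample). This module computes per-fraction functional
category profiles, matched-contig percentages, and pathway-set overlaps
between the two fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError, SchemaError
from .pathways import normalize_ec, normalize_symbol

__all__ = [
    "FRACTIONS",
    "GeneAnnotationTable",
    "tally_categories",
    "matched_fraction",
    "pathway_sets",
    "shared_pathway_counts",
]

FRACTIONS = ("virome", "microbiome")

ANNOTATION_COLUMNS = [
    "gene_id",
    "sample_id",
    "fraction",
    "ec",
    "ko",
    "category",
    "pathway_ids",
]


@dataclass
class GeneAnnotationTable:
    """Per-gene EC/KO/category/pathway assignments, split by fraction.

    Backed by a pandas DataFrame with columns ``gene_id, sample_id, fraction,
    ec, ko, category, pathway_ids``. Optional fields are empty strings.
    ``pathway_ids`` is a semicolon-separated list. The ``ko`` column carries
    either a KEGG Orthology label or a gene symbol (CTH, NarG, ...); symbol
    matching against pathway elements is case-insensitive.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"annotation table missing column(s): {missing}")
        df = self.frame.copy()
        for col in ANNOTATION_COLUMNS:
            df[col] = df[col].fillna("").astype(str)
        bad = ~df["fraction"].isin(FRACTIONS)
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(
                f"annotation row {row}: fraction must be one of {FRACTIONS}, "
                f"got {df.loc[row, 'fraction']!r}"
            )
        df["ec"] = df["ec"].map(lambda s: normalize_ec(s) if s else "")
        dup = df.duplicated(subset=["gene_id", "sample_id", "fraction"])
        if dup.any():
            row = df.index[dup][0]
            raise SchemaError(
                f"annotation row {row}: duplicate gene_id "
                f"{df.loc[row, 'gene_id']!r} within (sample, fraction)"
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def _select(self, fraction: str) -> pd.DataFrame:
        return self.frame[self.frame["fraction"] == fraction]

    def has_ec(self, ec: str, fraction: str) -> bool:
        return (self._select(fraction)["ec"] == normalize_ec(ec)).any()

    def has_symbol(self, symbol: str, fraction: str) -> bool:
        sym = normalize_symbol(symbol)
        return (
            self._select(fraction)["ko"].str.lower().str.strip() == sym
        ).any()

    def drop_fraction(self, fraction: str) -> "GeneAnnotationTable":
        return GeneAnnotationTable(
            self.frame[self.frame["fraction"] != fraction].copy()
        )


def tally_categories(
    annotations: GeneAnnotationTable, pooled: bool = False
) -> pd.DataFrame:
    """Functional-category proportions per (sample, fraction).

    Genes carrying a category letter are tallied per letter; the letter ``S``
    is the "function unknown" bucket for genes with orthology but no
    functional description and counts in the denominator like any other.
    Returns a tidy frame with columns ``sample_id, fraction, category,
    proportion, fraction_categorized`` where proportions sum to 1 within each
    (sample, fraction) and ``fraction_categorized`` is the percentage of all
    genes of that group that carry any category letter.

    With ``pooled=True`` samples are aggregated and ``sample_id`` is
    ``"pooled"``.
    """
    if len(annotations) == 0:
        raise ParameterError("tally_categories: empty annotation table")
    df = annotations.frame.copy()
    if pooled:
        df["sample_id"] = "pooled"
    rows = []
    for (sample, fraction), grp in df.groupby(["sample_id", "fraction"]):
        total = len(grp)
        cat = grp[grp["category"] != ""]
        frac_cat = 100.0 * len(cat) / total
        counts = cat["category"].value_counts()
        for letter, n in sorted(counts.items()):
            rows.append(
                {
                    "sample_id": sample,
                    "fraction": fraction,
                    "category": letter,
                    "proportion": n / len(cat),
                    "fraction_categorized": frac_cat,
                }
            )
        if counts.empty:
            rows.append(
                {
                    "sample_id": sample,
                    "fraction": fraction,
                    "category": "",
                    "proportion": float("nan"),
                    "fraction_categorized": 0.0,
                }
            )
    return pd.DataFrame(rows)


def matched_fraction(n_matched: int, n_contigs: int) -> float:
    """Percent of contigs with a database match: 100 * n_matched / n_contigs."""
    if n_contigs <= 0:
        raise ParameterError("matched_fraction: n_contigs must be positive")
    if not 0 <= n_matched <= n_contigs:
        raise ParameterError(
            f"matched_fraction: need 0 <= n_matched <= n_contigs, got "
            f"({n_matched}, {n_contigs})"
        )
    return 100.0 * n_matched / n_contigs


def pathway_sets(
    annotations: GeneAnnotationTable,
) -> dict[tuple[str, str], frozenset[str]]:
    """Deduplicated pathway-id set per (sample, fraction)."""
    out: dict[tuple[str, str], frozenset[str]] = {}
    for (sample, fraction), grp in annotations.frame.groupby(
        ["sample_id", "fraction"]
    ):
        ids: set[str] = set()
        for cell in grp["pathway_ids"]:
            ids.update(p for p in str(cell).split(";") if p)
        out[(sample, fraction)] = frozenset(ids)
    return out


def shared_pathway_counts(
    virome_set: frozenset[str], microbiome_set: frozenset[str]
) -> tuple[int, int, int]:
    """(n_microbial, n_viral, n_shared) pathway counts for one sample."""
    return (
        len(microbiome_set),
        len(virome_set),
        len(virome_set & microbiome_set),
    )
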