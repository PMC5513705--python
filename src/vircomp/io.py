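"""Validated TSV readers/writers, run configuration, and the pipeline driver.

All tables are plain TSV. Readers check headers and coerce types, reporting
the offending column or row in error messages; writers sort on stable keys so
repeated runs of the same configuration produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .compensation import CompensationReport, compensation_report
from .diversity import OtuTable, TaxonomyMap, diversity_table, family_rollup
from .errors import SchemaError
from .pathways import PathwayDatabase, load_pathway_db
from .tally import (
    ANNOTATION_COLUMNS,
    GeneAnnotationTable,
    pathway_sets,
    shared_pathway_counts,
    tally_categories,
)

__all__ = [
    "RunConfig",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_annotations",
    "write_annotations",
    "write_diversity_report",
    "write_compensation_report",
    "run_pipeline",
]

log = logging.getLogger("vircomp")

_FORMULA_HEADER = (
    "# shannon: H = -sum p_i ln p_i (nats); 95% CI normal approx with "
    "var(H) = [sum p ln^2 p - (sum p ln p)^2]/N + (S-1)/(2N^2)\n"
    "# simpson: D = sum n_i(n_i-1)/(N(N-1)); 95% CI normal approx with "
    "var(D) = 4/N (sum p^3 - (sum p^2)^2)\n"
    "# coverage: Good's C = (1 - singletons/N) * 100\n"
)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_otu_table(path) -> OtuTable:
    """Read an OTU table TSV (first column ``otu_id``, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["otu_id"], path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: no sample columns")
    df = df.set_index("otu_id")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            values = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: column {col!r} has a non-numeric count ({exc})"
            ) from exc
        if (values % 1 != 0).any():
            row = df.index[values % 1 != 0][0]
            raise SchemaError(
                f"{path}: non-integer count for OTU {row!r} in column {col!r}"
            )
        if (values < 0).any():
            row = df.index[values < 0][0]
            raise SchemaError(
                f"{path}: negative count for OTU {row!r} in column {col!r}"
            )
        out[col] = values.astype(int)
    return OtuTable(out)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.frame.sort_index()
    df.to_csv(path, sep="\t", index_label="otu_id")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["otu_id", "phylum", "family", "genus"], path)
    return {
        r.otu_id: (r.phylum, r.family, r.genus) for r in df.itertuples()
    }


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = [
        {"otu_id": otu, "phylum": p, "family": f, "genus": g}
        for otu, (p, f, g) in sorted(tax.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> GeneAnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    _require_columns(df, ANNOTATION_COLUMNS, path)
    return GeneAnnotationTable(df)


def write_annotations(annotations: GeneAnnotationTable, path) -> None:
    df = annotations.frame.sort_values(
        ["sample_id", "fraction", "gene_id"], ignore_index=True
    )
    df.to_csv(path, sep="\t", index=False)


def write_diversity_report(table: OtuTable, tax: TaxonomyMap | None,
                           outdir: Path, others_threshold: float = 1.0) -> None:
    """Write the per-sample diversity TSV and, with taxonomy, the family TSV."""
    outdir = Path(outdir)
    results = diversity_table(table)
    rows = [
        {
            "sample": r.sample_id,
            "n_reads": r.n_reads,
            "n_otus": r.n_otus,
            "coverage": f"{r.coverage:.2f}",
            "shannon": f"{r.shannon:.2f}",
            "shannon_lci": f"{r.shannon_ci[0]:.2f}",
            "shannon_hci": f"{r.shannon_ci[1]:.2f}",
            "simpson": f"{r.simpson:.2f}",
            "simpson_lci": f"{r.simpson_ci[0]:.2f}",
            "simpson_hci": f"{r.simpson_ci[1]:.2f}",
        }
        for r in sorted(results, key=lambda r: r.sample_id)
    ]
    path = outdir / "diversity.tsv"
    with open(path, "w") as fh:
        fh.write(_FORMULA_HEADER)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    if tax is not None:
        fam = family_rollup(table, tax, threshold=others_threshold)
        fam = fam.sort_values(["sample_id", "family"], ignore_index=True)
        fam["share_pct"] = fam["share_pct"].map(lambda v: f"{v:.2f}")
        fam.to_csv(outdir / "family_abundance.tsv", sep="\t", index=False)


def write_tally_report(annotations: GeneAnnotationTable, outdir: Path,
                       pooled: bool = False) -> None:
    outdir = Path(outdir)
    prof = tally_categories(annotations, pooled=pooled)
    prof = prof.sort_values(["sample_id", "fraction", "category"],
                            ignore_index=True)
    prof["proportion"] = prof["proportion"].map(lambda v: f"{v:.4f}")
    prof["fraction_categorized"] = prof["fraction_categorized"].map(
        lambda v: f"{v:.2f}"
    )
    prof.to_csv(outdir / "category_profile.tsv", sep="\t", index=False)

    sets = pathway_sets(annotations)
    samples = sorted({s for s, _ in sets})
    rows = []
    for s in samples:
        vir = sets.get((s, "virome"), frozenset())
        mic = sets.get((s, "microbiome"), frozenset())
        n_m, n_v, n_s = shared_pathway_counts(vir, mic)
        rows.append(
            {"sample": s, "n_microbial_pathways": n_m,
             "n_viral_pathways": n_v, "n_shared": n_s}
        )
    pd.DataFrame(rows).to_csv(outdir / "pathway_counts.tsv", sep="\t",
                              index=False)


def write_compensation_report(report: CompensationReport, outdir: Path) -> None:
    """Per-element TSV, machine-readable JSON summary, and a text summary."""
    outdir = Path(outdir)
    frame = report.to_frame().sort_values(
        ["pathway_id", "element_type", "element_id"], ignore_index=True
    )
    frame.to_csv(outdir / "compensation.tsv", sep="\t", index=False)
    with open(outdir / "compensation_summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = [
        "vircomp compensation summary",
        f"pathways analyzed: {report.n_pathways}",
        f"pathways compensated by viral-unique genes: {report.n_compensated}",
        "",
        "class histogram:",
    ]
    for cls, n in sorted(report.class_histogram.items()):
        lines.append(f"  {cls}: {n}")
    lines.append("")
    for p in report.pathways:
        flag = "COMPENSATED" if p.compensated else "not compensated"
        lines.append(f"{p.pathway_id} ({p.name}): {flag}")
    (outdir / "compensation_summary.txt").write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """All pipeline inputs and switches; defaults are applied explicitly."""

    outdir: Path
    otu_path: Path | None = None
    tax_path: Path | None = None
    annotations_path: Path | None = None
    pathway_db_path: Path | None = None
    scenarios_path: Path | None = None
    others_threshold: float = 1.0
    pooled: bool = False
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("otu_path", "tax_path", "annotations_path",
                     "pathway_db_path", "scenarios_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise SchemaError(f"{name}: file not found: {p}")


def _read_scenarios(path) -> list[frozenset[str]]:
    with open(path) as fh:
        doc = json.load(fh)
    return [frozenset(s) for s in doc["scenarios"]]


def run_pipeline(config: RunConfig) -> CompensationReport | None:
    """Run diversity → tally → compensation on the configured inputs.

    Writes all report files under ``config.outdir``; outputs are byte-stable
    across reruns of the same configuration. Returns the compensation report
    when a pathway database and annotations were supplied.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        log.info("vircomp %s", __version__)
        log.info("config: %s", config)
        log.info(
            "diversity formulas: Shannon in nats with normal-approximation CI;"
            " Simpson dominance form; Good's coverage; analytic rarefaction"
        )
        report: CompensationReport | None = None
        if config.otu_path is not None:
            table = read_otu_table(config.otu_path)
            tax = (read_taxonomy(config.tax_path)
                   if config.tax_path is not None else None)
            write_diversity_report(table, tax, outdir,
                                   others_threshold=config.others_threshold)
            log.info("diversity reports written")
        if config.annotations_path is not None:
            annotations = read_annotations(config.annotations_path)
            write_tally_report(annotations, outdir, pooled=config.pooled)
            log.info("tally reports written")
            if config.pathway_db_path is not None:
                db = load_pathway_db(config.pathway_db_path)
                scenarios = (
                    _read_scenarios(config.scenarios_path)
                    if config.scenarios_path is not None else None
                )
                report = compensation_report(db, annotations, scenarios)
                write_compensation_report(report, outdir)
                log.info(
                    "compensation: %d of %d pathways compensated",
                    report.n_compensated, report.n_pathways,
                )
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
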