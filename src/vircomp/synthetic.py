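"""Synthetic communities, annotation scenarios, and the packaged vent fixture.

Two generators with known ground truth let the whole pipeline run without any
sequencing data:

* :func:`generate_community` emulates the amplicon side of a vent sediment
  study — a handful of samples, each dominated by a single bacterial family
  (defaults: 3 samples, ~16 OTUs per sample, dominant family at 85% of reads,
  8 OTUs shared by all samples) — producing an OTU table and taxonomy map;
* :func:`generate_annotations` plants a configurable number of viral-unique
  compensation events of each class (gap fill, shortcut, parallel branch,
  branch extension, complex completion) into linear microbial pathways, and
  emits the ground-truth labels alongside, so classifier recovery can be
  checked exactly.

:func:`vent_fixture` returns the packaged six-pathway database and paired
virome/microbiome annotations describing the published vent compensation
panels (pyrimidine metabolism; alanine/aspartate/glutamate metabolism; the
nitrate/nitrite two-component system; selenocompound metabolism;
aminoacyl-tRNA biosynthesis; amino and nucleotide sugar metabolism).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .diversity import OtuTable, TaxonomyMap
from .errors import ParameterError
from .pathways import (
    Compound,
    Pathway,
    PathwayDatabase,
    ProteinComplex,
    Reaction,
    RegulatoryRule,
    load_pathway_db,
)
from .tally import ANNOTATION_COLUMNS, GeneAnnotationTable

__all__ = [
    "CommunityParams",
    "ScenarioParams",
    "ScenarioBundle",
    "generate_community",
    "generate_annotations",
    "vent_fixture",
    "build_vent_fixture",
]

PLANT_CLASSES = (
    "gap_fill",
    "shortcut",
    "parallel_branch",
    "branch_extension",
    "complex_completion",
)

_DOMINANT = ("Proteobacteria", "Pseudomonadaceae", "Pseudomonas")
# plausible vent sediment taxa for the non-dominant OTUs
_MINOR_TAXA = [
    ("Campylobacterota", "Helicobacteraceae", "Sulfurimonas"),
    ("Proteobacteria", "Thiotrichaceae", "Thiothrix"),
    ("Desulfobacterota", "Desulfobulbaceae", "Desulfobulbus"),
    ("Bacteroidota", "Flavobacteriaceae", "Lutibacter"),
    ("Proteobacteria", "Rhodobacteraceae", "Sulfitobacter"),
    ("Proteobacteria", "Moraxellaceae", "Acinetobacter"),
    ("Campylobacterota", "Sulfurovaceae", "Sulfurovum"),
    ("Proteobacteria", "Enterobacteriaceae", "Escherichia"),
    ("Firmicutes", "Bacillaceae", "Bacillus"),
    ("Actinomycetota", "Nocardiaceae", "Rhodococcus"),
    ("Chloroflexota", "Anaerolineaceae", "Anaerolinea"),
    ("Aquificota", "Aquificaceae", "Hydrogenobacter"),
]


@dataclass(frozen=True)
class CommunityParams:
    """Knobs of the community generator; defaults emulate a 3-vent study."""

    n_samples: int = 3
    n_otus_per_sample: int = 16
    read_depth: int = 60_000
    dominance: float = 0.85
    concentration: float = 1.0
    n_shared_otus: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if not 0.0 < self.dominance < 1.0:
            raise ParameterError("dominance must lie in (0, 1)")
        if not 1 <= self.n_shared_otus <= self.n_otus_per_sample:
            raise ParameterError(
                "n_shared_otus must satisfy 1 <= n_shared_otus <= "
                "n_otus_per_sample"
            )
        if self.read_depth < self.n_otus_per_sample:
            raise ParameterError("read_depth must be >= n_otus_per_sample")
        if self.concentration <= 0:
            raise ParameterError("concentration must be positive")


def generate_community(params: CommunityParams) -> tuple[OtuTable, TaxonomyMap]:
    """Draw an OTU count table and taxonomy map with planted structure.

    The dominant family's single shared OTU has expected relative abundance
    exactly ``dominance``; the remaining mass is split by a symmetric
    Dirichlet(``concentration``) draw and reads are multinomial. Every OTU of
    a sample receives one guaranteed read (with the multinomial probabilities
    rescaled so expectations are unchanged), which makes "exactly
    ``n_shared_otus`` OTUs nonzero in all samples" hold at any finite depth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_private = params.n_otus_per_sample - params.n_shared_otus

    shared_ids = [f"OTU_S{i + 1:03d}" for i in range(params.n_shared_otus)]
    sample_ids = [f"sample{i + 1}" for i in range(params.n_samples)]
    private_ids = {
        s: [f"OTU_{s}_P{j + 1:03d}" for j in range(n_private)]
        for s in sample_ids
    }
    all_ids = list(shared_ids)
    for s in sample_ids:
        all_ids.extend(private_ids[s])

    tax: TaxonomyMap = {}
    tax[shared_ids[0]] = _DOMINANT
    for i, otu in enumerate(all_ids[1:]):
        tax[otu] = _MINOR_TAXA[i % len(_MINOR_TAXA)]

    frame = pd.DataFrame(0, index=all_ids, columns=sample_ids, dtype=int)
    k = params.n_otus_per_sample
    depth = params.read_depth
    for s in sample_ids:
        otus = shared_ids + private_ids[s]
        rest = rng.dirichlet([params.concentration] * (k - 1))
        p = np.concatenate([[params.dominance], (1.0 - params.dominance) * rest])
        # one guaranteed read per OTU; rescale so E[count_i]/depth stays p_i
        p_adj = (depth * p - 1.0) / (depth - k)
        p_adj = np.clip(p_adj, 0.0, None)
        p_adj /= p_adj.sum()
        counts = 1 + rng.multinomial(depth - k, p_adj)
        frame.loc[otus, s] = counts
    return OtuTable(frame), tax


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of the annotation-scenario generator."""

    n_pathways: int = 6
    reactions_per_pathway: tuple[int, int] = (4, 8)
    planted_counts: dict[str, int] = field(
        default_factory=lambda: {c: 1 for c in PLANT_CLASSES}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_pathways < 1:
            raise ParameterError("n_pathways must be >= 1")
        lo, hi = self.reactions_per_pathway
        if not 2 <= lo <= hi:
            raise ParameterError(
                "reactions_per_pathway must be a range (lo, hi) with lo >= 2"
            )
        for cls, n in self.planted_counts.items():
            if cls not in PLANT_CLASSES:
                raise ParameterError(f"unknown planted class {cls!r}")
            if n < 0:
                raise ParameterError(f"planted count for {cls} must be >= 0")


@dataclass
class ScenarioBundle:
    """A generated scenario: database, annotations and sidecar truth labels."""

    db: PathwayDatabase
    annotations: GeneAnnotationTable
    labels: pd.DataFrame  # pathway_id, element_id, element_type, true_class


class _EcMinter:
    """Unique, well-formed synthetic EC numbers."""

    def __init__(self) -> None:
        self._n = 0

    def __call__(self) -> str:
        self._n += 1
        n = self._n
        return f"{n % 7 + 1}.{n % 23 + 1}.{n % 99 + 1}.{n}"


def generate_annotations(params: ScenarioParams) -> ScenarioBundle:
    """Plant compensation events of each class into linear microbial chains.

    Each pathway is a chain seed → c1 → ... → target of microbially annotated
    reactions. Reaction-level events are planted at chain positions spaced at
    least three steps apart so they cannot interact: a *gap_fill* flips one
    chain step to viral-only; a *shortcut* adds a viral two-step bypass; a
    *parallel_branch* duplicates one step with a distinct viral enzyme; a
    *branch_extension* adds a viral side reaction to a fresh non-target
    compound. *complex_completion* events add an all-viral multi-subunit
    complex. Raises :class:`ParameterError` when the requested events do not
    fit the generated chains.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    mint = _EcMinter()
    lo, hi = params.reactions_per_pathway

    lengths = rng.integers(lo, hi + 1, size=params.n_pathways)
    # slot = (pathway index, chain position); positions spaced >=3 apart and
    # <= L-2 so every event type (shortcut needs pos+2 <= L) fits anywhere
    slots: list[tuple[int, int]] = []
    for i, L in enumerate(lengths):
        slots.extend((i, j) for j in range(0, int(L) - 1, 3))
    n_reaction_events = sum(
        n for c, n in params.planted_counts.items() if c != "complex_completion"
    )
    if n_reaction_events > len(slots):
        raise ParameterError(
            f"planted_counts requests {n_reaction_events} reaction events but "
            f"only {len(slots)} non-interacting slots exist; increase "
            f"n_pathways or reactions_per_pathway"
        )
    order = rng.permutation(len(slots))
    slot_iter = iter(slots[i] for i in order)

    pathways: list[Pathway] = []
    ann_rows: list[dict] = []
    label_rows: list[dict] = []
    gene_n = 0

    def add_gene(fraction: str, pid: str, ec: str = "", ko: str = "") -> None:
        nonlocal gene_n
        gene_n += 1
        ann_rows.append(
            {
                "gene_id": f"gene{gene_n:04d}",
                "sample_id": "sim",
                "fraction": fraction,
                "ec": ec,
                "ko": ko,
                "category": str(rng.choice(list("CEFGHPQ_"))).replace("_", ""),
                "pathway_ids": pid,
            }
        )

    for i, L in enumerate(lengths):
        L = int(L)
        pid = f"SYN{i + 1:03d}"
        compounds = {
            f"{pid}_c{j}": Compound(
                id=f"{pid}_c{j}",
                name=f"compound {j}",
                is_seed=(j == 0),
                is_target=(j == L),
            )
            for j in range(L + 1)
        }
        reactions: dict[str, Reaction] = {}
        chain_fraction: dict[int, str] = {}
        for j in range(L):
            rid = f"{pid}_r{j}"
            reactions[rid] = Reaction(
                id=rid,
                ec=mint(),
                substrates=frozenset({f"{pid}_c{j}"}),
                products=frozenset({f"{pid}_c{j + 1}"}),
            )
            chain_fraction[j] = "microbiome"
        pathways.append(
            Pathway(id=pid, name=f"synthetic pathway {i + 1}",
                    compounds=compounds, reactions=reactions)
        )

    # assign reaction-level events to slots
    viral_chain_steps: dict[str, set[int]] = {}
    for cls in ("gap_fill", "shortcut", "parallel_branch", "branch_extension"):
        for _ in range(params.planted_counts.get(cls, 0)):
            i, j = next(slot_iter)
            p = pathways[i]
            pid = p.id
            if cls == "gap_fill":
                # the chain step itself goes viral-only: a gap in the
                # microbial route that only the virus fills
                rid = f"{pid}_r{j}"
                viral_chain_steps.setdefault(pid, set()).add(j)
                add_gene("virome", pid, ec=p.reactions[rid].ec)
                label_rows.append(
                    {"pathway_id": pid, "element_id": rid,
                     "element_type": "reaction", "true_class": cls}
                )
            else:
                rid = f"{pid}_v{j}_{cls}"
                if cls == "shortcut":
                    subs, prods = {f"{pid}_c{j}"}, {f"{pid}_c{j + 2}"}
                elif cls == "parallel_branch":
                    subs, prods = {f"{pid}_c{j}"}, {f"{pid}_c{j + 1}"}
                else:  # branch_extension
                    ext = f"{pid}_x{j}"
                    p.compounds[ext] = Compound(id=ext, name="side product")
                    subs, prods = {f"{pid}_c{j}"}, {ext}
                p.reactions[rid] = Reaction(
                    id=rid, ec=mint(), substrates=frozenset(subs),
                    products=frozenset(prods),
                )
                add_gene("virome", pid, ec=p.reactions[rid].ec)
                label_rows.append(
                    {"pathway_id": pid, "element_id": rid,
                     "element_type": "reaction", "true_class": cls}
                )

    # complex completions, assigned round-robin over pathways
    for m in range(params.planted_counts.get("complex_completion", 0)):
        p = pathways[m % len(pathways)]
        cid = f"{p.id}_cpx{m}"
        subunits = frozenset(f"{cid}_su{t}" for t in range(int(rng.integers(2, 5))))
        p.complexes[cid] = ProteinComplex(
            id=cid, subunits=subunits, function="planted viral complex"
        )
        for su in sorted(subunits):
            add_gene("virome", p.id, ko=su)
        label_rows.append(
            {"pathway_id": p.id, "element_id": cid,
             "element_type": "complex", "true_class": "complex_completion"}
        )

    # microbial gene rows for every chain step not flipped to viral
    for i, p in enumerate(pathways):
        viral_steps = viral_chain_steps.get(p.id, set())
        for j in range(int(lengths[i])):
            if j in viral_steps:
                continue
            add_gene("microbiome", p.id, ec=p.reactions[f"{p.id}_r{j}"].ec)

    db = PathwayDatabase(pathways)
    db.validate()
    annotations = GeneAnnotationTable(
        pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    )
    labels = pd.DataFrame(
        label_rows,
        columns=["pathway_id", "element_id", "element_type", "true_class"],
    ).sort_values(["pathway_id", "element_id"], ignore_index=True)
    return ScenarioBundle(db=db, annotations=annotations, labels=labels)



# ---------------------------------------------------------------------------
# The packaged six-pathway vent fixture
# ---------------------------------------------------------------------------


def build_vent_fixture() -> tuple[PathwayDatabase, GeneAnnotationTable]:
    """Construct the six vent compensation pathways and their annotations.

    Compounds drawn upstream of the first detected enzyme are collapsed into
    declared seeds; products the host must make are declared targets. The
    packaged data files are generated from this function.
    """
    p1 = Pathway(
        id="P1",
        name="pyrimidine metabolism",
        compounds={
            "trx_ox": Compound("trx_ox", "thioredoxin disulfide", is_seed=True),
            "trx": Compound("trx", "thioredoxin", is_seed=True),
        },
        reactions={
            "P1_R1": Reaction("P1_R1", frozenset({"trx_ox"}), frozenset({"trx"}),
                              ec="1.8.1.9"),
            "P1_R2": Reaction("P1_R2", frozenset({"trx"}), frozenset({"trx_ox"}),
                              ec="1.17.4.1"),
            "P1_R3": Reaction("P1_R3", frozenset({"trx"}), frozenset({"trx_ox"}),
                              ec="1.17.4.2"),
        },
    )
    p2 = Pathway(
        id="P2",
        name="alanine, aspartate and glutamate metabolism",
        compounds={
            "asp": Compound("asp", "L-aspartate", is_seed=True),
            "asuc": Compound("asuc", "adenylosuccinate"),
            "argsuc": Compound("argsuc", "L-argininosuccinate"),
            "fum": Compound("fum", "fumarate", is_target=True),
        },
        reactions={
            "P2_R1": Reaction("P2_R1", frozenset({"asp"}), frozenset({"asuc"}),
                              ec="6.3.4.4"),
            "P2_R2": Reaction("P2_R2", frozenset({"asuc"}), frozenset({"fum"}),
                              ec="4.3.2.2"),
            "P2_R3": Reaction("P2_R3", frozenset({"asp"}), frozenset({"argsuc"}),
                              ec="6.3.4.5"),
            "P2_R4": Reaction("P2_R4", frozenset({"argsuc"}), frozenset({"fum"}),
                              ec="4.3.2.1"),
            "P2_R5": Reaction("P2_R5", frozenset({"asp"}), frozenset({"fum"}),
                              ec="4.3.1.1"),
        },
    )
    p3 = Pathway(
        id="P3",
        name="two-component system / nitrogen metabolism",
        compounds={
            "no3": Compound("no3", "nitrate", is_seed=True),
            "no2": Compound("no2", "nitrite"),
            "hexp_out": Compound("hexp_out", "hexose phosphate (periplasm)",
                                 is_seed=True),
            "hexp_in": Compound("hexp_in", "hexose phosphate (cytoplasm)"),
        },
        reactions={
            "P3_UHPT": Reaction("P3_UHPT", frozenset({"hexp_out"}),
                                frozenset({"hexp_in"}), symbol="UhpT"),
        },
        complexes={
            "Frd": ProteinComplex(
                "Frd", frozenset({"FrdA", "FrdB", "FrdC", "FrdD"}),
                "fumarate reductase"),
            "Nar": ProteinComplex(
                "Nar", frozenset({"NarG", "NarH", "NarJ", "NarI"}),
                "nitrate reductase"),
        },
        rules={
            "P3_RULE_NO3": RegulatoryRule(
                "P3_RULE_NO3", signal="nitrate", sensor="NarX",
                regulator="NarL",
                effects=(("Frd", "inhibit"), ("Nar", "activate"))),
            "P3_RULE_NO2": RegulatoryRule(
                "P3_RULE_NO2", signal="nitrite", sensor="NarX",
                regulator="NarL",
                effects=(("Frd", "inhibit"), ("Nar", "activate"))),
            # oxygen activation is drawn without an explicit sensor
            "P3_RULE_O2": RegulatoryRule(
                "P3_RULE_O2", signal="oxygen", sensor=None, regulator=None,
                effects=(("Nar", "activate"),)),
            "P3_RULE_HEX": RegulatoryRule(
                "P3_RULE_HEX", signal="hexose-phosphate", sensor="UhpC",
                regulator="UhpA", effects=(("P3_UHPT", "activate"),)),
        },
    )
    p4 = Pathway(
        id="P4",
        name="selenocompound metabolism",
        compounds={
            "semsec": Compound("semsec", "Se-methyl-L-selenocysteine",
                               is_seed=True),
            "mesoh": Compound("mesoh", "methylselenol", is_target=True),
            "sertrna": Compound("sertrna", "L-seryl-tRNA(Sec)", is_seed=True),
            "sectrna": Compound("sectrna", "L-selenocysteinyl-tRNA(Sec)",
                                is_target=True),
        },
        reactions={
            "P4_R1": Reaction("P4_R1", frozenset({"semsec"}),
                              frozenset({"mesoh"}), symbol="CTH"),
            "P4_R2": Reaction("P4_R2", frozenset({"sertrna"}),
                              frozenset({"sectrna"}), ec="2.9.1.1"),
        },
    )
    p5 = Pathway(
        id="P5",
        name="aminoacyl-tRNA biosynthesis",
        compounds={
            "sertrna": Compound("sertrna", "L-seryl-tRNA(Sec)", is_seed=True),
            "sectrna": Compound("sectrna", "L-selenocysteinyl-tRNA(Sec)",
                                is_target=True),
        },
        reactions={
            "P5_R1": Reaction("P5_R1", frozenset({"sertrna"}),
                              frozenset({"sectrna"}), ec="2.9.1.1"),
        },
    )
    p6 = Pathway(
        id="P6",
        name="amino sugar and nucleotide sugar metabolism",
        compounds={
            "gdp4oxo": Compound("gdp4oxo", "GDP-4-oxo-6-deoxy-D-mannose",
                                is_seed=True),
            "gdpper": Compound("gdpper", "GDP-D-perosamine"),
            "gdprha": Compound("gdprha", "GDP-D-rhamnose"),
            "ara4o": Compound("ara4o", "UDP-L-Ara4O", is_seed=True),
            "ara4n": Compound("ara4n", "UDP-L-Ara4N"),
            "ara4fn": Compound("ara4fn", "UDP-L-Ara4FN"),
            "und_ara4fn": Compound(
                "und_ara4fn", "undecaprenyl phosphate alpha-L-Ara4FN",
                is_target=True),
        },
        reactions={
            "P6_R1": Reaction("P6_R1", frozenset({"gdp4oxo"}),
                              frozenset({"gdpper"}), ec="2.6.1.102"),
            "P6_R2": Reaction("P6_R2", frozenset({"gdp4oxo"}),
                              frozenset({"gdprha"}), ec="1.1.1.281"),
            "P6_R3": Reaction("P6_R3", frozenset({"ara4o"}),
                              frozenset({"ara4n"}), ec="2.6.1.87"),
            "P6_R4": Reaction("P6_R4", frozenset({"ara4n"}),
                              frozenset({"ara4fn"}), ec="2.1.2.13"),
            "P6_R5": Reaction("P6_R5", frozenset({"ara4fn"}),
                              frozenset({"und_ara4fn"}), ec="2.4.2.53"),
        },
    )
    db = PathwayDatabase([p1, p2, p3, p4, p5, p6])
    db.validate()

    micro = [
        ("1.8.1.9", "", "F", "P1"),
        ("1.17.4.1", "", "F", "P1"),
        ("6.3.4.4", "", "E", "P2"),
        ("4.3.2.2", "", "E", "P2"),
        ("6.3.4.5", "", "E", "P2"),
        ("4.3.2.1", "", "E", "P2"),
        ("", "FrdA", "C", "P3"),
        ("", "FrdB", "C", "P3"),
        ("", "FrdC", "C", "P3"),
        ("", "FrdD", "C", "P3"),
        ("", "NarX", "T", "P3"),
        ("", "NarL", "T", "P3"),
        ("2.6.1.102", "", "G", "P6"),
        ("2.1.2.13", "", "G", "P6"),
        ("2.4.2.53", "", "G", "P6"),
    ]
    viral = [
        ("1.17.4.2", "", "F", "P1"),
        ("4.3.1.1", "", "E", "P2"),
        ("", "NarG", "C", "P3"),
        ("", "NarH", "C", "P3"),
        ("", "NarJ", "C", "P3"),
        ("", "NarI", "C", "P3"),
        ("", "UhpC", "T", "P3"),
        ("", "CTH", "E", "P4"),
        ("2.9.1.1", "", "J", "P4;P5"),
        ("1.1.1.281", "", "G", "P6"),
        ("2.6.1.87", "", "G", "P6"),
    ]
    rows = []
    for i, (ec, ko, cat, pids) in enumerate(micro):
        rows.append(
            {"gene_id": f"mic{i + 1:03d}", "sample_id": "vent",
             "fraction": "microbiome", "ec": ec, "ko": ko, "category": cat,
             "pathway_ids": pids}
        )
    for i, (ec, ko, cat, pids) in enumerate(viral):
        rows.append(
            {"gene_id": f"vir{i + 1:03d}", "sample_id": "vent",
             "fraction": "virome", "ec": ec, "ko": ko, "category": cat,
             "pathway_ids": pids}
        )
    annotations = GeneAnnotationTable(
        pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    )
    return db, annotations


def vent_fixture() -> tuple[PathwayDatabase, GeneAnnotationTable]:
    """Load the packaged six-pathway fixture (database + annotations)."""
    data = resources.files("vircomp").joinpath("data")
    with resources.as_file(data.joinpath("vent_pathways.json")) as path:
        db = load_pathway_db(path)
    with resources.as_file(data.joinpath("vent_annotations.tsv")) as path:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return db, GeneAnnotationTable(frame)
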