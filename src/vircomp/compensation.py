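"""Classification of viral-unique contributions to microbial metabolism.

The central question: when a gene for a pathway reaction is detected in the
virome but not in the microbiome of the same habitat, what does that reaction
do for the host's metabolic network? Each viral-unique reaction is assigned
exactly one class:

``gap_fill``
    the reaction is needed to reach a declared target compound that microbial
    reactions alone cannot produce;
``shortcut``
    the product is microbially reachable from the reaction's substrates, but
    only via a route longer than one step;
``parallel_branch``
    a microbial reaction performs the same one-step transformation with a
    different enzyme;
``branch_extension``
    the product is not otherwise made and is not a declared target — the
    virus extends the network sideways;
``disconnected``
    the reaction's substrates cannot be produced at all, even pooling viral
    and microbial reactions.

Multi-subunit enzymes are handled by :func:`complex_status` (a complex whose
full subunit set exists only virally, or only when pooling fractions, is a
``complex_completion``), and two-component signalling by
:func:`evaluate_regulation` (``regulatory_rerouting`` when an active
regulator suppresses a microbial enzyme while the activated replacement is
expressible only through viral genes).

Classification is presence-based: no claim is made about in-vivo expression
or flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import LookupError_, ParameterError
from .pathways import (
    Pathway,
    PathwayDatabase,
    ProteinComplex,
    closure_levels,
    presence_map,
    reachable_compounds,
)
from .tally import GeneAnnotationTable

__all__ = [
    "COMPENSATION_CLASSES",
    "RuleOutcome",
    "PathwayResult",
    "CompensationReport",
    "classify_viral_reaction",
    "complex_status",
    "evaluate_regulation",
    "default_scenarios",
    "compensation_report",
]

#: Classes that count as metabolic compensation at the pathway level.
COMPENSATION_CLASSES = frozenset(
    {
        "gap_fill",
        "shortcut",
        "parallel_branch",
        "branch_extension",
        "complex_completion",
        "regulatory_rerouting",
    }
)


def _microbial_reactions(pathway: Pathway, presence: dict[str, str]) -> set[str]:
    # "both"-origin reactions are available to the host, so they route as microbial
    return {
        rid
        for rid in pathway.reactions
        if presence.get(rid) in ("microbial", "both")
    }


def _detected_reactions(pathway: Pathway, presence: dict[str, str]) -> set[str]:
    return {
        rid
        for rid in pathway.reactions
        if presence.get(rid) in ("microbial", "both", "viral")
    }


def classify_viral_reaction(
    pathway: Pathway, presence: dict[str, str], reaction_id: str
) -> str:
    """Assign one compensation class to a viral-unique reaction.

    Decision order (fixed tie-break):

    1. substrates unreachable from seeds using all detected (microbial +
       viral) reactions → ``disconnected``;
    2. every product reachable from the reaction's own substrates through
       microbial reactions alone → ``shortcut`` if the shortest microbial
       cascade needs more than one reaction step, ``parallel_branch`` if one;
    3. otherwise, ``gap_fill`` if a product is a declared target, or if some
       declared target is reachable with this reaction but not without it
       (a target downstream of the product via detected reactions);
       ``branch_extension`` if not.
    """
    if presence.get(reaction_id) != "viral":
        raise ParameterError(
            f"classify_viral_reaction: reaction {reaction_id!r} is not "
            f"viral-unique (origin={presence.get(reaction_id)!r})"
        )
    rxn = pathway.reactions[reaction_id]
    microbial = _microbial_reactions(pathway, presence)
    detected = _detected_reactions(pathway, presence)

    if not rxn.substrates <= reachable_compounds(pathway, detected):
        return "disconnected"

    # microbial-only closure started from this reaction's substrates; the
    # sweep level of a compound is its shortest cascade length in steps
    levels = closure_levels(pathway, microbial, rxn.substrates)
    if all(p in levels for p in rxn.products):
        route = max(levels[p] for p in rxn.products)
        return "shortcut" if route > 1 else "parallel_branch"

    targets = pathway.declared_targets
    if rxn.products & targets:
        return "gap_fill"
    with_rxn = reachable_compounds(pathway, detected)
    without_rxn = reachable_compounds(pathway, detected - {reaction_id})
    if (with_rxn - without_rxn) & targets:
        return "gap_fill"
    return "branch_extension"


def complex_status(
    complex: ProteinComplex, annotations: GeneAnnotationTable
) -> str:
    """Subunit-wise origin of a multi-subunit enzyme.

    ``microbial`` if every subunit is found in the microbiome; ``viral`` if
    every subunit is found in the virome; ``combined_only`` if the full set
    exists only when pooling the two fractions; ``absent`` otherwise
    (checked in that order). ``viral`` and ``combined_only`` count as
    complex_completion compensation.
    """
    in_m = [annotations.has_symbol(s, "microbiome") for s in complex.subunits]
    in_v = [annotations.has_symbol(s, "virome") for s in complex.subunits]
    if all(in_m):
        return "microbial"
    if all(in_v):
        return "viral"
    if all(m or v for m, v in zip(in_m, in_v)):
        return "combined_only"
    return "absent"


@dataclass(frozen=True)
class RuleOutcome:
    """Evaluation of one regulatory rule under one signal scenario."""

    rule_id: str
    regulator_active: bool
    #: target id -> "suppressed" | "expressed:<status>" | "absent" | "unregulated"
    targets: dict[str, str]
    rerouting: bool


def _element_status(
    pathway: Pathway, target: str, presence: dict[str, str],
    annotations: GeneAnnotationTable,
) -> str:
    if target in pathway.complexes:
        return complex_status(pathway.complexes[target], annotations)
    return presence.get(target, "absent")


def evaluate_regulation(
    pathway: Pathway,
    annotations: GeneAnnotationTable,
    scenario: frozenset[str] | set[str],
    presence: dict[str, str] | None = None,
) -> dict[str, RuleOutcome]:
    """Evaluate every regulatory rule of a pathway under a signal scenario.

    A rule's regulator is active iff its signal is present in the scenario
    and its sensor (when one is declared) is annotated in either fraction.
    An active regulator applies its effects: inhibited targets are suppressed
    regardless of origin; activated targets are expressed iff their status is
    not absent. ``rerouting`` is flagged when, within an active rule, an
    activated target is expressible only via viral (or combined_only) genes
    while a microbial alternative is suppressed.
    """
    scenario = frozenset(scenario)
    vocab = pathway.signals()
    unknown = scenario - vocab
    if unknown:
        raise LookupError_(
            f"pathway {pathway.id}: unknown signal(s) {sorted(unknown)}; "
            f"vocabulary is {sorted(vocab)}"
        )
    if presence is None:
        presence = presence_map(pathway, annotations)
    out: dict[str, RuleOutcome] = {}
    for rule in pathway.rules.values():
        sensor_seen = rule.sensor is None or (
            annotations.has_symbol(rule.sensor, "microbiome")
            or annotations.has_symbol(rule.sensor, "virome")
        )
        active = rule.signal in scenario and sensor_seen
        targets: dict[str, str] = {}
        viral_expressed = False
        microbial_suppressed = False
        for target, mode in rule.effects:
            status = _element_status(pathway, target, presence, annotations)
            if not active:
                targets[target] = "unregulated"
                continue
            if mode == "inhibit":
                targets[target] = "suppressed"
                if status in ("microbial", "both"):
                    microbial_suppressed = True
            else:  # activate
                if status == "absent":
                    targets[target] = "absent"
                else:
                    targets[target] = f"expressed:{status}"
                    if status in ("viral", "combined_only"):
                        viral_expressed = True
        out[rule.id] = RuleOutcome(
            rule_id=rule.id,
            regulator_active=active,
            targets=targets,
            rerouting=active and viral_expressed and microbial_suppressed,
        )
    return out


def default_scenarios(db: PathwayDatabase) -> list[frozenset[str]]:
    """One scenario per distinct signal in the database, plus the empty one."""
    return [frozenset()] + [frozenset({s}) for s in sorted(db.signals())]


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    presence: dict[str, str]
    reaction_classes: dict[str, str]
    complex_statuses: dict[str, str]
    complex_classes: dict[str, str]
    #: rule id -> scenario label -> RuleOutcome
    rule_outcomes: dict[str, dict[str, RuleOutcome]]
    rerouting_rules: frozenset[str]
    compensated: bool


@dataclass
class CompensationReport:
    pathways: list[PathwayResult]
    n_pathways: int
    n_compensated: int
    class_histogram: dict[str, int]
    scenarios: list[frozenset[str]] = field(default_factory=list)

    def pathway(self, pathway_id: str) -> PathwayResult:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def to_frame(self) -> pd.DataFrame:
        """Per-element table: pathway_id, element_id, element_type, origin, class."""
        rows = []
        for p in self.pathways:
            for rid in sorted(p.reaction_classes):
                rows.append(
                    {
                        "pathway_id": p.pathway_id,
                        "element_id": rid,
                        "element_type": "reaction",
                        "origin": p.presence[rid],
                        "class": p.reaction_classes[rid],
                    }
                )
            for cid in sorted(p.complex_classes):
                rows.append(
                    {
                        "pathway_id": p.pathway_id,
                        "element_id": cid,
                        "element_type": "complex",
                        "origin": p.complex_statuses[cid],
                        "class": p.complex_classes[cid],
                    }
                )
            for rule_id in sorted(p.rule_outcomes):
                rows.append(
                    {
                        "pathway_id": p.pathway_id,
                        "element_id": rule_id,
                        "element_type": "rule",
                        "origin": "",
                        "class": "regulatory_rerouting"
                        if rule_id in p.rerouting_rules
                        else "no_rerouting",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["pathway_id", "element_id", "element_type", "origin", "class"],
        )

    def summary(self) -> dict:
        return {
            "n_pathways": self.n_pathways,
            "n_compensated": self.n_compensated,
            "class_histogram": dict(sorted(self.class_histogram.items())),
        }


def _scenario_label(scenario: frozenset[str]) -> str:
    return "+".join(sorted(scenario)) if scenario else "none"


def compensation_report(
    db: PathwayDatabase,
    annotations: GeneAnnotationTable,
    scenarios: list[frozenset[str]] | None = None,
) -> CompensationReport:
    """Run the full compensation analysis over a pathway database.

    Applies :func:`vircomp.pathways.presence_map`,
    :func:`classify_viral_reaction`, :func:`complex_status` and
    :func:`evaluate_regulation` (over ``scenarios``, by default one per
    distinct signal plus the empty scenario) to every pathway, flags each
    pathway as compensated iff at least one of its elements classifies into
    a compensation class, and aggregates totals.
    """
    if scenarios is None:
        scenarios = default_scenarios(db)
    results: list[PathwayResult] = []
    histogram: dict[str, int] = {c: 0 for c in sorted(COMPENSATION_CLASSES)}
    histogram.update({"shared": 0, "microbe_only": 0, "disconnected": 0,
                      "undetected": 0})
    for pathway in db:
        presence = presence_map(pathway, annotations)
        reaction_classes: dict[str, str] = {}
        for rid in pathway.reactions:
            origin = presence[rid]
            if origin == "viral":
                reaction_classes[rid] = classify_viral_reaction(
                    pathway, presence, rid
                )
            elif origin == "both":
                reaction_classes[rid] = "shared"
            elif origin == "microbial":
                reaction_classes[rid] = "microbe_only"
            else:
                reaction_classes[rid] = "undetected"
        complex_statuses = {
            cid: complex_status(cx, annotations)
            for cid, cx in pathway.complexes.items()
        }
        complex_classes = {}
        for cid, status in complex_statuses.items():
            if status in ("viral", "combined_only"):
                complex_classes[cid] = "complex_completion"
            elif status == "microbial":
                complex_classes[cid] = "microbe_only"
            else:
                complex_classes[cid] = "undetected"
        rule_outcomes: dict[str, dict[str, RuleOutcome]] = {
            rule_id: {} for rule_id in pathway.rules
        }
        rerouting: set[str] = set()
        for scenario in scenarios:
            usable = scenario & pathway.signals()
            outcomes = evaluate_regulation(
                pathway, annotations, usable, presence=presence
            )
            label = _scenario_label(scenario)
            for rule_id, outcome in outcomes.items():
                rule_outcomes[rule_id][label] = outcome
                if outcome.rerouting:
                    rerouting.add(rule_id)
        classes = set(reaction_classes.values()) | set(complex_classes.values())
        if rerouting:
            classes.add("regulatory_rerouting")
        compensated = bool(classes & COMPENSATION_CLASSES)
        for c in reaction_classes.values():
            histogram[c] = histogram.get(c, 0) + 1
        for c in complex_classes.values():
            histogram[c] = histogram.get(c, 0) + 1
        histogram["regulatory_rerouting"] += len(rerouting)
        results.append(
            PathwayResult(
                pathway_id=pathway.id,
                name=pathway.name,
                presence=presence,
                reaction_classes=reaction_classes,
                complex_statuses=complex_statuses,
                complex_classes=complex_classes,
                rule_outcomes=rule_outcomes,
                rerouting_rules=frozenset(rerouting),
                compensated=compensated,
            )
        )
    return CompensationReport(
        pathways=results,
        n_pathways=len(db),
        n_compensated=sum(1 for r in results if r.compensated),
        class_histogram=histogram,
        scenarios=list(scenarios),
    )
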