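from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import found_classes, random_pathway
from vircomp.compensation import (
    classify_viral_reaction,
    compensation_report,
    complex_status,
    default_scenarios,
    evaluate_regulation,
)
from vircomp.errors import LookupError_, ParameterError
from vircomp.pathways import PathwayDatabase, presence_map
from vircomp.synthetic import ScenarioParams, generate_annotations
from vircomp.tally import ANNOTATION_COLUMNS, GeneAnnotationTable


# --- independent brute-force oracle -----------------------------------------


def _closure(edges, start):
    reached = set(start)
    changed = True
    while changed:
        changed = False
        for subs, prods in edges:
            if set(subs) <= reached and not set(prods) <= reached:
                reached |= set(prods)
                changed = True
    return reached


def _edges(pathway, rids):
    out = []
    for rid in rids:
        r = pathway.reactions[rid]
        out.append((r.substrates, r.products))
        if r.reversible:
            out.append((r.products, r.substrates))
    return out


def oracle_classify(pathway, presence, rid):
    """Exhaustive-enumeration classifier for small pathways.

    Route lengths are found by enumerating every subset of microbial
    reactions and taking, per product, the smallest subset whose closure from
    the viral reaction's substrates contains it.
    """
    rxn = pathway.reactions[rid]
    micro = [r for r in pathway.reactions
             if presence.get(r) in ("microbial", "both")]
    detected = [r for r in pathway.reactions
                if presence.get(r) in ("microbial", "both", "viral")]
    if not rxn.substrates <= _closure(_edges(pathway, detected), pathway.seeds):
        return "disconnected"
    per_product = {}
    for prod in rxn.products:
        best = None
        for k in range(len(micro) + 1):
            for combo in combinations(micro, k):
                if prod in _closure(_edges(pathway, combo), rxn.substrates):
                    best = k
                    break
            if best is not None:
                break
        per_product[prod] = best
    if all(v is not None for v in per_product.values()):
        return "shortcut" if max(per_product.values()) > 1 else "parallel_branch"
    targets = pathway.declared_targets
    if rxn.products & targets:
        return "gap_fill"
    with_rxn = _closure(_edges(pathway, detected), pathway.seeds)
    without = _closure(
        _edges(pathway, [r for r in detected if r != rid]), pathway.seeds
    )
    if (with_rxn - without) & targets:
        return "gap_fill"
    return "branch_extension"


# --- fixture-driven behaviour ------------------------------------------------


def test_fixture_presence_calls(vent_fixture):
    db, ann = vent_fixture
    presence = presence_map(db["P1"], ann)
    assert presence == {"P1_R1": "microbial", "P1_R2": "microbial",
                        "P1_R3": "viral"}
    presence3 = presence_map(db["P3"], ann)
    assert presence3["Frd"] == "microbial"
    assert presence3["Nar"] == "viral"
    assert presence3["P3_UHPT"] == "absent"


@pytest.mark.parametrize(
    "pid,rid,expected",
    [
        ("P1", "P1_R3", "parallel_branch"),  # same edge, different enzyme
        ("P2", "P2_R5", "shortcut"),         # direct aspartate -> fumarate
        ("P4", "P4_R1", "gap_fill"),         # CTH, no microbial route
        ("P4", "P4_R2", "gap_fill"),
        ("P5", "P5_R1", "gap_fill"),
        ("P6", "P6_R2", "branch_extension"),  # GDP-D-rhamnose, not a target
        ("P6", "P6_R3", "gap_fill"),          # on the route to the target
    ],
)
def test_fixture_reaction_classes(vent_fixture, pid, rid, expected):
    db, ann = vent_fixture
    pathway = db[pid]
    presence = presence_map(pathway, ann)
    assert classify_viral_reaction(pathway, presence, rid) == expected


def test_classify_rejects_non_viral(vent_fixture):
    db, ann = vent_fixture
    pathway = db["P1"]
    presence = presence_map(pathway, ann)
    with pytest.raises(ParameterError):
        classify_viral_reaction(pathway, presence, "P1_R1")


def test_complex_status_cases(vent_fixture):
    db, ann = vent_fixture
    p3 = db["P3"]
    assert complex_status(p3.complexes["Nar"], ann) == "viral"
    assert complex_status(p3.complexes["Frd"], ann) == "microbial"

    def table(rows):
        return GeneAnnotationTable(
            pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
        )

    split = table(
        [
            {"gene_id": f"g{i}", "sample_id": "s", "fraction": f, "ec": "",
             "ko": ko, "category": "", "pathway_ids": ""}
            for i, (f, ko) in enumerate(
                [("microbiome", "NarG"), ("microbiome", "NarH"),
                 ("virome", "NarJ"), ("virome", "NarI")]
            )
        ]
    )
    assert complex_status(p3.complexes["Nar"], split) == "combined_only"
    missing = table(
        [
            {"gene_id": f"g{i}", "sample_id": "s", "fraction": "virome",
             "ec": "", "ko": ko, "category": "", "pathway_ids": ""}
            for i, ko in enumerate(["NarG", "NarH", "NarJ"])
        ]
    )
    assert complex_status(p3.complexes["Nar"], missing) == "absent"


def test_regulation_nitrate_scenario(vent_fixture):
    db, ann = vent_fixture
    p3 = db["P3"]
    out = evaluate_regulation(p3, ann, {"nitrate"})
    rule = out["P3_RULE_NO3"]
    assert rule.regulator_active
    assert rule.targets["Frd"] == "suppressed"
    assert rule.targets["Nar"] == "expressed:viral"
    assert rule.rerouting
    assert not out["P3_RULE_NO2"].regulator_active


def test_regulation_empty_scenario(vent_fixture):
    db, ann = vent_fixture
    out = evaluate_regulation(db["P3"], ann, set())
    assert not any(r.regulator_active for r in out.values())
    assert not any(r.rerouting for r in out.values())
    assert all(v == "unregulated"
               for r in out.values() for v in r.targets.values())


def test_regulation_nar_knockout_loses_function(vent_fixture):
    db, ann = vent_fixture
    no_nar = GeneAnnotationTable(
        ann.frame[~ann.frame["ko"].isin(["NarG", "NarH", "NarJ", "NarI"])]
    )
    out = evaluate_regulation(db["P3"], no_nar, {"nitrate"})
    rule = out["P3_RULE_NO3"]
    assert rule.targets["Frd"] == "suppressed"
    assert rule.targets["Nar"] == "absent"
    assert not rule.rerouting


def test_regulation_oxygen_rule_has_no_sensor_requirement(vent_fixture):
    db, ann = vent_fixture
    out = evaluate_regulation(db["P3"], ann, {"oxygen"})
    assert out["P3_RULE_O2"].regulator_active
    assert out["P3_RULE_O2"].targets["Nar"] == "expressed:viral"
    # nothing microbial suppressed under oxygen -> no rerouting flag
    assert not out["P3_RULE_O2"].rerouting


def test_regulation_unknown_signal(vent_fixture):
    db, ann = vent_fixture
    with pytest.raises(LookupError_):
        evaluate_regulation(db["P3"], ann, {"sulfate"})


def test_report_on_fixture(vent_fixture):
    db, ann = vent_fixture
    report = compensation_report(db, ann)
    assert report.n_pathways == 6
    assert report.n_compensated == 6
    p3 = report.pathway("P3")
    assert p3.complex_classes["Nar"] == "complex_completion"
    assert {"P3_RULE_NO3", "P3_RULE_NO2"} <= set(p3.rerouting_rules)
    frame = report.to_frame()
    assert set(frame.columns) == {"pathway_id", "element_id", "element_type",
                                  "origin", "class"}


def test_no_viral_genes_no_compensation(vent_fixture):
    db, ann = vent_fixture
    report = compensation_report(db, ann.drop_fraction("virome"))
    assert report.n_compensated == 0


def test_default_scenarios_cover_all_signals(vent_fixture):
    db, _ = vent_fixture
    scenarios = default_scenarios(db)
    assert frozenset() in scenarios
    assert frozenset({"nitrate"}) in scenarios
    assert len(scenarios) == 1 + len(db.signals())


# --- randomized properties ---------------------------------------------------


def test_classifier_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(150):
        pathway, presence = random_pathway(rng)
        for rid, origin in presence.items():
            if origin != "viral":
                continue
            got = classify_viral_reaction(pathway, presence, rid)
            want = oracle_classify(pathway, presence, rid)
            assert got == want, (pathway, presence, rid)
            checked += 1
    assert checked > 100


def test_deleting_microbial_reactions_moves_toward_gap_fill():
    rank = {"parallel_branch": 0, "shortcut": 1,
            "branch_extension": 2, "gap_fill": 2}
    rng = np.random.default_rng(77)
    checked = 0
    for _ in range(150):
        pathway, presence = random_pathway(rng)
        viral = [r for r, o in presence.items() if o == "viral"]
        micro = [r for r, o in presence.items() if o in ("microbial", "both")]
        if not viral or not micro:
            continue
        victim = micro[int(rng.integers(len(micro)))]
        weaker = dict(presence)
        weaker[victim] = "absent"
        for rid in viral:
            before = classify_viral_reaction(pathway, presence, rid)
            after = classify_viral_reaction(pathway, weaker, rid)
            if before == "disconnected" or after == "disconnected":
                continue
            assert rank[after] >= rank[before]
            checked += 1
    assert checked > 50


def test_n_compensated_invariant_under_order_permutation():
    bundle = generate_annotations(ScenarioParams(seed=12))
    rep = compensation_report(bundle.db, bundle.annotations)
    shuffled = PathwayDatabase(list(reversed(bundle.db.pathways)))
    rep2 = compensation_report(shuffled, bundle.annotations)
    assert rep.n_compensated == rep2.n_compensated
    assert rep.class_histogram == rep2.class_histogram


def test_planted_ground_truth_recovered_exactly():
    params = ScenarioParams(
        n_pathways=7,
        planted_counts={"gap_fill": 3, "shortcut": 2, "parallel_branch": 2,
                        "branch_extension": 2, "complex_completion": 2},
        seed=99,
    )
    bundle = generate_annotations(params)
    report = compensation_report(bundle.db, bundle.annotations)
    truth = {
        (r.pathway_id, r.element_id): r.true_class
        for r in bundle.labels.itertuples()
    }
    assert found_classes(report) == truth
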