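import numpy as np
import pytest

import vircomp
from vircomp.pathways import Compound, Pathway, Reaction


@pytest.fixture(scope="session")
def vent_fixture():
    """Packaged six-pathway vent fixture: (PathwayDatabase, GeneAnnotationTable)."""
    return vircomp.vent_fixture()


def found_classes(report):
    """(pathway_id, element_id) -> class, for planted elements of a report."""
    interesting = {"gap_fill", "shortcut", "parallel_branch",
                   "branch_extension", "complex_completion", "disconnected"}
    out = {}
    for p in report.pathways:
        for rid, cls in p.reaction_classes.items():
            if cls in interesting:
                out[(p.pathway_id, rid)] = cls
        for cid, cls in p.complex_classes.items():
            if cls == "complex_completion":
                out[(p.pathway_id, cid)] = cls
    return out


def random_pathway(rng: np.random.Generator, max_compounds: int = 6,
                   max_reactions: int = 6):
    """A random small pathway plus a random presence map, for oracle tests."""
    n_c = int(rng.integers(3, max_compounds + 1))
    ids = [f"c{i}" for i in range(n_c)]
    seeds = set(rng.choice(ids, size=int(rng.integers(1, n_c)), replace=False))
    targets = set(
        rng.choice(ids, size=int(rng.integers(0, n_c)), replace=False)
    )
    compounds = {
        c: Compound(c, is_seed=c in seeds, is_target=c in targets) for c in ids
    }
    n_r = int(rng.integers(1, max_reactions + 1))
    reactions = {}
    presence = {}
    for j in range(n_r):
        subs = set(rng.choice(ids, size=int(rng.integers(1, 3)), replace=False))
        rest = [c for c in ids if c not in subs]
        if not rest:
            continue
        prods = set(
            rng.choice(rest, size=int(rng.integers(1, min(3, len(rest) + 1))),
                       replace=False)
        )
        rid = f"r{j}"
        reactions[rid] = Reaction(
            id=rid, ec=f"1.1.1.{j + 1}", substrates=frozenset(subs),
            products=frozenset(prods),
            reversible=bool(rng.random() < 0.2),
        )
        presence[rid] = str(
            rng.choice(["microbial", "viral", "both", "absent"],
                       p=[0.4, 0.35, 0.15, 0.1])
        )
    pathway = Pathway(id="RND", compounds=compounds, reactions=reactions)
    pathway.validate()
    return pathway, presence
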