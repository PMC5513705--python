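"""Directed compound–reaction pathway graphs with complexes and regulatory rules.

A :class:`Pathway` is a small hypergraph: compounds are nodes, reactions are
directed hyperedges consuming a substrate set and producing a product set.
Compounds carry ``is_seed`` (available input) and ``is_target`` (required
product) flags that anchor reachability and gap-fill semantics. Multi-subunit
enzymes (e.g. nitrate reductase NarGHJI) are :class:`ProteinComplex` records,
and two-component signalling (sensor kinase + response regulator, e.g.
NarX/NarL) is captured by :class:`RegulatoryRule` records whose effects
activate or inhibit complexes or reactions.

Reachability is conjunctive: a reaction fires only when *all* of its
substrates are reachable. Currency metabolites are simply not encoded rather
than special-cased.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, PathwayValidationError

__all__ = [
    "Compound",
    "Reaction",
    "ProteinComplex",
    "RegulatoryRule",
    "Pathway",
    "PathwayDatabase",
    "normalize_ec",
    "normalize_symbol",
    "load_pathway_db",
    "store_pathway_db",
    "presence_map",
    "reachable_compounds",
    "closure_levels",
]

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

ORIGINS = ("microbial", "viral", "both", "absent")


def normalize_ec(ec: str) -> str:
    """Normalize an EC string: drop an optional ``EC `` prefix, trim, lowercase.

    Partial ECs with a trailing ``-`` are kept verbatim and only ever match an
    identical partial string. Raises :class:`FormatError` on malformed input.
    """
    s = ec.strip()
    if s.lower().startswith("ec "):
        s = s[3:].strip()
    s = s.lower()
    if not _EC_RE.match(s):
        raise FormatError(f"malformed EC number: {ec!r}")
    return s


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive normalization for gene symbols (CTH, NarG, ...)."""
    return symbol.strip().lower()


@dataclass(frozen=True)
class Compound:
    id: str
    name: str = ""
    is_seed: bool = False
    is_target: bool = False


@dataclass(frozen=True)
class Reaction:
    """A directed transformation; identified by EC number and/or gene symbol."""

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    ec: str | None = None
    symbol: str | None = None
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if self.ec is not None:
            object.__setattr__(self, "ec", normalize_ec(self.ec))


@dataclass(frozen=True)
class ProteinComplex:
    id: str
    subunits: frozenset[str]
    function: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subunits", frozenset(self.subunits))


@dataclass(frozen=True)
class RegulatoryRule:
    """signal --sensor--> regulator --> (activate|inhibit) targets."""

    id: str
    signal: str
    effects: tuple[tuple[str, str], ...]
    sensor: str | None = None
    regulator: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "effects", tuple((str(t), str(m)) for t, m in self.effects)
        )


@dataclass
class Pathway:
    id: str
    name: str = ""
    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    complexes: dict[str, ProteinComplex] = field(default_factory=dict)
    rules: dict[str, RegulatoryRule] = field(default_factory=dict)

    def validate(self) -> None:
        """Check structural invariants; raise PathwayValidationError naming ids."""
        for rxn in self.reactions.values():
            if not rxn.substrates or not rxn.products:
                raise PathwayValidationError(
                    f"pathway {self.id}: reaction {rxn.id} has empty substrate "
                    f"or product set"
                )
            if rxn.substrates & rxn.products:
                raise PathwayValidationError(
                    f"pathway {self.id}: reaction {rxn.id} has overlapping "
                    f"substrates and products"
                )
            for cid in rxn.substrates | rxn.products:
                if cid not in self.compounds:
                    raise PathwayValidationError(
                        f"pathway {self.id}: reaction {rxn.id} references "
                        f"unknown compound {cid!r}"
                    )
        for cx in self.complexes.values():
            if len(cx.subunits) < 2:
                raise PathwayValidationError(
                    f"pathway {self.id}: complex {cx.id} needs >=2 subunits"
                )
        targets = set(self.reactions) | set(self.complexes)
        for rule in self.rules.values():
            for target, mode in rule.effects:
                if target not in targets:
                    raise PathwayValidationError(
                        f"pathway {self.id}: rule {rule.id} targets unknown "
                        f"element {target!r}"
                    )
                if mode not in ("activate", "inhibit"):
                    raise PathwayValidationError(
                        f"pathway {self.id}: rule {rule.id} has invalid mode "
                        f"{mode!r}"
                    )
        if not any(c.is_seed for c in self.compounds.values()):
            raise PathwayValidationError(
                f"pathway {self.id}: no seed compound declared"
            )

    @property
    def seeds(self) -> frozenset[str]:
        return frozenset(c.id for c in self.compounds.values() if c.is_seed)

    @property
    def declared_targets(self) -> frozenset[str]:
        return frozenset(c.id for c in self.compounds.values() if c.is_target)

    def signals(self) -> frozenset[str]:
        return frozenset(r.signal for r in self.rules.values())


@dataclass
class PathwayDatabase:
    pathways: list[Pathway] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.pathways:
            if p.id in seen:
                raise PathwayValidationError(f"duplicate pathway id {p.id!r}")
            seen.add(p.id)
            p.validate()

    def signals(self) -> frozenset[str]:
        sigs: set[str] = set()
        for p in self.pathways:
            sigs |= p.signals()
        return frozenset(sigs)


# ---------------------------------------------------------------------------
# JSON serialization (single document per database; schema in data/)
# ---------------------------------------------------------------------------


def _pathway_to_dict(p: Pathway) -> dict:
    return {
        "id": p.id,
        "name": p.name,
        "compounds": [
            {
                "id": c.id,
                "name": c.name,
                "is_seed": c.is_seed,
                "is_target": c.is_target,
            }
            for c in p.compounds.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "ec": r.ec,
                "symbol": r.symbol,
                "substrates": sorted(r.substrates),
                "products": sorted(r.products),
                "reversible": r.reversible,
            }
            for r in p.reactions.values()
        ],
        "complexes": [
            {"id": cx.id, "subunits": sorted(cx.subunits), "function": cx.function}
            for cx in p.complexes.values()
        ],
        "rules": [
            {
                "id": rule.id,
                "signal": rule.signal,
                "sensor": rule.sensor,
                "regulator": rule.regulator,
                "effects": [{"target": t, "mode": m} for t, m in rule.effects],
            }
            for rule in p.rules.values()
        ],
    }


def _pathway_from_dict(d: Mapping) -> Pathway:
    compounds = {
        c["id"]: Compound(
            id=c["id"],
            name=c.get("name", ""),
            is_seed=bool(c.get("is_seed", False)),
            is_target=bool(c.get("is_target", False)),
        )
        for c in d.get("compounds", [])
    }
    reactions = {
        r["id"]: Reaction(
            id=r["id"],
            ec=r.get("ec"),
            symbol=r.get("symbol"),
            substrates=frozenset(r["substrates"]),
            products=frozenset(r["products"]),
            reversible=bool(r.get("reversible", False)),
        )
        for r in d.get("reactions", [])
    }
    complexes = {
        cx["id"]: ProteinComplex(
            id=cx["id"],
            subunits=frozenset(cx["subunits"]),
            function=cx.get("function", ""),
        )
        for cx in d.get("complexes", [])
    }
    rules = {
        rule["id"]: RegulatoryRule(
            id=rule["id"],
            signal=rule["signal"],
            sensor=rule.get("sensor"),
            regulator=rule.get("regulator"),
            effects=tuple(
                (e["target"], e["mode"]) for e in rule.get("effects", [])
            ),
        )
        for rule in d.get("rules", [])
    }
    return Pathway(
        id=d["id"],
        name=d.get("name", ""),
        compounds=compounds,
        reactions=reactions,
        complexes=complexes,
        rules=rules,
    )


def load_pathway_db(path) -> PathwayDatabase:
    """Load and validate a pathway database from a single JSON document."""
    with open(path) as fh:
        doc = json.load(fh)
    db = PathwayDatabase([_pathway_from_dict(d) for d in doc["pathways"]])
    db.validate()
    return db


def store_pathway_db(db: PathwayDatabase, path) -> None:
    """Write a database as JSON; ``load(store(db)) == db``."""
    doc = {"pathways": [_pathway_to_dict(p) for p in db.pathways]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Presence calls and reachability
# ---------------------------------------------------------------------------


def _origin_from_fractions(in_micro: bool, in_viral: bool) -> str:
    if in_micro and in_viral:
        return "both"
    if in_micro:
        return "microbial"
    if in_viral:
        return "viral"
    return "absent"


def presence_map(pathway: Pathway, annotations) -> dict[str, str]:
    """Call each reaction's and complex's origin from annotation evidence.

    A reaction matches a fraction when that fraction contains a gene whose
    normalized EC equals the reaction's EC, or — when the reaction has no EC —
    whose symbol matches case-insensitively. A complex's origin is decided
    subunit-wise (see :func:`vircomp.compensation.complex_status`): all
    subunits in one fraction gives that fraction; a full set only when
    pooling gives ``both``; anything less is ``absent``.
    """
    from .compensation import complex_status  # subunit-wise rule lives there

    out: dict[str, str] = {}
    for rxn in pathway.reactions.values():
        if rxn.ec is not None:
            in_m = annotations.has_ec(rxn.ec, "microbiome")
            in_v = annotations.has_ec(rxn.ec, "virome")
        elif rxn.symbol is not None:
            in_m = annotations.has_symbol(rxn.symbol, "microbiome")
            in_v = annotations.has_symbol(rxn.symbol, "virome")
        else:
            in_m = in_v = False
        out[rxn.id] = _origin_from_fractions(in_m, in_v)
    for cx in pathway.complexes.values():
        status = complex_status(cx, annotations)
        out[cx.id] = {"combined_only": "both"}.get(status, status)
    return out


def reachable_compounds(
    pathway: Pathway, active_reactions: Iterable[str]
) -> frozenset[str]:
    """Fixed-point reachable set from the pathway's seeds.

    A reaction fires when all of its substrates are reachable; its products
    then become reachable. Reversible reactions fire in either direction.
    The fixed point is reached in at most ``len(reactions) + 1`` sweeps.
    """
    return frozenset(
        closure_levels(pathway, active_reactions, pathway.seeds)
    )


def closure_levels(
    pathway: Pathway,
    active_reactions: Iterable[str],
    start: Iterable[str],
) -> dict[str, int]:
    """Conjunctive closure from ``start``, annotated with the sweep index at
    which each compound first became reachable (start compounds are level 0).

    The level of a compound is the length, in reaction steps, of the shortest
    cascade that produces it when every fireable reaction fires each sweep.
    """
    active = set(active_reactions)
    unknown = active - set(pathway.reactions)
    if unknown:
        raise PathwayValidationError(
            f"pathway {pathway.id}: unknown active reaction(s) {sorted(unknown)}"
        )
    levels: dict[str, int] = {c: 0 for c in start}
    edges: list[tuple[frozenset[str], frozenset[str]]] = []
    for rid in active:
        rxn = pathway.reactions[rid]
        edges.append((rxn.substrates, rxn.products))
        if rxn.reversible:
            edges.append((rxn.products, rxn.substrates))
    sweep = 0
    changed = True
    while changed:
        sweep += 1
        changed = False
        reached = set(levels)
        for subs, prods in edges:
            if subs <= reached:
                for c in prods:
                    if c not in levels:
                        levels[c] = sweep
                        changed = True
    return levels
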