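"""Reaction catalog: parsing, filtering, and direction expansion.

The pipeline starts from a catalog of *enzyme reactions* — metabolite
transformations catalyzed by a *unique enzyme function* (an EC-number
annotation). One enzyme function may catalyze several reactions and one
reaction may be catalyzed by several enzyme functions, so the catalog
key is the (reaction_id, enzyme_id) pair. Stoichiometric coefficients
are parsed and discarded: the method scores relative turnover, not
quantity, so each side of a reaction is a *set* of metabolite ids.

Two input dialects are supported:

* ``generic-tsv`` — one reaction per row with columns ``reaction_id``,
  ``enzyme_id``, ``direction`` (``=>`` irreversible, ``<=>`` reversible),
  ``substrates``/``products`` (semicolon-separated), and optional
  ``pathway_ids``.
* ``kegg-flatfile`` — KEGG-REACTION-style records separated by ``///``;
  only ENTRY, ENZYME, EQUATION and PATHWAY lines are consumed, and a
  record listing k EC numbers yields k reactions sharing metabolites.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

GENERIC_TSV_COLUMNS = (
    "reaction_id",
    "enzyme_id",
    "direction",
    "substrates",
    "products",
    "pathway_ids",
)

#: leading stoichiometric coefficient token: "2", "(n+1)", "3n", "0.5" ...
_COEFF_RE = re.compile(r"^\(?(?:\d+(?:\.\d+)?|n(?:[+-]\d+)?|\d+n)\)?$")


@dataclass(frozen=True)
class Reaction:
    """A metabolite transformation catalyzed by one enzyme function.

    ``substrates`` and ``products`` are sets of metabolite ids (never
    empty); a reaction whose substrate set equals its product set is
    legal but contributes zero net connectivity downstream.
    """

    reaction_id: str
    enzyme_id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool
    pathway_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.enzyme_id:
            raise ValueError(f"reaction {self.reaction_id!r}: empty enzyme_id")
        if not self.substrates:
            raise ValueError(f"reaction {self.reaction_id!r}: empty substrate set")
        if not self.products:
            raise ValueError(f"reaction {self.reaction_id!r}: empty product set")


@dataclass(frozen=True)
class DirectedReaction:
    """One direction of a reaction: ``consumed`` -> ``produced``.

    A reversible reaction expands to two mirror-image directed
    reactions; an irreversible one to exactly one.
    """

    reaction_id: str
    enzyme_id: str
    consumed: frozenset[str]
    produced: frozenset[str]
    direction: str = "forward"  # forward | reverse


@dataclass
class ReactionCatalog:
    """The parsed, filtered set of enzyme reactions."""

    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rxn in self.reactions:
            key = (rxn.reaction_id, rxn.enzyme_id)
            if key in seen:
                raise ValueError(f"duplicate reaction/enzyme pair {key!r} in catalog")
            seen.add(key)

    @property
    def metabolite_universe(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.substrates | rxn.products
        return out

    @property
    def enzyme_universe(self) -> set[str]:
        return {rxn.enzyme_id for rxn in self.reactions}

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionCatalog):
            return NotImplemented
        return self.reactions == other.reactions


def _strip_coefficient(token: str) -> str:
    parts = token.split()
    if len(parts) > 1 and _COEFF_RE.match(parts[0]):
        parts = parts[1:]
    return " ".join(parts)


def _parse_metabolite_field(raw: str) -> frozenset[str]:
    items = [_strip_coefficient(part.strip()) for part in raw.split(";")]
    return frozenset(item for item in items if item)


def _open_lines(source) -> Iterable[str]:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8").splitlines()
    if isinstance(source, str):
        if "\n" not in source and "\t" not in source and Path(source).exists():
            return Path(source).read_text(encoding="utf-8").splitlines()
        return source.splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return list(source)


def parse_reaction_table(source, dialect: str = "generic-tsv") -> ReactionCatalog:
    """Parse a reaction catalog from ``source`` (path, text, or file).

    Raises ``ValueError`` on duplicate (reaction_id, enzyme_id) pairs,
    empty substrate/product fields, or unknown direction tokens, naming
    the offending line.
    """
    if dialect == "generic-tsv":
        return _parse_generic_tsv(_open_lines(source))
    if dialect == "kegg-flatfile":
        return _parse_kegg_flatfile(_open_lines(source))
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_generic_tsv(lines: Iterable[str]) -> ReactionCatalog:
    reactions: list[Reaction] = []
    seen: set[tuple[str, str]] = set()
    header: list[str] | None = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [h.strip() for h in fields]
            missing = [c for c in GENERIC_TSV_COLUMNS[:5] if c not in header]
            if missing:
                raise ValueError(f"line {lineno}: missing required columns {missing}")
            continue
        row = dict(zip(header, fields))
        rid = row.get("reaction_id", "").strip()
        eid = row.get("enzyme_id", "").strip()
        key = (rid, eid)
        if key in seen:
            raise ValueError(f"line {lineno}: duplicate reaction/enzyme pair {key!r}")
        direction = row.get("direction", "").strip()
        if direction == "<=>":
            reversible = True
        elif direction == "=>":
            reversible = False
        else:
            raise ValueError(f"line {lineno}: unknown direction token {direction!r}")
        substrates = _parse_metabolite_field(row.get("substrates", ""))
        products = _parse_metabolite_field(row.get("products", ""))
        if not substrates:
            raise ValueError(f"line {lineno}: empty substrate field")
        if not products:
            raise ValueError(f"line {lineno}: empty product field")
        pathway_ids = frozenset(
            p.strip() for p in row.get("pathway_ids", "").split(";") if p.strip()
        )
        reactions.append(
            Reaction(rid, eid, substrates, products, reversible, pathway_ids)
        )
        seen.add(key)
    if not reactions:
        logger.warning("parsed an empty reaction catalog")
    return ReactionCatalog(reactions)


def _parse_kegg_flatfile(lines: Iterable[str]) -> ReactionCatalog:
    reactions: list[Reaction] = []
    no_ec = 0
    record: dict[str, list[str]] = {}
    current_key = None
    records: list[dict[str, list[str]]] = []
    for line in lines:
        if line.startswith("///"):
            if record:
                records.append(record)
            record, current_key = {}, None
            continue
        if not line.strip():
            continue
        if line[:1] != " ":
            current_key = line[:12].strip()
            record.setdefault(current_key, []).append(line[12:].strip())
        elif current_key is not None:
            record[current_key].append(line.strip())
    if record:
        records.append(record)

    for rec in records:
        entry_field = rec.get("ENTRY", [""])[0]
        entry = entry_field.split()[0] if entry_field.split() else ""
        equation = " ".join(rec.get("EQUATION", []))
        enzymes: list[str] = []
        for chunk in rec.get("ENZYME", []):
            enzymes.extend(chunk.split())
        pathways = frozenset(
            chunk.split()[0] for chunk in rec.get("PATHWAY", []) if chunk.split()
        )
        if not equation or not entry:
            continue
        if not enzymes:
            no_ec += 1
            continue
        if "<=>" in equation:
            lhs, rhs = equation.split("<=>", 1)
            reversible = True
        elif "=>" in equation:
            lhs, rhs = equation.split("=>", 1)
            reversible = False
        else:
            raise ValueError(f"record {entry}: no direction token in EQUATION")
        substrates = frozenset(
            _strip_coefficient(t.strip()) for t in lhs.split(" + ") if t.strip()
        )
        products = frozenset(
            _strip_coefficient(t.strip()) for t in rhs.split(" + ") if t.strip()
        )
        if not substrates or not products:
            raise ValueError(f"record {entry}: empty equation side")
        for ec in enzymes:
            reactions.append(
                Reaction(entry, ec, substrates, products, reversible, pathways)
            )
    if no_ec:
        logger.info("dropped %d flat-file records lacking an EC number", no_ec)
    if not reactions:
        logger.warning("parsed an empty reaction catalog")
    return ReactionCatalog(reactions)


def write_reaction_table(catalog: ReactionCatalog, path) -> None:
    """Serialize a catalog to the generic-tsv dialect (lossless round-trip)."""
    out = ["\t".join(GENERIC_TSV_COLUMNS)]
    for rxn in catalog:
        out.append(
            "\t".join(
                [
                    rxn.reaction_id,
                    rxn.enzyme_id,
                    "<=>" if rxn.reversible else "=>",
                    ";".join(sorted(rxn.substrates)),
                    ";".join(sorted(rxn.products)),
                    ";".join(sorted(rxn.pathway_ids)),
                ]
            )
        )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def filter_by_pathways(
    catalog: ReactionCatalog, allowed: set[str]
) -> ReactionCatalog:
    """Keep reactions whose pathway tags intersect ``allowed``.

    Reactions with no pathway tags are dropped (and counted in the log):
    the catalog is meant to contain only reactions from curated
    metabolism pathways, so untagged entries cannot be vouched for.
    """
    if not allowed:
        raise ValueError("allowed pathway set must be non-empty")
    kept, untagged = [], 0
    for rxn in catalog:
        if not rxn.pathway_ids:
            untagged += 1
            continue
        if rxn.pathway_ids & allowed:
            kept.append(rxn)
    if untagged:
        logger.info("dropped %d reactions with no pathway tags", untagged)
    if not kept:
        logger.warning("pathway filter removed every reaction")
    return ReactionCatalog(kept)


def apply_metabolite_blacklist(
    catalog: ReactionCatalog, blacklist: set[str]
) -> ReactionCatalog:
    """Remove currency metabolites from every reaction side.

    A reaction whose substrate OR product side becomes empty is removed
    entirely (it no longer transforms anything specific).
    """
    if not blacklist:
        return ReactionCatalog(list(catalog.reactions))
    kept, dropped = [], 0
    for rxn in catalog:
        subs = rxn.substrates - blacklist
        prods = rxn.products - blacklist
        if not subs or not prods:
            dropped += 1
            continue
        kept.append(replace(rxn, substrates=subs, products=prods))
    if dropped:
        logger.info("blacklist emptied one side of %d reactions; dropped", dropped)
    return ReactionCatalog(kept)


def expand_directions(catalog: ReactionCatalog) -> list[DirectedReaction]:
    """Expand each reaction into directed reactions, forward before reverse.

    Output order is deterministic: catalog order, with the mirror image
    of a reversible reaction immediately following its forward form.
    """
    out: list[DirectedReaction] = []
    for rxn in catalog:
        out.append(
            DirectedReaction(
                rxn.reaction_id, rxn.enzyme_id, rxn.substrates, rxn.products
            )
        )
        if rxn.reversible:
            out.append(
                DirectedReaction(
                    rxn.reaction_id,
                    rxn.enzyme_id,
                    rxn.products,
                    rxn.substrates,
                    direction="reverse",
                )
            )
    return out


def load_blacklist(path) -> set[str]:
    """Read a blacklist file: one metabolite id per line, '#' comments."""
    out: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.add(entry)
    return out


def default_blacklist() -> set[str]:
    """Shipped currency-metabolite list (KEGG ids: water, NTP/NDPs, cofactors)."""
    text = (
        resources.files("prmt").joinpath("data/currency_metabolites.txt").read_text()
    )
    out = set()
    for line in text.splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.add(entry)
    return out
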