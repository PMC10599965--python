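"""GMT parsing, up/down set pairing, and restriction to the measured genes.

GMT has no native notion of signature direction, so directional signatures
are encoded as two lines sharing a stem: ``X.up`` and ``X.dn`` merge into a
single two-part :class:`~smoothscore.datamodel.GeneSet` named ``X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .datamodel import GeneSet, ValidationError

__all__ = ["read_gmt", "write_gmt", "pair_updown_sets", "restrict_to_universe", "RestrictedSet"]

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    """A GMT line does not have the required name/description/genes fields."""


def read_gmt(path: str) -> list[GeneSet]:
    """Parse a GMT file into up-only gene sets, one per line.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are deduplicated; trailing whitespace and empty
    trailing fields are ignored; lines with fewer than three fields (or no
    genes after cleanup) are rejected with their line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n").rstrip()
            if not line:
                continue
            fields = line.split("\t")
            while fields and not fields[-1].strip():
                fields.pop()
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one gene, got {len(fields)} field(s)"
                )
            name = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise GMTParseError(f"{path}: line {lineno}: gene list is empty")
            sets.append(GeneSet(name=name, up_genes=genes))
    return sets


def write_gmt(sets: list[GeneSet], path: str, up_suffix: str = ".up", down_suffix: str = ".dn") -> None:
    """Write gene sets as GMT; a two-part set becomes two suffixed lines."""
    with open(path, "w") as fh:
        for gs in sets:
            if gs.mode == "two-part":
                fh.write("\t".join([gs.name + up_suffix, ""] + sorted(gs.up_genes)) + "\n")
                fh.write("\t".join([gs.name + down_suffix, ""] + sorted(gs.down_genes)) + "\n")
            elif gs.mode == "up-only":
                fh.write("\t".join([gs.name, ""] + sorted(gs.up_genes)) + "\n")
            else:
                fh.write("\t".join([gs.name + down_suffix, ""] + sorted(gs.down_genes)) + "\n")


def pair_updown_sets(
    sets: list[GeneSet], up_suffix: str = ".up", down_suffix: str = ".dn"
) -> list[GeneSet]:
    """Merge ``X.up`` / ``X.dn`` pairs into two-part sets named ``X``.

    Unpaired suffixed sets pass through as up-only or down-only under their
    stem name; non-suffixed sets are unchanged.  A gene present in both
    halves of a pair is an error.
    """
    if not up_suffix or not down_suffix or up_suffix == down_suffix:
        raise ValueError("suffixes must be non-empty and distinct")
    stems: dict[str, dict] = {}
    order: list[tuple[str, str]] = []  # (kind, key) preserving input order

    for gs in sets:
        if gs.name.endswith(up_suffix) and len(gs.name) > len(up_suffix):
            stem, half = gs.name[: -len(up_suffix)], "up"
        elif gs.name.endswith(down_suffix) and len(gs.name) > len(down_suffix):
            stem, half = gs.name[: -len(down_suffix)], "down"
        else:
            order.append(("plain", gs.name))
            stems.setdefault("\0plain:" + gs.name, {})["plain"] = gs
            continue
        key = "\0stem:" + stem
        if key not in stems:
            order.append(("stem", stem))
            stems[key] = {}
        if half in stems[key]:
            raise ValidationError(f"gene set stem {stem!r}: duplicate {half} half")
        stems[key][half] = gs

    out: list[GeneSet] = []
    for kind, name in order:
        if kind == "plain":
            out.append(stems["\0plain:" + name]["plain"])
            continue
        halves = stems["\0stem:" + name]
        up = halves["up"].up_genes if "up" in halves else frozenset()
        down = halves["down"].up_genes if "down" in halves else frozenset()
        both = up & down
        if both:
            raise ValidationError(
                f"gene set {name!r}: gene(s) {sorted(both)[:5]} appear in both "
                "the up and down halves"
            )
        out.append(GeneSet(name=name, up_genes=up, down_genes=down))
    return out


@dataclass(frozen=True)
class RestrictedSet:
    """A gene set intersected with the measured gene universe."""

    name: str
    geneset: GeneSet | None  #: None when nothing in the set was measured
    coverage: float  #: fraction of the original genes that were measured
    scorable: bool


def restrict_to_universe(
    gs: GeneSet, universe, case_insensitive: bool = False
) -> RestrictedSet:
    """Intersect a gene set with the measured universe.

    Matching is exact and case-sensitive unless ``case_insensitive`` is set,
    in which case folded identifiers are compared and the universe spelling
    is kept.  Coverage below 0.5 is logged as a warning; an empty
    intersection flags the set unscorable (scores become missing values).
    """
    universe = set(universe)
    if case_insensitive:
        folded = {u.casefold(): u for u in universe}
        up = frozenset(folded[g.casefold()] for g in gs.up_genes if g.casefold() in folded)
        down = frozenset(folded[g.casefold()] for g in gs.down_genes if g.casefold() in folded)
    else:
        up = gs.up_genes & universe
        down = gs.down_genes & universe
    total = len(gs.all_genes)
    coverage = (len(up) + len(down)) / total if total else 0.0
    if not up and not down:
        logger.warning("gene set %r: no genes measured; set is unscorable", gs.name)
        return RestrictedSet(gs.name, None, 0.0, False)
    if coverage < 0.5:
        logger.warning(
            "gene set %r: only %.0f%% of its genes are measured", gs.name, 100 * coverage
        )
    return RestrictedSet(gs.name, GeneSet(gs.name, up, down), coverage, True)
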