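"""Taxonomy tree handling: taxdump parsing, eight-rank lineage homogenization, LCA.

The benchmarking framework compares classifier calls against expected taxa
rank by rank.  Real taxonomies attach free-form rank labels ("no rank",
"strain", "species group", ...) to nodes, so every taxid is first projected
onto a fixed eight-slot lineage — domain, phylum, class, order, family,
genus, species, subspecies — leaving gaps where a rank is genuinely absent.

Two on-disk dialects are read transparently:

* the NCBI taxdump dialect (``nodes.dmp`` / ``names.dmp``, fields separated
  by ``\\t|\\t`` and lines terminated by ``\\t|``);
* a simplified TSV dialect: 3 columns (id, parent id, rank) for nodes and
  2 columns (id, scientific name) for names.

The dialect is sniffed from the first line of each file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: The eight canonical ranks, shallow to deep.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "subspecies",
)

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Rank-label synonyms folded into a canonical slot.  NCBI writes the top
#: prokaryotic rank as "superkingdom"; both terms are used interchangeably
#: in the field.
RANK_SYNONYMS: dict[str, str] = {"superkingdom": "domain"}


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy dump (orphan, duplicate, cycle...)."""


class UnknownTaxidError(KeyError):
    """A taxid was looked up that the loaded taxonomy does not contain."""

    def __init__(self, taxid: int):
        super().__init__(taxid)
        self.taxid = taxid

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unknown taxid {self.taxid}"


@dataclass(frozen=True)
class Lineage:
    """Projection of a taxid's ancestor path onto the eight canonical ranks.

    ``slots[i]`` is the taxid occupying ``RANKS[i]``, or ``None`` where the
    source lineage has no node of that rank.  Gaps need not be prefix-shaped:
    a lineage may lack ``class`` yet have ``order``, mirroring real
    taxonomies.
    """

    slots: tuple[Optional[int], ...]
    source_taxid: int

    def __post_init__(self) -> None:
        if len(self.slots) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} slots, got {len(self.slots)}")

    def __getitem__(self, rank: str) -> Optional[int]:
        return self.slots[RANK_INDEX[rank]]

    @property
    def deepest_filled(self) -> Optional[int]:
        """Index of the deepest non-empty slot, or None for an empty lineage."""
        for i in range(len(RANKS) - 1, -1, -1):
            if self.slots[i] is not None:
                return i
        return None

    def is_empty(self) -> bool:
        return all(s is None for s in self.slots)

    def to_row(self) -> list[str]:
        """Serialize as 8 strings (empty string for an empty slot)."""
        return ["" if s is None else str(s) for s in self.slots]


@dataclass
class TaxonomyDB:
    """In-memory taxonomy: parent links, rank labels, scientific names.

    ``nodes`` maps taxid -> (parent taxid, rank label); the root is its own
    parent.  ``name_index`` maps a normalized (lower-cased, whitespace-
    collapsed) name to the sorted list of taxids bearing it — homonyms are
    real in taxonomy, so the index is one-to-many.
    """

    nodes: dict[int, tuple[int, str]]
    names: dict[int, str] = field(default_factory=dict)
    name_index: dict[str, list[int]] = field(default_factory=dict)
    root_id: int = 1

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxid: int) -> int:
        try:
            return self.nodes[taxid][0]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def rank(self, taxid: int) -> str:
        try:
            return self.nodes[taxid][1]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def name(self, taxid: int) -> str:
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        return self.names.get(taxid, str(taxid))

    def path_to_root(self, taxid: int) -> list[int]:
        """Taxids from ``taxid`` up to and including the root (leaf first)."""
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        path = [taxid]
        node = taxid
        while node != self.root_id:
            node = self.nodes[node][0]
            path.append(node)
        return path

    def children(self, taxid: int) -> list[int]:
        if taxid not in self.nodes:
            raise UnknownTaxidError(taxid)
        return sorted(
            n for n, (p, _) in self.nodes.items() if p == taxid and n != self.root_id
        )

    def nodes_at_rank(self, rank: str) -> list[int]:
        canon = RANK_SYNONYMS.get(rank, rank)
        return sorted(
            n
            for n, (_, r) in self.nodes.items()
            if RANK_SYNONYMS.get(r, r) == canon
        )

    def leaves(self) -> list[int]:
        """Taxids with no children, sorted."""
        parents = {p for n, (p, _) in self.nodes.items() if n != self.root_id}
        return sorted(n for n in self.nodes if n not in parents)


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).lower()


def _taxdump_fields(line: str) -> list[str]:
    """Split one line in either supported dialect."""
    line = line.rstrip("\n").rstrip("\r")
    if "\t|" in line:
        line = line.rstrip("|").rstrip("\t")
        return [f.strip() for f in line.split("\t|\t")]
    return [f.strip() for f in line.split("\t")]


def load_taxdump(
    nodes_path: str | Path,
    names_path: Optional[str | Path] = None,
    *,
    all_name_classes: bool = False,
) -> TaxonomyDB:
    """Load a taxonomy from nodes/names files in either dialect.

    Parameters
    ----------
    nodes_path
        ``nodes.dmp`` (NCBI dialect) or a 3-column TSV (id, parent, rank).
    names_path
        ``names.dmp`` or a 2-column TSV (id, name).  In the NCBI dialect only
        rows of name class ``scientific name`` populate the index unless
        ``all_name_classes`` is set.
    """
    nodes: dict[int, tuple[int, str]] = {}
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _taxdump_fields(line)
            if len(fields) < 3:
                raise TaxonomyError(
                    f"{nodes_path}:{lineno}: expected >=3 node fields, got {len(fields)}"
                )
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxonomyError(f"{nodes_path}:{lineno}: non-integer id: {exc}") from None
            if taxid in nodes:
                raise TaxonomyError(f"duplicate node id {taxid} at {nodes_path}:{lineno}")
            nodes[taxid] = (parent, fields[2])

    if not nodes:
        raise TaxonomyError(f"no nodes in {nodes_path}")

    roots = [n for n, (p, _) in nodes.items() if p == n]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one self-parented root, found {roots}")
    root_id = roots[0]

    for taxid, (parent, _) in nodes.items():
        if parent not in nodes:
            raise TaxonomyError(f"node {taxid} is orphaned: parent {parent} not in dump")

    # cycle check: every node must reach the root
    depth: dict[int, int] = {root_id: 0}
    for taxid in nodes:
        trail = []
        node = taxid
        while node not in depth:
            trail.append(node)
            node = nodes[node][0]
            if node in trail:
                raise TaxonomyError(f"cycle detected involving node {node}")
        base = depth[node]
        for i, t in enumerate(reversed(trail), start=1):
            depth[t] = base + i

    names: dict[int, str] = {}
    name_index: dict[str, list[int]] = {}
    if names_path is not None:
        with open(names_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = _taxdump_fields(line)
                if len(fields) < 2:
                    raise TaxonomyError(
                        f"{names_path}:{lineno}: expected >=2 name fields"
                    )
                try:
                    taxid = int(fields[0])
                except ValueError:
                    raise TaxonomyError(
                        f"{names_path}:{lineno}: non-integer id {fields[0]!r}"
                    ) from None
                name_class = fields[3] if len(fields) >= 4 else "scientific name"
                if name_class != "scientific name" and not all_name_classes:
                    continue
                name = fields[1]
                if taxid in nodes:
                    if name_class == "scientific name":
                        names.setdefault(taxid, name)
                    key = _normalize_name(name)
                    bucket = name_index.setdefault(key, [])
                    if taxid not in bucket:
                        bucket.append(taxid)
        for bucket in name_index.values():
            bucket.sort()

    return TaxonomyDB(nodes=nodes, names=names, name_index=name_index, root_id=root_id)


def homogenize(
    db: TaxonomyDB, taxid: int, *, strain_as_subspecies: bool = False
) -> Lineage:
    """Project ``taxid``'s ancestor path onto the eight canonical ranks.

    Walking the path root-ward, each ancestor whose rank label is one of the
    eight canonical labels (``superkingdom`` counting as ``domain``) fills
    the matching slot; all other ranks are ignored.  Slots are never
    overwritten — on a pathological lineage carrying a rank twice, the node
    nearest the root wins and a warning is logged.

    With ``strain_as_subspecies``, a ``strain``/``no rank`` node whose parent
    is a species fills the subspecies slot (off by default: taxonomies encode
    below-species nodes inconsistently).
    """
    slots: list[Optional[int]] = [None] * len(RANKS)
    # root-first order so that nearest-to-root wins on duplicate ranks
    for node in reversed(db.path_to_root(taxid)):
        label = RANK_SYNONYMS.get(db.rank(node), db.rank(node))
        idx = RANK_INDEX.get(label)
        if idx is None and strain_as_subspecies and label in ("strain", "no rank"):
            parent = db.parent(node)
            if node != db.root_id and db.rank(parent) == "species":
                idx = RANK_INDEX["subspecies"]
        if idx is None:
            continue
        if slots[idx] is not None:
            logger.warning(
                "taxid %d: rank %r occurs twice on lineage of %d; keeping %d",
                node, label, taxid, slots[idx],
            )
            continue
        slots[idx] = node
    return Lineage(slots=tuple(slots), source_taxid=taxid)


def lca(db: TaxonomyDB, taxids: Sequence[int]) -> int:
    """Lowest common ancestor of ``taxids``: the deepest node lying on every
    member's root path.  ``lca([x]) == x``."""
    if not taxids:
        raise ValueError("lca of an empty taxid list is undefined")
    paths = [list(reversed(db.path_to_root(t))) for t in taxids]  # root first
    deepest = db.root_id
    for level in zip(*paths):
        if all(n == level[0] for n in level):
            deepest = level[0]
        else:
            break
    return deepest


def resolve_name(db: TaxonomyDB, name: str) -> list[int]:
    """All taxids whose name matches (case-insensitive, whitespace-collapsed).

    Returns an empty list on no match — absence of a name is for the caller
    to interpret, not an error.  Homonyms return every bearer, sorted by id.
    """
    return list(db.name_index.get(_normalize_name(name), []))


def write_lineages(
    db: TaxonomyDB,
    taxids: Iterable[int],
    path: str | Path,
    *,
    strain_as_subspecies: bool = False,
) -> None:
    """Write homogenized lineages as TSV: taxid + 8 rank columns."""
    with open(path, "w") as out:
        out.write("taxid\t" + "\t".join(RANKS) + "\n")
        for t in taxids:
            lin = homogenize(db, t, strain_as_subspecies=strain_as_subspecies)
            out.write(str(t) + "\t" + "\t".join(lin.to_row()) + "\n")
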