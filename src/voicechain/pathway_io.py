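"""Reading, validating and writing pathway collections and terminal gene sets.

A pathway collection is a set of named gene sets (GMT dialect: one pathway
per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``), held in memory as
a :class:`PathwayEnsemble` together with its gene-to-pathway inverted index.
A :class:`TerminalSet` is the gene set a chain search terminates on — in the
motivating application, the genes lost in a chromosomal microdeletion region.

Gene symbols are HGNC-style tokens and are normalized by trimming and
uppercasing only; no alias resolution is attempted (an alias-map hook exists
but ships empty).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "GmtParseError",
    "Pathway",
    "PathwayEnsemble",
    "TerminalSet",
    "normalize_symbol",
    "read_gmt",
    "write_gmt",
    "read_terminal_sets",
    "write_terminal_sets",
]

#: Optional alias resolution applied after trim/uppercase.  Ships empty:
#: symbols are used as the source files print them.
SYMBOL_ALIASES: dict[str, str] = {}


class GmtParseError(ValueError):
    """Raised for structurally invalid gene-set or terminal-set files."""


def normalize_symbol(token: str) -> str:
    """Normalize a raw gene-symbol token to canonical form.

    Trims surrounding whitespace and uppercases; idempotent. Hyphens and
    other internal punctuation are preserved (HGNC symbols such as ``H1-4``
    are legal). Internal whitespace is rejected.
    """
    sym = token.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol token")
    if any(ch.isspace() for ch in sym):
        raise ValueError(f"gene symbol contains internal whitespace: {token!r}")
    return SYMBOL_ALIASES.get(sym, sym)


@dataclass(frozen=True)
class Pathway:
    """A biological pathway represented by the set of genes it involves."""

    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has no genes")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class PathwayEnsemble:
    """A keyed collection of pathways plus the gene -> pathway-ids index.

    The pathway-overlap graph (nodes = pathways, edge iff the two gene sets
    intersect) is implicit in the index and never materialized.
    """

    pathways: dict[str, Pathway] = field(default_factory=dict)
    gene_index: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_pathways(cls, pathways: Iterable[Pathway]) -> "PathwayEnsemble":
        byid: dict[str, Pathway] = {}
        for p in pathways:
            if p.id in byid:
                raise ValueError(f"duplicate pathway id {p.id!r}")
            byid[p.id] = p
        index: dict[str, set[str]] = {}
        for p in byid.values():
            for g in p.genes:
                index.setdefault(g, set()).add(p.id)
        return cls(byid, {g: frozenset(ids) for g, ids in index.items()})

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_index)

    def pathways_containing(self, gene: str) -> frozenset[str]:
        """Ids of every pathway whose gene set contains ``gene``."""
        return self.gene_index.get(gene, frozenset())


@dataclass(frozen=True)
class TerminalSet:
    """A named gene set a voice chain terminates on (e.g. a microdeletion region).

    ``implicated`` genes are those reported in the literature as driving the
    phenotype; they are recorded independently and need not be a subset of
    ``genes``.
    """

    name: str
    genes: frozenset[str]
    implicated: frozenset[str] = frozenset()
    effects_text: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"terminal set {self.name!r} has an empty gene list")


def _parse_gmt_line(line: str, lineno: int) -> tuple[str, frozenset[str]]:
    fields = line.rstrip("\n").split("\t")
    while fields and fields[-1] == "":
        fields.pop()
    if len(fields) < 3:
        raise GmtParseError(
            f"line {lineno}: expected >=3 tab-separated fields "
            f"(name, description, genes...), got {len(fields)}"
        )
    name = fields[0].strip()
    genes = [normalize_symbol(tok) for tok in fields[2:]]
    if len(set(genes)) < len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        logger.warning("line %d (%s): duplicate gene symbols collapsed: %s",
                       lineno, name, ", ".join(dupes))
    return name, frozenset(genes)


def read_gmt(path: str | Path) -> PathwayEnsemble:
    """Read a GMT gene-set file into a :class:`PathwayEnsemble`.

    Duplicate pathway names are disambiguated by appending an ordinal suffix
    to the id (``NAME.2``, ``NAME.3``, ...) with a logged warning.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            name, genes = _parse_gmt_line(line, lineno)
            seen[name] = seen.get(name, 0) + 1
            pid = name if seen[name] == 1 else f"{name}.{seen[name]}"
            if pid != name:
                logger.warning("duplicate pathway name %r; stored as %r", name, pid)
            pathways.append(Pathway(id=pid, name=name, genes=genes))
    if not pathways:
        raise GmtParseError(f"{path}: no pathway records found")
    return PathwayEnsemble.from_pathways(pathways)


def write_gmt(ensemble: PathwayEnsemble, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write an ensemble back to GMT (genes in lexicographic order)."""
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for p in ensemble:
            desc = descriptions.get(p.id, "na")
            fh.write("\t".join([p.id, desc, *sorted(p.genes)]) + "\n")


def _genes_from_field(raw: str | Sequence[str] | None) -> list[str]:
    if raw is None:
        return []
    if isinstance(raw, str):
        toks = raw.replace(",", " ").split()
    else:
        toks = [str(t) for t in raw]
    return [normalize_symbol(t) for t in toks]


def _terminal_from_record(rec: Mapping[str, object], where: str,
                          on_duplicate: str, seen: set[str]) -> TerminalSet | None:
    name = str(rec.get("name", "")).strip()
    if not name:
        raise GmtParseError(f"{where}: terminal-set record without a name")
    if name in seen:
        if on_duplicate == "error":
            raise GmtParseError(f"{where}: duplicate region name {name!r}")
        logger.warning("%s: duplicate region %r skipped (merge policy)", where, name)
        return None
    genes = _genes_from_field(rec.get("genes"))  # type: ignore[arg-type]
    if not genes:
        raise GmtParseError(f"{where}: region {name!r} has an empty gene list")
    implicated = _genes_from_field(rec.get("implicated"))  # type: ignore[arg-type]
    effects = str(rec.get("effects", "") or "")
    seen.add(name)
    return TerminalSet(name=name, genes=frozenset(genes),
                       implicated=frozenset(implicated), effects_text=effects)


def read_terminal_sets(path: str | Path, on_duplicate: str = "error") -> list[TerminalSet]:
    """Read terminal-set (region) definitions from a YAML or TSV file.

    YAML: a list of mappings with keys ``name``, ``genes`` and optional
    ``implicated`` / ``effects``. TSV: a header line with those column names,
    genes separated by commas or spaces. Input order is preserved.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        docs = yaml.safe_load(path.read_text())
        if not isinstance(docs, list):
            raise GmtParseError(f"{path}: expected a YAML list of region records")
        records = [(f"{path}[{i}]", rec) for i, rec in enumerate(docs)]
    else:
        with path.open() as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise GmtParseError(f"{path}: empty terminal-set file")
        header = [h.strip().lower() for h in lines[0].split("\t")]
        records = []
        for lineno, ln in enumerate(lines[1:], start=2):
            vals = ln.split("\t")
            rec = {header[i]: vals[i] if i < len(vals) else "" for i in range(len(header))}
            records.append((f"{path}:{lineno}", rec))
    out: list[TerminalSet] = []
    seen: set[str] = set()
    for where, rec in records:
        ts = _terminal_from_record(rec, where, on_duplicate, seen)
        if ts is not None:
            out.append(ts)
    return out


def write_terminal_sets(regions: Iterable[TerminalSet], path: str | Path) -> None:
    """Write terminal sets as TSV (round-trips through :func:`read_terminal_sets`)."""
    with Path(path).open("w") as fh:
        fh.write("name\tgenes\timplicated\teffects\n")
        for r in regions:
            fh.write("\t".join([r.name, ",".join(sorted(r.genes)),
                                ",".join(sorted(r.implicated)), r.effects_text]) + "\n")
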