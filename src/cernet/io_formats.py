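"""Readers and writers for the pipeline's external formats.

Interchange dialect is TSV throughout (matching starBase-style exports):
UTF-8, LF line endings, ``#`` comment lines. Gene sets use the standard
GMT layout (name, description, members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_CLASSES = ("miRNA", "lncRNA", "mRNA")

# Header tokens that mark a first row as a header, not data.
_HEADER_TOKENS = {
    "mirna", "mir", "regulator", "gene", "target", "mrna", "lncrna",
    "score", "energy", "geneid", "gene_id", "target_id",
}


@dataclass(frozen=True)
class Interaction:
    """One regulator->target edge (miRNA -> mRNA or miRNA -> lncRNA)."""

    regulator_id: str
    target_id: str
    target_class: str  # "mRNA" | "lncRNA"
    source_tag: str = ""


@dataclass
class InteractionSet:
    """Deduplicated regulator->target edges with provenance tags.

    Invariants: no duplicate (regulator, target) pairs; target_class is
    uniform per target_id within one set.
    """

    records: list[Interaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], Interaction] = {}
        classes: dict[str, str] = {}
        for rec in self.records:
            if rec.target_class not in ("mRNA", "lncRNA"):
                raise ValueError(f"unknown target class {rec.target_class!r}")
            prev = classes.setdefault(rec.target_id, rec.target_class)
            if prev != rec.target_class:
                raise ValueError(
                    f"target {rec.target_id!r} appears as both {prev} and "
                    f"{rec.target_class}"
                )
            seen.setdefault((rec.regulator_id, rec.target_id), rec)
        self.records = list(seen.values())

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(r.regulator_id, r.target_id) for r in self.records}

    def regulators(self) -> set[str]:
        return {r.regulator_id for r in self.records}

    def targets(self) -> set[str]:
        return {r.target_id for r in self.records}


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale intensities with a two-level group label.

    ``group_of`` maps every sample id to ``"control"`` or ``"case"``;
    each group must hold at least two samples.
    """

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = {g for g in self.group_of.values()} - {"control", "case"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in ("control", "case"):
            if len(self.samples(grp)) < 2:
                raise ValueError(f"group {grp!r} has <2 samples")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]


@dataclass
class GeneSetCollection:
    """Named gene sets: set_name -> (description, member ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields[:2])


def read_interaction_table(path: str | Path, target_class: str,
                           source_tag: str | None = None) -> InteractionSet:
    """Read a two-column (miRNA, target) TSV into an :class:`InteractionSet`.

    An optional single header row is auto-detected by non-identifier
    tokens ("miRNA", "gene", ...). Duplicate pairs are collapsed; raw
    and unique counts are logged.
    """
    path = Path(path)
    if target_class not in ("mRNA", "lncRNA"):
        raise ValueError(f"target_class must be mRNA or lncRNA, got {target_class!r}")
    tag = source_tag if source_tag is not None else path.name
    records: list[Interaction] = []
    n_raw = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: malformed row (need >=2 fields): {line!r}"
                )
            n_raw += 1
            records.append(Interaction(fields[0].strip(), fields[1].strip(),
                                       target_class, tag))
    out = InteractionSet(records)
    if n_raw == 0:
        logger.warning("interaction table %s is empty", path)
    logger.info("loaded %s: %d raw rows, %d unique pairs", path, n_raw, len(out))
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, member genes per line)."""
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(f for f in fields[2:] if f.strip()))
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def apply_id_map(ids: Sequence[str], id_map: Mapping[str, str]
                 ) -> tuple[list[str], int]:
    """Translate ids through a (possibly partial) mapping.

    Order-preserving. Unmapped ids are dropped and counted in the
    returned loss; many-to-one collapses keep the first occurrence and
    are logged (the net loss mirrors the attrition seen when converting
    identifiers between annotation databases).
    """
    mapped: list[str] = []
    seen: set[str] = set()
    lost = 0
    collapsed = 0
    for i in ids:
        if i not in id_map:
            lost += 1
            continue
        tgt = id_map[i]
        if tgt in seen:
            collapsed += 1
            continue
        seen.add(tgt)
        mapped.append(tgt)
    if collapsed:
        logger.info("apply_id_map: %d ids collapsed onto earlier targets", collapsed)
    if lost:
        logger.info("apply_id_map: %d ids had no mapping and were dropped", lost)
    return mapped, lost


# ---------------------------------------------------------------------------
# network edge lists

_EDGE_ATTR_FLOATS = ("p",)
_EDGE_ATTR_INTS = ("m", "t", "n", "r")


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a class-labelled network to TSV with a ``#`` header.

    Columns: node1, class1, node2, class2, then any of m/t/n/r/shared_ids/p
    present on the edges. Floats are written with 12 significant digits so
    hypergeometric p-values survive a round trip.
    """
    path = Path(path)
    attr_keys: list[str] = []
    for key in ("m", "t", "n", "r", "shared_ids", "p"):
        if any(key in d for _, _, d in net.edges(data=True)):
            attr_keys.append(key)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = ["node1", "class1", "node2", "class2", *attr_keys]
        fh.write("#" + "\t".join(cols) + "\n")
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (e[0], e[1])):
            u, v = sorted((u, v))
            row = [u, net.nodes[u]["kind"], v, net.nodes[v]["kind"]]
            for key in attr_keys:
                val = d.get(key, "")
                if key == "shared_ids":
                    val = ",".join(sorted(val)) if val != "" else ""
                elif key in _EDGE_ATTR_FLOATS and val != "":
                    val = format(float(val), ".12g")
                row.append(str(val))
            fh.write("\t".join(row) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_edge_list`."""
    path = Path(path)
    net = nx.Graph()
    attr_keys: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                cols = line[1:].split("\t")
                attr_keys = cols[4:]
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: edge row needs >=4 fields")
            u, cu, v, cv = fields[:4]
            for node, cls in ((u, cu), (v, cv)):
                if cls not in NODE_CLASSES:
                    raise ValueError(
                        f"{path}:{lineno}: unknown node class {cls!r} for {node!r}"
                    )
                if node in net.nodes and net.nodes[node]["kind"] != cls:
                    raise ValueError(
                        f"{path}:{lineno}: node {node!r} re-declared with class {cls!r}"
                    )
                net.add_node(node, kind=cls)
            attrs: dict[str, object] = {}
            for key, raw in zip(attr_keys, fields[4:]):
                if raw == "":
                    continue
                if key in _EDGE_ATTR_INTS:
                    attrs[key] = int(raw)
                elif key in _EDGE_ATTR_FLOATS:
                    attrs[key] = float(raw)
                elif key == "shared_ids":
                    attrs[key] = tuple(raw.split(","))
                else:
                    attrs[key] = raw
            net.add_edge(u, v, **attrs)
    return net


# ---------------------------------------------------------------------------
# expression matrices and small tables

def read_expression_matrix(values_path: str | Path,
                           groups_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a two-column sample->group file."""
    values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
    groups = pd.read_csv(groups_path, sep="\t", header=None, comment="#",
                         names=["sample", "group"])
    group_of = dict(zip(groups["sample"].astype(str), groups["group"]))
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, group_of)


def write_expression_matrix(expr: ExpressionMatrix, values_path: str | Path,
                            groups_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format="%.10g",
                       index_label="gene_id", lineterminator="\n")
    with open(groups_path, "w", encoding="utf-8", newline="\n") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.group_of[s]}\n")


def read_miranda_table(path: str | Path):
    """Read a miRanda-style TSV (mirna, lncrna, score, energy).

    Returns a list of :class:`cernet.cerna_network.MirandaRecord`.
    """
    from cernet.cerna_network import MirandaRecord

    records = []
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need 4 fields, got {len(fields)}")
            records.append(MirandaRecord(fields[0], fields[1],
                                         float(fields[2]), float(fields[3])))
    return records


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blanks ignored."""
    out = []
    with open(Path(path), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for i in ids:
            fh.write(f"{i}\n")
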