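"""Config-driven mitochondrial haplogroup classification.

A haplogroup tree is a rooted hierarchy of named clades, each defined by
a motif of diagnostic variants (transitions by default; explicit allele
changes where a transversion is diagnostic). A sample's variant profile
is scored against every root-to-node path, and the deepest best-scoring
node wins. Two field-specific rules are built in:

* **Reversion tolerance** — a missing marker on the accepted path is
  forgiven (treated as a back-mutation) provided the node itself, or a
  descendant, contributes matched evidence. A profile missing a node's
  entire motif with no downstream evidence is assigned to the last
  supported ancestor.
* **Conflict resolution between sibling branches** — when a profile
  carries markers of two sibling subclades, the branch with more matched
  evidence (in particular evidence below the contested branching point)
  wins, and the losing branch's matched markers are reported as
  conflicts. If the conflict cannot be resolved, the sample is assigned
  to the common ancestor with both branches recorded as conflicts.

All diagnostic positions are weighted equally, including hypervariable
control-region sites.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

from .refvar import TRANSITION, VariantProfile


class ConfigError(ValueError):
    """Raised for structurally invalid haplogroup configurations."""


@dataclass(frozen=True)
class MotifSite:
    """One diagnostic site of a haplogroup motif.

    ``change`` is ``"Ts"`` (transition relative to the reference base),
    an explicit substitution like ``"A>T"``, or ``"+X"`` for an
    insertion allele. ``placeholder`` marks non-authoritative config
    slots whose real defining mutation must be supplied by the user.
    """

    position: int
    change: str
    placeholder: bool = False

    def matches(self, profile: VariantProfile) -> bool:
        if self.change == "Ts":
            v = profile.substitution_at(self.position)
            return v is not None and v.mutation_class == TRANSITION
        if self.change.startswith("+"):
            v = profile.insertion_at(self.position)
            return v is not None and v.alt_allele == self.change[1:].upper()
        ref, _, alt = self.change.partition(">")
        v = profile.substitution_at(self.position)
        return v is not None and v.ref_allele == ref and v.alt_allele == alt

    @property
    def label(self) -> str:
        return f"{self.position}{self.change if self.change != 'Ts' else ' Ts'}"


@dataclass(frozen=True)
class HaplogroupNode:
    name: str
    parent: str | None
    motif: tuple[MotifSite, ...] = ()

    def __post_init__(self) -> None:
        positions = [m.position for m in self.motif]
        if len(positions) != len(set(positions)):
            raise ConfigError(f"node {self.name!r} repeats a motif position")


class HaplogroupTree:
    """A validated, single-rooted hierarchy of haplogroup nodes."""

    def __init__(self, nodes: Iterable[HaplogroupNode]) -> None:
        self.nodes: dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ConfigError(f"duplicate haplogroup name {node.name!r}")
            self.nodes[node.name] = node
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ConfigError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].name
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise ConfigError(
                    f"node {node.name!r} references unknown parent {node.parent!r}"
                )
            if node.parent == node.name:
                raise ConfigError(f"node {node.name!r} is its own parent")
        self._paths: dict[str, tuple[str, ...]] = {}
        for name in self.nodes:
            self._paths[name] = self._walk(name)

    def _walk(self, name: str) -> tuple[str, ...]:
        path: list[str] = []
        seen: set[str] = set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise ConfigError(f"cycle detected through node {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent
        return tuple(reversed(path))

    def path(self, name: str) -> tuple[str, ...]:
        """Names from the root down to ``name`` inclusive."""
        return self._paths[name]

    def depth(self, name: str) -> int:
        return len(self._paths[name]) - 1

    def lca(self, names: Sequence[str]) -> str:
        paths = [self._paths[n] for n in names]
        lca = self.root
        for level in range(min(len(p) for p in paths)):
            step = {p[level] for p in paths}
            if len(step) > 1:
                break
            lca = step.pop()
        return lca

    def path_motifs(self, name: str) -> list[tuple[str, MotifSite]]:
        return [(n, m) for n in self._paths[name] for m in self.nodes[n].motif]


def load_haplogroup_tree(
    source: Union[str, Path, Mapping],
) -> HaplogroupTree:
    """Load and validate a haplogroup tree from YAML (path or mapping)."""
    if isinstance(source, Mapping):
        data = source
    else:
        data = yaml.safe_load(Path(source).read_text())
    if not isinstance(data, Mapping) or "haplogroups" not in data:
        raise ConfigError("config must contain a 'haplogroups' list")
    nodes = []
    for spec in data["haplogroups"]:
        motif = tuple(
            MotifSite(
                position=int(m["position"]),
                change=str(m["change"]),
                placeholder=bool(m.get("placeholder", False)),
            )
            for m in spec.get("motif", []) or []
        )
        nodes.append(HaplogroupNode(spec["name"], spec.get("parent"), motif))
    return HaplogroupTree(nodes)


def default_tree() -> HaplogroupTree:
    """The bundled T1 subhaplogroup tree (T1a/T1d/T1e/T1f are placeholders)."""
    cfg = resources.files("mitopop").joinpath("data/haplogroups_t1.yaml")
    return load_haplogroup_tree(yaml.safe_load(cfg.read_text()))


@dataclass
class Assignment:
    """A sample's inferred haplogroup with its supporting evidence.

    ``missing`` lists unmatched markers on the accepted root-to-node path
    (interpreted as reversions); ``conflicts`` lists matched markers that
    lie on rejected branches.
    """

    sample_id: str
    haplogroup: str
    matched: list[MotifSite] = field(default_factory=list)
    missing: list[MotifSite] = field(default_factory=list)
    conflicts: list[MotifSite] = field(default_factory=list)
    score: int = 0
    population: str = ""


def assign_haplogroup(profile: VariantProfile, tree: HaplogroupTree) -> Assignment:
    """Assign a profile to the deepest haplogroup its markers support.

    The score of a node is the number of motif variants matched along the
    path from the root to that node. Candidate nodes are those with at
    least one matched marker of their own (plus the root), which encodes
    the reversion rule: missing path markers are tolerated only when the
    node or a descendant supplies direct evidence. Ties are broken by
    score, then depth, then matched evidence below the contested
    branching point; an unresolved tie assigns the common ancestor and
    reports both branches as conflicts.
    """
    matched_by_node = {
        name: [m for _, m in tree.path_motifs(name) if m.matches(profile)]
        for name in tree.nodes
    }
    scores = {name: len(v) for name, v in matched_by_node.items()}
    candidates = [
        name
        for name, node in tree.nodes.items()
        if name == tree.root or any(m.matches(profile) for m in node.motif)
    ]
    best_score = max(scores[c] for c in candidates)
    top = [c for c in candidates if scores[c] == best_score]
    best_depth = max(tree.depth(c) for c in top)
    top = sorted(c for c in top if tree.depth(c) == best_depth)
    if len(top) > 1:
        lca = tree.lca(top)
        below = {c: scores[c] - scores[lca] for c in top}
        most = max(below.values())
        top = [c for c in top if below[c] == most]
        if len(top) > 1:
            top = [lca]  # unresolved sibling conflict: fall back to the ancestor
    assigned = top[0]
    on_path = set(tree.path(assigned))
    matched = matched_by_node[assigned]
    missing = [m for _, m in tree.path_motifs(assigned) if not m.matches(profile)]
    conflicts: list[MotifSite] = []
    for name, node in tree.nodes.items():
        if name in on_path:
            continue
        for m in node.motif:
            if m.matches(profile) and m not in conflicts:
                conflicts.append(m)
    return Assignment(
        sample_id=profile.sample_id,
        haplogroup=assigned,
        matched=matched,
        missing=missing,
        conflicts=conflicts,
        score=len(matched),
        population=profile.population,
    )


# ---------------------------------------------------------------------------
# Frequency reporting
# ---------------------------------------------------------------------------

def _round_half_up(value: float, places: int = 1) -> float:
    quantum = Decimal(1).scaleb(-places)
    return float(Decimal(str(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def frequency_table(
    assignments: Iterable[Assignment],
    tree: HaplogroupTree,
    level: int = 2,
) -> pd.DataFrame:
    """Tabulate haplogroup counts and percentages per population.

    Assignments deeper than ``level`` (root = depth 0) are rolled up to
    their ancestor at that depth, so a table at the subhaplogroup level
    groups e.g. T1b1 members under T1b; samples assigned to a shallower
    internal node (a basal lineage with no downstream markers) count for
    that node itself. Percentages are per population, rounded half-up to
    one decimal; raw counts are always included so rounding artifacts
    stay visible.
    """
    assignments = list(assignments)
    columns = ["haplogroup", "population", "count", "percent"]
    if not assignments:
        return pd.DataFrame(columns=columns)
    rows = []
    for a in assignments:
        path = tree.path(a.haplogroup)
        rolled = path[level] if len(path) > level else a.haplogroup
        rows.append({"haplogroup": rolled, "population": a.population})
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["haplogroup", "population"]).size().rename("count").reset_index()
    )
    totals = df.groupby("population").size()
    counts["percent"] = [
        _round_half_up(100.0 * row["count"] / totals[row["population"]])
        for _, row in counts.iterrows()
    ]
    return counts.sort_values(["haplogroup", "population"]).reset_index(drop=True)[columns]


def frequency_table_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy frequency table to a haplogroup x population layout."""
    if tidy.empty:
        return pd.DataFrame()
    wide = tidy.pivot(index="haplogroup", columns="population", values=["count", "percent"])
    return wide.fillna(0)


def assignments_to_tsv(assignments: Iterable[Assignment], path: Union[str, Path]) -> Path:
    """Write an assignment report: one row per sample with its evidence."""
    path = Path(path)

    def fmt(sites: Iterable[MotifSite]) -> str:
        return ";".join(f"{m.position}:{m.change}" for m in sites)

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "population", "haplogroup", "score", "matched", "missing", "conflicts"]
        )
        for a in assignments:
            writer.writerow(
                [a.sample_id, a.population, a.haplogroup, a.score,
                 fmt(a.matched), fmt(a.missing), fmt(a.conflicts)]
            )
    return path
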