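"""Motif-based haplogroup assignment against a nested clade tree.

The classifier implements a matching / near-matching strategy: each observed
haplotype is scored against the *cumulative* diagnostic profile of every
clade in the tree (a child's diagnostic at a position supersedes its
ancestor's, so the 16147 G->A change and expected back mutations are handled
naturally), and is assigned to the clade of minimal weighted mismatch cost.

The cost components, from strongest to weakest evidence against a clade:
a diagnostic entirely absent (``missing``), a diagnostic site called with a
different base (``mismatch``), a private call the path does not explain
(``extra``).  An expected back mutation contributes a small penalty when the
ancestral mutation is still present and a small reward when it is absent as
predicted — this is what separates e.g. the 16086-less N1a1a2 types (which
lack 16172) from N1a1a1.  Ties between nested clades resolve to the deeper
clade; ties between incomparable clades resolve to their common ancestor
with status ``ambiguous``.

Coding-region diagnostics are only scored when the haplotype actually has
coding-region data; published control-region tables are never penalised for
them.  HVS-II diagnostics are only scored for records with a typed HVS-II.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .hvs_io import Haplotype, MutationCall, parse_token
from .reference import ReferenceAnnotation, load_reference

logger = logging.getLogger(__name__)


class CladeConfigError(ValueError):
    """Raised for malformed clade-definition configs."""


@dataclass
class CladeDefinition:
    name: str
    parent: str
    hvs1: list[MutationCall] = field(default_factory=list)
    hvs2: list[MutationCall] = field(default_factory=list)
    coding: list[MutationCall] = field(default_factory=list)
    anti_hvs1: list[int] = field(default_factory=list)

    def diagnostics(self, segment: str) -> list[MutationCall]:
        return getattr(self, segment)


@dataclass(frozen=True)
class MatchWeights:
    """Near-matching calibration of the classifier."""

    missing: float = 4.0
    mismatch: float = 3.0
    extra: float = 2.0
    back_violated: float = 1.0
    back_satisfied: float = -1.0


@dataclass
class Assignment:
    clade: str
    status: str  # exact | near | ambiguous | unassigned
    matched: int = 0
    missing: int = 0
    extra_private: int = 0
    cost: float = 0.0


class HaplogroupTree:
    """A validated nested clade tree with cumulative diagnostic profiles."""

    def __init__(self, clades: dict[str, CladeDefinition], root: str,
                 root_hvs2: list[MutationCall] | None = None):
        self.root = root
        self.clades = clades
        self.root_hvs2 = root_hvs2 or []
        self.children: dict[str, list[str]] = {root: []}
        for name in clades:
            self.children.setdefault(name, [])
        for name, cd in clades.items():
            if cd.parent != root and cd.parent not in clades:
                raise CladeConfigError(f"clade {name!r} has unknown parent {cd.parent!r}")
            self.children[cd.parent].append(name)
        # cycle / reachability check
        seen: set[str] = set()
        stack = [root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise CladeConfigError(f"cycle at clade {node!r}")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        orphans = set(clades) - seen
        if orphans:
            raise CladeConfigError(f"unreachable clades (cycle or orphan): {sorted(orphans)}")
        for name, cd in clades.items():
            if not (cd.hvs1 or cd.hvs2 or cd.coding or cd.anti_hvs1):
                logger.warning(
                    "clade %s has no diagnostics and no anti-diagnostics; "
                    "it is only reachable as a default child", name)
        self._profiles: dict[str, dict] = {}

    # -- topology helpers ---------------------------------------------------

    def path(self, name: str) -> list[str]:
        """Root-exclusive path from the root to ``name``."""
        out = []
        while name != self.root:
            out.append(name)
            name = self.clades[name].parent
        return out[::-1]

    def names(self) -> list[str]:
        return [self.root] + sorted(self.clades, key=lambda n: (len(self.path(n)), n))

    def depth(self, name: str) -> int:
        return 0 if name == self.root else len(self.path(name))

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is ``b`` or an ancestor of ``b``."""
        return a == self.root or a == b or a in self.path(b)

    def common_ancestor(self, names: list[str]) -> str:
        paths = [[self.root] + self.path(n) for n in names]
        anc = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                anc = level[0]
            else:
                break
        return anc

    # -- profiles -----------------------------------------------------------

    def profile(self, name: str) -> dict[str, dict[int, tuple[str, MutationCall | None]]]:
        """Cumulative expected state per segment: position -> (kind, call).

        ``kind`` is ``"state"`` (mutation expected), ``"absent"`` (expected
        back mutation) or ``"anti"`` (presence excludes the clade).
        """
        if name in self._profiles:
            return self._profiles[name]
        prof: dict[str, dict[int, tuple[str, MutationCall | None]]] = {
            "hvs1": {}, "hvs2": {}, "coding": {},
        }
        for call in self.root_hvs2:
            prof["hvs2"][call.position] = ("state", call)
        for clade in ([] if name == self.root else self.path(name)):
            cd = self.clades[clade]
            for segment in ("hvs1", "hvs2", "coding"):
                for call in cd.diagnostics(segment):
                    kind = "absent" if call.is_back_mutation else "state"
                    prof[segment][call.position] = (kind, call)
            for pos in cd.anti_hvs1:
                prof["hvs1"][pos] = ("anti", None)
        self._profiles[name] = prof
        return prof


def load_clade_tree(path=None, ref: ReferenceAnnotation | None = None) -> HaplogroupTree:
    """Load a clade-definition config (default: the shipped N1a tree)."""
    if ref is None:
        ref = load_reference()
    if path is None:
        from importlib import resources

        with resources.as_file(resources.files("mtn1a.data") / "n1a_clades.yaml") as p:
            raw = yaml.safe_load(open(p))
    else:
        raw = yaml.safe_load(open(path))
    root = raw.get("root", "root")
    clades: dict[str, CladeDefinition] = {}
    for name, spec in (raw.get("clades") or {}).items():
        parent = spec.get("parent")
        if parent is None:
            raise CladeConfigError(f"clade {name!r} has no parent")
        if parent == name:
            raise CladeConfigError(f"clade {name!r} is its own parent")
        clades[name] = CladeDefinition(
            name=name,
            parent=parent,
            hvs1=[parse_token(str(t), "hvs1", ref) for t in spec.get("hvs1", [])],
            hvs2=[parse_token(str(t), "hvs2", ref) for t in spec.get("hvs2", [])],
            coding=[parse_token(str(t), "coding", ref) for t in spec.get("coding", [])],
            anti_hvs1=[
                p + 16000 if int(p) < 16000 else int(p)
                for p in spec.get("anti_hvs1", [])
            ],
        )
    root_hvs2 = [parse_token(str(t), "hvs2", ref) for t in raw.get("root_hvs2", [])]
    return HaplogroupTree(clades, root, root_hvs2)


# ---------------------------------------------------------------------------
# scoring


def _score_segment(calls: list[MutationCall],
                   expected: dict[int, tuple[str, MutationCall | None]],
                   weights: MatchWeights):
    """Score one typed segment against a clade's cumulative profile."""
    by_pos: dict[int, MutationCall] = {}
    insertions = []
    for c in calls:
        if c.event == "insertion":
            insertions.append(c)
        else:
            by_pos[c.position] = c
    matched = missing = mismatch = extra = violated = satisfied = 0
    anti_hit = False
    for pos, (kind, exp) in expected.items():
        got = by_pos.get(pos)
        if kind == "state":
            if got is None:
                missing += 1
            elif got.derived == exp.derived and not got.is_back_mutation:
                matched += 1
            else:
                mismatch += 1
        elif kind == "absent":
            if got is None or got.is_back_mutation:
                satisfied += 1
            else:
                violated += 1
        elif kind == "anti":
            if got is not None and not got.is_back_mutation:
                anti_hit = True
    extra += sum(1 for p in by_pos if p not in expected)
    extra += len(insertions)
    cost = (weights.missing * missing + weights.mismatch * mismatch
            + weights.extra * extra + weights.back_violated * violated
            + weights.back_satisfied * satisfied)
    return cost, matched, missing + mismatch + violated, extra, anti_hit


def score(h: Haplotype, tree: HaplogroupTree, clade: str,
          weights: MatchWeights = MatchWeights()):
    """Total weighted cost of placing ``h`` in ``clade`` (inf if anti hit)."""
    prof = tree.profile(clade)
    total = 0.0
    matched = missing = extra = 0
    segments = [("hvs1", h.hvs1)]
    if h.hvs2_typed:
        segments.append(("hvs2", h.hvs2))
    if h.coding:
        segments.append(("coding", h.coding))
    for segment, calls in segments:
        c, m, mi, ex, anti = _score_segment(calls, prof[segment], weights)
        if anti:
            return float("inf"), 0, 0, 0
        total += c
        matched += m
        missing += mi
        extra += ex
    return total, matched, missing, extra


def assign(h: Haplotype, tree: HaplogroupTree, mode: str = "near",
           weights: MatchWeights = MatchWeights()) -> Assignment:
    """Assign a haplotype to its best-matching clade.

    ``near`` mode minimises the weighted mismatch cost over all clades;
    ``strict`` mode only considers clades whose visible diagnostics are all
    present (private extras allowed) and picks the deepest.
    """
    if mode not in ("strict", "near"):
        raise ValueError(f"unknown mode {mode!r}")
    results = {}
    for name in tree.names():
        cost, matched, missing, extra = score(h, tree, name, weights)
        results[name] = (cost, matched, missing, extra)
    if mode == "strict":
        eligible = [n for n, (c, m, mi, ex) in results.items()
                    if c != float("inf") and mi == 0]
        depth = max(tree.depth(n) for n in eligible)
        best = [n for n in eligible if tree.depth(n) == depth]
    else:
        min_cost = min(c for c, *_ in results.values())
        best = [n for n, (c, *_) in results.items() if c == min_cost]
        # keep only the deepest within each ancestor chain
        best = [n for n in best
                if not any(m != n and tree.is_ancestor(n, m) for m in best)]
    if len(best) == 1:
        clade = best[0]
        ambiguous = False
    else:
        clade = tree.common_ancestor(best)
        ambiguous = True
        logger.info("haplotype %s ambiguous between %s; assigned %s",
                    h.id, sorted(best), clade)
    cost, matched, missing, extra = results[clade]
    if clade == tree.root:
        status = "unassigned"
    elif ambiguous:
        status = "ambiguous"
    elif missing == 0:
        status = "exact"
    else:
        status = "near"
    return Assignment(clade=clade, status=status, matched=matched,
                      missing=missing, extra_private=extra, cost=cost)


def classify_table(haplotypes: list[Haplotype], tree: HaplogroupTree,
                   mode: str = "near",
                   weights: MatchWeights = MatchWeights()):
    """Classify a haplotype table; returns (assignments frame, report).

    The report carries per-clade weighted counts (each row weighted by its
    N), cumulative counts including descendant clades, and the concordance
    of assignments with the table's recorded labels.
    """
    if not haplotypes:
        raise ValueError("empty haplotype list")
    rows = []
    for h in haplotypes:
        a = assign(h, tree, mode=mode, weights=weights)
        h.assigned_clade = a.clade
        rows.append({
            "id": h.id, "recorded": h.recorded_haplogroup, "assigned": a.clade,
            "status": a.status, "matched": a.matched, "missing": a.missing,
            "extra_private": a.extra_private, "cost": a.cost, "n": h.count,
            "population": h.population, "region": h.region, "source": h.source,
        })
    df = pd.DataFrame(rows)
    counts = df.groupby("assigned")["n"].sum().to_dict()
    cumulative = {
        name: int(sum(c for cl, c in counts.items()
                      if cl != tree.root and tree.is_ancestor(name, cl)))
        for name in tree.names()
    }
    with_label = df[df["recorded"] != ""]
    if len(with_label):
        agree = with_label["assigned"] == with_label["recorded"]
        concordance = float((with_label["n"] * agree).sum() / with_label["n"].sum())
        for _, r in with_label[~agree].iterrows():
            logger.warning("discordant row %s: recorded %s, assigned %s (%s)",
                           r["id"], r["recorded"], r["assigned"], r["status"])
    else:
        concordance = float("nan")
    report = {
        "total": int(df["n"].sum()),
        "counts": {k: int(v) for k, v in counts.items()},
        "cumulative_counts": cumulative,
        "concordance": concordance,
    }
    return df, report
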