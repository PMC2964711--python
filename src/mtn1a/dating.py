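"""Mutation classification and rho-statistic coalescence dating.

The clade age estimator is the classic rho statistic: the mean number of
(class-filtered) mutations from the inferred ancestral haplotype to each
sampled mtDNA, with the tree-structured standard error of Saillard et al.,

    sigma^2 = sum over edges ( (tips below the edge / n)^2 x mutations on it ),

converted to years through a calibration (years per mutation of the class).
Two mutation classes drive the clocks: all coding-region base substitutions,
and only synonymous transitions (a transition inside a protein-coding gene
that leaves the amino acid unchanged in every overlapping reading frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import pandas as pd

from .hvs_io import MutationCall
from .network import MutationTree, Site, TreeNode
from .reference import (
    GENE_MAP,
    TRANSITION_PARTNER,
    ReferenceAnnotation,
    translate_codon,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class MutationClassifier:
    """Classify point mutations against the reference gene map."""

    def __init__(self, ref: ReferenceAnnotation):
        self.ref = ref
        self.proteins = [f for f in GENE_MAP if f[4] == "protein"]
        self.rnas = [f for f in GENE_MAP if f[4] in ("rrna", "trna")]

    def _codon(self, feature, position: int) -> tuple[str, int] | None:
        """The reference codon containing ``position`` and the offset of the
        position within it (0..2, in the reading direction); None if the
        codon is incomplete at the feature boundary."""
        name, start, end, strand, _ = feature
        if strand == 1:
            off = position - start
            c0 = start + 3 * (off // 3)
            if c0 + 2 > end:
                return None
            codon = self.ref.sequence[c0 - 1 : c0 + 2]
            return codon, off % 3
        off = end - position
        c0 = end - 3 * (off // 3)
        if c0 - 2 < start:
            return None
        heavy = self.ref.sequence[c0 - 3 : c0]
        codon = "".join(_COMPLEMENT[b] for b in reversed(heavy))
        return codon, off % 3

    def is_synonymous(self, position: int, alt: str) -> bool:
        """Synonymous in *every* protein-coding frame overlapping the site."""
        feats = [f for f in self.proteins if f[1] <= position <= f[2]]
        any_frame = False
        for f in feats:
            cod = self._codon(f, position)
            if cod is None:
                continue
            any_frame = True
            codon, k = cod
            base = alt if f[3] == 1 else _COMPLEMENT[alt]
            mutated = codon[:k] + base + codon[k + 1 :]
            if translate_codon(codon) != translate_codon(mutated):
                return False
        return any_frame

    def classify(self, call: MutationCall) -> str:
        """One of control | synonymous_transition | nonsynonymous |
        coding_other | rna | indel."""
        if call.is_indel:
            return "indel"
        pos = call.position
        lo, hi = self.ref.coding_window
        if not lo <= pos <= hi:
            return "control"
        feats = self.ref.features_at(pos)
        prot = [f for f in feats if f[4] == "protein"]
        if prot:
            if self.is_synonymous(pos, call.derived):
                if call.event == "transition":
                    return "synonymous_transition"
                return "coding_other"  # synonymous transversion
            return "nonsynonymous"
        if feats:
            return "rna"
        logger.debug("position %d inside the coding window but in no "
                     "annotated feature; classified 'other'", pos)
        return "coding_other"


CODING_LABELS = frozenset({"synonymous_transition", "nonsynonymous", "coding_other"})


def make_class_filter(mutation_class, classifier: MutationClassifier) -> Callable:
    """Build a predicate over edge mutations for a named class."""
    if callable(mutation_class):
        return mutation_class

    def flt(mut) -> bool:
        call = mut.call if isinstance(mut, Site) else mut
        label = classifier.classify(call)
        if mutation_class == "coding_substitution":
            return label in CODING_LABELS
        if mutation_class == "synonymous_transition":
            return label == "synonymous_transition"
        if mutation_class == "control":
            return label == "control"
        if mutation_class == "all":
            return label != "indel"
        raise ValueError(f"unknown mutation class {mutation_class!r}")

    return flt


# ---------------------------------------------------------------------------
# rho and sigma


def _count(edge: Iterable, flt: Callable) -> int:
    return sum(1 for m in edge if flt(m))


def rho(tree: MutationTree, class_filter: Callable,
        root: TreeNode | None = None) -> tuple[float, int]:
    """Mean class-filtered mutation count from the (sub)tree root to each
    sampled mtDNA, weighting haplotypes by multiplicity.  Returns (rho, n)."""
    root = root or tree.root
    n = 0
    total = 0
    stack = [(root, 0)]
    while stack:
        node, depth = stack.pop()
        if node is not root:
            depth += _count(node.edge, class_filter)
        n += node.multiplicity
        total += node.multiplicity * depth
        for c in node.children:
            stack.append((c, depth))
    if n == 0:
        raise ValueError("rho undefined: no sampled mtDNAs below this node")
    return total / n, n


def sigma_saillard(tree: MutationTree, class_filter: Callable,
                   root: TreeNode | None = None) -> float:
    """Tree-structured standard error of rho (Saillard et al.)."""
    root = root or tree.root

    def subtree_mult(node: TreeNode) -> int:
        return node.multiplicity + sum(subtree_mult(c) for c in node.children)

    n = subtree_mult(root)
    if n == 0:
        raise ValueError("sigma undefined: no sampled mtDNAs below this node")
    var = 0.0

    def walk(node: TreeNode):
        for c in node.children:
            below = subtree_mult(c)
            var_contrib = (below / n) ** 2 * _count(c.edge, class_filter)
            nonlocal_acc.append(var_contrib)
            walk(c)

    nonlocal_acc: list[float] = []
    walk(root)
    var = sum(nonlocal_acc)
    return var ** 0.5


# ---------------------------------------------------------------------------
# calibrations and age estimates


@dataclass(frozen=True)
class Calibration:
    label: str
    mutation_class: str
    years_per_mutation: float
    citation: str = ""

    def __post_init__(self):
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")


def load_calibrations(path=None) -> list[Calibration]:
    """Load a calibration table (default: the six packaged clock rates)."""
    if path is None:
        from importlib import resources

        with resources.as_file(resources.files("mtn1a.data") / "calibrations.tsv") as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        Calibration(str(r.label), str(r.mutation_class),
                    float(r.years_per_mutation), str(r.citation))
        for r in df.itertuples()
    ]


@dataclass
class AgeEstimate:
    clade: str
    calibration: str
    mutation_class: str
    n: int
    rho: float
    sigma: float
    age_years: float
    age_se_years: float


def estimate_ages(tree: MutationTree, clades: dict[str, TreeNode],
                  calibrations: list[Calibration],
                  classifier: MutationClassifier) -> pd.DataFrame:
    """Rho ages per clade and calibration; internal values unrounded.

    ``clades`` maps clade names to the ancestral node of each subclade in
    the tree.  Ages are age = rho x rate, SE = sigma x rate.
    """
    if not calibrations:
        raise ValueError("no calibrations given")
    if not clades:
        raise ValueError("no clades given")
    rows = []
    for name, node in clades.items():
        for cal in calibrations:
            flt = make_class_filter(cal.mutation_class, classifier)
            r, n = rho(tree, flt, root=node)
            s = sigma_saillard(tree, flt, root=node)
            if r == 0:
                logger.warning("clade %s has no %s mutations under calibration "
                               "%s; age 0 +/- 0", name, cal.mutation_class, cal.label)
            rows.append(AgeEstimate(
                clade=name, calibration=cal.label,
                mutation_class=cal.mutation_class, n=n, rho=r, sigma=s,
                age_years=r * cal.years_per_mutation,
                age_se_years=s * cal.years_per_mutation,
            ))
    return pd.DataFrame([vars(a) for a in rows])


def ages_report(ages: pd.DataFrame) -> pd.DataFrame:
    """Wide per-clade report with 'age +/- se' strings, rounded to years."""
    df = ages.copy()
    df["cell"] = [
        f"{round(a):,} ± {round(s):,}"
        for a, s in zip(df.age_years, df.age_se_years)
    ]
    wide = df.pivot_table(index=["clade", "n"], columns="calibration",
                          values="cell", aggfunc="first", sort=False)
    return wide.reset_index()
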