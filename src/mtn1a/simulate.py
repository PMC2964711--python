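"""Ground-truth synthetic data: genealogies, mitogenomes and motif tables.

The generator emulates the data-generating assumptions behind rho-statistic
clock dating: a rooted clock-like genealogy whose branches accrue Poisson
mutation counts at class-specific rates (all coding-region substitutions,
synonymous transitions, control-region mutations), with mutation positions
drawn uniformly from the exact legal site pool of each class.  Simulated
genomes are the packaged reference with each tip's root-to-tip mutations
applied, so the variant caller, network construction and dating stages can
be validated against known truth without any downloads.

Defaults mirror the published study scale: 19 mtDNAs, a clade age of
10,000 years (inside the published subclade age range), the packaged clock
rates (5,140 y per coding substitution, 6,764 y per synonymous transition)
and a control-region rate of 20,180 y per transition (the classic HVS
transition rate).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from Bio import Phylo

from .classify import HaplogroupTree
from .hvs_io import MutationCall, apply_mutations
from .network import MutationTree, TreeNode
from .reference import (
    TRANSITION_PARTNER,
    ReferenceAnnotation,
    synonymous_transition_sites,
)


class SimulationConfigError(ValueError):
    pass


DEFAULT_RATES = {
    "coding_substitution": 5140.0,
    "synonymous_transition": 6764.0,
    "control": 20180.0,
}

DEFAULT_REGIONS = {
    "Eastern Europe": 0.35,
    "Central Europe": 0.25,
    "Central Asia": 0.2,
    "Near East": 0.2,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    topology: str = "star"          # star | yule | a fixed Newick string
    n_tips: int = 19
    tmrca_years: float = 10000.0
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    regional_sampling: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    clade_plan: list | None = None  # [(clade name, n records), ...]
    private_rate: float = 0.5       # mean private control mutations per record
    plant_back_mutations: bool = False

    def __post_init__(self):
        if self.n_tips < 2:
            raise SimulationConfigError("n_tips must be >= 2")
        if any(r <= 0 for r in self.rates.values()):
            raise SimulationConfigError("all rates must be positive")
        total = sum(self.regional_sampling.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"regional sampling probabilities must sum to 1, got {total}")
        cod = self.rates["coding_substitution"]
        syn = self.rates["synonymous_transition"]
        if 1.0 / cod < 1.0 / syn:
            raise SimulationConfigError(
                "coding_substitution rate implies fewer coding changes than "
                "synonymous transitions alone")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruth:
    tree: MutationTree              # edges carry planted MutationCall lists
    tmrca_years: float
    config: SimulationConfig
    class_counts: dict              # planted totals per class label
    site_pools: dict                # class label -> pool size


_POOL_CACHE: dict[int, dict] = {}


def _site_pools(ref: ReferenceAnnotation) -> dict[str, list[int]]:
    cached = _POOL_CACHE.get(id(ref))
    if cached is not None:
        return cached
    syn = synonymous_transition_sites(ref)
    syn_set = set(syn)
    coding_protein = []
    from .reference import GENE_MAP

    for name, lo, hi, strand, kind in GENE_MAP:
        if kind != "protein":
            continue
        coding_protein.extend(range(lo, hi + 1))
    nonsyn = sorted(set(coding_protein) - syn_set)
    pools = {
        "synonymous_transition": syn,
        "nonsynonymous": nonsyn,
        "control": ref.control_sites(),
    }
    _POOL_CACHE[id(ref)] = pools
    return pools


def _topology(cfg: SimulationConfig, rng: np.random.Generator) -> TreeNode:
    """Clock-like genealogy; every edge gets a ``length_years`` attribute
    (stored on the child as ``_length``)."""
    if cfg.topology == "star":
        root = TreeNode("root")
        for i in range(cfg.n_tips):
            child = TreeNode(f"T{i + 1:02d}", multiplicity=1)
            root.add_child(child, [])
            child._length = cfg.tmrca_years
        return root
    if cfg.topology == "yule":
        # random coalescent-style clock tree rescaled to the requested TMRCA
        times = np.sort(rng.uniform(0, 1, cfg.n_tips - 1))
        times = times / times[-1] * cfg.tmrca_years
        lineages = [(TreeNode(f"T{i + 1:02d}", multiplicity=1), 0.0)
                    for i in range(cfg.n_tips)]
        for k, t in enumerate(times):
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            (a, ta), (b, tb) = lineages[i], lineages[j]
            anc = TreeNode(f"anc{k + 1}")
            anc.add_child(a, [])
            a._length = t - ta
            anc.add_child(b, [])
            b._length = t - tb
            lineages = [x for m, x in enumerate(lineages) if m not in (i, j)]
            lineages.append((anc, t))
        root = lineages[0][0]
        root.name = "root"
        return root
    # fixed Newick
    tree = Phylo.read(io.StringIO(cfg.topology), "newick")
    counter = [0]

    def convert(clade) -> TreeNode:
        counter[0] += 1
        name = clade.name or f"node{counter[0]}"
        node = TreeNode(name, multiplicity=0 if clade.clades else 1)
        node._length = float(clade.branch_length or 0.0)
        for c in clade.clades:
            child = convert(c)
            node.add_child(child, [])
        return node

    root = convert(tree.root)
    return root


def simulate_genealogy(cfg: SimulationConfig, ref: ReferenceAnnotation,
                       rng: np.random.Generator | None = None) -> GroundTruth:
    """Drop class-specific Poisson mutations on a clock genealogy.

    Positions are drawn uniformly from the exact legal pool of each class
    (synonymous sites enumerated codon-by-codon from the gene map; control
    sites from the hypervariable windows minus exclusions) and are never
    reused along a root-to-tip path.  With ``plant_back_mutations`` each
    edge may, with probability 0.1 per candidate, revert one mutation
    present on its ancestral path.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    pools = _site_pools(ref)
    for label, pool in pools.items():
        if not pool:
            raise SimulationConfigError(f"empty legal site set for {label}")
    syn_rate = cfg.rates["synonymous_transition"]
    cod_rate = cfg.rates["coding_substitution"]
    intensities = {
        "synonymous_transition": 1.0 / syn_rate,
        "nonsynonymous": 1.0 / cod_rate - 1.0 / syn_rate,
        "control": 1.0 / cfg.rates["control"],
    }
    root = _topology(cfg, rng)
    counts = {k: 0 for k in intensities}

    def drop(node: TreeNode, used: dict[int, MutationCall]):
        length = getattr(node, "_length", 0.0)
        muts: list[MutationCall] = []
        if node.parent is not None and length > 0:
            for label, inten in intensities.items():
                k = rng.poisson(length * inten)
                pool = pools[label]
                for _ in range(k):
                    for _try in range(100):
                        pos = int(pool[rng.integers(len(pool))])
                        if pos not in used:
                            break
                    else:
                        raise SimulationConfigError(
                            f"cannot place a {label} mutation without reuse")
                    ref_base = ref.base(pos)
                    call = MutationCall(pos, ref_base, "transition",
                                        TRANSITION_PARTNER[ref_base])
                    used[pos] = call
                    muts.append(call)
                    counts[label] += 1
            if cfg.plant_back_mutations and used and rng.random() < 0.1:
                upstream = [c for c in used.values() if c not in muts
                            and not c.is_back_mutation]
                if upstream:
                    target = upstream[int(rng.integers(len(upstream)))]
                    back = MutationCall(target.position, target.ref_base,
                                        target.event, target.derived,
                                        is_back_mutation=True)
                    del used[target.position]
                    muts.append(back)
            node.edge = sorted(muts, key=lambda c: c.position)
        for child in node.children:
            drop(child, dict(used))

    drop(root, {})
    tree = MutationTree(root)
    depth = _max_depth_years(root)
    return GroundTruth(tree=tree, tmrca_years=depth, config=cfg,
                       class_counts=counts,
                       site_pools={k: len(v) for k, v in pools.items()})


def _max_depth_years(root: TreeNode) -> float:
    best = 0.0

    def walk(node, d):
        nonlocal best
        d += getattr(node, "_length", 0.0) if node.parent is not None else 0.0
        best = max(best, d)
        for c in node.children:
            walk(c, d)

    walk(root, 0.0)
    return best


def emit_sequences(gt: GroundTruth, ref: ReferenceAnnotation):
    """Each tip's genome: the reference with its path mutations applied.

    Returns (records, truth) where records is a list of (name, sequence)
    and truth a frame listing every planted call per tip.
    """
    records = []
    truth_rows = []
    for tip in gt.tree.tips():
        calls = gt.tree.path_mutations(tip)
        # back mutations cancel their target; apply in path order
        active: dict[int, MutationCall] = {}
        for c in calls:
            if c.is_back_mutation:
                active.pop(c.position, None)
            else:
                active[c.position] = c
        seq = apply_mutations(ref.sequence, sorted(active.values(),
                                                   key=lambda c: c.position))
        records.append((tip.name, seq))
        for c in active.values():
            truth_rows.append({"tip": tip.name, "position": c.position,
                               "ref": c.ref_base, "derived": c.derived,
                               "event": c.event})
    truth = pd.DataFrame(truth_rows,
                         columns=["tip", "position", "ref", "derived", "event"])
    return records, truth.sort_values(["tip", "position"]).reset_index(drop=True)


def emit_motif_table(cfg: SimulationConfig, tree: HaplogroupTree,
                     ref: ReferenceAnnotation,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """A published-style motif table with planted clade diagnostics.

    Each record carries its clade's full control-region diagnostic path plus
    Poisson(private_rate) private control-region mutations, with an origin
    drawn from the regional sampling map.  The ``haplogroup`` column holds
    the true (planted) label.
    """
    from .hvs_io import format_motif, parse_token

    rng = rng or np.random.default_rng(cfg.seed)
    plan = cfg.clade_plan or []
    regions = sorted(cfg.regional_sampling)
    probs = np.array([cfg.regional_sampling[r] for r in regions])
    # private mutations are drawn outside every diagnostic site of the tree,
    # so a record's planted clade stays recoverable by construction
    diagnostic_pos = set()
    for name in tree.clades:
        diagnostic_pos.update(tree.profile(name)["hvs1"])
    hvs1_pool = [p for p in ref.control_sites()
                 if ref.in_window(p, ref.hvs1_window)
                 and p not in diagnostic_pos]
    rows = []
    for clade, n in plan:
        if clade not in tree.clades:
            raise SimulationConfigError(f"unknown clade {clade!r} in clade_plan")
        prof = tree.profile(clade)
        base1 = [c for kind, c in prof["hvs1"].values() if kind == "state"]
        base2 = [c for kind, c in prof["hvs2"].values() if kind == "state"]
        for _ in range(int(n)):
            extras = []
            for _k in range(rng.poisson(cfg.private_rate)):
                for _try in range(100):
                    pos = int(hvs1_pool[rng.integers(len(hvs1_pool))])
                    if pos not in {c.position for c in extras}:
                        break
                else:
                    continue
                extras.append(parse_token(str(pos - 16000), "hvs1", ref))
            region = regions[int(rng.choice(len(regions), p=probs))]
            rows.append({
                "haplogroup": clade,
                "hvs1_motif": format_motif(sorted(base1 + extras,
                                                  key=lambda c: c.position), "hvs1"),
                "hvs2_motif": format_motif(base2, "hvs2"),
                "n": 1,
                "population": region,
                "region": region,
                "source": "simulated",
            })
    return pd.DataFrame(rows, columns=["haplogroup", "hvs1_motif", "hvs2_motif",
                                       "n", "population", "region", "source"])


def n1a_like_newick() -> str:
    """A fixed 19-tip clock genealogy mimicking the published clade sizes
    (10 mtDNAs in the central subcluster, 3 in its inner subclade, 4 and 2
    in the side branches, 1 + 2 basal); depths in years, TMRCA 18,000 y."""
    return (
        "(((((T01:2000,T02:2000,T03:2000)N1a1a1a:3000,"
        "T04:5000,T05:5000,T06:5000,T07:5000,T08:5000,T09:5000,T10:5000)N1a1a1:3000,"
        "(T11:4000,T12:4000,T13:4000,T14:4000)N1a1a2:4000,"
        "(T15:5000,T16:5000)N1a1a3:3000)N1a1a:4000,T17:12000)N1a1:6000,"
        "T18:18000,T19:18000)N1a;"
    )
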