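"""Regional frequency summaries and haplotype-heterogeneity statistics.

The heterogeneity of a subclade's haplotype distribution across sampling
origins is evaluated with a Pearson chi-square test on the (distinct
haplotype) x (origin group) contingency table.  Haplotype identity defaults
to the canonically formatted HVS-I motif (records differing only in HVS-II
merge); the origin grouping is an explicit, user-visible map because the
choice of columns fixes the degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import HaplogroupTree
from .hvs_io import Haplotype, format_motif

logger = logging.getLogger(__name__)


def load_grouping(path=None) -> dict[str, str]:
    """Two-column population->group merge map (default: the shipped map that
    pools all Kazakh samples into one column)."""
    if path is None:
        from importlib import resources

        with resources.as_file(
            resources.files("mtn1a.data") / "n1a1a1a_grouping.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def _group_of(h: Haplotype, grouping) -> str:
    if grouping == "population":
        return h.population
    if grouping == "region":
        return h.region
    if isinstance(grouping, dict):
        return grouping.get(h.population, h.population)
    raise ValueError(f"unknown grouping {grouping!r}")


def build_table(haplotypes: list[Haplotype], grouping="population",
                key: str = "hvs1") -> pd.DataFrame:
    """Contingency table: distinct haplotypes x origin groups, weighted by N.

    All records must belong to one clade (the caller selects them); rows are
    keyed by the canonical HVS-I motif by default, so records differing only
    in HVS-II merge.
    """
    if not haplotypes:
        raise ValueError("empty clade: no haplotypes to tabulate")
    clades = {h.assigned_clade for h in haplotypes if h.assigned_clade}
    if len(clades) > 1:
        raise ValueError(f"haplotypes span several clades: {sorted(clades)}")
    rows = []
    for h in haplotypes:
        if key == "hvs1":
            k = format_motif(h.hvs1, "hvs1")
        elif key == "hvs1+hvs2":
            k = format_motif(h.hvs1, "hvs1") + "/" + format_motif(h.hvs2, "hvs2")
        else:
            raise ValueError(f"unknown haplotype key {key!r}")
        rows.append({"haplotype": k, "group": _group_of(h, grouping), "n": h.count})
    df = pd.DataFrame(rows)
    table = df.pivot_table(index="haplotype", columns="group", values="n",
                           aggfunc="sum", fill_value=0)
    return table.sort_index().sort_index(axis=1)


@dataclass
class HeterogeneityResult:
    chi2: float
    df: int
    p: float
    n: int

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("chi-square test needs at least 1 degree of freedom")


def chi_square(table: pd.DataFrame) -> HeterogeneityResult:
    """Pearson chi-square (no continuity correction), upper-tail p."""
    values = np.asarray(table, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    chi2, p, dof, expected = sps.chi2_contingency(values, correction=False)
    if (expected < 5).any():
        logger.warning("%d of %d expected counts are < 5; the chi-square "
                       "approximation is rough", int((expected < 5).sum()),
                       expected.size)
    return HeterogeneityResult(chi2=float(chi2), df=int(dof), p=float(p),
                               n=int(values.sum()))


def permutation_pvalue(table: pd.DataFrame, n_draws: int = 10000,
                       rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo null for the chi-square statistic: permute group labels
    of individuals, keeping both margins' totals."""
    rng = rng or np.random.default_rng(0)
    values = np.asarray(table, dtype=int)
    obs = chi_square(table).chi2
    rows = np.repeat(np.arange(values.shape[0]), values.sum(axis=1))
    cols = np.repeat(np.arange(values.shape[1]), values.sum(axis=0))
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(cols)
        t = np.zeros_like(values)
        np.add.at(t, (rows, perm), 1)
        c2, _, _, _ = sps.chi2_contingency(t, correction=False)
        if c2 >= obs - 1e-12:
            hits += 1
    return hits / n_draws


def clade_frequency_report(haplotypes: list[Haplotype], tree: HaplogroupTree,
                           grouping="region",
                           include_descendants: bool = False) -> pd.DataFrame:
    """Per-(clade, group) counts and within-clade frequencies.

    With ``include_descendants`` a record contributes to every ancestral
    clade on its path (cumulative counts, e.g. a subcluster "including" its
    subclades).  Fractions sum to 1 within each clade.
    """
    assigned = [h for h in haplotypes if h.assigned_clade]
    if not assigned:
        raise ValueError("no assigned haplotypes; classify first")
    rows = []
    for h in assigned:
        targets = [h.assigned_clade]
        if include_descendants:
            targets = [c for c in tree.names()
                       if c != tree.root and tree.is_ancestor(c, h.assigned_clade)]
        for clade in targets:
            rows.append({"clade": clade, "group": _group_of(h, grouping),
                         "records": 1, "n": h.count})
    df = (pd.DataFrame(rows)
          .groupby(["clade", "group"], as_index=False)[["records", "n"]].sum())
    totals = df.groupby("clade")["n"].transform("sum")
    df["clade_total"] = totals
    df["fraction"] = df["n"] / totals
    return df.sort_values(["clade", "group"]).reset_index(drop=True)


def survey_totals(haplotypes: list[Haplotype],
                  unpublished_regions: frozenset[str] = frozenset({"North America"})
                  ) -> dict[str, int]:
    """Grand total and published-only total of a survey table.

    Public-participant records contributed by the surveying study itself
    (source starting with "Present", sampled in ``unpublished_regions``)
    are excluded from the published total.
    """
    total = sum(h.count for h in haplotypes)
    unpub = sum(h.count for h in haplotypes
                if h.source.startswith("Present") and h.region in unpublished_regions)
    return {"total": total, "published": total - unpub, "unpublished": unpub}
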